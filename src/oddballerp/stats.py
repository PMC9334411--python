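"""Mixed ANOVAs, sphericity correction, follow-up tests, and the analysis
battery run on pipeline outputs.

The workhorse is a univariate split-plot (mixed) ANOVA for one
between-subject factor and up to three fully-crossed within-subject
factors, with Greenhouse-Geisser epsilon per within-effect (applied when
sphericity is violated), Holm-Bonferroni-adjusted follow-up t-tests, and
generalized eta squared effect sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# --------------------------------------------------------------------------
# Result containers
# --------------------------------------------------------------------------


@dataclass
class AnovaResult:
    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    epsilon: float = 1.0
    gg_applied: bool = False
    eta_squared_generalized: float = float("nan")
    eta_squared_partial: float = float("nan")
    ss: float = float("nan")
    ss_error: float = float("nan")


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float
    p: float
    effect_size: float
    kind: str  # "paired_t" | "welch_t" | "pearson_r"
    adjusted_p: float | None = None
    n: int = 0


# --------------------------------------------------------------------------
# Mixed ANOVA
# --------------------------------------------------------------------------


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning the contrast space (row sums 0)."""
    m = np.eye(k) - np.ones((k, k)) / k
    vals, vecs = np.linalg.eigh(m)
    return vecs[:, vals > 0.5].T


def greenhouse_geisser_epsilon(cov: np.ndarray) -> float:
    """GG epsilon from the covariance of orthonormal within-contrasts.

    epsilon = tr(S)^2 / (d * tr(S^2)), clipped to [1/d, 1], where S is the
    contrast-space covariance (d contrasts).
    """
    s = np.atleast_2d(cov)
    d = s.shape[0]
    if d < 1:
        raise ValueError("need at least one contrast")
    tr = np.trace(s)
    denom = d * np.sum(s * s.T)
    if denom <= 0:
        return 1.0 / d if d > 1 else 1.0
    eps = tr**2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def mauchly_p(cov: np.ndarray, n_error_df: int) -> float:
    """Mauchly sphericity test on the contrast covariance; p-value."""
    s = np.atleast_2d(cov)
    d = s.shape[0]
    if d < 2:
        return 1.0
    det = np.linalg.det(s)
    mean_var = np.trace(s) / d
    if det <= 0 or mean_var <= 0:
        return 0.0  # singular -> treat sphericity as rejected
    w = det / mean_var**d
    if w <= 0:
        return 0.0
    factor = n_error_df - (2 * d**2 + d + 2) / (6.0 * d)
    chi2 = -factor * np.log(w)
    df = d * (d + 1) // 2 - 1
    return float(sps.chi2.sf(chi2, df))


def _pivot(
    tbl: pd.DataFrame,
    dv: str,
    subject: str,
    between: str | None,
    within: list[str],
) -> tuple[np.ndarray, np.ndarray, list[str], list[list[str]]]:
    subjects = list(dict.fromkeys(tbl[subject]))
    levels = [sorted(map(str, tbl[w].astype(str).unique())) for w in within]
    shape = [len(subjects)] + [len(l) for l in levels]
    y = np.full(shape, np.nan)
    idx = {s: i for i, s in enumerate(subjects)}
    lidx = [{l: j for j, l in enumerate(ls)} for ls in levels]
    for _, row in tbl.iterrows():
        key = (idx[row[subject]],) + tuple(
            lidx[i][str(row[w])] for i, w in enumerate(within)
        )
        if not np.isnan(y[key]):
            raise ValueError(f"duplicate cell for subject {row[subject]!r}")
        y[key] = row[dv]
    if np.isnan(y).any():
        missing = np.argwhere(np.isnan(y))[0]
        raise ValueError(
            f"incomplete design: subject {subjects[missing[0]]!r} missing a cell"
        )
    if between is None:
        groups = np.zeros(len(subjects), int)
        gnames = ["all"]
    else:
        by_subj = tbl.groupby(subject, sort=False)[between].agg(
            lambda v: v.iloc[0] if (v == v.iloc[0]).all() else None
        )
        if by_subj.isna().any():
            raise ValueError("between-factor level varies within a subject")
        gnames = sorted(map(str, by_subj.astype(str).unique()))
        gmap = {g: i for i, g in enumerate(gnames)}
        groups = np.array([gmap[str(by_subj[s])] for s in subjects])
        if np.bincount(groups).min() < 2:
            raise ValueError("need at least 2 subjects per between level")
    return y, groups, gnames, levels


def mixed_anova(
    tbl: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    between: str | None = None,
    within: list[str] | None = None,
    gg_threshold: float = 0.75,
    sphericity_alpha: float = 0.05,
) -> list[AnovaResult]:
    """Split-plot ANOVA: one between factor, fully-crossed within factors.

    Sums of squares follow the classical weighted-means partition with the
    subject-nested error strata of the split-plot design.  For each
    within-effect with more than one degree of freedom, the GG epsilon is
    computed from the pooled within-group covariance of orthonormal effect
    contrasts and applied when epsilon < ``gg_threshold`` or a Mauchly test
    rejects sphericity at ``sphericity_alpha``.
    """
    within = within or []
    y, groups, gnames, levels = _pivot(tbl, dv, subject, between, within)
    n_subj = y.shape[0]
    n_groups = len(gnames)
    ks = [len(l) for l in levels]
    w_cells = int(np.prod(ks)) if ks else 1
    n_g = np.bincount(groups, minlength=n_groups)

    results: list[AnovaResult] = []

    # --- between-subject stratum
    m_s = y.reshape(n_subj, -1).mean(axis=1)
    grand = m_s.mean()
    gmeans = np.array([m_s[groups == g].mean() for g in range(n_groups)])
    ss_subj = w_cells * float(
        sum((m_s[s] - gmeans[groups[s]]) ** 2 for s in range(n_subj))
    )
    df_subj = n_subj - n_groups
    strata_errors = [ss_subj]

    between_entry = None
    if between is not None:
        ss_b = w_cells * float(np.sum(n_g * (gmeans - grand) ** 2))
        between_entry = (between, ss_b, n_groups - 1)

    # --- within strata
    within_entries = []  # (name, ss_eff, df_eff, ss_bx, df_bx, ss_err, df_err, eps, gg)
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(range(len(within)), r):
            other = [i for i in range(len(within)) if i not in combo]
            e = y.mean(axis=tuple(a + 1 for a in other), keepdims=False) if other else y.copy()
            # e now has axes (subject, factors in `combo` order)
            for ax in range(1, e.ndim):
                e = e - e.mean(axis=ax, keepdims=True)
            mult = int(np.prod([ks[i] for i in other])) if other else 1
            ebar = e.mean(axis=0)  # grand within-effect means
            egrp = np.stack([e[groups == g].mean(axis=0) for g in range(n_groups)])
            ss_eff = mult * n_subj * float(np.sum(ebar**2))
            ss_bx = mult * float(
                sum(n_g[g] * np.sum((egrp[g] - ebar) ** 2) for g in range(n_groups))
            )
            resid = e - egrp[groups]
            ss_err = mult * float(np.sum(resid**2))
            df_eff = int(np.prod([ks[i] - 1 for i in combo]))
            df_err = (n_subj - n_groups) * df_eff
            strata_errors.append(ss_err)

            # GG epsilon from orthonormal contrast scores
            contrasts = [
                _orthonormal_contrasts(ks[i]) if i in combo else np.full((1, ks[i]), 1.0 / ks[i])
                for i in range(len(within))
            ]
            t = np.array([[1.0]])
            for cmat in contrasts:
                t = np.kron(t, cmat)
            z = y.reshape(n_subj, -1) @ t.T  # subject scores, d columns
            zc = z - np.stack([z[groups == g].mean(axis=0) for g in range(n_groups)])[groups]
            cov = zc.T @ zc / max(1, n_subj - n_groups)
            eps = greenhouse_geisser_epsilon(cov)
            gg = df_eff > 1 and (
                eps < gg_threshold or mauchly_p(cov, n_subj - n_groups) < sphericity_alpha
            )
            name = " x ".join(within[i] for i in combo)
            within_entries.append(
                (name, ss_eff, df_eff, ss_bx, df_err, ss_err, eps, gg)
            )

    total_error = float(sum(strata_errors))

    def _emit(effect, ss, dfn, ss_err, dfd, eps=1.0, gg=False):
        ms_err = ss_err / dfd if dfd > 0 else np.nan
        f = (ss / dfn) / ms_err if ms_err > 0 else np.nan
        if gg:
            p = float(sps.f.sf(f, eps * dfn, eps * dfd))
        else:
            p = float(sps.f.sf(f, dfn, dfd))
        results.append(
            AnovaResult(
                effect, float(f), float(dfn), float(dfd), p,
                float(eps if gg else 1.0), bool(gg),
                eta_squared_generalized=float(ss / (ss + total_error)),
                eta_squared_partial=float(ss / (ss + ss_err)),
                ss=float(ss), ss_error=float(ss_err),
            )
        )

    if between_entry is not None:
        _emit(between_entry[0], between_entry[1], between_entry[2], ss_subj, df_subj)
    for name, ss_eff, df_eff, ss_bx, df_err, ss_err, eps, gg in within_entries:
        _emit(name, ss_eff, df_eff, ss_err, df_err, eps, gg)
        if between is not None:
            _emit(f"{between} x {name}", ss_bx, (n_groups - 1) * df_eff, ss_err, df_err, eps, gg)
    return results


def anova_table(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results]).set_index("effect")


# --------------------------------------------------------------------------
# Follow-up tests and corrections
# --------------------------------------------------------------------------


def holm_adjust(pvals: list[float]) -> list[float]:
    """Holm-Bonferroni step-down adjusted p-values (order preserved)."""
    if len(pvals) == 0:
        return []
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return list(multipletests(p, method="holm")[1])


def paired_t(x, y, name: str = "paired_t") -> TestResult:
    """Two-sided paired t with Cohen's d = mean(diff)/sd(diff)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired samples must be aligned with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return TestResult(name, 0.0, len(d) - 1, 1.0, 0.0, "paired_t", n=len(d))
        raise ValueError("degenerate paired data")
    t, p = sps.ttest_rel(x, y)
    return TestResult(
        name, float(t), float(len(d) - 1), float(p), float(d.mean() / sd),
        "paired_t", n=len(d),
    )


def welch_t(x, y, name: str = "welch_t") -> TestResult:
    """Two-sided Welch t with Satterthwaite df and pooled-SD Cohen's d."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need n >= 2 per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both samples")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    nx, ny = len(x), len(y)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    sp = np.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    d = (x.mean() - y.mean()) / sp if sp > 0 else np.nan
    return TestResult(name, float(t), float(df), float(p), float(d), "welch_t", n=nx + ny)


def pearson_correlation(x, y, name: str = "pearson_r") -> TestResult:
    """Pearson r with the t-based two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return TestResult(name, float(r), float(len(x) - 2), float(p), float(r), "pearson_r", n=len(x))


def adjust_family(tests: list[TestResult]) -> list[TestResult]:
    """Holm-adjust a family of follow-up tests in place; returns it."""
    adj = holm_adjust([t.p for t in tests])
    for t, a in zip(tests, adj):
        t.adjusted_p = float(a)
    return tests


# --------------------------------------------------------------------------
# The study battery (research questions 1-4)
# --------------------------------------------------------------------------


def run_study(tables: dict[str, pd.DataFrame]) -> dict:
    """Run the full analysis battery on pipeline output tables.

    Expected tables (see the study workflow for their construction):

    - ``behavior``: subject, group, ci_side, ear, deviant, hit_rate,
      mean_rt, effort
    - ``peaks``: subject, group, ci_side, ear, condition, component,
      amplitude, latency
    - ``source``: subject, group, ci_side, ear, hemisphere, peak_value,
      peak_latency
    - optional ``control_*`` twins with condition (original/vocoded) and
      side (left/right) instead of group/ear for the normal-hearing
      control battery.

    Returns a JSON-serializable nested report; every follow-up family is
    Holm-adjusted and its size logged.
    """
    beh = tables["behavior"]
    peaks = tables["peaks"]
    src = tables["source"]
    report: dict[str, dict] = {"q1": {}, "q2": {}, "q3": {}, "q4": {}, "families": {}}

    def _fam(name: str, tests: list[TestResult]) -> list[dict]:
        adjust_family(tests)
        report["families"][name] = len(tests)
        return [asdict(t) for t in tests]

    # ---- Q1: proficiency and the two-deviant paradigm
    rt = beh.dropna(subset=["mean_rt"])
    complete = rt.groupby("subject")["mean_rt"].count() == 4
    rt = rt[rt["subject"].isin(complete[complete].index)]
    report["q1"]["rt_anova"] = [
        asdict(r) for r in mixed_anova(rt, "mean_rt", "subject", None, ["ear", "deviant"])
    ]
    report["q1"]["hit_anova"] = [
        asdict(r)
        for r in mixed_anova(beh, "hit_rate", "subject", "group", ["ear", "deviant"])
    ]
    erp_anovas = {}
    for ear in ("CI", "NH"):
        for comp, measure in (
            ("N1", "amplitude"), ("N1", "latency"), ("P2", "amplitude"),
            ("P3b", "amplitude"), ("P3b", "latency"),
        ):
            sel = peaks[
                (peaks["ear"] == ear)
                & (peaks["component"] == comp)
                & (peaks["condition"].isin(["deviant1", "deviant2"]))
            ]
            # subjects without a measurable average in every cell (e.g. zero
            # hits for the difficult deviant) drop out of this analysis
            cell_counts = sel.groupby("subject")["condition"].nunique()
            sel = sel[sel["subject"].isin(cell_counts[cell_counts == 2].index)]
            erp_anovas[f"{ear}_{comp}_{measure}"] = [
                asdict(r)
                for r in mixed_anova(sel, measure, "subject", "group", ["condition"])
            ]
    report["q1"]["erp_anovas"] = erp_anovas

    cors = []
    p3 = peaks[
        (peaks["ear"] == "CI")
        & (peaks["component"] == "P3b")
        & (peaks["condition"] == "deviant2")
    ].set_index("subject")
    hr = beh[(beh["ear"] == "CI") & (beh["deviant"] == "deviant2")].set_index("subject")
    for grp in sorted(beh["group"].unique()):
        subs = [s for s in p3.index if p3.loc[s, "group"] == grp and s in hr.index]
        if len(subs) >= 3:
            cors.append(
                pearson_correlation(
                    p3.loc[subs, "amplitude"], hr.loc[subs, "hit_rate"],
                    name=f"p3b_vs_hit_{grp}",
                )
            )
    report["q1"]["p3b_hit_correlations"] = [asdict(t) for t in cors]

    # ---- Q2: CI ear vs NH ear (deviant 1 only)
    b1 = beh[beh["deviant"] == "deviant1"].pivot_table(
        index="subject", columns="ear", values=["hit_rate", "mean_rt", "effort"]
    )
    fam2 = [
        paired_t(b1["hit_rate"]["CI"], b1["hit_rate"]["NH"], "hit_rate_ci_vs_nh"),
        paired_t(b1["mean_rt"]["CI"], b1["mean_rt"]["NH"], "rt_ci_vs_nh"),
    ]
    if not b1["effort"].isna().any().any():
        fam2.append(paired_t(b1["effort"]["CI"], b1["effort"]["NH"], "effort_ci_vs_nh"))
    report["q2"]["behavior"] = _fam("q2_behavior", fam2)

    fam2e = []
    for comp, measure in (
        ("N1", "amplitude"), ("N1", "latency"), ("P2", "amplitude"),
        ("P3b", "amplitude"), ("P3b", "latency"),
    ):
        conds = ["standard", "deviant1"] if comp in ("N1", "P2") else ["deviant1"]
        sel = peaks[(peaks["component"] == comp) & (peaks["condition"].isin(conds))]
        piv = sel.pivot_table(index="subject", columns="ear", values=measure)
        fam2e.append(paired_t(piv["CI"], piv["NH"], f"{comp}_{measure}_ci_vs_nh"))
    report["q2"]["erp"] = _fam("q2_erp", fam2e)

    s2 = src.pivot_table(index="subject", columns="ear", values=["peak_latency", "peak_value"])
    report["q2"]["source"] = _fam(
        "q2_source",
        [
            paired_t(s2["peak_latency"]["CI"], s2["peak_latency"]["NH"], "source_latency_ci_vs_nh"),
            paired_t(s2["peak_value"]["CI"], s2["peak_value"]["NH"], "source_amplitude_ci_vs_nh"),
        ],
    )

    if "control_behavior" in tables:
        report["q2"]["control"] = _control_vocoded_battery(tables)

    # ---- Q3: side of implantation, CI ear, source asymmetry
    s_ci = src[src["ear"] == "CI"]
    report["q3"]["anova"] = [
        asdict(r)
        for r in mixed_anova(s_ci, "peak_value", "subject", "ci_side", ["hemisphere"])
    ]
    fam3 = []
    for side in sorted(s_ci["ci_side"].unique()):
        piv = s_ci[s_ci["ci_side"] == side].pivot_table(
            index="subject", columns="hemisphere", values="peak_value"
        )
        fam3.append(paired_t(piv["right"], piv["left"], f"hemi_diff_{side}_implanted"))
    report["q3"]["followups"] = _fam("q3_hemi", fam3)

    if "control_source" in tables:
        cs = tables["control_source"]
        voc = cs[cs["condition"] == "vocoded"]
        report["q3"]["control_anova"] = [
            asdict(r)
            for r in mixed_anova(voc, "peak_value", "subject", None, ["side", "hemisphere"])
        ]
        fam3c = []
        for side in sorted(voc["side"].unique()):
            piv = voc[voc["side"] == side].pivot_table(
                index="subject", columns="hemisphere", values="peak_value"
            )
            fam3c.append(paired_t(piv["right"], piv["left"], f"control_hemi_diff_{side}_ear"))
        report["q3"]["control_followups"] = _fam("q3_control_hemi", fam3c)

    # ---- Q4: side of stimulation, NH ear
    s_nh = src[src["ear"] == "NH"]
    report["q4"]["anova"] = [
        asdict(r)
        for r in mixed_anova(s_nh, "peak_value", "subject", "ci_side", ["hemisphere"])
    ]
    fam4 = []
    for side in sorted(s_nh["ci_side"].unique()):
        piv = s_nh[s_nh["ci_side"] == side].pivot_table(
            index="subject", columns="hemisphere", values="peak_value"
        )
        fam4.append(paired_t(piv["left"], piv["right"], f"nh_hemi_diff_{side}_implanted"))
    report["q4"]["followups"] = _fam("q4_hemi", fam4)

    p3lat = peaks[
        (peaks["ear"] == "NH")
        & (peaks["component"] == "P3b")
        & (peaks["condition"] == "deviant1")
    ]
    sides = sorted(p3lat["ci_side"].unique())
    if len(sides) == 2:
        a = p3lat[p3lat["ci_side"] == sides[0]]["latency"]
        b = p3lat[p3lat["ci_side"] == sides[1]]["latency"]
        report["q4"]["p3b_latency_between_groups"] = asdict(
            welch_t(a, b, f"p3b_latency_{sides[0]}_vs_{sides[1]}")
        )
    return report


def _control_vocoded_battery(tables: dict[str, pd.DataFrame]) -> dict:
    """Vocoded-vs-original contrasts within the NH control group."""
    out: dict[str, list] = {}
    cb = tables["control_behavior"]
    b = cb[cb["deviant"] == "deviant1"].pivot_table(
        index="subject", columns="condition", values=["hit_rate", "mean_rt", "effort"]
    )
    fam = [
        paired_t(b["hit_rate"]["vocoded"], b["hit_rate"]["original"], "ctrl_hit_voc_vs_orig"),
        paired_t(b["mean_rt"]["vocoded"], b["mean_rt"]["original"], "ctrl_rt_voc_vs_orig"),
    ]
    if not b["effort"].isna().any().any():
        fam.append(
            paired_t(b["effort"]["vocoded"], b["effort"]["original"], "ctrl_effort_voc_vs_orig")
        )
    out["behavior"] = [asdict(t) for t in adjust_family(fam)]
    if "control_peaks" in tables:
        cp = tables["control_peaks"]
        fam_e = []
        for comp in ("N1", "P2", "P3b"):
            piv = cp[cp["component"] == comp].pivot_table(
                index="subject", columns="condition", values="amplitude"
            )
            fam_e.append(
                paired_t(piv["vocoded"], piv["original"], f"ctrl_{comp}_amp_voc_vs_orig")
            )
        out["erp"] = [asdict(t) for t in adjust_family(fam_e)]
    if "control_source" in tables:
        cs = tables["control_source"]
        piv = cs.pivot_table(index="subject", columns="condition", values="peak_value")
        lat = cs.pivot_table(index="subject", columns="condition", values="peak_latency")
        out["source"] = [
            asdict(t)
            for t in adjust_family(
                [
                    paired_t(piv["vocoded"], piv["original"], "ctrl_source_amp_voc_vs_orig"),
                    paired_t(lat["vocoded"], lat["original"], "ctrl_source_lat_voc_vs_orig"),
                ]
            )
        ]
    return out
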