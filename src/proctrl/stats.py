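"""Inferential layer: binned paired t-tests with BH-FDR, repeated-measures
ANOVA with Greenhouse-Geisser correction, Wilcoxon signed-rank tests and
power-RT correlation.

All tests are two-sided. Degenerate inputs (zero-variance differences, all
zero Wilcoxon differences) produce flagged results rather than infinite
statistics. FDR families follow the source analyses: the 100-ms bins of one
contrast within one hemisphere form a family for the cue-target interval;
the seed-to-electrode connections of one contrast form a family for the
phase-coupling comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "paired_t",
    "fdr_bh",
    "binned_contrast",
    "gg_epsilon",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "wilcoxon_signed_rank",
    "plv_contrast",
    "power_rt_correlation",
]


@dataclass
class TTestResult:
    t: float
    p: float
    df: int
    mean_diff: float
    degenerate: bool = False


def paired_t(x, y) -> TTestResult:
    """Classical paired t on the differences, two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t expects two equal-length 1-d arrays")
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = x - y
    md = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if md == 0:  # identical samples: no effect, maximal p
            return TTestResult(t=0.0, p=1.0, df=n - 1, mean_diff=0.0)
        return TTestResult(t=np.nan, p=np.nan, df=n - 1, mean_diff=md, degenerate=True)
    t = md / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TTestResult(t=t, p=p, df=n - 1, mean_diff=md)


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values).

    Rejects all p(i) with i <= max{i : p(i) <= q*i/m}. NaN p-values are
    never rejected and stay NaN in the adjusted vector.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    valid = ~np.isnan(p)
    m = int(valid.sum())
    reject = np.zeros(p.shape, bool)
    adj = np.full(p.shape, np.nan)
    if m == 0:
        return reject, adj
    pv = p[valid]
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.flatnonzero(ranked <= thresh)
    k = below[-1] + 1 if len(below) else 0
    rej_sorted = np.zeros(m, bool)
    rej_sorted[:k] = True
    adj_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    rej_v = np.zeros(m, bool)
    adj_v = np.zeros(m)
    rej_v[order] = rej_sorted
    adj_v[order] = adj_sorted
    reject[valid] = rej_v
    adj[valid] = adj_v
    return reject, adj


def make_bins(start_s: float = 0.2, stop_s: float = 1.1, width_s: float = 0.1):
    """Contiguous non-overlapping bin edges, e.g. nine 100-ms bins 200-1100 ms."""
    edges = np.round(np.arange(start_s, stop_s + width_s / 2, width_s), 10)
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def bin_means(timecourse: np.ndarray, times: np.ndarray, bins) -> np.ndarray:
    """Per-bin time means of (n_subjects, n_time) -> (n_subjects, n_bins)."""
    out = np.empty(timecourse.shape[:-1] + (len(bins),))
    for i, (t0, t1) in enumerate(bins):
        sel = (times >= t0) & (times < t1)
        if not sel.any():
            raise ValueError(f"bin [{t0}, {t1}) outside the epoch")
        out[..., i] = timecourse[..., sel].mean(axis=-1)
    return out


def binned_contrast(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    times: np.ndarray,
    bins=None,
    q: float = 0.05,
    label: str = "",
) -> pd.DataFrame:
    """Paired t per 100-ms bin between two conditions, FDR across the bins.

    ``cond_a``/``cond_b`` are (n_subjects, n_time) ROI-band time courses.
    Returns one row per bin: mean difference (a-b), t, p, FDR significance.
    """
    if bins is None:
        bins = make_bins()
    a = bin_means(np.asarray(cond_a, float), times, bins)
    b = bin_means(np.asarray(cond_b, float), times, bins)
    rows = []
    for i, (t0, t1) in enumerate(bins):
        r = paired_t(a[:, i], b[:, i])
        rows.append({"contrast": label, "bin_start_s": t0, "bin_end_s": t1,
                     "mean_diff": r.mean_diff, "t": r.t, "df": r.df, "p": r.p})
    tbl = pd.DataFrame(rows)
    reject, adj = fdr_bh(tbl["p"].to_numpy(), q=q)
    tbl["p_fdr"] = adj
    tbl["significant"] = reject
    return tbl


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a subjects x conditions matrix.

    Box's formula on the double-centered sample covariance; clipped to
    [1/(k-1), 1]. Two conditions are always spherical (epsilon = 1).
    """
    data = np.asarray(data, float)
    n, k = data.shape
    if k < 2:
        raise ValueError("need k >= 2 conditions")
    if k == 2:
        return 1.0
    S = np.cov(data, rowvar=False)
    J = np.eye(k) - np.ones((k, k)) / k
    D = J @ S @ J
    num = np.trace(D) ** 2
    den = (k - 1) * np.sum(D * D)
    lower = 1.0 / (k - 1)
    if den <= 0:
        return lower
    return float(np.clip(num / den, lower, 1.0))


@dataclass
class AnovaEffect:
    name: str
    F: float
    df1: int
    df2: int
    epsilon: float
    p: float  # GG-corrected for effects with df1 > 1
    p_uncorrected: float


def _f_p(F: float, df1: float, df2: float) -> float:
    return float(sps.f.sf(F, df1, df2))


def rm_anova_oneway(data: np.ndarray) -> AnovaEffect:
    """One-way repeated-measures ANOVA (subjects x k conditions).

    Reports uncorrected degrees of freedom with the Greenhouse-Geisser
    corrected probability, as is conventional.
    """
    d = np.asarray(data, float)
    n, k = d.shape
    grand = d.mean()
    ss_cond = n * np.sum((d.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((d.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((d - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else 0.0
    eps = gg_epsilon(d)
    return AnovaEffect(
        "Condition", F, df1, df2, eps,
        p=_f_p(F, eps * df1, eps * df2), p_uncorrected=_f_p(F, df1, df2),
    )


def rm_anova_twoway(data: np.ndarray, factor_names=("Condition", "Hemisphere")):
    """Two-way fully within-subject ANOVA on subjects x a x b cell means.

    Returns effects for both main factors and their interaction; effects
    with more than one numerator df carry GG-corrected probabilities.
    """
    d = np.asarray(data, float)
    if d.ndim != 3:
        raise ValueError("expect subjects x levelsA x levelsB")
    if np.any(~np.isfinite(d)):
        raise ValueError("missing cells")
    n, a, b = d.shape
    grand = d.mean()
    mean_s = d.mean(axis=(1, 2))
    mean_a = d.mean(axis=(0, 2))
    mean_b = d.mean(axis=(0, 1))
    mean_sa = d.mean(axis=2)
    mean_sb = d.mean(axis=1)
    mean_ab = d.mean(axis=0)

    ss_a = n * b * np.sum((mean_a - grand) ** 2)
    ss_b = n * a * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_sa = b * np.sum((mean_sa - mean_s[:, None] - mean_a[None, :] + grand) ** 2)
    ss_sb = a * np.sum((mean_sb - mean_s[:, None] - mean_b[None, :] + grand) ** 2)
    resid = (
        d - mean_sa[:, :, None] - mean_sb[:, None, :] - mean_ab[None, :, :]
        + mean_s[:, None, None] + mean_a[None, :, None] + mean_b[None, None, :]
        - grand
    )
    ss_sab = np.sum(resid**2)

    effects = []
    specs = [
        (factor_names[0], ss_a, a - 1, ss_sa, (a - 1) * (n - 1), mean_sa),
        (factor_names[1], ss_b, b - 1, ss_sb, (b - 1) * (n - 1), mean_sb),
    ]
    for name, ss, df1, ss_e, df2, cellmat in specs:
        F = (ss / df1) / (ss_e / df2) if ss_e > 0 else 0.0
        eps = gg_epsilon(cellmat) if df1 > 1 else 1.0
        effects.append(AnovaEffect(name, F, df1, df2, eps,
                                   p=_f_p(F, eps * df1, eps * df2),
                                   p_uncorrected=_f_p(F, df1, df2)))
    df1 = (a - 1) * (b - 1)
    df2 = (a - 1) * (b - 1) * (n - 1)
    F = (ss_ab / df1) / (ss_sab / df2) if ss_sab > 0 else 0.0
    if df1 > 1:
        # epsilon on the interaction contrast variables (differences across b)
        inter = d[:, :, 0] - d[:, :, 1] if b == 2 else d.reshape(n, a * b)
        eps = gg_epsilon(inter)
    else:
        eps = 1.0
    effects.append(AnovaEffect(f"{factor_names[0]} x {factor_names[1]}", F, df1, df2,
                               eps, p=_f_p(F, eps * df1, eps * df2),
                               p_uncorrected=_f_p(F, df1, df2)))
    return effects


@dataclass
class WilcoxonResult:
    w: float
    z: float | None
    p: float
    n_used: int
    exact: bool


def wilcoxon_signed_rank(x, y, exact_limit: int = 15) -> WilcoxonResult:
    """Wilcoxon signed-rank test for paired samples, two-sided.

    Zero differences are dropped. Exact enumeration of all 2^n sign
    assignments for n <= ``exact_limit``; otherwise the normal approximation
    with continuity and tie corrections (z reported only on that path).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        # distribution of W+ over all sign assignments of these ranks
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        more_extreme = np.minimum(
            np.mean(totals <= w_plus + 1e-9), np.mean(totals >= w_plus - 1e-9)
        )
        p = min(1.0, 2.0 * more_extreme)
        return WilcoxonResult(w=w_plus, z=None, p=p, n_used=n, exact=True)
    mean = n * (n + 1) / 4.0
    ties = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(ties**3 - ties) / 48.0
    delta = w_plus - mean
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(w=w_plus, z=float(z), p=min(1.0, p), n_used=n, exact=False)


def plv_contrast(
    plv_a: np.ndarray,
    plv_b: np.ndarray,
    electrodes: list[str],
    q: float = 0.05,
    label: str = "",
    skip: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Wilcoxon per seed-to-electrode connection, FDR across connections.

    ``plv_a``/``plv_b`` are (n_subjects, n_electrodes) window-averaged PLVs
    per condition. ``skip`` names electrodes excluded from the family (the
    seed itself, whose PLV is identically 1).
    """
    a, b = np.asarray(plv_a, float), np.asarray(plv_b, float)
    if a.shape != b.shape:
        raise ValueError("PLV matrices must match")
    rows = []
    for j, e in enumerate(electrodes):
        if e in skip:
            continue
        try:
            r = wilcoxon_signed_rank(a[:, j], b[:, j])
            rows.append({"contrast": label, "electrode": e, "median_diff":
                         float(np.median(a[:, j] - b[:, j])), "w": r.w,
                         "z": r.z, "p": r.p, "n": r.n_used})
        except ValueError:
            rows.append({"contrast": label, "electrode": e, "median_diff": 0.0,
                         "w": np.nan, "z": None, "p": np.nan, "n": 0})
    tbl = pd.DataFrame(rows)
    reject, adj = fdr_bh(tbl["p"].to_numpy(), q=q)
    tbl["p_fdr"] = adj
    tbl["significant"] = reject
    return tbl


def power_rt_correlation(beta_power, rt) -> tuple[float, float]:
    """Pearson correlation of per-subject beta power with reaction time."""
    x, y = np.asarray(beta_power, float), np.asarray(rt, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired subjects")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
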