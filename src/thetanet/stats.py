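"""Inferential statistics for connectivity asymmetries and group contrasts.

Covers the paired and pooled-variance independent t-tests, the exact
effect-size conversions (paired d = t/sqrt(n); independent
d = t*sqrt(1/n1 + 1/n2)), default JZS Bayes factors (Cauchy effect-size
prior, scale sqrt(2)/2) with Lee-Wagenmakers evidence bands,
Benjamini-Hochberg FDR, point-wise spectral map tests, the 2x2 mixed
ANOVA (within: flicker frequency, between: group), and the table
builders that mirror the connectivity-statistics row layout
(phase, connection, mean +/- SEM per direction, t, d, p, p_FDR, BF10,
evidence label).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import integrate, stats as sstats
from statsmodels.stats.multitest import multipletests

from .containers import ConnectivityResult

__all__ = [
    "paired_t",
    "independent_t",
    "cohen_d_paired",
    "cohen_d_independent",
    "jzs_bf",
    "evidence_label",
    "bh_fdr",
    "pointwise_map_test",
    "mixed_anova",
    "asymmetry_table",
    "group_table",
]

DEFAULT_PRIOR_SCALE = np.sqrt(2.0) / 2.0


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Classical two-sided paired t-test on the differences.

    Returns (t, df, p) with df = n - 1. Zero-variance, zero-mean
    differences give t = 0, p = 1 (identical inputs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 paired observations")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, n - 1, 1.0
        raise ZeroDivisionError("constant nonzero differences; t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sstats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def independent_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test; df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        raise ZeroDivisionError("zero pooled variance with unequal means")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return float(t), df, float(p)


def cohen_d_paired(t: float, n: int) -> float:
    """Paired-design Cohen's d from the t statistic: d = t / sqrt(n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return float(t) / np.sqrt(n)


def cohen_d_independent(t: float, n1: int, n2: int) -> float:
    """Independent-design Cohen's d: d = t * sqrt(1/n1 + 1/n2), signed."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    return float(t) * np.sqrt(1.0 / n1 + 1.0 / n2)


def jzs_bf(
    t: float,
    n: int,
    n2: int | None = None,
    design: str = "paired",
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> float:
    """Default two-sided JZS Bayes factor BF10 for a t statistic.

    The effect size carries a zero-centred Cauchy prior with scale
    ``prior_scale`` (default sqrt(2)/2); the Bayes factor is the
    marginal-likelihood ratio obtained by numerical quadrature over the
    prior (Cauchy written as an inverse-gamma mixture of normals).
    ``design='paired'`` (or one-sample) uses effective sample size n and
    df = n - 1; ``design='independent'`` uses n*n2/(n + n2) and
    df = n + n2 - 2.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if design == "paired":
        if n2 is not None:
            raise ValueError("paired design takes a single n")
        n_eff, df = float(n), n - 1
    elif design == "independent":
        if n2 is None:
            raise ValueError("independent design needs both group sizes")
        n_eff, df = n * n2 / (n + n2), n + n2 - 2
    else:
        raise ValueError(f"unknown design {design!r}")
    r2 = prior_scale**2
    t2 = t * t

    def integrand(g: float) -> float:
        c = 1.0 + n_eff * g * r2
        return (
            c**-0.5
            * (1.0 + t2 / (c * df)) ** (-(df + 1) / 2.0)
            * (2.0 * np.pi) ** -0.5
            * g**-1.5
            * np.exp(-1.0 / (2.0 * g))
        )

    num, num_err = integrate.quad(integrand, 0.0, np.inf, epsabs=0.0, epsrel=1e-10,
                                  limit=200)
    if not np.isfinite(num) or num <= 0 or num_err / num > 1e-5:
        raise RuntimeError(
            f"Bayes factor quadrature failed (value {num}, abs err {num_err})"
        )
    den = (1.0 + t2 / df) ** (-(df + 1) / 2.0)
    return float(num / den)


# Lee-Wagenmakers bands; upper edges belong to the weaker-evidence band.
_H1_BANDS = [(3.0, "Anecdotal H1"), (10.0, "Moderate H1"), (30.0, "Strong H1"),
             (100.0, "Very strong H1"), (np.inf, "Extreme H1")]
_H0_BANDS = [(1.0 / 3.0, "Anecdotal H0"), (0.1, "Moderate H0"), (0.03, "Strong H0"),
             (0.01, "Very strong H0"), (0.0, "Extreme H0")]


def evidence_label(bf10: float) -> str:
    """Lee-Wagenmakers evidence band for a Bayes factor.

    Evidence for H1 requires BF10 > 1; BF10 = 1 (and boundary values in
    general) fall in the weaker-evidence band, so BF10 = 1 is
    "Anecdotal H0" and BF10 = 3 is "Anecdotal H1".
    """
    if not (np.isfinite(bf10) and bf10 > 0):
        raise ValueError("BF10 must be positive and finite")
    if bf10 > 1.0:
        for upper, label in _H1_BANDS:
            if bf10 <= upper:
                return label
    for lower, label in _H0_BANDS:
        if bf10 >= lower:
            return label
    return "Extreme H0"  # pragma: no cover


def bh_fdr(pvals: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns (adjusted p-values, rejection mask at level alpha). Adjusted
    p_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def pointwise_map_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    valid: np.ndarray | None = None,
    alpha: float = 0.05,
) -> dict[str, np.ndarray]:
    """Paired t-test at every (channel, time) point across subjects.

    ``maps_a``/``maps_b`` are (n_subjects, n_channels, n_times) power
    maps on a common grid (one condition each). BH-FDR is applied over
    all tested points jointly; ``valid`` (channels x times bool)
    restricts testing to wavelet-valid samples.
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape != maps_b.shape or maps_a.ndim != 3:
        raise ValueError("maps must be (n_subjects, n_channels, n_times) and matched")
    n_subj = maps_a.shape[0]
    if n_subj < 2:
        raise ValueError("point-wise test needs at least 2 subjects")
    if valid is None:
        valid = np.ones(maps_a.shape[1:], dtype=bool)
    diff = maps_a - maps_b
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map = mean / (sd / np.sqrt(n_subj))
    t_map = np.where(sd == 0, np.where(mean == 0, 0.0, np.inf), t_map)
    p_map = 2.0 * sstats.t.sf(np.abs(t_map), n_subj - 1)
    p_fdr = np.full_like(p_map, np.nan)
    sig = np.zeros_like(p_map, dtype=bool)
    flat = p_map[valid]
    adj, rej = bh_fdr(flat, alpha)
    p_fdr[valid] = adj
    sig[valid] = rej
    return {"t": t_map, "p": p_map, "p_fdr": p_fdr, "sig": sig}


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "power",
    within: str = "flicker_freq",
    between: str = "group",
    subject: str = "subject",
) -> pd.DataFrame:
    """2 (within) x 2 (between) mixed-design ANOVA.

    Returns one row per effect (between main effect, within main effect,
    interaction) with F, df1, df2, p and partial eta squared
    (SS_effect / (SS_effect + SS_error)). The layout must be complete:
    every subject measured at both within-factor levels.
    """
    counts = data.groupby([subject])[within].nunique()
    if counts.nunique() != 1 or counts.iloc[0] != data[within].nunique():
        raise ValueError("every subject must be measured at every within-factor level")
    if data[dv].nunique() == 1:
        # perfectly flat data: every sum of squares is zero
        n_between = data.groupby(between)[subject].nunique()
        df2 = int(n_between.sum() - len(n_between))
        return pd.DataFrame(
            {
                "effect": [between, within, "Interaction"],
                "F": 0.0,
                "df1": 1,
                "df2": df2,
                "p": 1.0,
                "partial_eta_sq": 0.0,
            }
        )
    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject
    )
    out = aov.rename(
        columns={"Source": "effect", "DF1": "df1", "DF2": "df2",
                 "p_unc": "p", "p-unc": "p", "np2": "partial_eta_sq"}
    )
    return out[["effect", "F", "df1", "df2", "p", "partial_eta_sq"]]


def _direction_values(
    subjects: Sequence[ConnectivityResult], a: str, b: str, measure: str
) -> tuple[np.ndarray, np.ndarray]:
    fwd, bwd = [], []
    for s_idx, res in enumerate(subjects):
        if a not in res.roi_names or b not in res.roi_names:
            missing = a if a not in res.roi_names else b
            raise KeyError(f"subject {s_idx} is missing ROI {missing!r} for pair ({a}, {b})")
        ia, ib = res.roi_names.index(a), res.roi_names.index(b)
        mat = res.lC if measure == "linear" else res.NC
        fwd.append(mat[ia, ib])
        bwd.append(mat[ib, ia])
    return np.asarray(fwd), np.asarray(bwd)


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size))


def asymmetry_table(
    subjects: Sequence[ConnectivityResult],
    pairs: Sequence[tuple[str, str]],
    phase: str,
    measures: Sequence[str] = ("linear", "nonlinear"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Bidirectional-asymmetry statistics for one phase.

    One row per (measure, pair): per-direction mean +/- SEM, paired t,
    |d|, p, BH-FDR-adjusted p (family: all pairs within this phase and
    measure), BF10 and its evidence label.
    """
    if len(subjects) < 2:
        raise ValueError("asymmetry statistics need at least 2 subjects")
    n = len(subjects)
    blocks = []
    for measure in measures:
        rows = []
        for a, b in pairs:
            fwd, bwd = _direction_values(subjects, a, b, measure)
            t, df, p = paired_t(fwd, bwd)
            bf = jzs_bf(t, n, design="paired")
            rows.append(
                {
                    "phase": phase,
                    "measure": measure,
                    "connection": f"{a}<>{b}",
                    "mean_ab": fwd.mean(),
                    "sem_ab": _sem(fwd),
                    "mean_ba": bwd.mean(),
                    "sem_ba": _sem(bwd),
                    "t": t,
                    "d": abs(cohen_d_paired(t, n)),
                    "p": p,
                    "BF10": bf,
                    "evidence": evidence_label(bf),
                }
            )
        block = pd.DataFrame(rows)
        block["p_fdr"], block["sig_fdr"] = bh_fdr(block["p"].to_numpy(), alpha)
        blocks.append(block)
    cols = ["phase", "measure", "connection", "mean_ab", "sem_ab", "mean_ba",
            "sem_ba", "t", "d", "p", "p_fdr", "sig_fdr", "BF10", "evidence"]
    return pd.concat(blocks, ignore_index=True)[cols]


def group_table(
    group_a: Sequence[ConnectivityResult],
    group_b: Sequence[ConnectivityResult],
    shared_rois: Sequence[str],
    phase: str = "",
    measures: Sequence[str] = ("linear", "nonlinear"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Between-group comparison of each directed connection.

    Only connections among ``shared_rois`` (regions defined in both
    groups) are compared; d is signed; the FDR family is all compared
    connections within a measure.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("group statistics need at least 2 subjects per group")
    n1, n2 = len(group_a), len(group_b)
    directed = [(a, b) for a in shared_rois for b in shared_rois if a != b]
    blocks = []
    for measure in measures:
        rows = []
        for a, b in directed:
            va = np.array(
                [_edge_value(res, a, b, measure, idx) for idx, res in enumerate(group_a)]
            )
            vb = np.array(
                [_edge_value(res, a, b, measure, idx) for idx, res in enumerate(group_b)]
            )
            t, df, p = independent_t(va, vb)
            bf = jzs_bf(t, n1, n2, design="independent")
            rows.append(
                {
                    "phase": phase,
                    "measure": measure,
                    "connection": f"{a} -> {b}",
                    "mean_a": va.mean(),
                    "sem_a": _sem(va),
                    "mean_b": vb.mean(),
                    "sem_b": _sem(vb),
                    "t": t,
                    "df": df,
                    "d": cohen_d_independent(t, n1, n2),
                    "p": p,
                    "BF10": bf,
                    "evidence": evidence_label(bf),
                }
            )
        block = pd.DataFrame(rows)
        block["p_fdr"], block["sig_fdr"] = bh_fdr(block["p"].to_numpy(), alpha)
        blocks.append(block)
    cols = ["phase", "measure", "connection", "mean_a", "sem_a", "mean_b", "sem_b",
            "t", "df", "d", "p", "p_fdr", "sig_fdr", "BF10", "evidence"]
    return pd.concat(blocks, ignore_index=True)[cols]


def _edge_value(res: ConnectivityResult, a: str, b: str, measure: str, s_idx: int) -> float:
    if a not in res.roi_names or b not in res.roi_names:
        missing = a if a not in res.roi_names else b
        raise KeyError(f"subject {s_idx} is missing ROI {missing!r}")
    mat = res.lC if measure == "linear" else res.NC
    return float(mat[res.roi_names.index(a), res.roi_names.index(b)])
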