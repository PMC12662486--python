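"""Heterogeneity, pleiotropy, and influence diagnostics.

The IVW estimate is only trustworthy when the per-SNP Wald ratios agree.
This module quantifies disagreement (Cochran's Q), tests for directional
pleiotropy (MR-Egger intercept), measures per-instrument influence
(leave-one-out), detects pleiotropic outliers by simulation (an
MR-PRESSO-style global and per-SNP test), and exports the scatter/funnel
plot data used to eyeball both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedPair, usable_pairs
from .mr_core import (
    EstimatorError,
    MREstimate,
    _arrays,
    _egger_wls,
    _estimate,
    _normal_p,
    _ratio_weights,
    ivw,
    mr_egger,
)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q over the Wald ratios, chi-square(k−1) reference."""

    q: float
    df: int
    pval: float


@dataclass(frozen=True)
class PressoResult:
    """Simulation-based global heterogeneity and per-SNP outlier test."""

    global_rss: float
    global_pval: float
    outlier_snps: list[tuple[str, float]]
    corrected_estimate: Optional[MREstimate]
    n_sim: int
    seed: int


@dataclass(frozen=True)
class LeaveOneOutRow:
    excluded_snp: str
    estimate: MREstimate
    sign_change: bool
    significance_change: bool


def cochran_q(
    pairs: Sequence[HarmonizedPair], ivw_beta: Optional[float] = None
) -> HeterogeneityResult:
    """Q = sum of w_j (ratio_j − beta_IVW)²; p from chi-square with k−1 df.

    ``ivw_beta`` defaults to the fixed-effects IVW estimate, the value that
    minimizes Q.
    """
    bx, _, by, sy = _arrays(pairs)
    k = len(bx)
    if k < 2:
        raise EstimatorError(f"Cochran's Q needs >= 2 instruments, got {k}")
    ratios, w = _ratio_weights(bx, by, sy)
    if ivw_beta is None:
        ivw_beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - ivw_beta) ** 2))
    df = k - 1
    return HeterogeneityResult(q=q, df=df, pval=float(stats.chi2.sf(q, df)))


def egger_intercept_test(pairs: Sequence[HarmonizedPair]) -> tuple[float, float, float]:
    """(intercept, SE, two-sided p); a small p flags directional pleiotropy."""
    fit = mr_egger(pairs)
    return fit.intercept, fit.intercept_se, fit.intercept_pval


def leave_one_out(
    pairs: Sequence[HarmonizedPair], model: str = "random"
) -> list[LeaveOneOutRow]:
    """Re-estimate IVW with each instrument excluded in turn.

    Rows flag instruments whose removal flips the sign of the estimate or
    moves it across the 0.05 significance line.
    """
    use = usable_pairs(list(pairs))
    if len(use) < 3:
        raise EstimatorError(f"leave-one-out needs >= 3 instruments, got {len(use)}")
    full = ivw(use, model=model)
    rows: list[LeaveOneOutRow] = []
    for i, pair in enumerate(use):
        est = ivw(use[:i] + use[i + 1 :], model=model)
        rows.append(
            LeaveOneOutRow(
                excluded_snp=pair.snp_id,
                estimate=est,
                sign_change=(est.beta * full.beta) < 0,
                significance_change=est.significant != full.significant,
            )
        )
    return rows


def leave_one_out_frame(rows: list[LeaveOneOutRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "excluded_snp": [r.excluded_snp for r in rows],
            "beta": [r.estimate.beta for r in rows],
            "se": [r.estimate.se for r in rows],
            "pval": [r.estimate.pval for r in rows],
            "sign_change": [r.sign_change for r in rows],
            "significance_change": [r.significance_change for r in rows],
        }
    )


def mr_presso(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """Global heterogeneity and per-SNP outlier test by parametric simulation.

    The observed global statistic is a leave-one-out weighted residual sum of
    squares: RSS = sum_j w_j (beta_out_j − b(−j)·beta_exp_j)², where b(−j) is
    the IVW slope with instrument j removed and w_j = 1/se_out_j². Its null
    distribution is built by redrawing beta_exp_j ~ N(obs, se_exp_j) and
    beta_out_j ~ N(b(−j)·obs_exp_j, se_out_j) ``n_sim`` times. The global p
    is (1 + #{sim >= obs})/(n_sim + 1); each SNP's residual term is compared
    with its own simulated distribution the same way and flagged as an
    outlier at the Bonferroni level ``outlier_alpha``/k. When outliers are
    found, the corrected estimate is IVW on the remaining instruments.
    """
    use = usable_pairs(list(pairs))
    k = len(use)
    if k < 4:
        raise EstimatorError(f"MR-PRESSO needs >= 4 instruments, got {k}")
    if n_sim < 100:
        raise ValueError(f"n_sim must be >= 100, got {n_sim}")
    bx, sx, by, sy = _arrays(use)
    w = 1.0 / sy**2

    # leave-one-out IVW slopes, computed from sufficient statistics
    num = np.sum(w * bx * by)
    den = np.sum(w * bx * bx)
    b_loo = (num - w * bx * by) / (den - w * bx * bx)

    obs_terms = w * (by - b_loo * bx) ** 2
    obs_rss = float(np.sum(obs_terms))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, k))
    by_sim = rng.normal(b_loo * bx, sy, size=(n_sim, k))
    # per-simulation leave-one-out slopes under the fitted model
    num_s = np.sum(w * bx_sim * by_sim, axis=1, keepdims=True)
    den_s = np.sum(w * bx_sim**2, axis=1, keepdims=True)
    b_loo_s = (num_s - w * bx_sim * by_sim) / (den_s - w * bx_sim**2)
    sim_terms = w * (by_sim - b_loo_s * bx_sim) ** 2
    sim_rss = np.sum(sim_terms, axis=1)

    global_pval = float((1 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1))
    snp_pvals = (1 + np.sum(sim_terms >= obs_terms, axis=0)) / (n_sim + 1)

    bonferroni = outlier_alpha / k
    outliers = [
        (use[j].snp_id, float(snp_pvals[j])) for j in range(k) if snp_pvals[j] < bonferroni
    ]
    corrected = None
    if outliers:
        flagged = {s for s, _ in outliers}
        keep = [p for p in use if p.snp_id not in flagged]
        if keep:
            corrected = ivw(keep, model="random")
    return PressoResult(
        global_rss=obs_rss,
        global_pval=global_pval,
        outlier_snps=outliers,
        corrected_estimate=corrected,
        n_sim=n_sim,
        seed=seed,
    )


def funnel_scatter_data(
    pairs: Sequence[HarmonizedPair],
    estimates: Sequence[MREstimate] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables; rendering is left to the caller.

    Scatter: per-SNP (beta_exp, beta_out) with SE bars plus one fitted line
    (slope, intercept) per supplied estimate (Egger keeps its intercept; the
    others pass through the origin). Funnel: Wald ratio vs its precision
    1/se(ratio), which under homogeneity is symmetric about the IVW beta.
    """
    use = usable_pairs(list(pairs))
    if not use:
        raise EstimatorError("no usable harmonized instruments")
    bx, sx, by, sy = _arrays(use)
    ratios, w = _ratio_weights(bx, by, sy)
    scatter = pd.DataFrame(
        {
            "snp_id": [p.snp_id for p in use],
            "beta_exp": bx,
            "se_exp": sx,
            "beta_out": by,
            "se_out": sy,
        }
    )
    for est in estimates:
        intercept = 0.0
        if est.method == "egger_slope":
            b0, _, _, _, _ = _egger_wls(bx, by, sy)
            intercept = b0
        scatter[f"fit_{est.method}"] = intercept + est.beta * np.abs(bx) * np.sign(bx)
    funnel = pd.DataFrame(
        {
            "snp_id": [p.snp_id for p in use],
            "wald_ratio": ratios,
            "precision": np.sqrt(w),
        }
    )
    return scatter, funnel


def sensitivity_report(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """One-row summary: Q/df/p, Egger intercept triple, PRESSO global p and
    outlier count — the per-pair sensitivity battery."""
    het = cochran_q(pairs)
    row: dict[str, object] = {
        "q": het.q,
        "q_df": het.df,
        "q_pval": het.pval,
    }
    use = usable_pairs(list(pairs))
    if len(use) >= 3:
        b0, se0, p0 = egger_intercept_test(use)
        row.update(
            {"egger_intercept": b0, "egger_intercept_se": se0, "egger_intercept_pval": p0}
        )
    if len(use) >= 4:
        presso = mr_presso(use, n_sim=n_sim, seed=seed)
        row.update(
            {
                "presso_global_pval": presso.global_pval,
                "presso_n_outliers": len(presso.outlier_snps),
                "presso_outliers": ";".join(s for s, _ in presso.outlier_snps),
            }
        )
    return pd.DataFrame([row])
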