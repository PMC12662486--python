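"""Causal-effect estimators for two-sample MR.

Given harmonized per-SNP effects (beta_exp, se_exp, beta_out, se_out), the
per-SNP causal estimate is the Wald ratio beta_out/beta_exp with first-order
standard error se_out/|beta_exp|. Estimators over k instruments:

* IVW — precision-weighted mean of the Wald ratios, weights 1/se(ratio)²;
  algebraically identical to weighted least squares of beta_out on beta_exp
  through the origin with weights 1/se_out². Fixed-effects SE is
  1/sqrt(sum of weights); the multiplicative random-effects SE inflates it
  by sqrt(max(1, Q/(k−1))), never narrowing the interval below fixed.
* MR-Egger — the same regression with an unconstrained intercept, after
  orienting every instrument to beta_exp > 0; a nonzero intercept estimates
  the average directional pleiotropic effect and the slope remains a causal
  estimate under the InSIDE assumption.
* Weighted median — the ratio at cumulative standardized weight 1/2 over
  the sorted Wald ratios (linear interpolation); consistent while valid
  instruments carry a majority of the weight. SE by seeded parametric
  bootstrap.

For a binary outcome beta is a log odds ratio; OR = exp(beta) with
95% CI exp(beta ± 1.96·se). p-values use the normal reference distribution
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedPair, usable_pairs

Z_95 = 1.96  # conventional 95% normal quantile, matching printed-CI practice

METHODS = ("wald", "ivw_fixed", "ivw_random", "egger_slope", "weighted_median")


class EstimatorError(Exception):
    """Degenerate or insufficient instruments."""


@dataclass(frozen=True)
class MREstimate:
    """A causal effect with its uncertainty, on both beta and OR scales."""

    method: str
    beta: float
    se: float
    pval: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_snp: int

    @property
    def significant(self) -> bool:
        return self.pval < 0.05


@dataclass(frozen=True)
class EggerFit:
    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta / se)))


def _estimate(method: str, beta: float, se: float, n_snp: int) -> MREstimate:
    or_, lo, hi, p = beta_to_or(beta, se)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        pval=p,
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        n_snp=n_snp,
    )


def beta_to_or(beta: float, se: float) -> tuple[float, float, float, float]:
    """(OR, 95% CI low, 95% CI high, two-sided normal p) from beta and SE."""
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    or_ = float(np.exp(beta))
    return (
        or_,
        float(np.exp(beta - Z_95 * se)),
        float(np.exp(beta + Z_95 * se)),
        _normal_p(beta, se),
    )


def or_ci_to_beta_se(
    odds_ratio: float, ci_low: float, ci_high: float
) -> tuple[float, float, float]:
    """Recover (beta, se, p) from a printed OR with its symmetric 95% CI."""
    if not (0.0 < ci_low < odds_ratio < ci_high):
        raise ValueError(
            f"need 0 < ci_low < OR < ci_high, got {ci_low}, {odds_ratio}, {ci_high}"
        )
    beta = float(np.log(odds_ratio))
    se = float((np.log(ci_high) - np.log(ci_low)) / (2.0 * Z_95))
    return beta, se, _normal_p(beta, se)


def _arrays(pairs: Sequence[HarmonizedPair]) -> tuple[np.ndarray, ...]:
    use = usable_pairs(list(pairs))
    if not use:
        raise EstimatorError("no usable harmonized instruments")
    bx = np.array([p.beta_exp for p in use], dtype=float)
    sx = np.array([p.se_exp for p in use], dtype=float)
    by = np.array([p.beta_out for p in use], dtype=float)
    sy = np.array([p.se_out for p in use], dtype=float)
    return bx, sx, by, sy


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-SNP causal estimate: beta_out/beta_exp, SE = se_out/|beta_exp|."""
    if pair.beta_exp == 0:
        raise EstimatorError(f"{pair.snp_id}: exposure effect is 0 (degenerate instrument)")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return _estimate("wald", beta, se, 1)


def _ratio_weights(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if np.any(bx == 0):
        raise EstimatorError("exposure effect of 0 among instruments")
    ratios = by / bx
    weights = (bx / sy) ** 2  # = 1 / se(ratio)^2 with se(ratio) = sy/|bx|
    return ratios, weights


def ivw(pairs: Sequence[HarmonizedPair], model: str = "random") -> MREstimate:
    """Inverse-variance-weighted combination of Wald ratios.

    ``model='fixed'`` uses SE 1/sqrt(sum w); ``model='random'`` (default, the
    multiplicative random-effects variant) scales that SE by
    sqrt(max(1, Q/(k−1))) so heterogeneity can widen but never narrow the
    interval. With a single instrument both reduce to the Wald ratio.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    bx, _, by, sy = _arrays(pairs)
    ratios, w = _ratio_weights(bx, by, sy)
    k = len(ratios)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    method = "ivw_fixed" if model == "fixed" else "ivw_random"
    if model == "random" and k >= 2:
        q = float(np.sum(w * (ratios - beta) ** 2))
        se *= float(np.sqrt(max(1.0, q / (k - 1))))
    return _estimate(method, beta, se, k)


def _egger_wls(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray
) -> tuple[float, float, float, float, int]:
    """Weighted regression with intercept, instruments oriented to bx > 0.

    Returns (intercept, slope, se_intercept, se_slope, k). Parameter SEs use
    the multiplicative random-effects convention: the weighted residual
    variance factor is floored at 1.
    """
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    k = len(x)
    X = np.column_stack([np.ones(k), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    phi = float(np.sum(w * resid**2) / (k - 2)) if k > 2 else 1.0
    phi = max(1.0, phi)
    cov = np.linalg.inv(xtwx) * phi
    se = np.sqrt(np.diag(cov))
    return float(coef[0]), float(coef[1]), float(se[0]), float(se[1]), k


def mr_egger(pairs: Sequence[HarmonizedPair]) -> EggerFit:
    """MR-Egger regression: slope (causal effect) and intercept (pleiotropy)."""
    bx, _, by, sy = _arrays(pairs)
    if len(bx) < 3:
        raise EstimatorError(f"MR-Egger needs >= 3 instruments, got {len(bx)}")
    if np.any(bx == 0):
        raise EstimatorError("exposure effect of 0 among instruments")
    b0, b1, se0, se1, k = _egger_wls(bx, by, sy)
    return EggerFit(
        slope=_estimate("egger_slope", b1, se1, k),
        intercept=b0,
        intercept_se=se0,
        intercept_pval=_normal_p(b0, se0),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    # cumulative weight at each sorted ratio, centered on the ratio's own mass
    cum = np.cumsum(w) - w / 2.0
    if 0.5 <= cum[0]:
        return float(r[0])
    if 0.5 >= cum[-1]:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 5000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate interpolates the sorted Wald ratios at cumulative
    standardized inverse-variance weight 1/2; with equal weights and odd k it
    is the plain median. The SE is the standard deviation of the estimate
    over ``n_boot`` seeded redraws of beta_exp and beta_out from their normal
    sampling distributions.
    """
    bx, sx, by, sy = _arrays(pairs)
    if len(bx) < 3:
        raise EstimatorError(f"weighted median needs >= 3 instruments, got {len(bx)}")
    if n_boot < 1:
        raise ValueError("n_boot must be a positive integer")
    ratios, w = _ratio_weights(bx, by, sy)
    point = _weighted_median_point(ratios, w)

    rng = np.random.default_rng(seed)
    k = len(bx)
    bx_draw = rng.normal(bx, sx, size=(n_boot, k))
    by_draw = rng.normal(by, sy, size=(n_boot, k))
    bx_draw = np.where(bx_draw == 0, np.finfo(float).tiny, bx_draw)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        r_i = by_draw[i] / bx_draw[i]
        w_i = (bx_draw[i] / sy) ** 2
        reps[i] = _weighted_median_point(r_i, w_i)
    se = float(np.std(reps, ddof=1))
    if se == 0:  # degenerate bootstrap (e.g. all SEs tiny); avoid p of NaN
        se = np.finfo(float).tiny
    return _estimate("weighted_median", point, se, k)


def estimate_all(
    pairs: Sequence[HarmonizedPair],
    ivw_model: str = "random",
    n_boot: int = 5000,
    seed: int = 0,
) -> list[MREstimate]:
    """IVW (primary) plus Egger slope and weighted median when k allows.

    With a single instrument only the Wald ratio is returned.
    """
    use = usable_pairs(list(pairs))
    if not use:
        raise EstimatorError("no usable harmonized instruments")
    if len(use) == 1:
        return [wald_ratio(use[0])]
    out = [ivw(use, model=ivw_model)]
    if len(use) >= 3:
        out.append(mr_egger(use).slope)
        out.append(weighted_median(use, n_boot=n_boot, seed=seed))
    return out


def estimates_frame(
    estimates: Sequence[MREstimate],
    exposure: str = "",
    outcome: str = "",
):
    """Forest-plot-ready table: method, exposure, outcome, n_snp, beta, se,
    OR, ci_low, ci_high, pval."""
    import pandas as pd

    return pd.DataFrame(
        {
            "method": [e.method for e in estimates],
            "exposure": exposure,
            "outcome": outcome,
            "n_snp": [e.n_snp for e in estimates],
            "beta": [e.beta for e in estimates],
            "se": [e.se for e in estimates],
            "OR": [e.odds_ratio for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "pval": [e.pval for e in estimates],
        }
    )
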