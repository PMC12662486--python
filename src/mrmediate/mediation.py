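"""Two-step mediation MR: decompose a total effect into direct and
mediated components.

The causal chain exposure -> mediator -> outcome is quantified with three
MR estimates from non-overlapping GWAS samples:

* ``c`` — total effect of the exposure on the outcome (exposure instruments);
* ``a`` — effect of the exposure on the mediator (exposure instruments);
* ``b`` — effect of the mediator on the outcome (the *mediator's own*
  instruments, so the estimate is not contaminated by the exposure path).

The indirect (mediated) effect is the product a·b with a first-order
delta-method SE sqrt(a²·se_b² + b²·se_a²); the direct effect is defined by
subtraction, c' = c − a·b, so direct + indirect = total holds exactly.
The mediated proportion is 100·a·b/c, reported only when the configured
suppression rule allows: the strict rule also suppresses when the indirect
effect's 95% CI includes zero, while ``negative_only`` suppresses only
inconsistent mediation (indirect and total effects of opposite sign, i.e. a
negative proportion).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .harmonize import HarmonizeConfig, HarmonizedPair, harmonize, usable_pairs
from .instruments import LDReference, SelectionConfig, clump, select_by_pvalue
from .mr_core import Z_95, EstimatorError, MREstimate, ivw, wald_ratio
from .sumstats import SummaryStatSet

SUPPRESSION_RULES = ("footnote", "negative_only")

SUPPRESSION_MARKER = "\\"


@dataclass(frozen=True)
class IndirectEffect:
    """a·b with delta-method (or Monte-Carlo) uncertainty."""

    point: float
    se: float
    ci_low: float
    ci_high: float

    @property
    def ci_includes_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


@dataclass(frozen=True)
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    a: MREstimate
    b: MREstimate
    c: MREstimate
    indirect: IndirectEffect
    direct: float
    proportion_pct: Optional[float]
    suppression_reason: str = "none"


def total_effect(pairs: Sequence[HarmonizedPair], model: str = "random") -> MREstimate:
    """Total exposure->outcome effect ``c``: IVW over the exposure's
    instruments (a single instrument reduces to its Wald ratio)."""
    use = usable_pairs(list(pairs))
    if len(use) == 1:
        return wald_ratio(use[0])
    return ivw(use, model=model)


def indirect_effect(
    a: float,
    se_a: float,
    b: float,
    se_b: float,
    n_mc: int = 0,
    seed: int = 0,
) -> IndirectEffect:
    """Product-of-coefficients indirect effect a·b.

    Default SE is the first-order delta method sqrt(a²·se_b² + b²·se_a²);
    with ``n_mc`` > 0 the SE and CI come instead from a seeded Monte-Carlo
    sample of products of independent normals (useful when either path is
    weak and the delta approximation degrades).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    point = a * b
    if n_mc > 0:
        rng = np.random.default_rng(seed)
        prod = rng.normal(a, se_a, n_mc) * rng.normal(b, se_b, n_mc)
        se = float(np.std(prod, ddof=1))
        lo, hi = (float(q) for q in np.quantile(prod, [0.025, 0.975]))
        return IndirectEffect(point=point, se=se, ci_low=lo, ci_high=hi)
    se = float(np.sqrt(a * a * se_b * se_b + b * b * se_a * se_a))
    return IndirectEffect(
        point=point, se=se, ci_low=point - Z_95 * se, ci_high=point + Z_95 * se
    )


def decompose(
    c: MREstimate,
    a: MREstimate,
    b: MREstimate,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
    rule: str = "footnote",
    n_mc: int = 0,
    seed: int = 0,
) -> MediationResult:
    """Full decomposition: indirect = a·b, direct = c − a·b (exact identity),
    proportion = 100·a·b/c, with the suppression rule applied."""
    ind = indirect_effect(a.beta, a.se, b.beta, b.se, n_mc=n_mc, seed=seed)
    direct = c.beta - ind.point
    if c.beta == 0.0:
        result = MediationResult(
            exposure_id=exposure_id,
            mediator_id=mediator_id,
            outcome_id=outcome_id,
            a=a,
            b=b,
            c=c,
            indirect=ind,
            direct=direct,
            proportion_pct=None,
            suppression_reason="undefined_total",
        )
        return result
    proportion = 100.0 * ind.point / c.beta
    result = MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        a=a,
        b=b,
        c=c,
        indirect=ind,
        direct=direct,
        proportion_pct=proportion,
        suppression_reason="none",
    )
    return apply_suppression(result, rule=rule)


def apply_suppression(result: MediationResult, rule: str = "footnote") -> MediationResult:
    """Suppress the mediated proportion per the configured rule.

    ``footnote``: suppress when the indirect effect's 95% CI includes zero
    or the proportion is negative. ``negative_only``: suppress only when the
    indirect and total effects point in opposite directions (negative
    proportion).
    """
    if rule not in SUPPRESSION_RULES:
        raise ValueError(f"rule must be one of {SUPPRESSION_RULES}, got {rule!r}")
    if result.suppression_reason == "undefined_total":
        return result
    raw_proportion = (
        100.0 * result.indirect.point / result.c.beta if result.c.beta != 0 else None
    )
    negative = raw_proportion is not None and raw_proportion < 0
    reason = "none"
    if negative:
        reason = "negative_direction"
    elif rule == "footnote" and result.indirect.ci_includes_zero:
        reason = "ci_includes_zero"
    if reason == "none":
        return replace(result, proportion_pct=raw_proportion, suppression_reason="none")
    return replace(result, proportion_pct=None, suppression_reason=reason)


@dataclass(frozen=True)
class MediationScanConfig:
    """Knobs for a mediator scan over one exposure-outcome pair."""

    selection: SelectionConfig = SelectionConfig()
    harmonization: HarmonizeConfig = HarmonizeConfig()
    alpha: float = 0.05
    rule: str = "footnote"
    ivw_model: str = "random"


def _instrumented_estimate(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    ld: Optional[LDReference],
    config: MediationScanConfig,
) -> Optional[MREstimate]:
    """select -> clump -> harmonize -> IVW; None when no instruments survive."""
    selected = select_by_pvalue(exposure, config.selection)
    if ld is not None and len(selected):
        selected = clump(selected, ld, config.selection)
    if not len(selected):
        return None
    pairs = usable_pairs(harmonize(selected, outcome, config.harmonization))
    if not pairs:
        return None
    try:
        return total_effect(pairs, model=config.ivw_model)
    except EstimatorError:
        return None


def mediation_scan(
    exposure: SummaryStatSet,
    mediators: Sequence[SummaryStatSet],
    outcome: SummaryStatSet,
    config: MediationScanConfig = MediationScanConfig(),
    ld: Optional[LDReference] = None,
    c: Optional[MREstimate] = None,
) -> list[MediationResult]:
    """Two-step scan over candidate mediators of one exposure-outcome pair.

    A mediator enters the result table only when step 1 (exposure->mediator,
    exposure instruments) and step 2 (mediator->outcome, the mediator's own
    instruments) are both significant at ``config.alpha``. Output order
    follows the input mediator order. The total effect ``c`` is estimated
    once (or supplied) and shared by every row, so mediated proportions of
    co-mediators are directly comparable.
    """
    if c is None:
        c = _instrumented_estimate(exposure, outcome, ld, config)
    if c is None:
        return []
    results: list[MediationResult] = []
    for med in mediators:
        a = _instrumented_estimate(exposure, med, ld, config)
        if a is None or a.pval >= config.alpha:
            continue
        b = _instrumented_estimate(med, outcome, ld, config)
        if b is None or b.pval >= config.alpha:
            continue
        results.append(
            decompose(
                c,
                a,
                b,
                exposure_id=exposure.trait_id,
                mediator_id=med.trait_id,
                outcome_id=outcome.trait_id,
                rule=config.rule,
            )
        )
    return results


def mediation_frame(results: Sequence[MediationResult], decimals: int = 2) -> pd.DataFrame:
    """Report table: mediator, indirect β with 95% CI, mediated proportion
    in percent (2 decimals) or the suppression marker ``\\``."""
    rows = []
    for r in results:
        prop = (
            SUPPRESSION_MARKER
            if r.proportion_pct is None
            else f"{r.proportion_pct:.{decimals}f}"
        )
        rows.append(
            {
                "mediator": r.mediator_id,
                "indirect_beta": r.indirect.point,
                "ci_low": r.indirect.ci_low,
                "ci_high": r.indirect.ci_high,
                "mediated_proportion_pct": prop,
                "suppression_reason": r.suppression_reason,
                "direct_beta": r.direct,
                "total_beta": r.c.beta,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mediator",
            "indirect_beta",
            "ci_low",
            "ci_high",
            "mediated_proportion_pct",
            "suppression_reason",
            "direct_beta",
            "total_beta",
        ],
    )
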