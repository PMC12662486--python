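"""Allele harmonization of exposure and outcome summary statistics.

Two-sample MR divides an outcome effect by an exposure effect SNP by SNP,
which is only meaningful when both effects are expressed per copy of the
*same* allele. For each SNP present in both GWAS this module aligns the
outcome record to the exposure's effect allele:

* same allele pair, same orientation -> kept unchanged;
* same pair, swapped orientation -> outcome beta negated and its frequency
  complemented (``flipped``);
* alleles reported on the opposite strand -> complemented and re-matched;
* palindromic SNPs (A/T or C/G), whose strand cannot be resolved from the
  alleles, are aligned by allele frequency when both frequencies are far
  from 0.5, and dropped as ambiguous otherwise;
* irreconcilable allele pairs -> dropped as mismatches.

Dropped SNPs carry no estimator weight; every action is recorded so
instrument attrition is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .sumstats import SummaryStatSet

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTIONS = ("kept", "flipped", "dropped_palindromic", "dropped_mismatch")


def complement(allele: str) -> str:
    """Reverse-strand representation of an allele (per-base complement)."""
    return "".join(_COMPLEMENT.get(b, b) for b in allele)


def is_palindromic(allele1: str, allele2: str) -> bool:
    """True iff the unordered pair is {A,T} or {C,G}.

    Multi-base (indel) alleles are never palindromic: their strand is
    resolvable from the sequence itself.
    """
    if len(allele1) != 1 or len(allele2) != 1:
        return False
    pair = frozenset((allele1, allele2))
    return pair == frozenset("AT") or pair == frozenset("CG")


@dataclass(frozen=True)
class HarmonizeConfig:
    """Palindromic-SNP policy.

    ``palindrome_eaf_margin`` is the half-width of the frequency window
    around 0.5 inside which a palindromic SNP's strand is considered
    unresolvable (default 0.08: drop when either eaf lies in (0.42, 0.58)).
    """

    palindrome_eaf_margin: float = 0.08
    drop_palindromic_always: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.palindrome_eaf_margin < 0.5):
            raise ValueError("palindrome_eaf_margin must be in [0, 0.5)")

    def ambiguous(self, eaf: Optional[float]) -> bool:
        if eaf is None:
            return True
        return abs(eaf - 0.5) < self.palindrome_eaf_margin


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP, on a common effect allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf: Optional[float] = None
    action: str = "kept"

    @property
    def usable(self) -> bool:
        return self.action in ("kept", "flipped")


def harmonize(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    config: HarmonizeConfig = HarmonizeConfig(),
) -> list[HarmonizedPair]:
    """Align outcome records to the exposure's effect alleles.

    Returns one :class:`HarmonizedPair` per SNP present in both sets, in the
    exposure set's order. The harmonized ``eaf`` is the exposure's effect-
    allele frequency when present (the instrument-selection side), otherwise
    the outcome's frequency re-expressed for the exposure's effect allele.
    Dropped SNPs are retained in the output with their drop action so they
    can be logged, but :attr:`HarmonizedPair.usable` is False for them.
    """
    out_by_id = outcome.by_id()
    pairs: list[HarmonizedPair] = []
    for exp in exposure.records:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            continue

        def make(
            action: str, beta_out: float = 0.0, out_eaf_aligned: Optional[float] = None
        ) -> HarmonizedPair:
            eaf = exp.eaf if exp.eaf is not None else out_eaf_aligned
            return HarmonizedPair(
                snp_id=exp.snp_id,
                beta_exp=exp.beta,
                se_exp=exp.se,
                beta_out=beta_out,
                se_out=out.se,
                eaf=eaf,
                action=action,
            )

        def comp_eaf(flip: bool) -> Optional[float]:
            if out.eaf is None:
                return None
            return 1.0 - out.eaf if flip else out.eaf

        ea_x, oa_x = exp.effect_allele, exp.other_allele
        ea_y, oa_y = out.effect_allele, out.other_allele

        if is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                pairs.append(make("dropped_mismatch"))
                continue
            if (
                config.drop_palindromic_always
                or config.ambiguous(exp.eaf)
                or config.ambiguous(out.eaf)
            ):
                pairs.append(make("dropped_palindromic"))
                continue
            # Allele labels cannot distinguish strands here; align by which
            # side of 0.5 each study's effect-allele frequency falls on.
            out_eaf_for_ea_x = out.eaf if ea_y == ea_x else 1.0 - out.eaf
            same_side = (exp.eaf - 0.5) * (out_eaf_for_ea_x - 0.5) > 0
            beta_for_ea_x = out.beta if ea_y == ea_x else -out.beta
            eaf_for_ea_x = comp_eaf(ea_y != ea_x)
            if same_side:
                pairs.append(
                    make(
                        "kept" if ea_y == ea_x else "flipped",
                        beta_for_ea_x,
                        eaf_for_ea_x,
                    )
                )
            else:
                # Frequencies disagree: the outcome file is on the other
                # strand, which for a palindrome is equivalent to a swap.
                pairs.append(
                    make(
                        "flipped" if ea_y == ea_x else "kept",
                        -beta_for_ea_x,
                        None if eaf_for_ea_x is None else 1.0 - eaf_for_ea_x,
                    )
                )
            continue

        if (ea_y, oa_y) == (ea_x, oa_x):
            pairs.append(make("kept", out.beta, comp_eaf(False)))
        elif (ea_y, oa_y) == (oa_x, ea_x):
            pairs.append(make("flipped", -out.beta, comp_eaf(True)))
        elif (complement(ea_y), complement(oa_y)) == (ea_x, oa_x):
            pairs.append(make("kept", out.beta, comp_eaf(False)))
        elif (complement(ea_y), complement(oa_y)) == (oa_x, ea_x):
            pairs.append(make("flipped", -out.beta, comp_eaf(True)))
        else:
            pairs.append(make("dropped_mismatch"))
    return pairs


def usable_pairs(pairs: list[HarmonizedPair]) -> list[HarmonizedPair]:
    """Pairs that carry estimator weight (kept or flipped)."""
    return [p for p in pairs if p.usable]


def harmonization_log(pairs: list[HarmonizedPair]) -> pd.DataFrame:
    """Audit table of snp_id, action, reason — one row per matched SNP."""
    reasons = {
        "kept": "alleles already aligned",
        "flipped": "outcome effect allele swapped; beta negated",
        "dropped_palindromic": "palindromic SNP with ambiguous strand",
        "dropped_mismatch": "allele pairs irreconcilable",
    }
    return pd.DataFrame(
        {
            "snp_id": [p.snp_id for p in pairs],
            "action": [p.action for p in pairs],
            "reason": [reasons[p.action] for p in pairs],
        }
    )


def write_harmonization_log(pairs: list[HarmonizedPair], path: str | Path) -> None:
    harmonization_log(pairs).to_csv(path, sep="\t", index=False)
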