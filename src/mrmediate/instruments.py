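"""Instrument selection: p-value screening, greedy LD clumping, strength.

Instruments are SNPs passing a genome-wide-suggestive p-value cutoff
(default 1e-5) and pruned to approximate independence by greedy clumping:
repeatedly keep the remaining SNP with the smallest p-value and discard all
SNPs within a distance window of it (same chromosome) whose LD r² with it
reaches the threshold (defaults: 10,000 kb window, r² 0.001).

Instrument strength is quantified per SNP as R² = 2·EAF·(1−EAF)·β² — the
exposure variance explained by an additive biallelic variant under
Hardy–Weinberg with a standardized trait — and F = R²·(N−2)/(1−R²), the
single-instrument first-stage F-statistic. F < 10 conventionally flags a
weak instrument; flagged instruments are reported, not silently removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .sumstats import SummaryStatSet

WEAK_F_THRESHOLD = 10.0


class InstrumentError(Exception):
    """Raised for missing LD information or domain violations."""


@dataclass(frozen=True)
class SelectionConfig:
    """Instrument-selection constants.

    p_threshold: suggestive-significance cutoff applied as ``pval < p_threshold``.
    clump_window_kb: center-to-center distance window, kilobases.
    clump_r2: SNP pairs with r² >= this value are considered dependent.
    """

    p_threshold: float = 1e-5
    clump_window_kb: float = 10_000.0
    clump_r2: float = 0.001

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError(f"p_threshold must be in (0, 1), got {self.p_threshold}")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ValueError("clump_r2 must be in [0, 1]")


@dataclass
class LDReference:
    """SNP coordinates plus a sparse symmetric pairwise-r² lookup.

    ``positions`` maps snp_id -> (chrom, pos_bp), 1-based positions.
    ``r2_pairs`` stores r² for unordered pairs; absent pairs default to 0
    (independent), and r²(i, i) is 1 by definition.
    """

    positions: dict[str, tuple[str, int]] = field(default_factory=dict)
    r2_pairs: dict[frozenset, float] = field(default_factory=dict)

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {r2}")
        if a != b:
            self.r2_pairs[frozenset((a, b))] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.r2_pairs.get(frozenset((a, b)), 0.0)

    @classmethod
    def from_files(cls, coords_path: str | Path, matrix_path: Optional[str | Path] = None) -> "LDReference":
        """Load coordinates (TSV: snp_id, chrom, pos_bp) and an optional
        square r² matrix whose header row/index column are SNP IDs."""
        ref = cls()
        coords = pd.read_csv(coords_path, sep="\t", dtype={"snp_id": str, "chrom": str})
        for row in coords.itertuples(index=False):
            ref.positions[str(row.snp_id)] = (str(row.chrom), int(row.pos_bp))
        if matrix_path is not None:
            mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
            ids = [str(c) for c in mat.columns]
            vals = mat.to_numpy(dtype=float)
            if not np.allclose(vals, vals.T, atol=1e-12):
                raise InstrumentError(f"{matrix_path}: r² matrix is not symmetric")
            for i, a in enumerate(ids):
                for j in range(i + 1, len(ids)):
                    if vals[i, j] != 0.0:
                        ref.set_r2(a, ids[j], float(vals[i, j]))
        return ref

    def to_files(self, coords_path: str | Path, matrix_path: str | Path) -> None:
        ids = sorted(self.positions)
        pd.DataFrame(
            {
                "snp_id": ids,
                "chrom": [self.positions[s][0] for s in ids],
                "pos_bp": [self.positions[s][1] for s in ids],
            }
        ).to_csv(coords_path, sep="\t", index=False)
        mat = pd.DataFrame(
            [[self.r2(a, b) for b in ids] for a in ids], index=ids, columns=ids
        )
        mat.to_csv(matrix_path, sep="\t")


@dataclass(frozen=True)
class InstrumentStrength:
    snp_id: str
    r_squared: float
    f_statistic: float

    @property
    def is_weak(self) -> bool:
        return self.f_statistic < WEAK_F_THRESHOLD


def select_by_pvalue(sset: SummaryStatSet, config: SelectionConfig = SelectionConfig()) -> SummaryStatSet:
    """Keep records with pval strictly below the threshold, order preserved."""
    return SummaryStatSet(
        trait_id=sset.trait_id,
        trait_type=sset.trait_type,
        records=[r for r in sset.records if r.pval < config.p_threshold],
    )


def clump(
    sset: SummaryStatSet,
    ld: LDReference,
    config: SelectionConfig = SelectionConfig(),
) -> SummaryStatSet:
    """Greedy best-p-first LD clumping.

    Repeatedly keep the remaining SNP with the smallest p-value (ties broken
    by lexicographic snp_id, so the result is invariant to input row order),
    then remove every unkept SNP on the same chromosome within the window
    whose r² with the kept SNP is >= the threshold. Returns the kept records
    ordered by (pval, snp_id). Window distance is center-to-center;
    cross-chromosome pairs are never clumped.
    """
    for rec in sset.records:
        if rec.snp_id not in ld.positions:
            raise InstrumentError(f"SNP {rec.snp_id} has no coordinates in the LD reference")
    remaining = sorted(sset.records, key=lambda r: (r.pval, r.snp_id))
    kept = []
    window_bp = config.clump_window_kb * 1000.0
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        chrom_l, pos_l = ld.positions[lead.snp_id]
        survivors = []
        for rec in remaining:
            chrom_r, pos_r = ld.positions[rec.snp_id]
            in_window = chrom_r == chrom_l and abs(pos_r - pos_l) <= window_bp
            if in_window and ld.r2(lead.snp_id, rec.snp_id) >= config.clump_r2:
                continue
            survivors.append(rec)
        remaining = survivors
    return SummaryStatSet(trait_id=sset.trait_id, trait_type=sset.trait_type, records=kept)


def variance_explained(eaf: float, beta: float) -> float:
    """Exposure variance explained by one SNP: 2·EAF·(1−EAF)·β².

    Assumes an additive biallelic variant in Hardy–Weinberg equilibrium and a
    unit-variance trait; symmetric under eaf <-> 1−eaf.
    """
    if not (0.0 < eaf < 1.0):
        raise ValueError(f"eaf must be in (0, 1), got {eaf}")
    return 2.0 * eaf * (1.0 - eaf) * beta * beta


def f_statistic(r_squared: float, n: int) -> float:
    """Single-instrument strength: F = R²·(N−2)/(1−R²)."""
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    if not (0.0 <= r_squared < 1.0):
        raise ValueError(f"r_squared must be in [0, 1), got {r_squared}")
    return r_squared * (n - 2) / (1.0 - r_squared)


def instrument_strength(sset: SummaryStatSet, default_n: Optional[int] = None) -> list[InstrumentStrength]:
    """Per-SNP R² and F for every record carrying eaf and a sample size.

    Records missing eaf or n (with no ``default_n``) are skipped — strength
    cannot be computed for them.
    """
    out: list[InstrumentStrength] = []
    for rec in sset.records:
        n = rec.n if rec.n is not None else default_n
        if rec.eaf is None or n is None or n <= 2:
            continue
        r2 = variance_explained(rec.eaf, rec.beta)
        if r2 >= 1.0:
            continue
        out.append(InstrumentStrength(rec.snp_id, r2, f_statistic(r2, n)))
    return out


def filter_weak(
    sset: SummaryStatSet,
    min_f: float,
    default_n: Optional[int] = None,
) -> SummaryStatSet:
    """Optionally drop instruments below an F cutoff (off by default upstream)."""
    strengths = {s.snp_id: s for s in instrument_strength(sset, default_n)}
    keep = [
        r
        for r in sset.records
        if r.snp_id not in strengths or strengths[r.snp_id].f_statistic >= min_f
    ]
    return SummaryStatSet(trait_id=sset.trait_id, trait_type=sset.trait_type, records=keep)
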