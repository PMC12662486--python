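"""GWAS summary-statistics data model and delimited-text I/O.

One :class:`SummaryStatRecord` holds a single SNP's marginal association
with one trait (effect/other allele, effect-allele frequency, beta, SE,
p-value, sample size); a :class:`SummaryStatSet` is one GWAS — an ordered,
ID-unique collection of records for a named trait.

Files are plain delimited text (TSV by default, CSV selectable), optionally
gzip-compressed by extension. Column headers are remapped through a
:class:`Dialect`, so arbitrary GWAS export layouts can be ingested without
rewriting files.
"""

from __future__ import annotations

import gzip
import logging
import math
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

logger = logging.getLogger("mrmediate")

#: smallest positive normal double; p-values of exactly 0 are clamped here
#: so downstream -log10 transforms stay finite.
MIN_PVAL = sys.float_info.min

_VALID_BASES = frozenset("ACGT")

TRAIT_TYPES = ("microbiota", "metabolite", "disease")


class SumstatsError(Exception):
    """Base error for summary-statistics parsing and validation."""


class DialectError(SumstatsError):
    """A required column is missing from the file or the dialect mapping."""


class ParseError(SumstatsError):
    """A row could not be parsed into a valid record (strict mode)."""


def _is_allele(a: str) -> bool:
    return len(a) >= 1 and all(b in _VALID_BASES for b in a)


@dataclass(frozen=True, slots=True)
class SummaryStatRecord:
    """Marginal association of one SNP with one trait.

    ``beta`` is the per-effect-allele effect size: log-odds for a binary
    trait, (standardized) linear units for a quantitative one. ``eaf`` and
    ``n`` are optional because many public GWAS exports omit them.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: Optional[float] = None
    n: Optional[int] = None

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty if valid)."""
        out: list[str] = []
        if not self.snp_id:
            out.append("empty snp_id")
        if not _is_allele(self.effect_allele):
            out.append(f"invalid effect_allele {self.effect_allele!r}")
        if not _is_allele(self.other_allele):
            out.append(f"invalid other_allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            out.append("effect_allele equals other_allele")
        if not (self.se > 0) or not math.isfinite(self.se):
            out.append(f"se must be > 0, got {self.se}")
        if not (0.0 <= self.pval <= 1.0):
            out.append(f"pval outside [0, 1]: {self.pval}")
        if not math.isfinite(self.beta):
            out.append(f"non-finite beta: {self.beta}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            out.append(f"eaf outside (0, 1): {self.eaf}")
        if self.n is not None and self.n <= 0:
            out.append(f"non-positive n: {self.n}")
        return out

    @property
    def is_valid(self) -> bool:
        return not self.violations()


@dataclass
class SummaryStatSet:
    """One GWAS: an ordered collection of per-SNP records for one trait."""

    trait_id: str
    trait_type: str = "metabolite"
    records: list[SummaryStatRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trait_id:
            raise ValueError("trait_id must be non-empty")
        if self.trait_type not in TRAIT_TYPES:
            raise ValueError(
                f"trait_type must be one of {TRAIT_TYPES}, got {self.trait_type!r}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryStatRecord]:
        return iter(self.records)

    def by_id(self) -> dict[str, SummaryStatRecord]:
        """snp_id -> record mapping (later duplicates win, as in pandas)."""
        return {r.snp_id: r for r in self.records}

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStatSet":
        """New set restricted to ``snp_ids``, preserving input record order."""
        wanted = set(snp_ids)
        return SummaryStatSet(
            trait_id=self.trait_id,
            trait_type=self.trait_type,
            records=[r for r in self.records if r.snp_id in wanted],
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "SNP": [r.snp_id for r in self.records],
            "effect_allele": [r.effect_allele for r in self.records],
            "other_allele": [r.other_allele for r in self.records],
            "eaf": [r.eaf for r in self.records],
            "beta": [r.beta for r in self.records],
            "se": [r.se for r in self.records],
            "pval": [r.pval for r in self.records],
            "N": [r.n for r in self.records],
        }
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class Dialect:
    """Mapping from logical columns to the headers used in a file.

    ``eaf`` and ``n`` may be set to None for files that lack them.
    ``sep`` is the field delimiter; the default layout is tab-separated with
    '.' decimals.
    """

    snp: str = "SNP"
    effect_allele: str = "effect_allele"
    other_allele: str = "other_allele"
    beta: str = "beta"
    se: str = "se"
    pval: str = "pval"
    eaf: Optional[str] = "eaf"
    n: Optional[str] = "N"
    sep: str = "\t"

    def required(self) -> dict[str, str]:
        return {
            "snp": self.snp,
            "effect_allele": self.effect_allele,
            "other_allele": self.other_allele,
            "beta": self.beta,
            "se": self.se,
            "pval": self.pval,
        }


DEFAULT_DIALECT = Dialect()


def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _parse_float(raw, row_idx: int, col: str, strict: bool) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        if strict:
            raise ParseError(
                f"row {row_idx}: cannot parse {col}={raw!r} as a number"
            ) from None
        return None


def read_sumstats(
    path: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
    trait_id: Optional[str] = None,
    trait_type: str = "metabolite",
    strict: bool = True,
) -> SummaryStatSet:
    """Read a delimited summary-statistics file into a :class:`SummaryStatSet`.

    In strict mode any row violating a record invariant raises
    :class:`ParseError` naming the row; in lenient mode such rows are dropped
    and the count is logged. p-values of exactly 0 are clamped to the smallest
    positive double with a warning (they would otherwise break -log10-based
    selection displays).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = dialect.sep
    if path.suffix == ".csv" or str(path).endswith(".csv.gz"):
        sep = ","
    with _open_text(path, "r") as fh:
        df = pd.read_csv(fh, sep=sep, dtype=str)
    missing = [h for h in dialect.required().values() if h not in df.columns]
    if missing:
        raise DialectError(
            f"{path}: required column(s) {missing} not found; "
            f"available: {list(df.columns)}"
        )

    records: list[SummaryStatRecord] = []
    n_dropped = 0
    n_clamped = 0
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            beta = _parse_float(row_d[dialect.beta], idx, "beta", strict)
            se = _parse_float(row_d[dialect.se], idx, "se", strict)
            pval = _parse_float(row_d[dialect.pval], idx, "pval", strict)
            eaf = None
            if dialect.eaf and dialect.eaf in df.columns:
                eaf = _parse_float(row_d[dialect.eaf], idx, "eaf", strict)
            n = None
            if dialect.n and dialect.n in df.columns:
                n_f = _parse_float(row_d[dialect.n], idx, "n", strict)
                n = int(n_f) if n_f is not None else None
        except ParseError:
            raise
        if beta is None or se is None or pval is None:
            if strict:
                raise ParseError(f"row {idx}: missing required numeric field")
            n_dropped += 1
            continue
        if pval == 0.0:
            pval = MIN_PVAL
            n_clamped += 1
        rec = SummaryStatRecord(
            snp_id=str(row_d[dialect.snp]),
            effect_allele=str(row_d[dialect.effect_allele]).upper(),
            other_allele=str(row_d[dialect.other_allele]).upper(),
            beta=beta,
            se=se,
            pval=pval,
            eaf=eaf,
            n=n,
        )
        viol = rec.violations()
        if viol:
            if strict:
                raise ParseError(f"row {idx} ({rec.snp_id}): " + "; ".join(viol))
            n_dropped += 1
            continue
        records.append(rec)

    if n_clamped:
        logger.warning("%s: clamped %d zero p-value(s) to %g", path, n_clamped, MIN_PVAL)
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s) in lenient mode", path, n_dropped)
    return SummaryStatSet(
        trait_id=trait_id or path.name.split(".")[0],
        trait_type=trait_type,
        records=records,
    )


def write_sumstats(
    sset: SummaryStatSet, path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> Path:
    """Write a set as delimited text; inverse of :func:`read_sumstats`.

    Floats are written with 10 significant digits, which bounds round-trip
    error well below anything the estimators can resolve.
    """
    path = Path(path)
    sep = dialect.sep
    if path.suffix == ".csv" or str(path).endswith(".csv.gz"):
        sep = ","
    header = list(dialect.required().values())
    if dialect.eaf:
        header.insert(3, dialect.eaf)
    if dialect.n:
        header.append(dialect.n)

    def fmt(x) -> str:
        if x is None:
            return ""
        if isinstance(x, int):
            return str(x)
        return f"{x:.10g}"

    with _open_text(path, "w") as fh:
        fh.write(sep.join(header) + "\n")
        for r in sset.records:
            fields = [r.snp_id, r.effect_allele, r.other_allele]
            if dialect.eaf:
                fields.append(fmt(r.eaf))
            fields += [fmt(r.beta), fmt(r.se), fmt(r.pval)]
            if dialect.n:
                fields.append(fmt(r.n))
            fh.write(sep.join(fields) + "\n")
    return path


@dataclass
class ValidationReport:
    """Counts of problems found in a :class:`SummaryStatSet`."""

    n_records: int = 0
    duplicate_ids: list[str] = field(default_factory=list)
    invariant_violations: dict[str, list[str]] = field(default_factory=dict)
    n_missing_eaf: int = 0
    n_missing_n: int = 0

    @property
    def is_clean(self) -> bool:
        """True iff all invariants hold and IDs are unique.

        Missing optional fields are reported but do not make a set unclean.
        """
        return not self.duplicate_ids and not self.invariant_violations


def validate_sumstats(sset: SummaryStatSet) -> ValidationReport:
    """Audit a set: duplicate IDs, invariant violations, missing optionals."""
    report = ValidationReport(n_records=len(sset))
    seen: set[str] = set()
    for rec in sset.records:
        if rec.snp_id in seen:
            report.duplicate_ids.append(rec.snp_id)
        seen.add(rec.snp_id)
        viol = rec.violations()
        if viol:
            report.invariant_violations[rec.snp_id] = viol
        if rec.eaf is None:
            report.n_missing_eaf += 1
        if rec.n is None:
            report.n_missing_n += 1
    return report


def flip_record(rec: SummaryStatRecord) -> SummaryStatRecord:
    """Re-orient a record to the opposite effect allele (sign/frequency flip)."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )
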