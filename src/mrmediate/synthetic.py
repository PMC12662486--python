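"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator encodes the mediation path diagram as a linear structural
model over unlinked biallelic SNPs g_j ~ Binomial(2, MAF_j)/HWE:

    X = sum_j gamma_j g_j + eps_x                      (exposure)
    Z = a X + sum_k delta_k h_k + eps_z                (mediator)
    Y = c' X + b Z + sum_{j invalid} alpha_j g_j + eps_y  (outcome)

so the total exposure->outcome effect is c = c' + a·b and the true mediated
proportion is 100·a·b/c. The exposure has its own instrument SNPs (g) and
the mediator has its own (h) — without the latter, step 2 of two-step MR
would estimate c/a instead of b. Pleiotropy enters as direct SNP->outcome
effects alpha_j on a configurable fraction of the exposure instruments,
balanced (mean 0) or directional (mean = scale).

Marginal per-SNP summary statistics are produced analytically: the expected
marginal effect from the structural model plus Gaussian sampling noise with
the standard error a GWAS of that size would report,
se = 1/sqrt(2·MAF·(1−MAF)·n_eff), where n_eff is the sample size for a
quantitative trait and n·cf·(1−cf) for a binary one (cf = case fraction).
The three cohorts receive independent noise draws, matching the two-sample
design's non-overlapping sources. Everything is deterministic given the
seed. A genotype-level mode (:func:`simulate_individual_level`) exists for
validating the analytic shortcut at small n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDReference
from .sumstats import MIN_PVAL, SummaryStatRecord, SummaryStatSet

PLEIOTROPY_MODES = ("none", "balanced", "directional")

_ALLELE_PAIRS = (
    ("A", "C"),
    ("A", "G"),
    ("A", "T"),
    ("C", "G"),
    ("C", "T"),
    ("G", "T"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters; defaults form a well-powered benchmark study.

    Cohort sizes follow the three-source design (a microbiome-scale exposure
    GWAS, a metabolite-scale mediator GWAS, a large case-control outcome
    GWAS); the outcome default is balanced case-control so estimator
    properties are measured at good power. ``case_fraction`` can be dropped
    to biobank-like imbalance (see :func:`finngen_like`).
    """

    n_snps: int = 50
    n_snps_mediator: Optional[int] = None  # defaults to n_snps
    n_exp: int = 20_000
    n_med: int = 20_000
    n_out: int = 350_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_scale: float = 0.12
    delta_scale: Optional[float] = None  # defaults to gamma_scale
    a_true: float = 0.3
    b_true: float = 0.2
    c_prime_true: float = 0.1
    pleiotropy_mode: str = "none"
    pleiotropy_frac: float = 0.0
    pleiotropy_scale: float = 0.0
    outcome_binary: bool = True
    case_fraction: float = 0.5
    ld_blocks: Optional[Sequence[tuple[int, float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n in (("n_exp", self.n_exp), ("n_med", self.n_med), ("n_out", self.n_out)):
            if n < 100:
                raise ValueError(f"{name} must be >= 100, got {n}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range bounds must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.pleiotropy_frac <= 1.0):
            raise ValueError("pleiotropy_frac must be in [0, 1]")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise ValueError(f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}")
        if not (0.0 < self.case_fraction <= 0.5):
            raise ValueError("case_fraction must be in (0, 0.5]")

    @property
    def k_mediator(self) -> int:
        return self.n_snps_mediator if self.n_snps_mediator is not None else self.n_snps

    @property
    def delta(self) -> float:
        return self.delta_scale if self.delta_scale is not None else self.gamma_scale


def finngen_like(**overrides) -> SimulationConfig:
    """Biobank-style preset: rare-disease case imbalance (case fraction
    0.005 over ~410k participants). Far noisier than the default benchmark;
    intended for realism studies, not estimator validation."""
    params = dict(n_out=410_000, case_fraction=0.005, n_exp=14_306, n_med=8_299)
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth structural parameters for recovery testing."""

    exposure_snps: tuple[str, ...]
    mediator_snps: tuple[str, ...]
    gamma: np.ndarray  # per-SNP true SNP->exposure effects
    delta: np.ndarray  # per-SNP true SNP->mediator effects
    alpha: np.ndarray  # per-SNP direct SNP->outcome (pleiotropic) effects
    maf_exposure: np.ndarray
    maf_mediator: np.ndarray
    a_true: float
    b_true: float
    c_prime_true: float
    seed: int

    @property
    def c_true(self) -> float:
        return self.c_prime_true + self.a_true * self.b_true

    @property
    def proportion_true(self) -> float:
        return 100.0 * self.a_true * self.b_true / self.c_true

    def to_dict(self) -> dict:
        return {
            "a_true": self.a_true,
            "b_true": self.b_true,
            "c_prime_true": self.c_prime_true,
            "c_true": self.c_true,
            "proportion_true": self.proportion_true,
            "seed": self.seed,
            "exposure_snps": list(self.exposure_snps),
            "mediator_snps": list(self.mediator_snps),
            "gamma": self.gamma.tolist(),
            "delta": self.delta.tolist(),
            "alpha": self.alpha.tolist(),
        }


def _draw_pleiotropy(
    rng: np.random.Generator,
    gamma: np.ndarray,
    mode: str,
    frac: float,
    scale: float,
) -> np.ndarray:
    """Direct SNP->outcome effects for the invalid-instrument fraction.

    Directional pleiotropy is aligned with each instrument's exposure-effect
    sign: after the convention of orienting instruments to a positive
    exposure effect, the direct effects share a common sign, which is what
    makes the bias directional (and detectable by an Egger intercept) rather
    than balanced.
    """
    alpha = np.zeros(len(gamma))
    if mode == "none" or frac <= 0:
        return alpha
    n_invalid = int(math.ceil(frac * len(gamma)))
    invalid = rng.choice(len(gamma), size=n_invalid, replace=False)
    mean = scale if mode == "directional" else 0.0
    draws = rng.normal(mean, scale, size=n_invalid)
    if mode == "directional":
        draws = draws * np.sign(gamma[invalid])
    alpha[invalid] = draws
    return alpha


def _p_from_z(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, MIN_PVAL, 1.0)


def _build_ld(ids: list[str], config: SimulationConfig) -> LDReference:
    """Place SNPs far apart (independent) or in proximal blocks of given r²."""
    ref = LDReference()
    if not config.ld_blocks:
        for i, snp in enumerate(ids):
            chrom = str(i % 22 + 1)
            ref.positions[snp] = (chrom, 1_000_000 + (i // 22) * 20_000_000)
        return ref
    blocks: list[list[str]] = []
    queue = list(ids)
    bi = 0
    while queue:
        size, _ = config.ld_blocks[bi % len(config.ld_blocks)]
        blocks.append([queue.pop(0) for _ in range(min(size, len(queue)))])
        bi += 1
    for b_idx, block in enumerate(blocks):
        chrom = str(b_idx % 22 + 1)
        base = 1_000_000 + (b_idx // 22) * 50_000_000
        _, r2 = config.ld_blocks[b_idx % len(config.ld_blocks)]
        for i, snp in enumerate(block):
            ref.positions[snp] = (chrom, base + i * 100_000)
            for prev in block[:i]:
                ref.set_r2(snp, prev, r2)
    return ref


def _records(
    ids: list[str],
    alleles: list[tuple[str, str]],
    maf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    n: int,
    flip_mask: np.ndarray,
) -> list[SummaryStatRecord]:
    """Assemble records, re-orienting flagged SNPs to their other allele —
    the allele bookkeeping real GWAS exports disagree on and harmonization
    must undo."""
    pvals = _p_from_z(beta, se)
    recs = []
    for i, snp in enumerate(ids):
        ea, oa = alleles[i]
        b, f = float(beta[i]), float(maf[i])
        if flip_mask[i]:
            ea, oa, b, f = oa, ea, -b, 1.0 - f
        recs.append(
            SummaryStatRecord(
                snp_id=snp,
                effect_allele=ea,
                other_allele=oa,
                beta=b,
                se=float(se[i]),
                pval=float(pvals[i]),
                eaf=f,
                n=n,
            )
        )
    return recs


def simulate_tripartite(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[SummaryStatSet, SummaryStatSet, SummaryStatSet, SimulationTruth, LDReference]:
    """Generate (exposure, mediator, outcome) summary statistics + truth + LD.

    Returns sets whose SNP panel is the union of the exposure's instruments
    and the mediator's instruments; every trait reports marginal statistics
    for all SNPs, as real GWAS do.
    """
    rng = np.random.default_rng(config.seed)
    kx = config.n_snps
    kz = config.k_mediator

    maf_x = rng.uniform(*config.maf_range, size=kx)
    maf_z = rng.uniform(*config.maf_range, size=kz)

    # true per-SNP effects: random sign, magnitude uniform around the scale
    gamma = rng.choice([-1.0, 1.0], kx) * rng.uniform(0.5, 1.5, kx) * config.gamma_scale
    delta = rng.choice([-1.0, 1.0], kz) * rng.uniform(0.5, 1.5, kz) * config.delta

    var_gx = 2.0 * maf_x * (1.0 - maf_x)
    var_hz = 2.0 * maf_z * (1.0 - maf_z)
    r2_x = float(np.sum(var_gx * gamma**2))
    r2_z_direct = float(np.sum(var_hz * delta**2))
    if r2_x >= 0.95 or config.a_true**2 + r2_z_direct >= 0.95:
        raise ValueError(
            "structural variance exceeds trait variance; lower gamma_scale/"
            "delta_scale or n_snps"
        )

    alpha = _draw_pleiotropy(rng, gamma, config.pleiotropy_mode,
                             config.pleiotropy_frac, config.pleiotropy_scale)

    c_total = config.c_prime_true + config.a_true * config.b_true

    ids_x = [f"rs{i + 1:05d}" for i in range(kx)]
    ids_z = [f"rs{kx + i + 1:05d}" for i in range(kz)]
    all_ids = ids_x + ids_z
    maf_all = np.concatenate([maf_x, maf_z])
    var_g_all = 2.0 * maf_all * (1.0 - maf_all)

    # expected marginal effects per trait over the whole panel
    true_x = np.concatenate([gamma, np.zeros(kz)])
    true_z = np.concatenate([config.a_true * gamma, delta])
    true_y = np.concatenate(
        [c_total * gamma + alpha, config.b_true * delta]
    )

    se_x = 1.0 / np.sqrt(var_g_all * config.n_exp)
    se_z = 1.0 / np.sqrt(var_g_all * config.n_med)
    n_eff_out = (
        config.n_out * config.case_fraction * (1.0 - config.case_fraction)
        if config.outcome_binary
        else config.n_out
    )
    se_y = 1.0 / np.sqrt(var_g_all * n_eff_out)

    beta_x = true_x + rng.normal(0.0, se_x)
    beta_z = true_z + rng.normal(0.0, se_z)
    beta_y = true_y + rng.normal(0.0, se_y)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=len(all_ids))
    alleles = [_ALLELE_PAIRS[i] for i in pair_idx]
    no_flip = np.zeros(len(all_ids), dtype=bool)
    flip_z = rng.random(len(all_ids)) < 0.5
    flip_y = rng.random(len(all_ids)) < 0.5

    exposure = SummaryStatSet(
        trait_id="sim_taxon",
        trait_type="microbiota",
        records=_records(all_ids, alleles, maf_all, beta_x, se_x, config.n_exp, no_flip),
    )
    mediator = SummaryStatSet(
        trait_id="sim_metabolite",
        trait_type="metabolite",
        records=_records(all_ids, alleles, maf_all, beta_z, se_z, config.n_med, flip_z),
    )
    outcome = SummaryStatSet(
        trait_id="sim_disease",
        trait_type="disease",
        records=_records(all_ids, alleles, maf_all, beta_y, se_y, config.n_out, flip_y),
    )
    truth = SimulationTruth(
        exposure_snps=tuple(ids_x),
        mediator_snps=tuple(ids_z),
        gamma=gamma,
        delta=delta,
        alpha=alpha,
        maf_exposure=maf_x,
        maf_mediator=maf_z,
        a_true=config.a_true,
        b_true=config.b_true,
        c_prime_true=config.c_prime_true,
        seed=config.seed,
    )
    return exposure, mediator, outcome, truth, _build_ld(all_ids, config)


def simulate_individual_level(
    config: SimulationConfig, n_per_cohort: int = 2000
) -> tuple[SummaryStatSet, SummaryStatSet, SummaryStatSet, SimulationTruth]:
    """Genotype-level simulation for validating the analytic generator.

    Draws HWE genotypes for three independent cohorts, builds the traits
    from the structural model (outcome on the continuous liability scale),
    and computes per-SNP marginal OLS effects. Slow relative to the analytic
    path — intended for small-n cross-checks only.
    """
    rng = np.random.default_rng(config.seed)
    kx, kz = config.n_snps, config.k_mediator
    maf_x = rng.uniform(*config.maf_range, size=kx)
    maf_z = rng.uniform(*config.maf_range, size=kz)
    gamma = rng.choice([-1.0, 1.0], kx) * rng.uniform(0.5, 1.5, kx) * config.gamma_scale
    delta = rng.choice([-1.0, 1.0], kz) * rng.uniform(0.5, 1.5, kz) * config.delta
    maf_all = np.concatenate([maf_x, maf_z])
    ids = [f"rs{i + 1:05d}" for i in range(kx + kz)]

    def cohort_traits():
        g = rng.binomial(2, maf_all, size=(n_per_cohort, kx + kz)).astype(float)
        gx, hz = g[:, :kx], g[:, kx:]
        var_explained = float(np.sum(2 * maf_x * (1 - maf_x) * gamma**2))
        x = gx @ gamma + rng.normal(0, math.sqrt(max(0.05, 1 - var_explained)), n_per_cohort)
        z = config.a_true * x + hz @ delta + rng.normal(0, 1.0, n_per_cohort)
        y = config.c_prime_true * x + config.b_true * z + rng.normal(0, 1.0, n_per_cohort)
        return g, x, z, y

    def marginal(g: np.ndarray, trait: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gc = g - g.mean(axis=0)
        tc = trait - trait.mean()
        ssg = np.sum(gc**2, axis=0)
        beta = gc.T @ tc / ssg
        rss = np.sum(tc**2) - beta**2 * ssg  # residual SS of each simple fit
        se = np.sqrt(rss / (n_per_cohort - 2) / ssg)
        return beta, se

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=len(ids))
    alleles = [_ALLELE_PAIRS[i] for i in pair_idx]
    sets = []
    for trait_id, trait_type, which in (
        ("sim_taxon", "microbiota", 1),
        ("sim_metabolite", "metabolite", 2),
        ("sim_disease", "disease", 3),
    ):
        g, x, z, y = cohort_traits()
        trait = (x, z, y)[which - 1]
        beta, se = marginal(g, trait)
        sets.append(
            SummaryStatSet(
                trait_id=trait_id,
                trait_type=trait_type,
                records=_records(
                    ids, alleles, maf_all, beta, se, n_per_cohort,
                    np.zeros(len(ids), dtype=bool),
                ),
            )
        )
    truth = SimulationTruth(
        exposure_snps=tuple(ids[:kx]),
        mediator_snps=tuple(ids[kx:]),
        gamma=gamma,
        delta=delta,
        alpha=np.zeros(kx),
        maf_exposure=maf_x,
        maf_mediator=maf_z,
        a_true=config.a_true,
        b_true=config.b_true,
        c_prime_true=config.c_prime_true,
        seed=config.seed,
    )
    return sets[0], sets[1], sets[2], truth


@dataclass(frozen=True)
class StudySimSpec:
    """A full screening study: many taxa, many candidate metabolites, one
    disease, with a single true taxon->metabolite->disease pathway.

    Taxon 0 is the causal taxon (structural coefficients from ``base``);
    metabolite 0 is the true mediator; all other taxa and metabolites are
    null. The disease has its own instruments (effect scale ``eta_scale``
    on the log-odds), and can be given a reverse effect on selected taxa to
    exercise bidirectionality screening. Every trait reports marginal
    statistics for the union SNP panel, as real GWAS do.
    """

    n_taxa: int = 21
    n_metabolites: int = 11
    n_disease_snps: int = 50
    eta_scale: float = 0.1
    reverse_effect: float = 0.0
    reverse_taxa: tuple[int, ...] = ()
    base: SimulationConfig = SimulationConfig()

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_metabolites < 1:
            raise ValueError("need at least one taxon and one metabolite")
        if any(t < 0 or t >= self.n_taxa for t in self.reverse_taxa):
            raise ValueError("reverse_taxa indices out of range")


@dataclass
class StudyData:
    """Simulated study bundle consumed by the pipeline."""

    taxa: list[SummaryStatSet]
    metabolites: list[SummaryStatSet]
    outcome: SummaryStatSet
    ld: LDReference
    truth: SimulationTruth
    true_taxon: str
    true_mediator: str
    reverse_taxa: tuple[str, ...]


def simulate_study(spec: StudySimSpec = StudySimSpec(), seed: Optional[int] = None) -> StudyData:
    """Generate the full screening study defined by ``spec``.

    ``seed`` overrides ``spec.base.seed``. Deterministic given the seed.
    """
    cfg = spec.base
    use_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(use_seed)
    k = cfg.n_snps
    km = cfg.k_mediator
    kd = spec.n_disease_snps

    n_units = spec.n_taxa + spec.n_metabolites
    total_snps = spec.n_taxa * k + spec.n_metabolites * km + kd
    maf = rng.uniform(*cfg.maf_range, size=total_snps)
    var_g = 2.0 * maf * (1.0 - maf)
    ids = [f"rs{i + 1:06d}" for i in range(total_snps)]

    # SNP index ranges per unit
    taxa_idx = [slice(i * k, (i + 1) * k) for i in range(spec.n_taxa)]
    off = spec.n_taxa * k
    metab_idx = [slice(off + j * km, off + (j + 1) * km) for j in range(spec.n_metabolites)]
    dis_idx = slice(off + spec.n_metabolites * km, total_snps)

    def draw_effects(size: int, scale: float) -> np.ndarray:
        return rng.choice([-1.0, 1.0], size) * rng.uniform(0.5, 1.5, size) * scale

    gammas = [draw_effects(k, cfg.gamma_scale) for _ in range(spec.n_taxa)]
    deltas = [draw_effects(km, cfg.delta) for _ in range(spec.n_metabolites)]
    eta = draw_effects(kd, spec.eta_scale)

    alpha = _draw_pleiotropy(rng, gammas[0], cfg.pleiotropy_mode,
                             cfg.pleiotropy_frac, cfg.pleiotropy_scale)

    c_total = cfg.c_prime_true + cfg.a_true * cfg.b_true

    se_exp = 1.0 / np.sqrt(var_g * cfg.n_exp)
    se_med = 1.0 / np.sqrt(var_g * cfg.n_med)
    n_eff_out = (
        cfg.n_out * cfg.case_fraction * (1.0 - cfg.case_fraction)
        if cfg.outcome_binary
        else cfg.n_out
    )
    se_out = 1.0 / np.sqrt(var_g * n_eff_out)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=total_snps)
    alleles = [_ALLELE_PAIRS[i] for i in pair_idx]
    no_flip = np.zeros(total_snps, dtype=bool)

    def build_set(trait_id, trait_type, true_marg, se, n, flip) -> SummaryStatSet:
        beta = true_marg + rng.normal(0.0, se)
        return SummaryStatSet(
            trait_id=trait_id,
            trait_type=trait_type,
            records=_records(ids, alleles, maf, beta, se, n, flip),
        )

    taxa_sets: list[SummaryStatSet] = []
    for i in range(spec.n_taxa):
        true_marg = np.zeros(total_snps)
        true_marg[taxa_idx[i]] = gammas[i]
        if spec.reverse_effect != 0.0 and i in spec.reverse_taxa:
            true_marg[dis_idx] += spec.reverse_effect * eta
        taxa_sets.append(
            build_set(f"taxon_{i:02d}", "microbiota", true_marg, se_exp, cfg.n_exp, no_flip)
        )

    metab_sets: list[SummaryStatSet] = []
    for j in range(spec.n_metabolites):
        true_marg = np.zeros(total_snps)
        true_marg[metab_idx[j]] = deltas[j]
        if j == 0:  # the true mediator responds to the causal taxon
            true_marg[taxa_idx[0]] += cfg.a_true * gammas[0]
        flip = rng.random(total_snps) < 0.5
        metab_sets.append(
            build_set(f"metabolite_{j:02d}", "metabolite", true_marg, se_med, cfg.n_med, flip)
        )

    true_marg_y = np.zeros(total_snps)
    true_marg_y[taxa_idx[0]] = c_total * gammas[0] + alpha
    true_marg_y[metab_idx[0]] = cfg.b_true * deltas[0]
    true_marg_y[dis_idx] = eta
    flip_y = rng.random(total_snps) < 0.5
    outcome = build_set("disease", "disease", true_marg_y, se_out, cfg.n_out, flip_y)

    truth = SimulationTruth(
        exposure_snps=tuple(ids[taxa_idx[0]]),
        mediator_snps=tuple(ids[metab_idx[0]]),
        gamma=gammas[0],
        delta=deltas[0],
        alpha=alpha,
        maf_exposure=maf[taxa_idx[0]],
        maf_mediator=maf[metab_idx[0]],
        a_true=cfg.a_true,
        b_true=cfg.b_true,
        c_prime_true=cfg.c_prime_true,
        seed=use_seed,
    )
    return StudyData(
        taxa=taxa_sets,
        metabolites=metab_sets,
        outcome=outcome,
        ld=_build_ld(ids, cfg),
        truth=truth,
        true_taxon=taxa_sets[0].trait_id,
        true_mediator=metab_sets[0].trait_id,
        reverse_taxa=tuple(taxa_sets[i].trait_id for i in spec.reverse_taxa),
    )


# ---------------------------------------------------------------------------
# Reference fixtures from the published two-step MR study of gut microbiota,
# plasma metabolites and Crohn disease that this package's design follows.
# Used as worked examples and consistency checks, not as data to refit.
# ---------------------------------------------------------------------------

#: Reported mediation table: 15 plasma metabolites mediating the effect of
#: genus Ruminococcaceae UCG013 on Crohn disease. ``proportion_pct`` is NaN
#: where the source suppressed the proportion (all four such rows have a
#: negative mediation beta).
_TABLE_ROWS = [
    ("Carnitine levels", 0.0128, -0.0214, 0.0470, 13.34),
    ("Isovalerate (i5:0) levels", 0.0003, -0.0520, 0.0526, 0.33),
    ("2-Hydroxyoctanoate levels", -0.0099, -0.0308, 0.0109, None),
    ("6-Hydroxyindole sulfate levels", 0.0039, -0.0860, 0.0939, 4.15),
    ("Heptenedioate (C7:1-DC) levels", 0.0288, -0.0730, 0.1307, 30.10),
    ("4-Methylhexanoylglutamine levels", -0.0380, -0.1035, 0.0274, None),
    ("Uridine levels", 0.0076, -0.0585, 0.0739, 8.00),
    ("X-13866 levels", -0.0140, -0.0625, 0.0345, None),
    ("X-17354 levels", 0.0167, -0.0418, 0.0752, 17.42),
    ("X-18345 levels", 0.0115, -0.0097, 0.0328, 12.07),
    ("X-22834 levels", -0.0173, -0.0672, 0.0325, None),
    ("X-25519 levels", 0.0351, -0.0301, 0.1004, 36.69),
    ("Serine to pyruvate ratio", 0.0111, -0.1114, 0.1337, 11.59),
    ("Uridine to 2'-deoxyuridine ratio", 0.0003, -0.0354, 0.0361, 0.36),
    ("Histidine to glutamine ratio", 0.0055, -0.0434, 0.0545, 5.81),
]


def make_table1_fixture() -> pd.DataFrame:
    """Reference mediation table (15 mediator rows) for consistency tests.

    Columns: mediator, indirect_beta, ci_low, ci_high, proportion_pct (NaN
    where suppressed), suppressed.
    """
    df = pd.DataFrame(
        _TABLE_ROWS,
        columns=["mediator", "indirect_beta", "ci_low", "ci_high", "proportion_pct"],
    )
    df["proportion_pct"] = df["proportion_pct"].astype(float)
    df["suppressed"] = df["proportion_pct"].isna()
    return df


#: Reported OR (95% CI, printed p) worked examples: forward taxon->disease
#: estimates, one step-1 taxon->metabolite estimate and one step-2
#: metabolite->disease estimate for the carnitine pathway.
_OR_ROWS = [
    ("Subdoligranulum", "Crohn disease", "forward", 0.65, 0.441, 0.959, 0.029),
    ("Adlercreutzia", "Crohn disease", "forward", 1.43, 1.047, 1.948, 0.024),
    ("Ruminiclostridium UCG013", "Crohn disease", "forward", 0.60, 0.413, 0.883, 0.009),
    ("Ruminococcus torques group", "Crohn disease", "forward", 0.45, 0.280, 0.731, 0.001),
    ("Eisenbergiella", "Crohn disease", "forward", 0.77, 0.623, 0.951, 0.015),
    ("Ruminococcaceae UCG013", "Carnitine levels", "step1", 0.89, 0.823, 0.979, 0.015),
    ("Carnitine levels", "Crohn disease", "step2", 0.79, 0.684, 0.914, 0.001),
]


def reference_or_estimates() -> pd.DataFrame:
    """Published OR/CI/p triplets used as worked examples for the
    beta<->OR conversion utilities."""
    return pd.DataFrame(
        _OR_ROWS,
        columns=["exposure", "outcome", "step", "odds_ratio", "ci_low", "ci_high", "pval_printed"],
    )
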