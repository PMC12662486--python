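"""Study orchestration: forward screen, reverse-MR exclusion, mediation scan.

The full design mirrors a microbiome -> metabolome -> disease screening
study:

1. **Forward screen** — every taxon is tested as an exposure against the
   disease (select instruments, clump, harmonize, IVW primary with Egger
   and weighted-median complements, sensitivity battery).
2. **Reverse screen** — the disease is used as the exposure against every
   taxon; taxa with a significant reverse estimate are flagged
   bidirectional and excluded (their forward estimate may be confounded by
   reverse causation).
3. **Mediation scan** — for each carried-forward taxon, every candidate
   metabolite is tested as a mediator by two-step MR and the mediated
   proportion decomposed.

``run_full_study`` drives all three from a YAML/dict configuration (either
named summary-statistics files or a simulation block) and writes TSV/JSON
reports plus a run manifest, so a study is a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .harmonize import HarmonizeConfig, harmonize, harmonization_log, usable_pairs
from .instruments import LDReference, SelectionConfig, clump, select_by_pvalue
from .mediation import (
    MediationResult,
    MediationScanConfig,
    mediation_frame,
    mediation_scan,
    total_effect,
)
from .mr_core import EstimatorError, MREstimate, estimate_all, estimates_frame
from .sensitivity import sensitivity_report
from .sumstats import Dialect, SummaryStatSet, read_sumstats
from .synthetic import SimulationConfig, StudySimSpec, simulate_study

logger = logging.getLogger("mrmediate")


class ConfigError(Exception):
    """Malformed study configuration (raised before any computation)."""


@dataclass(frozen=True)
class ScreenResult:
    """Bidirectionality status of one exposure."""

    exposure_id: str
    forward: Optional[MREstimate]
    reverse: Optional[MREstimate]
    bidirectional_flag: bool
    carried_forward: bool


@dataclass
class StudyConfig:
    """Validated study configuration."""

    selection: SelectionConfig = SelectionConfig()
    harmonization: HarmonizeConfig = HarmonizeConfig()
    alpha: float = 0.05
    suppression_rule: str = "footnote"
    ivw_model: str = "random"
    n_sim: int = 1000
    n_boot: int = 500
    seed: int = 0
    run_sensitivity: bool = True
    simulation: Optional[StudySimSpec] = None
    data_files: Optional[dict] = None

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        if not isinstance(raw, dict):
            raise ConfigError("study config must be a mapping")
        known = {
            "selection",
            "harmonization",
            "alpha",
            "suppression_rule",
            "ivw_model",
            "n_sim",
            "n_boot",
            "seed",
            "run_sensitivity",
            "simulation",
            "data",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            selection = SelectionConfig(**raw.get("selection", {}))
            harmonization = HarmonizeConfig(**raw.get("harmonization", {}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        alpha = float(raw.get("alpha", 0.05))
        if not (0.0 < alpha <= 1.0):
            raise ConfigError(f"alpha must be in (0, 1], got {alpha}")
        rule = raw.get("suppression_rule", "footnote")
        if rule not in ("footnote", "negative_only"):
            raise ConfigError(f"unknown suppression_rule {rule!r}")
        sim = None
        if "simulation" in raw:
            sim_raw = dict(raw["simulation"] or {})
            base = sim_raw.pop("base", {})
            try:
                sim = StudySimSpec(base=SimulationConfig(**base), **sim_raw)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid simulation block: {exc}") from exc
        data = raw.get("data")
        if data is not None:
            for key in ("taxa", "metabolites", "outcome"):
                if key not in data:
                    raise ConfigError(f"data block missing {key!r}")
        if sim is None and data is None:
            raise ConfigError("config needs either a 'simulation' or a 'data' block")
        if sim is not None and data is not None:
            raise ConfigError("'simulation' and 'data' blocks are mutually exclusive")
        return cls(
            selection=selection,
            harmonization=harmonization,
            alpha=alpha,
            suppression_rule=rule,
            ivw_model=raw.get("ivw_model", "random"),
            n_sim=int(raw.get("n_sim", 1000)),
            n_boot=int(raw.get("n_boot", 500)),
            seed=int(raw.get("seed", 0)),
            run_sensitivity=bool(raw.get("run_sensitivity", True)),
            simulation=sim,
            data_files=data,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})


def _prepare_instruments(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    config: StudyConfig,
    ld: Optional[LDReference],
):
    """select -> clump -> harmonize; returns (usable pairs, all pairs, counts)."""
    selected = select_by_pvalue(exposure, config.selection)
    n_selected = len(selected)
    if ld is not None and n_selected:
        selected = clump(selected, ld, config.selection)
    n_clumped = len(selected)
    pairs = harmonize(selected, outcome, config.harmonization) if n_clumped else []
    use = usable_pairs(pairs)
    counts = {
        "selected": n_selected,
        "clumped": n_clumped,
        "harmonized": len(use),
        "dropped": len(pairs) - len(use),
    }
    return use, pairs, counts


def screen_one(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    config: StudyConfig,
    ld: Optional[LDReference] = None,
) -> tuple[Optional[MREstimate], list, dict]:
    """One exposure -> outcome analysis; (IVW-primary estimate, pairs, counts).

    Returns (None, [], counts) when no instruments survive — recorded as
    not-analyzable, never fatal.
    """
    use, _, counts = _prepare_instruments(exposure, outcome, config, ld)
    if not use:
        return None, [], counts
    try:
        primary = total_effect(use, model=config.ivw_model)
    except EstimatorError:
        return None, [], counts
    return primary, use, counts


def run_forward_screen(
    exposures: Sequence[SummaryStatSet],
    outcome: SummaryStatSet,
    config: StudyConfig,
    ld: Optional[LDReference] = None,
) -> tuple[pd.DataFrame, dict[str, MREstimate], dict[str, list]]:
    """Screen every exposure against the outcome.

    Returns the estimate table (one row per exposure x method), the primary
    (IVW) estimate per analyzable exposure, and the retained harmonized
    pairs per exposure for downstream sensitivity analyses.
    """
    frames = []
    primaries: dict[str, MREstimate] = {}
    kept_pairs: dict[str, list] = {}
    for exposure in exposures:
        primary, use, counts = screen_one(exposure, outcome, config, ld)
        logger.info(
            "forward %s: selected=%d clumped=%d harmonized=%d dropped=%d",
            exposure.trait_id, counts["selected"], counts["clumped"],
            counts["harmonized"], counts["dropped"],
        )
        if primary is None:
            continue
        primaries[exposure.trait_id] = primary
        kept_pairs[exposure.trait_id] = use
        ests = (
            estimate_all(use, ivw_model=config.ivw_model, n_boot=config.n_boot,
                         seed=config.seed)
            if len(use) >= 3
            else [primary]
        )
        frames.append(estimates_frame(ests, exposure=exposure.trait_id,
                                      outcome=outcome.trait_id))
    table = pd.concat(frames, ignore_index=True) if frames else estimates_frame([])
    return table, primaries, kept_pairs


def run_reverse_screen(
    outcome_as_exposure: SummaryStatSet,
    taxa: Sequence[SummaryStatSet],
    config: StudyConfig,
    ld: Optional[LDReference] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """MR with the disease as exposure and each taxon as outcome.

    Taxa whose reverse estimate is significant at alpha are returned as the
    exclusion list (bidirectional relationships are dropped from mediation).
    The disease's instruments are selected at the same p-threshold as the
    forward direction.
    """
    rows = []
    excluded: list[str] = []
    estimates: dict[str, MREstimate] = {}
    selected = select_by_pvalue(outcome_as_exposure, config.selection)
    if ld is not None and len(selected):
        selected = clump(selected, ld, config.selection)
    for taxon in taxa:
        if not len(selected):
            continue
        use = usable_pairs(harmonize(selected, taxon, config.harmonization))
        if not use:
            continue
        try:
            est = total_effect(use, model=config.ivw_model)
        except EstimatorError:
            continue
        estimates[taxon.trait_id] = est
        rows.append(
            {
                "exposure": outcome_as_exposure.trait_id,
                "outcome": taxon.trait_id,
                "n_snp": est.n_snp,
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
            }
        )
        if est.pval < config.alpha:
            excluded.append(taxon.trait_id)
    table = pd.DataFrame(rows, columns=["exposure", "outcome", "n_snp", "beta", "se", "pval"])
    table.attrs["estimates"] = estimates
    return table, excluded


def screen(
    taxa: Sequence[SummaryStatSet],
    outcome: SummaryStatSet,
    config: StudyConfig,
    ld: Optional[LDReference] = None,
) -> list[ScreenResult]:
    """Combined forward + reverse screen with carried-forward flags."""
    _, primaries, _ = run_forward_screen(taxa, outcome, config, ld)
    reverse_table, excluded = run_reverse_screen(outcome, taxa, config, ld)
    reverse_estimates = reverse_table.attrs.get("estimates", {})
    results = []
    for taxon in taxa:
        fwd = primaries.get(taxon.trait_id)
        rev_sig = taxon.trait_id in excluded
        fwd_sig = fwd is not None and fwd.pval < config.alpha
        results.append(
            ScreenResult(
                exposure_id=taxon.trait_id,
                forward=fwd,
                reverse=reverse_estimates.get(taxon.trait_id),
                bidirectional_flag=fwd_sig and rev_sig,
                carried_forward=fwd_sig and not rev_sig,
            )
        )
    return results


def _manifest(config: StudyConfig, seed: int) -> dict:
    canon = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return {
        "package": "mrmediate",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(canon.encode()).hexdigest(),
    }


def _load_data_files(config: StudyConfig):
    data = config.data_files
    dialect = Dialect(**data.get("dialect", {})) if data.get("dialect") else Dialect()
    taxa = [
        read_sumstats(p, dialect=dialect, trait_type="microbiota")
        for p in data["taxa"]
    ]
    metabolites = [
        read_sumstats(p, dialect=dialect, trait_type="metabolite")
        for p in data["metabolites"]
    ]
    outcome = read_sumstats(data["outcome"], dialect=dialect, trait_type="disease")
    ld = None
    if data.get("ld_coords"):
        ld = LDReference.from_files(data["ld_coords"], data.get("ld_matrix"))
    return taxa, metabolites, outcome, ld, None


def run_full_study(
    config: StudyConfig | dict | str | Path,
    seed: Optional[int] = None,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Execute forward screen -> reverse exclusion -> mediation scan.

    Returns a report bundle (tables and metadata); when ``out_dir`` is given
    the bundle is also written as TSV/JSON files.
    """
    if isinstance(config, (str, Path)):
        config = StudyConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = StudyConfig.from_dict(config)
    use_seed = config.seed if seed is None else seed

    truth_info = None
    if config.simulation is not None:
        study = simulate_study(config.simulation, seed=use_seed)
        taxa, metabolites, outcome, ld = (
            study.taxa, study.metabolites, study.outcome, study.ld,
        )
        truth_info = {
            "true_taxon": study.true_taxon,
            "true_mediator": study.true_mediator,
            "c_true": study.truth.c_true,
            "proportion_true_pct": study.truth.proportion_true,
            "reverse_taxa": list(study.reverse_taxa),
        }
    else:
        taxa, metabolites, outcome, ld, _ = _load_data_files(config)

    forward_table, primaries, kept_pairs = run_forward_screen(taxa, outcome, config, ld)
    reverse_table, excluded = run_reverse_screen(outcome, taxa, config, ld)

    screen_rows = []
    for taxon in taxa:
        fwd = primaries.get(taxon.trait_id)
        fwd_sig = fwd is not None and fwd.pval < config.alpha
        rev_sig = taxon.trait_id in excluded
        screen_rows.append(
            {
                "exposure": taxon.trait_id,
                "analyzable": fwd is not None,
                "forward_pval": None if fwd is None else fwd.pval,
                "forward_significant": fwd_sig,
                "reverse_significant": rev_sig,
                "bidirectional": fwd_sig and rev_sig,
                "carried_forward": fwd_sig and not rev_sig,
            }
        )
    screen_table = pd.DataFrame(screen_rows)

    scan_config = MediationScanConfig(
        selection=config.selection,
        harmonization=config.harmonization,
        alpha=config.alpha,
        rule=config.suppression_rule,
        ivw_model=config.ivw_model,
    )
    mediation_results: list[MediationResult] = []
    for taxon in taxa:
        if not screen_table.loc[
            screen_table["exposure"] == taxon.trait_id, "carried_forward"
        ].any():
            continue
        mediation_results.extend(
            mediation_scan(
                taxon,
                metabolites,
                outcome,
                config=scan_config,
                ld=ld,
                c=primaries[taxon.trait_id],
            )
        )
    mediation_table = mediation_frame(mediation_results)
    mediation_table.insert(0, "exposure", [r.exposure_id for r in mediation_results])

    sensitivity_tables = {}
    harmonization_logs = {}
    if config.run_sensitivity:
        for trait_id, use in kept_pairs.items():
            if len(use) >= 2:
                sensitivity_tables[trait_id] = sensitivity_report(
                    use, n_sim=config.n_sim, seed=use_seed
                )
            harmonization_logs[trait_id] = harmonization_log(use)

    bundle = {
        "manifest": _manifest(config, use_seed),
        "forward": forward_table,
        "reverse": reverse_table,
        "screen": screen_table,
        "mediation": mediation_table,
        "sensitivity": sensitivity_tables,
        "harmonization": harmonization_logs,
        "mediation_results": mediation_results,
        "truth": truth_info,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["forward"].to_csv(out_dir / "forward_estimates.tsv", sep="\t", index=False)
    bundle["reverse"].to_csv(out_dir / "reverse_estimates.tsv", sep="\t", index=False)
    bundle["screen"].to_csv(out_dir / "screen.tsv", sep="\t", index=False)
    bundle["mediation"].to_csv(out_dir / "mediation.tsv", sep="\t", index=False)
    if bundle["sensitivity"]:
        pd.concat(
            bundle["sensitivity"], names=["exposure", "row"]
        ).reset_index(level=0).to_csv(out_dir / "sensitivity.tsv", sep="\t", index=False)
    if bundle["harmonization"]:
        pd.concat(
            bundle["harmonization"], names=["exposure", "row"]
        ).reset_index(level=0).to_csv(
            out_dir / "harmonization_log.tsv", sep="\t", index=False
        )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
    if bundle["truth"] is not None:
        with open(out_dir / "simulation_truth.json", "w") as fh:
            json.dump(bundle["truth"], fh, indent=2, sort_keys=True)
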