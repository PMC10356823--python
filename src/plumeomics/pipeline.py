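"""End-to-end orchestration with one configuration and reproducible seeds.

Stages run in dependency order: geochemistry feeds the energy-attribution and
network-complexity stages; the population-genetics stage feeds the sweep
screens; the synthetic-data stage runs only in demo mode, where it fabricates
every input from the configured seed.  Each stage writes plain TSV outputs
into the run directory, and a machine-readable ``summary.json`` records the
package version, seed, parameters, per-stage record counts, and SHA-256
checksums of every output file (no timestamps, so identical configurations
produce identical summaries).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (__version__, coremicrobiome, geochem, growthrate, metaconnect,
               microdiv, netcomplexity, omics_energy, synthio)

logger = logging.getLogger("plumeomics")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


ALL_STAGES = ("synth", "energy", "attribute", "connect", "complexity",
              "popgen", "growth", "core")


@dataclass
class PipelineConfig:
    outdir: str = "plume_run"
    seed: int = 42
    demo: bool = True
    stages: tuple[str, ...] = ALL_STAGES
    # geochem / energy
    profile: str = "sulfide-rich"
    temperatures: tuple[float, ...] = (3.0, 4.9)
    biomass_yield: float = 1.0e4
    rho: float | None = None            # default: from the mixture state
    # metaconnect / netcomplexity
    block_size: int = 4
    # microdiv
    min_cov: int = 5
    min_freq: float = 0.05
    min_count: int = 2
    sigma: float = 2.5
    # coremicrobiome
    prevalence_min: float = 0.66
    abundance_min: float = 0.01
    # non-demo inputs
    fluid_path: str | None = None
    seawater_path: str | None = None
    allele_matrix_path: str | None = None
    gene_models_path: str | None = None
    reference_fasta_path: str | None = None
    coverage_track_path: str | None = None
    function_table_path: str | None = None
    gene_weights_path: str | None = None
    abundance_table_path: str | None = None

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if not 0.0 <= self.prevalence_min <= 1.0:
            raise ConfigError("prevalence_min outside [0, 1]")
        if not 0.0 <= self.abundance_min <= 1.0:
            raise ConfigError("abundance_min outside [0, 1]")
        if self.rho is not None and not 0.0 <= self.rho <= 1.0:
            raise ConfigError("rho outside [0, 1]")
        if self.block_size not in (2, 3, 4):
            raise ConfigError("block_size must be 2, 3, or 4")
        if not self.demo:
            for name in ("fluid_path", "seawater_path", "allele_matrix_path",
                         "gene_models_path", "reference_fasta_path",
                         "coverage_track_path", "function_table_path",
                         "gene_weights_path", "abundance_table_path"):
                value = getattr(self, name)
                if value is not None and not Path(value).exists():
                    raise ConfigError(f"{name}: file not found: {value}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the summary dictionary.

    Any stage failure raises :class:`StageError` with the stage name; outputs
    of completed stages are preserved in the run directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    counts: dict[str, int] = {}
    state: dict = {}
    try:
        for stage in ALL_STAGES:
            if stage not in config.stages:
                continue
            logger.info("stage %s starting", stage)
            try:
                n = _STAGE_FUNCS[stage](config, outdir, state)
            except Exception as exc:
                logger.error("stage %s failed: %s", stage, exc)
                raise StageError(stage, exc) from exc
            counts[stage] = n
            logger.info("stage %s done (%d records)", stage, n)
    finally:
        logger.removeHandler(handler)
        handler.close()

    checksums = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name not in ("summary.json", "run.log")
    }
    summary = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()
                       if not k.endswith("_path") and k != "outdir"},
        "stage_record_counts": counts,
        "checksums": checksums,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


# ---------------------------------------------------------------------------
# stages


def _stage_synth(config: PipelineConfig, outdir: Path, state: dict) -> int:
    if not config.demo:
        return 0
    indir = outdir / "inputs"
    indir.mkdir(exist_ok=True)
    scenario = synthio.SyntheticScenario(seed=config.seed)
    state["scenario"] = scenario

    pileups = synthio.generate_two_population_pileups(scenario)
    state["pileups"] = pileups
    synthio.write_allele_matrix(pileups.matrix, indir / "allele_matrix.tsv")
    microdiv.write_gene_models(pileups.genes, indir / "gene_models.tsv")
    synthio.write_truth_table(pileups.truth, indir / "sweep_truth.tsv")
    synthio.write_fasta({synthio.CONTIG_NAME: pileups.reference},
                        indir / "reference.fasta")

    track = synthio.generate_coverage_track(
        genome_length=100_000, oriter_ratio=scenario.oriter_ratio,
        depth=scenario.depth_mean, noise_cv=0.05, seed=scenario.seed + 2)
    state["track"] = track
    growthrate.write_coverage_track(track, indir / "coverage_track.tsv")

    vent, sw = synthio.generate_vent_chemistry(config.profile)
    state["vent"], state["seawater"] = vent, sw
    geochem.write_chemistry(vent, indir / "endmember_fluid.tsv")
    geochem.write_chemistry(sw, indir / "seawater.tsv")

    ftable = synthio.generate_function_table(scenario)
    state["function_table"] = ftable
    metaconnect.write_function_table(ftable, indir / "function_table.tsv")

    weights = synthio.generate_gene_weight_table(ftable, seed=scenario.seed + 3)
    state["gene_weights"] = weights
    omics_energy.write_gene_weights(weights, indir / "gene_weights.tsv")

    core_spec = [(1.0, 0.05), (0.9, 0.03), (0.8, 0.02), (0.5, 0.05)]
    abund = synthio.generate_abundance_table(
        n_plume=12, n_background=4, n_genera=20, core_spec=core_spec,
        seed=scenario.seed + 4)
    state["abundance_table"] = abund
    coremicrobiome.write_abundance_table(abund, indir / "abundance_table.tsv")
    state["mag_taxonomy"] = {mag: f"genus_{i + 1:02d}"
                             for i, mag in enumerate(ftable.mags)}
    return len(pileups.matrix)


def _stage_energy(config: PipelineConfig, outdir: Path, state: dict) -> int:
    if "vent" not in state:
        state["vent"] = geochem.read_chemistry(config.fluid_path)
        state["seawater"] = geochem.read_chemistry(config.seawater_path)
        state["seawater"] = geochem.SeawaterComposition(
            concentrations=state["seawater"].concentrations,
            temperature=state["seawater"].temperature)
    vent, sw = state["vent"], state["seawater"]
    reactions = geochem.default_reactions()
    state["reactions"] = reactions
    n = 0
    landscapes = {}
    for t in config.temperatures:
        f = (t - sw.temperature) / (vent.temperature - sw.temperature)
        mix = geochem.mix_fluids(vent, sw, f)
        scape = geochem.energy_landscape(reactions, mix,
                                         biomass_yield=config.biomass_yield)
        landscapes[t] = scape
        state.setdefault("mixtures", {})[t] = mix
        geochem.write_landscape(scape, outdir / f"energy_T{t:g}.tsv")
        n += len(scape.table)
    state["landscapes"] = landscapes
    return n


def _stage_attribute(config: PipelineConfig, outdir: Path, state: dict) -> int:
    if "gene_weights" not in state:
        state["gene_weights"] = omics_energy.read_gene_weights(config.gene_weights_path)
    weights = state["gene_weights"]
    reactions = state.get("reactions", geochem.default_reactions())
    t0 = config.temperatures[0]
    scape = state["landscapes"][t0]
    contrib = omics_energy.donor_energy_contribution(
        weights, scape, reactions, basis="metagenome")
    omics_energy.write_donor_contribution(contrib, outdir / "donor_contribution.tsv")

    rho = config.rho
    if rho is None:
        rho = omics_energy.rho_from_state(state["mixtures"][t0])
    adjusted = omics_energy.acceptor_adjusted_contribution(
        weights, scape, scape, reactions, rho=rho, basis="metagenome")
    omics_energy.write_donor_contribution(
        adjusted, outdir / "donor_contribution_acceptor_adjusted.tsv")

    taxonomy = state.get("mag_taxonomy", {})
    top_function = weights.groupby("function")["coverage"].sum().idxmax()
    taxa = omics_energy.taxon_function_contribution(
        weights, taxonomy, top_function)
    taxa.insert(0, "function", top_function)
    from ._tsv import write_tsv
    write_tsv(taxa, outdir / "taxon_contribution.tsv")
    return len(contrib.percents) + len(adjusted.percents) + len(taxa)


def _stage_connect(config: PipelineConfig, outdir: Path, state: dict) -> int:
    if "function_table" not in state:
        state["function_table"] = metaconnect.read_function_table(
            config.function_table_path)
    table = state["function_table"]
    scores = metaconnect.compute_mw_scores(table)
    from ._tsv import write_tsv
    write_tsv(scores, outdir / "mw_scores.tsv")
    network = metaconnect.build_functional_network(table)
    metaconnect.write_edge_list(network, outdir / "functional_network_edges.tsv")
    metaconnect.write_graphml(network, outdir / "functional_network.graphml")
    return len(scores)


def _stage_complexity(config: PipelineConfig, outdir: Path, state: dict) -> int:
    reactions = state.get("reactions", geochem.default_reactions())
    t0 = config.temperatures[0]
    scape = state["landscapes"][t0]
    network = netcomplexity.build_reaction_network(reactions, scape)
    report = netcomplexity.node_delta_complexity(network,
                                                 block_size=config.block_size)
    netcomplexity.write_network(network, outdir / "reaction_network_edges.tsv")
    netcomplexity.write_report(report, outdir / "complexity_report.tsv")
    return len(report.table)


def _stage_popgen(config: PipelineConfig, outdir: Path, state: dict) -> int:
    if "pileups" in state:
        pileups = state["pileups"]
        matrix, genes = pileups.matrix, pileups.genes
        reference = pileups.reference
        genome_length = state["scenario"].genome_length
    else:
        matrix = synthio.read_allele_matrix(config.allele_matrix_path)
        genes = microdiv.read_gene_models(config.gene_models_path)
        reference = next(iter(synthio.read_fasta(config.reference_fasta_path).values()))
        genome_length = len(reference)
    callset, fst, stats1, stats2 = microdiv.run_sweep_screens(
        matrix, genes, reference, genome_length,
        min_cov=config.min_cov, min_freq=config.min_freq,
        min_count=config.min_count, sigma=config.sigma)
    from ._tsv import write_tsv
    write_tsv(fst.per_gene, outdir / "gene_fst.tsv")
    write_tsv(stats1, outdir / "gene_stats_env1.tsv")
    write_tsv(stats2, outdir / "gene_stats_env2.tsv")
    write_tsv(callset.high_fst, outdir / "sweep_calls_high_fst.tsv")
    write_tsv(callset.sulfur_fixed, outdir / "sweep_calls_sulfur.tsv")
    for group in ("env1", "env2"):
        profile = microdiv.profile_genome(matrix, genes, group, reference,
                                          genome_length,
                                          min_cov=config.min_cov,
                                          min_freq=config.min_freq,
                                          min_count=config.min_count)
        write_tsv(pd.DataFrame([vars(profile)]),
                  outdir / f"genome_profile_{group}.tsv")
    state["callset"], state["fst"] = callset, fst
    return len(callset.high_fst) + len(callset.sulfur_fixed)


def _stage_growth(config: PipelineConfig, outdir: Path, state: dict) -> int:
    if "track" not in state:
        state["track"] = growthrate.read_coverage_track(config.coverage_track_path)
    est = growthrate.estimate_irep(state["track"])
    from ._tsv import write_tsv
    write_tsv(pd.DataFrame([vars(est)]), outdir / "growth_estimate.tsv")
    state["growth"] = est
    return 1


def _stage_core(config: PipelineConfig, outdir: Path, state: dict) -> int:
    if "abundance_table" not in state:
        state["abundance_table"] = coremicrobiome.read_abundance_table(
            config.abundance_table_path)
    table = state["abundance_table"]
    core = coremicrobiome.identify_core_taxa(
        table, prevalence_min=config.prevalence_min,
        abundance_min=config.abundance_min)
    coremicrobiome.write_core(core, outdir / "core_taxa.tsv")
    if "function_table" in state and "mag_taxonomy" in state:
        traits = coremicrobiome.profile_core_metabolism(
            core, state["mag_taxonomy"], state["function_table"])
        from ._tsv import write_tsv
        write_tsv(traits, outdir / "core_trait_profile.tsv")
    state["core"] = core
    return len(core.table)


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "energy": _stage_energy,
    "attribute": _stage_attribute,
    "connect": _stage_connect,
    "complexity": _stage_complexity,
    "popgen": _stage_popgen,
    "growth": _stage_growth,
    "core": _stage_core,
}
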