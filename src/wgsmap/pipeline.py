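"""Run configuration, closed-loop simulation, and analysis dispatch.

This module ties the cross simulator, read simulator and mapping
analysis into reproducible end-to-end runs. A :class:`RunConfig`
(usually loaded from YAML) fully determines a simulated experiment;
``simulate_run`` writes pool VCFs plus a truth table, and
``analyze_run`` / ``map_design`` re-reads those files and calls the
interval-detection procedure appropriate to the cross design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cross_sim import (
    CrossDesign,
    MAPPING_LABEL,
    MarkerSpec,
    MUTANT_LABEL,
    MutationSpec,
    PoolSample,
    f2_generator,
    f3_homozygote_screen,
    phenotype_of,
    pool_genotype_table,
    select_f2_pool,
)
from .errors import MapStructureError, PoolExhaustionError, UnsupportedDesignError
from .genome import ChromosomeMap, DiploidGenome, GeneticMap
from .mapping import (
    MappingInterval,
    VariantCallSet,
    binned_homozygous_frequency,
    call_variants,
    candidate_variants,
    detect_cluster_interval,
    detect_gap_interval,
    detect_peak_interval,
    filter_homozygous,
    fit_loess,
    frequency_floor_filter,
    reciprocal_interval,
    snp_frequency_series,
    subtract_background,
)
from .readsim import (
    AlleleCountTable,
    BackgroundVariantSet,
    CoverageModel,
    SNPPanel,
    detection_limit,
    read_pool_vcf,
    simulate_background,
    simulate_counts,
    simulate_panel,
    write_pool_vcf,
)

__all__ = [
    "AnalysisParams",
    "RunConfig",
    "RunReport",
    "load_config",
    "build_pool",
    "simulate_run",
    "analyze_run",
    "map_design",
    "tiny_genetic_map",
]


def tiny_genetic_map(n_chromosomes: int = 3, length_bp: int = 2_000_000,
                     length_cm: float = 50.0) -> GeneticMap:
    """A miniature genome for fixtures and fast closed-loop tests."""
    names = ["I", "II", "III", "IV", "V", "X"][:n_chromosomes]
    return GeneticMap(tuple(
        ChromosomeMap(n, length_bp, length_cm) for n in names
    ))


@dataclass
class AnalysisParams:
    """Thresholds of the mapping analysis; defaults mirror the pipeline
    the designs were validated with."""

    min_reads: int = 3
    floor: float | None = None  # None: detection limit of the observed depth
    span: float = 0.1
    degree: int = 2
    grid_step: int = 10_000
    gap_threshold: float = 0.1
    bin_bp: int = 500_000
    hom_threshold: float = 0.95
    plateau_drop: float = 0.2
    hom_min_depth: int = 15
    hom_min_fraction: float = 0.8
    cluster_max_gap: float = 2e6
    cluster_min_members: int = 3
    reciprocal_threshold: float = 0.75
    reciprocal_span: float = 0.3


@dataclass
class RunConfig:
    """Everything needed to simulate and analyze one mapping run."""

    gmap: GeneticMap
    mutation: MutationSpec
    design: CrossDesign
    markers: MarkerSpec | None = None
    panel_density_per_bp: float = 0.001
    panel_file: str | None = None
    n_passengers: int = 40
    n_shared: int = 30
    coverage: CoverageModel = field(default_factory=CoverageModel)
    interference: str = "complete"
    seed: int = 0
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def validate(self) -> None:
        self.mutation.validate_on(self.gmap)
        if self.markers is not None:
            self.markers.validate_on(self.gmap, self.mutation)
        if self.design.is_marked and self.markers is None:
            raise MapStructureError(f"design {self.design.tag!r} requires markers")


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw, base_dir=Path(path).parent)


def config_from_dict(raw: dict, base_dir: Path | None = None) -> RunConfig:
    try:
        chroms = tuple(
            ChromosomeMap(str(c["name"]), int(c["length_bp"]), float(c["length_cm"]))
            for c in raw["genome"]["chromosomes"]
        )
        gmap = GeneticMap(chroms)
        mut_raw = raw["mutation"]
        mutation = MutationSpec(
            loci=tuple((str(l["chromosome"]), int(l["position"]))
                       for l in mut_raw["loci"]),
            dominance=mut_raw.get("dominance", "recessive"),
            interaction=mut_raw.get("interaction", "single"),
            penetrance=float(mut_raw.get("penetrance", 1.0)),
        )
        distortion = None
        if raw.get("distortion"):
            d = raw["distortion"]
            distortion = (str(d["chromosome"]), int(d["position"]), float(d["viability"]))
        design = CrossDesign(
            tag=raw["design"],
            pool_size=int(raw.get("pool_size", 50)),
            n_f3_per_f2=raw.get("n_f3_per_f2"),
            distortion=distortion,
        )
        markers = None
        if raw.get("markers"):
            markers = MarkerSpec(tuple(
                (str(m["chromosome"]), int(m["position"]), str(m["side"]))
                for m in raw["markers"]
            ))
        cov_raw = raw.get("coverage", {})
        coverage = CoverageModel(
            mean_depth=float(cov_raw.get("mean_depth", 25.0)),
            error_rate=float(cov_raw.get("error_rate", 0.002)),
            library_complexity=cov_raw.get("library_complexity"),
        )
        panel_raw = raw.get("panel", {})
        panel_file = panel_raw.get("file")
        if panel_file and base_dir is not None:
            p = Path(panel_file)
            if not p.is_absolute():
                panel_file = str(base_dir / p)
        ana = AnalysisParams(**raw.get("analysis", {}))
        cfg = RunConfig(
            gmap=gmap, mutation=mutation, design=design, markers=markers,
            panel_density_per_bp=float(panel_raw.get("density_per_kbp", 1.0)) / 1000.0,
            panel_file=panel_file,
            n_passengers=int(raw.get("background", {}).get("n_passengers", 40)),
            n_shared=int(raw.get("background", {}).get("n_shared", 30)),
            coverage=coverage,
            interference=raw.get("interference", "complete"),
            seed=int(raw.get("seed", 0)),
            analysis=ana,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise MapStructureError(f"invalid run config: {exc}") from exc
    cfg.validate()
    if panel_file is not None and not Path(panel_file).exists():
        raise MapStructureError(f"panel file not found: {panel_file}")
    return cfg


# ---------------------------------------------------------------------------
# Pool construction per design
# ---------------------------------------------------------------------------

def build_pool(config: RunConfig, rng: np.random.Generator,
               markers: MarkerSpec | None = None,
               f2_stream=None) -> PoolSample:
    """Assemble the design's sequencing pool from a fresh F2 stream.

    For F3 designs the stream is screened individual by individual and
    only classified homozygotes enter the pool, as in the wet protocol.
    """
    design = config.design
    spec = config.mutation
    markers = markers if markers is not None else config.markers
    if f2_stream is None:
        f2_stream = f2_generator(
            config.gmap, config.interference,
            np.random.SeedSequence(int(rng.integers(0, 2**31))),
        )
    if design.tag in ("dominant_f3", "semidominant_f3"):
        # Pick phenotype-eligible F2s, screen each, keep the homozygotes.
        want = {"dominant_f3": ("mutant",),
                "semidominant_f3": ("mutant", "intermediate")}[design.tag]
        members = []
        attempts = 0
        cap = int(np.ceil(100 * design.pool_size / 0.25))
        for g in f2_stream:
            if len(members) >= design.pool_size:
                break
            attempts += 1
            if attempts > cap:
                raise PoolExhaustionError(
                    f"{design.tag}: {len(members)}/{design.pool_size} homozygotes "
                    f"after screening {attempts} F2s"
                )
            if phenotype_of(g, spec, rng) not in want:
                continue
            if f3_homozygote_screen(g, design.n_f3_per_f2, spec, config.gmap,
                                    rng, config.interference):
                members.append(g)
        return PoolSample(members, design, "F3-screened homozygous F2")
    return select_f2_pool(f2_stream, design, spec, markers, rng)


# ---------------------------------------------------------------------------
# Simulation to files
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRun:
    """In-memory products of one simulated experiment."""

    config: RunConfig
    panel: SNPPanel | None
    background: BackgroundVariantSet
    pools: dict[str, PoolSample]
    counts: dict[str, AlleleCountTable]


def _reference_count_table(background: BackgroundVariantSet,
                           panel: SNPPanel | None,
                           model: CoverageModel, gmap: GeneticMap,
                           label: str, rng) -> AlleleCountTable:
    """Counts for a homozygous single-strain sample (parental or wild type)."""
    genome = DiploidGenome.homozygous(gmap, label)
    design = CrossDesign(tag="recessive_hawaiian", pool_size=1)
    pool = PoolSample([genome], design, f"{label} strain sample")
    return simulate_counts(pool, panel, background, model, rng)


def simulate_run(config: RunConfig, rng=None) -> SimulatedRun:
    """Simulate every sequencing sample the design calls for."""
    config.validate()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    design = config.design
    needs_panel = not design.is_marked
    panel = None
    if needs_panel:
        if config.panel_file:
            panel = SNPPanel.from_tsv(config.panel_file)
        else:
            panel = simulate_panel(config.gmap, config.panel_density_per_bp,
                                   MAPPING_LABEL, rng)
    background = simulate_background(
        config.gmap, config.n_passengers, causative=config.mutation.loci,
        n_shared=config.n_shared if design.is_marked else 0,
        panel=panel, rng=rng,
    )
    pools: dict[str, PoolSample] = {}
    counts: dict[str, AlleleCountTable] = {}
    if design.tag == "marked_reciprocal":
        pools["pool_left"] = build_pool(config, rng, markers=config.markers.side("left"))
        pools["pool_right"] = build_pool(config, rng, markers=config.markers.side("right"))
    else:
        pools["pool"] = build_pool(config, rng)
    for name, pool in pools.items():
        counts[name] = simulate_counts(pool, panel, background, config.coverage, rng)
    if design.tag == "dominant_reverse":
        # Candidate identification needs the mutation-bearing parental strain.
        counts["parental"] = _reference_count_table(
            background, panel, config.coverage, config.gmap, MUTANT_LABEL, rng)
    if design.is_marked:
        # Wild-type comparison sample used for background subtraction.
        counts["reference"] = _reference_count_table(
            background, panel, config.coverage, config.gmap, MAPPING_LABEL, rng)
    return SimulatedRun(config, panel, background, pools, counts)


def write_run(sim: SimulatedRun, out_dir) -> dict[str, str]:
    """Write a simulated run's VCFs, panel, truth table and metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    lengths = sim.config.gmap.lengths_bp()
    for name, table in sim.counts.items():
        p = out / f"{name}.vcf"
        write_pool_vcf(table, name, p, contig_lengths=lengths)
        paths[name] = str(p)
    if sim.panel is not None:
        p = out / "panel.tsv"
        sim.panel.to_tsv(p)
        paths["panel"] = str(p)
    p = out / "background_truth.tsv"
    sim.background.to_tsv(p)
    paths["background_truth"] = str(p)
    truth_rows = [{"kind": "mutation", "chromosome": c, "position": pos}
                  for c, pos in sim.config.mutation.loci]
    if sim.config.markers is not None:
        truth_rows += [{"kind": f"marker_{side}", "chromosome": c, "position": pos}
                       for c, pos, side in sim.config.markers.markers]
    p = out / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(p, sep="\t", index=False)
    paths["truth"] = str(p)
    for name, pool in sim.pools.items():
        p = out / f"{name}_genotypes.tsv"
        pool_genotype_table(pool).to_csv(p, sep="\t", index=False)
        paths[f"{name}_genotypes"] = str(p)
    meta = {
        "seed": sim.config.seed,
        "design": sim.config.design.tag,
        "pool_size": sim.config.design.pool_size,
        "version": __version__,
        "chromosome_lengths": lengths,
        "coverage": asdict(sim.config.coverage),
    }
    p = out / "run_meta.json"
    p.write_text(json.dumps(meta, indent=2) + "\n")
    paths["meta"] = str(p)
    return paths


# ---------------------------------------------------------------------------
# Analysis dispatch
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Serializable summary of one mapping analysis."""

    design: str
    seed: int | None
    intervals: list[MappingInterval]
    thresholds: dict
    n_candidates: int
    candidates: pd.DataFrame | None = None
    version: str = __version__

    def to_json(self, path=None) -> str:
        payload = {
            "design": self.design,
            "seed": self.seed,
            "version": self.version,
            "thresholds": self.thresholds,
            "intervals": [iv.to_dict() for iv in self.intervals],
            "n_candidates": self.n_candidates,
        }
        text = json.dumps(payload, indent=2, default=float) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "RunReport":
        raw = json.loads(Path(path).read_text())
        return cls(
            design=raw["design"], seed=raw.get("seed"),
            intervals=[MappingInterval(**iv) for iv in raw["intervals"]],
            thresholds=raw["thresholds"], n_candidates=raw["n_candidates"],
            version=raw.get("version", "unknown"),
        )


GAP_DESIGNS = ("recessive_hawaiian", "dominant_f3", "semidominant_f3",
               "two_gene_hawaiian")


def _filtered_calls(counts: AlleleCountTable, params: AnalysisParams):
    calls = call_variants(counts, min_reads=params.min_reads)
    depth = counts.counts["depth"]
    floor = params.floor
    if floor is None:
        mean_depth = float(depth[depth > 0].mean()) if (depth > 0).any() else 1.0
        floor = detection_limit(max(mean_depth, 1.0))
    return frequency_floor_filter(calls, floor), floor


def map_design(design_tag: str, counts: dict[str, AlleleCountTable],
               panel: SNPPanel | None, lengths: dict[str, int],
               params: AnalysisParams | None = None, seed: int | None = None,
               effect_annotation: pd.DataFrame | None = None) -> RunReport:
    """Run the interval detection appropriate to a cross design.

    ``counts`` carries the design's samples under conventional keys:
    ``pool`` (all single-pool designs), ``pool_left``/``pool_right``
    (reciprocal), ``parental`` (reverse mapping) and ``reference``
    (marked designs). The returned report carries ranked intervals and
    the candidate-variant list from the top interval.
    """
    params = params or AnalysisParams()
    thresholds = asdict(params)
    if design_tag in GAP_DESIGNS:
        if panel is None:
            raise MapStructureError("gap designs require a SNP panel")
        calls, floor = _filtered_calls(counts["pool"], params)
        thresholds["floor"] = floor
        series = snp_frequency_series(calls, panel, lengths)
        curve = fit_loess(series, params.span, params.degree, params.grid_step)
        intervals = detect_gap_interval(series, curve, params.gap_threshold)
        novel = filter_homozygous(calls, params.hom_min_depth, params.hom_min_fraction)
        novel = VariantCallSet(
            novel.calls[novel.calls["site_class"] == "background"],
            novel.min_reads, novel.floor)
        cands = (candidate_variants(novel, intervals[0], effect_annotation)
                 if intervals else pd.DataFrame())
    elif design_tag == "dominant_reverse":
        if panel is None:
            raise MapStructureError("reverse mapping requires a SNP panel")
        calls, floor = _filtered_calls(counts["pool"], params)
        thresholds["floor"] = floor
        bins = binned_homozygous_frequency(calls, panel, lengths,
                                           params.bin_bp, params.hom_threshold)
        interval = detect_peak_interval(bins, params.plateau_drop)
        intervals = [interval]
        if "parental" not in counts:
            raise UnsupportedDesignError(
                "reverse mapping cannot list candidates without the "
                "mutation-bearing parental sample (key 'parental')"
            )
        par_calls, _ = _filtered_calls(counts["parental"], params)
        novel = filter_homozygous(par_calls, params.hom_min_depth,
                                  params.hom_min_fraction)
        novel = VariantCallSet(
            novel.calls[novel.calls["site_class"] == "background"],
            novel.min_reads, novel.floor)
        cands = candidate_variants(novel, interval, effect_annotation)
    elif design_tag in ("marked_single", "marked_reciprocal"):
        if "reference" not in counts:
            raise UnsupportedDesignError(
                "marked designs require the wild-type comparison sample "
                "(key 'reference') for background subtraction"
            )
        ref_calls, _ = _filtered_calls(counts["reference"], params)

        def novel_hom(key):
            calls, _ = _filtered_calls(counts[key], params)
            novel = subtract_background(calls, ref_calls)
            return filter_homozygous(novel, params.hom_min_depth,
                                     params.hom_min_fraction), calls

        if design_tag == "marked_single":
            hom, calls = novel_hom("pool")
            interval = detect_cluster_interval(hom, params.cluster_max_gap,
                                               params.cluster_min_members)
            intervals = [interval]
            cands = candidate_variants(hom, interval, effect_annotation)
        else:
            hom_a, calls_a = novel_hom("pool_left")
            hom_b, calls_b = novel_hom("pool_right")
            cl_a = detect_cluster_interval(hom_a, params.cluster_max_gap,
                                           params.cluster_min_members)
            cl_b = detect_cluster_interval(hom_b, params.cluster_max_gap,
                                           params.cluster_min_members)
            rec = reciprocal_interval(hom_a, hom_b, lengths,
                                      span=params.reciprocal_span,
                                      threshold=params.reciprocal_threshold,
                                      grid_step=params.grid_step,
                                      calls_a=calls_a, calls_b=calls_b)
            intervals = [rec, cl_a, cl_b]
            both = VariantCallSet(
                pd.concat([hom_a.calls, hom_b.calls]).drop_duplicates(
                    ["chromosome", "position", "alt"]).reset_index(drop=True),
                hom_a.min_reads, hom_a.floor)
            cands = candidate_variants(both, rec, effect_annotation)
    else:
        raise UnsupportedDesignError(f"unknown design tag {design_tag!r}")
    return RunReport(design=design_tag, seed=seed, intervals=intervals,
                     thresholds=thresholds, n_candidates=len(cands),
                     candidates=cands)


def analyze_run(sim: SimulatedRun,
                effect_annotation: pd.DataFrame | None = None) -> RunReport:
    """Closed loop: analyze a simulated run's count tables."""
    return map_design(sim.config.design.tag, sim.counts, sim.panel,
                      sim.config.gmap.lengths_bp(), sim.config.analysis,
                      seed=sim.config.seed, effect_annotation=effect_annotation)


def analyze_files(design_tag: str, vcf_paths: dict[str, str],
                  panel_path: str | None, lengths: dict[str, int],
                  params: AnalysisParams | None = None,
                  annotation_path: str | None = None) -> RunReport:
    """Analysis entry point from on-disk inputs (the CLI's `map`)."""
    counts = {name: read_pool_vcf(p) for name, p in vcf_paths.items()}
    panel = SNPPanel.from_tsv(panel_path) if panel_path else None
    annotation = (pd.read_csv(annotation_path, sep="\t", dtype={"chromosome": str})
                  if annotation_path else None)
    return map_design(design_tag, counts, panel, lengths, params,
                      effect_annotation=annotation)
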