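"""End-to-end pipeline: simulate/load -> QC -> scan -> collapse -> network.

One :class:`RunConfig` (TOML file or keyword construction) drives the whole
run; every stage writes its table under the output directory and the run
finishes with a JSON manifest echoing the config and reconciling row counts
across stage boundaries. Reruns with the same config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .collapse import (
    GenePairGI,
    collapse_to_gene_pairs,
    eligible_intergenic_pairs,
    map_snps_to_genes,
)
from .epistasis import scan_pairs
from .io import (
    GenotypeDataset,
    read_annotation_bed,
    read_plink,
    write_results_tsv,
)
from .network import (
    ThresholdSet,
    call_significant,
    classify_directions,
    hub_degrees,
    twofold_filter,
)
from .qc import PRESETS, QCReport, apply_qc
from .simulate import (
    PlantedInteraction,
    SimulationConfig,
    inject_artifacts,
    simulate_annotation,
    simulate_cohort,
    write_simulation,
)

logger = logging.getLogger("epinet")


@dataclass(frozen=True)
class RunConfig:
    out_dir: str = "epinet_run"
    seed: int = 0
    # input: either an existing PLINK prefix + annotation BED, or simulate
    input_prefix: str | None = None
    annotation: str | None = None
    simulate: SimulationConfig | None = None
    # stage toggles
    run_qc: bool = True
    run_scan: bool = True
    run_network: bool = True
    # stage parameters
    qc_preset: str = "imputed"
    qc_min_overlap: int = 50
    qc_ld_r2_max: float = 0.5
    screen_alpha: float = 1e-4
    alpha: float = 0.05
    m_tests: int | None = None  # None -> C(n_genes, 2) of the annotation
    nominal_p: float = 1e-5

    def __post_init__(self) -> None:
        if self.input_prefix is None and self.simulate is None:
            raise ValueError("config must give input_prefix or a [simulate] section")
        if self.qc_preset not in PRESETS:
            raise ValueError(f"unknown qc preset {self.qc_preset!r}; options: {sorted(PRESETS)}")


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Parse a TOML run configuration; unknown keys are rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim_raw = raw.pop("simulate", None)
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    sim = None
    if sim_raw is not None:
        planted_raw = sim_raw.pop("planted_interactions", [])
        unknown = set(sim_raw) - _SIM_KEYS
        if unknown:
            raise ValueError(f"unknown [simulate] keys: {sorted(unknown)}")
        if "maf_range" in sim_raw:
            sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
        planted = tuple(PlantedInteraction(**p) for p in planted_raw)
        sim = SimulationConfig(planted_interactions=planted, **sim_raw)
    return RunConfig(simulate=sim, **raw)


def _config_echo(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.simulate is not None:
        d["simulate"]["planted_interactions"] = [
            dataclasses.asdict(p) for p in config.simulate.planted_interactions
        ]
        d["simulate"]["maf_range"] = list(config.simulate.maf_range)
    return d


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, seconds: float, **counts) -> None:
        self.stages.append({"stage": name, "wall_seconds": round(seconds, 3), **counts})

    def write(self, path: Path) -> None:
        path.write_text(json.dumps({"config": self.config, "version": self.version,
                                    "stages": self.stages}, indent=1))


def _qc_report_rows(report: QCReport):
    @dataclass
    class Row:
        step: str
        removed_variants: int
        removed_samples: int
        removed_ids: str

    rows = []
    for s in report.steps:
        ids = sorted(s["removed_variant_ids"]) + sorted(s["removed_sample_ids"])
        rows.append(Row(s["step"], len(s["removed_variant_ids"]),
                        len(s["removed_sample_ids"]), ",".join(ids) or "none"))
    return rows, Row


@dataclass
class _AnnotatedRow:
    gene_a: str
    gene_b: str
    best_snp_a: str
    best_snp_b: str
    p: float
    or_value: float
    direction: str
    nominal: int
    bonferroni: int
    fdr: int


@dataclass
class PipelineResult:
    """In-memory results of a full run, for programmatic use and tests."""

    manifest: RunManifest
    dataset: GenotypeDataset
    qc_report: QCReport | None
    pair_results: list
    gis: list[GenePairGI]
    gis_intragenic: list[GenePairGI]
    thresholds: ThresholdSet | None
    hubs: list


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all enabled stages; see the module docstring for outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_config_echo(config), version=__version__)

    # --- input stage -------------------------------------------------------
    t0 = time.perf_counter()
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        dataset, truth = simulate_cohort(sim_cfg)
        gene_models = simulate_annotation(sim_cfg)
        needs_artifacts = (
            sim_cfg.missing_rate > 0
            or sim_cfg.n_hwe_violating_snps > 0
            or sim_cfg.n_duplicate_samples > 0
        )
        if needs_artifacts:
            dataset, _manifest = inject_artifacts(dataset, sim_cfg)
        write_simulation(dataset, truth, gene_models, out_dir / "cohort")
        logger.info("simulated cohort: %d samples x %d variants",
                    dataset.n_samples, dataset.n_variants)
        manifest.add("simulate", time.perf_counter() - t0,
                     n_samples=dataset.n_samples, n_variants=dataset.n_variants)
    else:
        dataset = read_plink(config.input_prefix)
        if config.annotation is None:
            raise ValueError("annotation BED is required with input_prefix")
        gene_models = read_annotation_bed(config.annotation)
        logger.info("loaded cohort: %d samples x %d variants",
                    dataset.n_samples, dataset.n_variants)
        manifest.add("load", time.perf_counter() - t0,
                     n_samples=dataset.n_samples, n_variants=dataset.n_variants)

    # --- qc ----------------------------------------------------------------
    qc_report = None
    if config.run_qc:
        t0 = time.perf_counter()
        dataset, qc_report = apply_qc(
            dataset, PRESETS[config.qc_preset],
            ld_r2_max=config.qc_ld_r2_max, min_overlap=config.qc_min_overlap,
        )
        rows, row_type = _qc_report_rows(qc_report)
        write_results_tsv(rows, out_dir / "qc_report.tsv", record_type=row_type)
        logger.info("QC: %d/%d samples, %d/%d variants retained",
                    qc_report.output_samples, qc_report.input_samples,
                    qc_report.output_variants, qc_report.input_variants)
        manifest.add("qc", time.perf_counter() - t0,
                     n_samples=dataset.n_samples, n_variants=dataset.n_variants)

    if not config.run_scan:
        manifest.write(out_dir / "manifest.json")
        return PipelineResult(manifest, dataset, qc_report, [], [], [], None, [])

    # --- scan --------------------------------------------------------------
    t0 = time.perf_counter()
    assignment = map_snps_to_genes(dataset, gene_models)
    pairs = eligible_intergenic_pairs(assignment)
    pair_results = scan_pairs(dataset, pairs, screen_alpha=config.screen_alpha)
    from .epistasis import SnpPairResult
    write_results_tsv(pair_results, out_dir / "pairs.tsv", record_type=SnpPairResult)
    n_followed = sum(1 for r in pair_results if r.p_wald is not None)
    logger.info("scan: %d eligible pairs, %d follow-ups", len(pairs), n_followed)
    manifest.add("scan", time.perf_counter() - t0,
                 n_pairs=len(pairs), n_followups=n_followed)

    # --- collapse ----------------------------------------------------------
    t0 = time.perf_counter()
    gis = classify_directions(collapse_to_gene_pairs(pair_results, assignment))
    write_results_tsv(gis, out_dir / "gis.tsv", record_type=GenePairGI)
    # intragenic (gene-body) GIs feed the hub analysis
    body_assignment = map_snps_to_genes(dataset, gene_models, sources=("body",))
    gis_intragenic = classify_directions(
        collapse_to_gene_pairs(pair_results, body_assignment)
    )
    logger.info("collapse: %d gene-pair GIs (%d intragenic)", len(gis), len(gis_intragenic))
    manifest.add("collapse", time.perf_counter() - t0,
                 n_gis=len(gis), n_gis_intragenic=len(gis_intragenic))

    if not config.run_network:
        manifest.write(out_dir / "manifest.json")
        return PipelineResult(manifest, dataset, qc_report, pair_results,
                              gis, gis_intragenic, None, [])

    # --- network -----------------------------------------------------------
    t0 = time.perf_counter()
    m = config.m_tests
    if m is None:
        from .network import estimate_test_count
        m = max(estimate_test_count(max(len(gene_models), 2)), len(gis))
    thresholds = ThresholdSet.build(
        [gi.p for gi in gis], alpha=config.alpha, m=m, nominal_p=config.nominal_p
    )
    annotated = call_significant(gis, thresholds)
    rows = [
        _AnnotatedRow(
            a.gi.gene_a, a.gi.gene_b, a.gi.best_snp_a, a.gi.best_snp_b,
            a.gi.p, a.gi.or_value, a.gi.direction,
            int(a.nominal), int(a.bonferroni), int(a.fdr),
        )
        for a in annotated
    ]
    write_results_tsv(rows, out_dir / "gis_annotated.tsv", record_type=_AnnotatedRow)
    hub_input = twofold_filter(
        [gi for gi in gis_intragenic if gi.p <= thresholds.nominal_p]
    )
    hubs = hub_degrees(hub_input)
    from .network import HubSummary
    write_results_tsv(hubs, out_dir / "hub_genes.tsv", record_type=HubSummary)
    logger.info("network: %d two-fold intragenic GIs, %d hub genes",
                len(hub_input), len(hubs))
    manifest.add("network", time.perf_counter() - t0,
                 n_gis=len(gis), n_twofold=len(hub_input), n_hub_genes=len(hubs))

    manifest.write(out_dir / "manifest.json")
    return PipelineResult(manifest, dataset, qc_report, pair_results,
                          gis, gis_intragenic, thresholds, hubs)
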