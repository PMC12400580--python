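"""One-command orchestration: load inputs, call holistic targets, enrich,
screen the bioactive compounds group, build the multilayer network, and run
the reversal analysis — from a single YAML config, with a structured,
schema-versioned run report.

Stage order follows the analysis: profiles -> holistic targets ->
function/pathway enrichment -> syndrome screen -> multilayer network ->
expression reversal. Each stage's outputs are written before the next
begins; identical config + inputs give identical outputs. ``resume=True``
skips stages whose output files already exist.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import data_io, enrichment, multilayer, network_target, transcriptome

logger = logging.getLogger("formula_nettarget")

REPORT_SCHEMA_VERSION = 1


def configure_logging(log_path: str | Path | None = None) -> None:
    """Timestamped, stage-prefixed logging to stderr and optionally a file."""
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", "%Y-%m-%d %H:%M:%S"
    )
    logger.setLevel(logging.INFO)
    logger.handlers = [h for h in logger.handlers
                       if not isinstance(h, (logging.StreamHandler,))]
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(fmt)
    logger.addHandler(stream)
    if log_path is not None:
        fh = logging.FileHandler(log_path)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run."""

    compounds: str
    herbs: str
    profiles: str
    syndromes: str
    outdir: str
    functions: str | None = None
    ppi: str | None = None
    deg_model: str | None = None
    deg_treatment: str | None = None
    module_classes: dict[str, str] = field(default_factory=dict)
    allow_unassigned: bool = True
    universe_size: int = 20000
    max_rank: int = 100
    alpha_holistic: float = 0.05
    correction: str = "bh"
    alpha_screen: float = 0.05
    min_syndromes: int = 1
    min_ppi_score: float = 0.7
    lfc_cut: float = 1.0
    padj_cut: float = 0.05
    network_format: str = "tsv_pair"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("compounds", "herbs", "profiles", "syndromes"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise PipelineError("config", f"input {name!r} not found: {path}")
        for name in ("functions", "ppi", "deg_model", "deg_treatment"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise PipelineError("config", f"input {name!r} not found: {path}")
        if self.deg_model is not None and self.deg_treatment is None:
            raise PipelineError(
                "config", "deg_model given without deg_treatment"
            )


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunReport:
    """Structured record of a pipeline run; round-trips through JSON."""

    schema_version: int = REPORT_SCHEMA_VERSION
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, **info) -> None:
        self.stages.append({"stage": name, **info})

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"schema_version": self.schema_version, "stages": self.stages},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunReport":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(
            schema_version=raw["schema_version"], stages=raw["stages"]
        )


def _stage_outputs_exist(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def run_pipeline(config: RunConfig, resume: bool = False) -> RunReport:
    """Execute the full analysis described by ``config``.

    Returns the run report; every stage that ran (or was resumed) has a
    record with input sizes, parameters, warnings and output paths.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    configure_logging(outdir / "run.log")
    report = RunReport()

    # ---- load ------------------------------------------------------------
    logger.info("[load] reading input tables")
    try:
        compounds, herbs, profiles = data_io.read_dataset(
            config.compounds, config.herbs, config.profiles,
            max_rank=config.max_rank,
        )
        syndromes = data_io.read_gene_sets_gmt(config.syndromes)
    except data_io.DataIOError as exc:
        raise PipelineError("load", str(exc)) from exc
    report.add_stage(
        "load",
        n_compounds=len(compounds),
        n_herbs=len(herbs),
        n_profiles=len(profiles),
        n_syndrome_sets=len(syndromes),
    )

    # ---- holistic targets ------------------------------------------------
    holistic_path = outdir / "holistic_targets.tsv"
    prior = network_target.PriorModel.from_profiles(
        profiles, universe_size=config.universe_size
    )
    logger.info("[holistic] calling holistic targets over %d profiles",
                len(profiles))
    results = network_target.holistic_targets(
        profiles, prior, alpha=config.alpha_holistic,
        correction=config.correction,
    )
    if not (resume and holistic_path.exists()):
        network_target.holistic_frame(results).to_csv(
            holistic_path, sep="\t", index=False
        )
    significant = [r.gene for r in results if r.significant]
    report.add_stage(
        "holistic",
        n_genes_tested=len(results),
        n_significant=len(significant),
        alpha=config.alpha_holistic,
        correction=config.correction,
        universe_size=config.universe_size,
        out=str(holistic_path),
    )

    # ---- function enrichment (optional) ---------------------------------
    functions = None
    if config.functions is not None:
        logger.info("[enrich] enriching significant genes")
        functions = data_io.read_gene_sets_gmt(config.functions)
        enrich_path = outdir / "function_enrichment.tsv"
        query = significant or [r.gene for r in results]
        enr = enrichment.enrich_gene_sets(
            set(query), functions, background=config.universe_size
        )
        if not (resume and enrich_path.exists()):
            pd.DataFrame([dataclasses.asdict(r) for r in enr]).to_csv(
                enrich_path, sep="\t", index=False
            )
        report.add_stage(
            "enrich",
            n_sets=len(functions),
            n_query=len(query),
            n_significant_sets=sum(
                r.adjusted_p <= config.alpha_holistic for r in enr
            ),
            out=str(enrich_path),
        )

    # ---- syndrome screen -------------------------------------------------
    logger.info("[screen] screening compounds against %d syndrome sets",
                len(syndromes))
    screen = enrichment.screen_bcg(
        profiles, syndromes, compounds, herbs,
        alpha=config.alpha_screen,
        min_syndromes=config.min_syndromes,
        background_size=config.universe_size,
    )
    screen_path = outdir / "screen_matrix.tsv"
    selected_path = outdir / "selected_bcg.txt"
    if not (resume and _stage_outputs_exist([screen_path, selected_path])):
        screen.p_frame.to_csv(screen_path, sep="\t")
        selected_path.write_text(
            "".join(f"{c}\n" for c in screen.selected_bcg), encoding="utf-8"
        )
    report.add_stage(
        "screen",
        n_compounds=len(screen.p_frame),
        n_selected=len(screen.selected_bcg),
        selection_rule=screen.selection_rule,
        out=str(screen_path),
    )

    # ---- multilayer network (optional) ----------------------------------
    if config.ppi is not None:
        if functions is None:
            raise PipelineError(
                "network", "network stage needs a functions GMT"
            )
        logger.info("[network] building herb-target-function network")
        ppi = data_io.read_ppi_edges(config.ppi)
        sig_set = set(significant)
        herb_targets = {}
        comp_by_id = {c.compound_id: c for c in compounds}
        for prof in profiles:
            for herb_id in comp_by_id[prof.compound_id].herb_ids:
                herb_targets.setdefault(herb_id, set()).update(
                    prof.gene_set & sig_set
                )
        herb_targets = {h: g for h, g in herb_targets.items() if g}
        net = multilayer.build_multilayer(
            herbs, herb_targets, ppi,
            min_ppi_score=config.min_ppi_score,
            function_annotations=functions,
            module_classes=config.module_classes,
            allow_unassigned=config.allow_unassigned,
        )
        written = multilayer.export_network(
            net, config.network_format, outdir / "network"
        )
        report.add_stage(
            "network",
            n_nodes=len(net.nodes),
            n_edges=len(net.edges),
            build_report=net.build_report,
            out=[str(p) for p in written],
        )

    # ---- reversal (optional) --------------------------------------------
    if config.deg_model is not None:
        logger.info("[reversal] reversal analysis")
        model = data_io.read_deg_table(config.deg_model, "model")
        treatment = data_io.read_deg_table(config.deg_treatment, "treatment")
        rev = transcriptome.find_reversed(
            model, treatment,
            lfc_cut=config.lfc_cut, padj_cut=config.padj_cut,
        )
        rev_path = outdir / "reversed_genes.tsv"
        if not (resume and rev_path.exists()):
            rev.records.to_csv(rev_path, sep="\t", index=False)
        report.add_stage(
            "reversal",
            n_model_rows=len(model),
            n_treatment_rows=len(treatment),
            n_reversed=len(rev.reversed_genes),
            lfc_cut=config.lfc_cut,
            padj_cut=config.padj_cut,
            out=str(rev_path),
        )

    report.to_json(outdir / "run_report.json")
    logger.info("[done] %d stages", len(report.stages))
    return report
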