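"""Synthetic benchmark generator with recorded ground truth.

Emulates the scale and statistical structure of the motivating formula
study — 49 compounds over 10 herbs, truncated 100-gene target profiles
over a 20000-gene universe, four syndrome gene sets, and paired
differential-expression contrasts — while planting three recoverable
signals:

* **key targets**: genes inserted into every profile independently with a
  fixed presence probability, so their recurrence count is far above the
  Poisson-binomial null;
* **bioactive compounds**: a subset of compounds whose profiles receive a
  block of genes from one designated syndrome set, so the hypergeometric
  screen flags them; they are also the only compounds that are
  quality-control-flagged or sovereign(JUN)-sourced, making exact recovery
  the correct expectation for the screen's AND-rule;
* **reversed genes**: genes constructed to pass the DEG cuts in both
  contrasts with opposite fold-change signs.

All non-planted content is drawn uniformly without replacement from the
universe, which makes the hypergeometric distribution the exactly correct
null for the screen and gives calibration tests an analytic reference.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import (
    CompoundRecord,
    DEGTable,
    GeneSetCollection,
    HerbRecord,
    PPIEdgeList,
    TargetProfile,
    write_compound_table,
    write_deg_table,
    write_gene_sets_gmt,
    write_herb_table,
    write_ppi_edges,
    write_profiles,
)

__all__ = [
    "BenchmarkConfig",
    "SyntheticTruth",
    "BenchmarkDataset",
    "generate_benchmark",
    "generate_deg_tables",
    "MARQUEE_KEY_TARGETS",
    "CB_HERBS",
]

#: Readable demo names for planted key targets (immune / heat-shock /
#: cell-cycle regulators highlighted in leukopenia biology).
MARQUEE_KEY_TARGETS = (
    "MNDA", "BST2", "HSPA1A", "HLA-A", "HLA-G", "PPP1CC",
    "CDK1", "CDK2", "CDK4", "CDK6", "RB1",
)

#: The ten herbs of the reference formula with their compatibility roles:
#: sovereign (JUN), minister (CHEN), assistant (ZUO_SHI).
CB_HERBS = (
    HerbRecord("BHSSC", "Scleromitrion diffusum", "JUN"),
    HerbRecord("CWJ", "Eleutherococcus senticosus", "JUN"),
    HerbRecord("FL", "Poria", "CHEN"),
    HerbRecord("BZ", "Atractylodes macrocephala", "CHEN"),
    HerbRecord("DS", "Codonopsis radix", "CHEN"),
    HerbRecord("GQZ", "Lycium chinense", "CHEN"),
    HerbRecord("TSZ", "Cuscuta", "CHEN"),
    HerbRecord("NZZ", "Ligustri lucidi fructus", "CHEN"),
    HerbRecord("HZ", "Reynoutria japonica", "ZUO_SHI"),
    HerbRecord("WWZ", "Schisandra chinensis", "ZUO_SHI"),
)

#: Chemical-class counts of the 49-compound reference formula.
CB_CLASS_COUNTS = (
    ("flavonoid", 14),
    ("terpenoid", 9),
    ("lignan", 8),
    ("coumarin", 5),
    ("phenylethanoid glycoside", 4),
    ("phenolic acid", 3),
    ("volatile oil", 3),
    ("polyacetylene", 2),
    ("amino acid", 1),
)

SYNDROME_NAMES = ("FD", "WSK", "IB", "CDFS")
SYNDROME_DESCRIPTIONS = {
    "FD": "febrile disease",
    "WSK": "weakened spleen and kidneys",
    "IB": "insufficient blood",
    "CDFS": "chronic deficiency or fatigue syndrome",
}


@dataclass
class BenchmarkConfig:
    """Generator parameters; defaults mirror the reference study's scale."""

    n_compounds: int = 49
    n_herbs: int = 10
    universe_size: int = 20000
    profile_size: int = 100
    n_key_targets: int = 10
    key_target_presence: float = 0.6
    n_syndromes: int = 4
    syndrome_set_size: int = 300
    n_planted_bioactive: int = 5
    planted_overlap: int = 30
    ppi_edge_prob: float = 0.02
    ppi_score_range: tuple[float, float] = (0.4, 1.0)
    deg_n_genes: int = 2000
    deg_n_reversed: int = 16
    deg_n_concordant: int = 30
    deg_n_model_only: int = 50
    deg_lfc_range: tuple[float, float] = (1.5, 4.0)
    deg_sig_padj_max: float = 0.01
    use_marquee_names: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.planted_overlap > self.syndrome_set_size:
            raise ValueError(
                "planted_overlap exceeds syndrome_set_size: infeasible"
            )
        if self.planted_overlap + self.n_key_targets > self.profile_size:
            raise ValueError(
                "planted_overlap + n_key_targets exceeds profile_size"
            )
        if self.n_planted_bioactive > self.n_compounds:
            raise ValueError("n_planted_bioactive exceeds n_compounds")
        if not 0.0 <= self.key_target_presence <= 1.0:
            raise ValueError("key_target_presence must lie in [0,1]")
        if not 0.0 <= self.ppi_edge_prob <= 1.0:
            raise ValueError("ppi_edge_prob must lie in [0,1]")
        if self.deg_n_reversed + self.deg_n_concordant + self.deg_n_model_only > self.deg_n_genes:
            raise ValueError("DEG category counts exceed deg_n_genes")
        if self.n_herbs < 1 or self.n_compounds < 1:
            raise ValueError("need at least one herb and one compound")
        if self.universe_size < self.profile_size + self.n_key_targets:
            raise ValueError("universe too small for the profile size")
        if self.use_marquee_names and self.n_key_targets > len(
            MARQUEE_KEY_TARGETS
        ):
            raise ValueError(
                f"at most {len(MARQUEE_KEY_TARGETS)} marquee names available"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("ppi_score_range", "deg_lfc_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    key_targets: list[str]
    bioactive_compounds: list[str]
    reversed_genes: list[str]
    config: BenchmarkConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "key_targets": self.key_targets,
            "bioactive_compounds": self.bioactive_compounds,
            "reversed_genes": self.reversed_genes,
            "config": dataclasses.asdict(self.config),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class BenchmarkDataset:
    """In-memory benchmark; ``write`` emits the standard file family."""

    compounds: list[CompoundRecord]
    herbs: list[HerbRecord]
    profiles: list[TargetProfile]
    syndromes: GeneSetCollection
    ppi: PPIEdgeList
    truth: SyntheticTruth = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "compounds": outdir / "compounds.tsv",
            "herbs": outdir / "herbs.tsv",
            "profiles": outdir / "profiles.tsv",
            "syndromes": outdir / "syndromes.gmt",
            "ppi": outdir / "ppi.tsv",
            "truth": outdir / "truth.json",
        }
        write_compound_table(self.compounds, paths["compounds"])
        write_herb_table(self.herbs, paths["herbs"])
        write_profiles(self.profiles, paths["profiles"])
        write_gene_sets_gmt(self.syndromes, paths["syndromes"])
        write_ppi_edges(self.ppi, paths["ppi"])
        if self.truth is not None:
            self.truth.to_json(paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _gene_labels(universe_size: int) -> np.ndarray:
    width = max(6, len(str(universe_size)))
    return np.array([f"G{i:0{width}d}" for i in range(1, universe_size + 1)])


def _make_herbs(config: BenchmarkConfig, rng: np.random.Generator):
    if config.n_herbs == len(CB_HERBS):
        return list(CB_HERBS)
    herbs = []
    n_jun = max(1, round(0.2 * config.n_herbs))
    n_chen = max(0, round(0.6 * config.n_herbs))
    for i in range(config.n_herbs):
        if i < n_jun:
            role = "JUN"
        elif i < n_jun + n_chen:
            role = "CHEN"
        else:
            role = "ZUO_SHI"
        herbs.append(HerbRecord(f"H{i + 1:02d}", f"Herb {i + 1}", role))
    return herbs


def _make_compounds(
    config: BenchmarkConfig,
    herbs: list[HerbRecord],
    rng: np.random.Generator,
) -> tuple[list[CompoundRecord], list[str]]:
    if config.n_compounds == 49:
        classes = [
            cls for cls, count in CB_CLASS_COUNTS for _ in range(count)
        ]
    else:
        names = [cls for cls, _ in CB_CLASS_COUNTS]
        classes = list(rng.choice(names, size=config.n_compounds))
    rng.shuffle(classes)
    jun = [h.herb_id for h in herbs if h.role == "JUN"]
    other = [h.herb_id for h in herbs if h.role != "JUN"] or jun
    planted_idx = sorted(
        rng.choice(config.n_compounds, size=config.n_planted_bioactive,
                   replace=False)
    )
    planted_set = set(planted_idx)
    compounds = []
    planted_ids = []
    for i in range(config.n_compounds):
        cid = f"C{i + 1:03d}"
        if i in planted_set:
            # planted bioactive: sovereign-sourced and QC-flagged — the
            # only flag-eligible compounds, so screen recovery isolates
            # the enrichment signal
            herb_ids = (str(rng.choice(jun)),)
            qc = True
            planted_ids.append(cid)
        else:
            n_src = int(rng.integers(1, min(3, len(other)) + 1))
            herb_ids = tuple(
                sorted(rng.choice(other, size=n_src, replace=False))
            )
            qc = False
        compounds.append(
            CompoundRecord(cid, f"Compound {i + 1}", classes[i], herb_ids, qc)
        )
    return compounds, planted_ids


def generate_benchmark(
    config: BenchmarkConfig | None = None,
) -> tuple[BenchmarkDataset, SyntheticTruth]:
    """Generate the full benchmark dataset plus its planted truth.

    Deterministic given ``config.seed``. Non-planted profile genes are
    uniform draws without replacement from the universe excluding the key
    targets; syndrome sets are uniform draws from the same pool, so
    compound-syndrome overlaps are exactly hypergeometric under no
    planting.
    """
    config = config or BenchmarkConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = _gene_labels(config.universe_size)

    key_targets = [str(g) for g in labels[: config.n_key_targets]]
    if config.use_marquee_names:
        rename = dict(zip(key_targets, MARQUEE_KEY_TARGETS))
        key_targets = [rename[g] for g in key_targets]
    filler_pool = labels[config.n_key_targets:]

    herbs = _make_herbs(config, rng)
    compounds, planted_ids = _make_compounds(config, herbs, rng)
    planted_set = set(planted_ids)

    syndromes = GeneSetCollection()
    syndrome_names = [
        SYNDROME_NAMES[i] if i < len(SYNDROME_NAMES) else f"SYN{i + 1}"
        for i in range(config.n_syndromes)
    ]
    syndrome_genes: dict[str, np.ndarray] = {}
    for name in syndrome_names:
        genes = rng.choice(
            filler_pool, size=config.syndrome_set_size, replace=False
        )
        syndrome_genes[name] = genes
        syndromes.add(
            name, SYNDROME_DESCRIPTIONS.get(name, "synthetic syndrome"), genes
        )
    designated = syndrome_names[0] if syndrome_names else None

    profiles = []
    key_arr = np.array(key_targets) if key_targets else np.array([], dtype=str)
    for comp in compounds:
        chosen: list[str] = []
        if config.n_key_targets:
            mask = rng.random(config.n_key_targets) < config.key_target_presence
            chosen.extend(key_arr[mask])
        if comp.compound_id in planted_set and designated is not None:
            planted_genes = rng.choice(
                syndrome_genes[designated],
                size=config.planted_overlap,
                replace=False,
            )
            chosen.extend(planted_genes)
        need = config.profile_size - len(chosen)
        # oversample then drop collisions with already-chosen genes
        buffer = len(chosen) + 8
        draw = rng.choice(filler_pool, size=need + buffer, replace=False)
        chosen_set = set(chosen)
        fillers = [g for g in draw if g not in chosen_set][:need]
        chosen.extend(fillers)
        order = rng.permutation(len(chosen))
        targets = tuple(str(chosen[i]) for i in order)
        profiles.append(
            TargetProfile(
                comp.compound_id, targets, max_rank=config.profile_size
            )
        )

    ppi = _make_ppi(config, profiles, key_targets, rng)

    truth = SyntheticTruth(
        key_targets=sorted(key_targets),
        bioactive_compounds=sorted(planted_ids),
        reversed_genes=[],
        config=config,
    )
    dataset = BenchmarkDataset(
        compounds=compounds,
        herbs=herbs,
        profiles=profiles,
        syndromes=syndromes,
        ppi=ppi,
        truth=truth,
    )
    return dataset, truth


def _make_ppi(
    config: BenchmarkConfig,
    profiles: list[TargetProfile],
    key_targets: list[str],
    rng: np.random.Generator,
) -> PPIEdgeList:
    """Erdos-Renyi edges over recurrent genes (those in >= 2 profiles,
    plus the key targets), with uniform confidence scores."""
    if config.ppi_edge_prob <= 0.0:
        return PPIEdgeList(edges=[])
    counts: dict[str, int] = {}
    for prof in profiles:
        for gene in prof.gene_set:
            counts[gene] = counts.get(gene, 0) + 1
    nodes = sorted(
        set(g for g, c in counts.items() if c >= 2) | set(key_targets)
    )
    n = len(nodes)
    if n < 2:
        return PPIEdgeList(edges=[])
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < config.ppi_edge_prob
    lo, hi = config.ppi_score_range
    scores = rng.uniform(lo, hi, size=int(keep.sum()))
    records = [
        (nodes[i], nodes[j], round(float(s), 3))
        for i, j, s in zip(iu[keep], ju[keep], scores)
    ]
    return PPIEdgeList.from_records(records)


def generate_deg_tables(
    config: BenchmarkConfig | None = None,
) -> tuple[DEGTable, DEGTable, SyntheticTruth]:
    """Generate paired DEG tables with planted expression reversals.

    Contrast orientations: model = irradiated vs control ("IR_vs_CT"),
    treatment = treated vs irradiated ("CB_vs_IR"). Reversed genes pass
    |log2FC| > 1 and padj < 0.05 in both tables with opposite signs;
    concordant DEGs share the sign; model-only DEGs fail the treatment
    cuts; all remaining genes are null (padj >= 0.05 by construction).
    """
    config = config or BenchmarkConfig()
    config.validate()
    # decorrelate from the profile stream but stay seed-driven
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    labels = _gene_labels(config.universe_size)
    genes = rng.choice(labels, size=config.deg_n_genes, replace=False)

    n_rev = config.deg_n_reversed
    n_con = config.deg_n_concordant
    n_mod = config.deg_n_model_only
    lo, hi = config.deg_lfc_range
    pmax = config.deg_sig_padj_max

    lfc_model = rng.normal(0.0, 0.35, size=config.deg_n_genes)
    lfc_treat = rng.normal(0.0, 0.35, size=config.deg_n_genes)
    padj_model = rng.uniform(0.05, 1.0, size=config.deg_n_genes)
    padj_treat = rng.uniform(0.05, 1.0, size=config.deg_n_genes)

    idx = 0
    rev_slice = slice(idx, idx + n_rev)
    idx += n_rev
    con_slice = slice(idx, idx + n_con)
    idx += n_con
    mod_slice = slice(idx, idx + n_mod)

    sign_rev = rng.choice([-1.0, 1.0], size=n_rev)
    lfc_model[rev_slice] = sign_rev * rng.uniform(lo, hi, size=n_rev)
    lfc_treat[rev_slice] = -sign_rev * rng.uniform(lo, hi, size=n_rev)
    padj_model[rev_slice] = rng.uniform(1e-8, pmax, size=n_rev)
    padj_treat[rev_slice] = rng.uniform(1e-8, pmax, size=n_rev)

    sign_con = rng.choice([-1.0, 1.0], size=n_con)
    lfc_model[con_slice] = sign_con * rng.uniform(lo, hi, size=n_con)
    lfc_treat[con_slice] = sign_con * rng.uniform(lo, hi, size=n_con)
    padj_model[con_slice] = rng.uniform(1e-8, pmax, size=n_con)
    padj_treat[con_slice] = rng.uniform(1e-8, pmax, size=n_con)

    sign_mod = rng.choice([-1.0, 1.0], size=n_mod)
    lfc_model[mod_slice] = sign_mod * rng.uniform(lo, hi, size=n_mod)
    padj_model[mod_slice] = rng.uniform(1e-8, pmax, size=n_mod)
    # treatment side stays null for model-only DEGs

    model = DEGTable(
        "IR_vs_CT",
        pd.DataFrame(
            {
                "gene": genes,
                "log2_fold_change": lfc_model,
                "adjusted_p": padj_model,
            }
        ),
    )
    treatment = DEGTable(
        "CB_vs_IR",
        pd.DataFrame(
            {
                "gene": genes,
                "log2_fold_change": lfc_treat,
                "adjusted_p": padj_treat,
            }
        ),
    )
    truth = SyntheticTruth(
        key_targets=[],
        bioactive_compounds=[],
        reversed_genes=sorted(str(g) for g in genes[rev_slice]),
        config=config,
    )
    return model, treatment, truth


def write_deg_pair(
    model: DEGTable, treatment: DEGTable, outdir: str | Path
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "deg_model": outdir / "deg_model.tsv",
        "deg_treatment": outdir / "deg_treatment.tsv",
    }
    write_deg_table(model, paths["deg_model"])
    write_deg_table(treatment, paths["deg_treatment"])
    return paths
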