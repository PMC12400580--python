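"""Readers, writers and record types for every table the pipeline touches.

All tabular inputs are UTF-8 TSV with a required header row; gene sets use
the GMT convention (name TAB description TAB gene ...). Gene identifiers are
treated as opaque uppercase symbol strings — no alias resolution is applied
unless an explicit two-column alias map is supplied at load time. Missing
values (empty cells or a bare ".") are a hard error: the loaders fail loudly
rather than guess.

Writers mirror readers bit-exactly for canonical ordering (rows sorted by
primary key), so every format round-trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("formula_nettarget")

#: The nine chemical classes of the formula's constituent compounds.
DEFAULT_CHEMICAL_CLASSES: tuple[str, ...] = (
    "flavonoid",
    "terpenoid",
    "lignan",
    "coumarin",
    "phenylethanoid glycoside",
    "phenolic acid",
    "volatile oil",
    "polyacetylene",
    "amino acid",
)

#: Herb roles under the sovereign/minister/assistant compatibility scheme.
HERB_ROLES: tuple[str, ...] = ("JUN", "CHEN", "ZUO_SHI")

_MISSING_MARKERS = {"", "."}


class DataIOError(ValueError):
    """Raised for any malformed or inconsistent input table."""


def normalize_gene(symbol: str) -> str:
    """Normalize a gene identifier: strip whitespace, uppercase."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    """One chemical constituent of the formula.

    ``herb_ids`` lists every source herb; ``quality_control_marker`` flags
    compounds used as pharmacopoeia quality-control markers.
    """

    compound_id: str
    name: str
    chemical_class: str
    herb_ids: tuple[str, ...]
    quality_control_marker: bool


@dataclass(frozen=True)
class HerbRecord:
    """One herb with its compatibility role (JUN / CHEN / ZUO_SHI)."""

    herb_id: str
    name: str
    role: str


@dataclass(frozen=True)
class TargetProfile:
    """A compound's ranked, truncated predicted-target list.

    ``targets[0]`` is the best-ranked gene; the list never exceeds
    ``max_rank`` entries and contains no duplicates.
    """

    compound_id: str
    targets: tuple[str, ...]
    max_rank: int = 100

    def __post_init__(self) -> None:
        if len(self.targets) > self.max_rank:
            raise DataIOError(
                f"profile for {self.compound_id!r} has {len(self.targets)} "
                f"targets, exceeding max_rank={self.max_rank}"
            )
        if len(set(self.targets)) != len(self.targets):
            raise DataIOError(
                f"profile for {self.compound_id!r} contains duplicate genes"
            )

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.targets)


@dataclass
class GeneSetCollection:
    """Named gene sets: ``sets[name] = (description, frozenset of genes)``."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def add(self, name: str, description: str, genes: Iterable[str]) -> None:
        if name in self.sets:
            raise DataIOError(f"duplicate gene-set name {name!r}")
        norm = frozenset(normalize_gene(g) for g in genes)
        if not norm:
            raise DataIOError(f"gene set {name!r} is empty after normalization")
        self.sets[name] = (description, norm)


@dataclass
class DEGTable:
    """A differential-expression contrast: one row per gene.

    ``frame`` has columns ``gene``, ``log2_fold_change``, ``adjusted_p``.
    ``contrast_label`` documents the orientation (e.g. "IR_vs_CT").
    """

    contrast_label: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["gene", "log2_fold_change", "adjusted_p"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise DataIOError(f"DEG table missing columns {missing}")
        dup = self.frame["gene"][self.frame["gene"].duplicated()]
        if len(dup):
            raise DataIOError(
                f"DEG table {self.contrast_label!r}: duplicate gene "
                f"{dup.iloc[0]!r}"
            )
        bad = self.frame[
            (self.frame["adjusted_p"] < 0) | (self.frame["adjusted_p"] > 1)
        ]
        if len(bad):
            raise DataIOError(
                f"DEG table {self.contrast_label!r}: adjusted_p outside [0,1] "
                f"for gene {bad['gene'].iloc[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.frame)

    def genes(self) -> list[str]:
        return list(self.frame["gene"])


@dataclass
class PPIEdgeList:
    """Undirected protein-protein interaction edges with confidence scores.

    Edges are stored with canonically ordered endpoints (a < b), self-loops
    removed and duplicates collapsed keeping the maximum score.
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float]]
    ) -> "PPIEdgeList":
        best: dict[tuple[str, str], float] = {}
        for a, b, score in records:
            a, b = normalize_gene(a), normalize_gene(b)
            score = float(score)
            if not 0.0 <= score <= 1.0:
                raise DataIOError(
                    f"PPI score {score} for edge ({a}, {b}) outside [0,1]"
                )
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            if score > best.get(key, -1.0):
                best[key] = score
        edges = [(a, b, s) for (a, b), s in sorted(best.items())]
        return cls(edges=edges)

    def __len__(self) -> int:
        return len(self.edges)

    def filtered(self, min_score: float) -> "PPIEdgeList":
        return PPIEdgeList(
            edges=[e for e in self.edges if e[2] >= min_score]
        )


# ---------------------------------------------------------------------------
# Low-level helpers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataIOError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataIOError(f"{path}: missing required columns {missing}")
    for col in required:
        bad = df[col].isin(_MISSING_MARKERS)
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise DataIOError(
                f"{path}: missing value in column {col!r} at line {row}"
            )
    return df


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV alias map (alias TAB canonical symbol)."""
    df = _read_tsv(path, ["alias", "symbol"])
    return {
        normalize_gene(a): normalize_gene(s)
        for a, s in zip(df["alias"], df["symbol"])
    }


def _apply_alias(gene: str, alias: Mapping[str, str] | None) -> str:
    g = normalize_gene(gene)
    return alias.get(g, g) if alias else g


# ---------------------------------------------------------------------------
# Compound / herb / profile tables
# ---------------------------------------------------------------------------


def read_compound_table(
    path: str | Path,
    vocabulary: Sequence[str] = DEFAULT_CHEMICAL_CLASSES,
) -> list[CompoundRecord]:
    """Read the compound table (compound_id, name, chemical_class, herb_ids,
    quality_control_marker)."""
    df = _read_tsv(
        path,
        ["compound_id", "name", "chemical_class", "herb_ids",
         "quality_control_marker"],
    )
    vocab = set(vocabulary)
    seen: set[str] = set()
    out: list[CompoundRecord] = []
    for _, row in df.iterrows():
        cid = row["compound_id"].strip()
        if cid in seen:
            raise DataIOError(f"duplicate compound_id {cid!r}")
        seen.add(cid)
        cls = row["chemical_class"].strip()
        if cls not in vocab:
            raise DataIOError(
                f"compound {cid!r}: unknown chemical_class {cls!r}; "
                f"allowed: {sorted(vocab)}"
            )
        herb_ids = tuple(
            h.strip() for h in row["herb_ids"].split(",") if h.strip()
        )
        if not herb_ids:
            raise DataIOError(f"compound {cid!r}: empty herb_ids")
        qc_raw = row["quality_control_marker"].strip().lower()
        if qc_raw in {"true", "1", "yes"}:
            qc = True
        elif qc_raw in {"false", "0", "no"}:
            qc = False
        else:
            raise DataIOError(
                f"compound {cid!r}: unparseable quality_control_marker "
                f"{row['quality_control_marker']!r}"
            )
        out.append(
            CompoundRecord(cid, row["name"].strip(), cls, herb_ids, qc)
        )
    return out


def read_herb_table(path: str | Path) -> list[HerbRecord]:
    """Read the herb table (herb_id, name, role)."""
    df = _read_tsv(path, ["herb_id", "name", "role"])
    seen: set[str] = set()
    out: list[HerbRecord] = []
    for _, row in df.iterrows():
        hid = row["herb_id"].strip()
        if hid in seen:
            raise DataIOError(f"duplicate herb_id {hid!r}")
        seen.add(hid)
        role = row["role"].strip().upper().replace("/", "_")
        if role not in HERB_ROLES:
            raise DataIOError(
                f"herb {hid!r}: unknown role {row['role']!r}; "
                f"allowed: {list(HERB_ROLES)}"
            )
        out.append(HerbRecord(hid, row["name"].strip(), role))
    return out


def read_profiles(
    path: str | Path,
    max_rank: int = 100,
    alias: Mapping[str, str] | None = None,
) -> list[TargetProfile]:
    """Read long-format ranked target profiles (compound_id, rank, target).

    Each compound's rows are sorted by rank and truncated to ``max_rank``.
    """
    df = _read_tsv(path, ["compound_id", "rank", "target"])
    if len(df) == 0:
        return []
    try:
        df = df.assign(rank=df["rank"].astype(int))
    except ValueError as exc:
        raise DataIOError(f"{path}: non-integer rank value ({exc})") from exc
    out: list[TargetProfile] = []
    for cid, grp in df.groupby("compound_id", sort=True):
        grp = grp.sort_values("rank", kind="stable").head(max_rank)
        targets = tuple(_apply_alias(t, alias) for t in grp["target"])
        if len(set(targets)) != len(targets):
            raise DataIOError(
                f"profile for {cid!r} contains duplicate genes after "
                f"normalization"
            )
        out.append(TargetProfile(str(cid), targets, max_rank=max_rank))
    return out


def read_dataset(
    compound_path: str | Path,
    herb_path: str | Path,
    profiles_path: str | Path,
    max_rank: int = 100,
    vocabulary: Sequence[str] = DEFAULT_CHEMICAL_CLASSES,
) -> tuple[list[CompoundRecord], list[HerbRecord], list[TargetProfile]]:
    """Read and cross-validate the compound, herb and profile tables.

    Every profile must reference a known compound and every compound's
    source herbs must exist in the herb table.
    """
    compounds = read_compound_table(compound_path, vocabulary=vocabulary)
    herbs = read_herb_table(herb_path)
    profiles = read_profiles(profiles_path, max_rank=max_rank)
    known_compounds = {c.compound_id for c in compounds}
    known_herbs = {h.herb_id for h in herbs}
    for p in profiles:
        if p.compound_id not in known_compounds:
            raise DataIOError(
                f"profile references unknown compound {p.compound_id!r}"
            )
    for c in compounds:
        unknown = [h for h in c.herb_ids if h not in known_herbs]
        if unknown:
            raise DataIOError(
                f"compound {c.compound_id!r} references unknown herb(s) "
                f"{unknown}"
            )
    return compounds, herbs, profiles


def write_compound_table(
    compounds: Iterable[CompoundRecord], path: str | Path
) -> None:
    rows = [
        {
            "compound_id": c.compound_id,
            "name": c.name,
            "chemical_class": c.chemical_class,
            "herb_ids": ",".join(c.herb_ids),
            "quality_control_marker": str(c.quality_control_marker).lower(),
        }
        for c in sorted(compounds, key=lambda c: c.compound_id)
    ]
    pd.DataFrame(
        rows,
        columns=["compound_id", "name", "chemical_class", "herb_ids",
                 "quality_control_marker"],
    ).to_csv(path, sep="\t", index=False)


def write_herb_table(herbs: Iterable[HerbRecord], path: str | Path) -> None:
    rows = [
        {"herb_id": h.herb_id, "name": h.name, "role": h.role}
        for h in sorted(herbs, key=lambda h: h.herb_id)
    ]
    pd.DataFrame(rows, columns=["herb_id", "name", "role"]).to_csv(
        path, sep="\t", index=False
    )


def write_profiles(
    profiles: Iterable[TargetProfile], path: str | Path
) -> None:
    rows = [
        {"compound_id": p.compound_id, "rank": r + 1, "target": t}
        for p in sorted(profiles, key=lambda p: p.compound_id)
        for r, t in enumerate(p.targets)
    ]
    pd.DataFrame(rows, columns=["compound_id", "rank", "target"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gene_sets_gmt(
    path: str | Path, alias: Mapping[str, str] | None = None
) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene TAB gene ..."""
    path = Path(path)
    if not path.exists():
        raise DataIOError(f"GMT file not found: {path}")
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataIOError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    f"need at least 3 (name, description, >=1 gene)"
                )
            name, desc, *genes = fields
            genes = [_apply_alias(g, alias) for g in genes if g.strip()]
            coll.add(name, desc, genes)
    return coll


def write_gene_sets_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(coll.sets):
            desc, genes = coll.sets[name]
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------


def read_deg_table(
    path: str | Path,
    contrast_label: str,
    gene_col: str = "gene",
    lfc_col: str = "log2FoldChange",
    padj_col: str = "padj",
    alias: Mapping[str, str] | None = None,
) -> DEGTable:
    """Read a differential-expression table (CSV or TSV by extension).

    Column names are configurable to accommodate different DE tools'
    output conventions.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    if not path.exists():
        raise DataIOError(f"DEG file not found: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (gene_col, lfc_col, padj_col):
        if col not in df.columns:
            raise DataIOError(f"{path}: missing column {col!r}")
        bad = df[col].isin(_MISSING_MARKERS)
        if bad.any():
            raise DataIOError(
                f"{path}: missing value in column {col!r} at line "
                f"{int(bad.idxmax()) + 2}"
            )
    try:
        lfc = df[lfc_col].astype(float)
    except ValueError as exc:
        raise DataIOError(f"{path}: non-numeric fold change ({exc})") from exc
    try:
        padj = df[padj_col].astype(float)
    except ValueError as exc:
        raise DataIOError(f"{path}: non-numeric adjusted p ({exc})") from exc
    frame = pd.DataFrame(
        {
            "gene": [_apply_alias(g, alias) for g in df[gene_col]],
            "log2_fold_change": lfc.to_numpy(),
            "adjusted_p": padj.to_numpy(),
        }
    )
    return DEGTable(contrast_label=contrast_label, frame=frame)


def write_deg_table(table: DEGTable, path: str | Path) -> None:
    out = table.frame.sort_values("gene", kind="stable")
    out = out.rename(
        columns={"log2_fold_change": "log2FoldChange", "adjusted_p": "padj"}
    )
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# PPI edges
# ---------------------------------------------------------------------------


def read_ppi_edges(path: str | Path) -> PPIEdgeList:
    """Read a PPI edge list (gene_a, gene_b, score in [0,1])."""
    df = _read_tsv(path, ["gene_a", "gene_b", "score"])
    try:
        scores = df["score"].astype(float)
    except ValueError as exc:
        raise DataIOError(f"{path}: non-numeric PPI score ({exc})") from exc
    return PPIEdgeList.from_records(
        zip(df["gene_a"], df["gene_b"], scores)
    )


def write_ppi_edges(ppi: PPIEdgeList, path: str | Path) -> None:
    pd.DataFrame(
        ppi.edges, columns=["gene_a", "gene_b", "score"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged example formula
# ---------------------------------------------------------------------------


def load_example_formula() -> tuple[list[CompoundRecord], list[HerbRecord]]:
    """Load the packaged 49-compound / 10-herb example formula.

    The herb table (ids, species, JUN/CHEN/ZUO_SHI roles) and the
    chemical-class composition match the reference formula; individual
    compound names and herb assignments beyond the documented ones are
    synthetic stand-ins (the file is named accordingly).
    """
    from importlib.resources import files

    data = files("formula_nettarget") / "data"
    compounds = read_compound_table(str(data / "cb_compounds_synthetic.tsv"))
    herbs = read_herb_table(str(data / "cb_herbs.tsv"))
    return compounds, herbs


# ---------------------------------------------------------------------------
# Convenience summaries
# ---------------------------------------------------------------------------


def class_composition(compounds: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Count and percentage of compounds per chemical class, descending."""
    counts = pd.Series(
        [c.chemical_class for c in compounds]
    ).value_counts()
    df = pd.DataFrame(
        {
            "chemical_class": counts.index,
            "n": counts.to_numpy(),
            "pct": (100.0 * counts / len(compounds)).round(1).to_numpy(),
        }
    )
    return df.reset_index(drop=True)
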