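"""Ligand-receptor interaction database: loading, merging, ortholog mapping, filtering.

The interaction database is the union of curated ligand-receptor pair tables
(e.g. CellTalkDB-style simple pairs and CellPhoneDB-style complex-aware tables).
Receptor or ligand "complexes" (multi-gene units) are represented as pseudo-genes
whose per-cell expression is the minimum over their component genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class EmptyDatabaseError(ValueError):
    """An input table contained no interaction records."""


@dataclass(frozen=True)
class InteractionRecord:
    """One directed ligand -> receptor interaction with its source database tags."""

    ligand: str
    receptor: str
    sources: frozenset = frozenset()

    def __post_init__(self):
        if not self.ligand:
            raise ValueError("ligand identifier must be non-empty")
        if not self.receptor:
            raise ValueError("receptor identifier must be non-empty")

    @property
    def key(self) -> tuple:
        return (self.ligand, self.receptor)


@dataclass(frozen=True)
class ComplexDefinition:
    """A multi-gene ligand/receptor complex (expression = min over components)."""

    complex_id: str
    components: tuple

    def __post_init__(self):
        if len(self.components) < 2:
            raise ValueError(f"complex {self.complex_id!r} needs >=2 components")
        if len(set(self.components)) != len(self.components):
            raise ValueError(f"complex {self.complex_id!r} has duplicate components")


@dataclass
class OrthologMap:
    """Two-column species gene mapping with a policy for multi-mapped destinations.

    ``pairs`` maps source-species symbols to destination-species symbols.  A
    destination reached from several sources is either represented by a synthetic
    averaged gene (policy ``"average"``) or, if listed in ``drop``, removed from
    the database entirely.
    """

    pairs: list  # list of (source, dest)
    drop: frozenset = frozenset()

    @classmethod
    def from_tsv(cls, path, drop: Iterable[str] = ()) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in ("source_symbol", "dest_symbol"):
            if col not in df.columns:
                raise SchemaError(f"ortholog map missing required column {col!r}")
        return cls(pairs=list(df[["source_symbol", "dest_symbol"]].itertuples(index=False, name=None)),
                   drop=frozenset(drop))

    def by_source(self) -> Mapping[str, list]:
        out: dict = {}
        for s, d in self.pairs:
            out.setdefault(s, []).append(d)
        return out

    def by_dest(self) -> Mapping[str, list]:
        out: dict = {}
        for s, d in self.pairs:
            out.setdefault(d, []).append(s)
        return out


@dataclass
class InteractionDatabase:
    """Deduplicated ligand-receptor records plus complex definitions.

    The (ligand, receptor) tuple is the unique key; reversed pairs are distinct
    records because directionality matters for donor/target assignment.
    """

    records: dict = field(default_factory=dict)  # key -> InteractionRecord
    complexes: dict = field(default_factory=dict)  # complex_id -> ComplexDefinition

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, key) -> bool:
        return tuple(key) in self.records

    @property
    def keys(self) -> set:
        return set(self.records)

    def add(self, record: InteractionRecord) -> None:
        prev = self.records.get(record.key)
        if prev is None:
            self.records[record.key] = record
        else:
            self.records[record.key] = InteractionRecord(
                record.ligand, record.receptor, prev.sources | record.sources
            )

    def genes(self) -> set:
        """All gene-or-complex identifiers referenced by records."""
        out = set()
        for r in self:
            out.add(r.ligand)
            out.add(r.receptor)
        return out

    def component_genes(self) -> set:
        """Plain gene identifiers, expanding complexes into their components."""
        out = set()
        for g in self.genes():
            if g in self.complexes:
                out.update(self.complexes[g].components)
            else:
                out.add(g)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ligand": r.ligand, "receptor": r.receptor,
             "sources": ";".join(sorted(r.sources))}
            for r in self
        ]
        return pd.DataFrame(rows, columns=["ligand", "receptor", "sources"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def from_pairs(pairs: Iterable, source: str = "", complexes: Iterable[ComplexDefinition] = ()) -> InteractionDatabase:
    """Build a database from (ligand, receptor) tuples (convenience constructor)."""
    db = InteractionDatabase()
    tag = frozenset([source]) if source else frozenset()
    for lig, rec in pairs:
        db.add(InteractionRecord(lig, rec, tag))
    for c in complexes:
        db.complexes[c.complex_id] = c
    return db


def load_pair_table(path, dialect: str = "simple", source: str | None = None,
                    complex_path=None) -> InteractionDatabase:
    """Load a ligand-receptor pair table.

    ``dialect="simple"``: TSV with columns ligand_gene_symbol, receptor_gene_symbol.
    ``dialect="complex-aware"``: CSV with columns partner_a, partner_b plus an
    optional companion complex-composition CSV (complex_name, component_1..n);
    partners naming a complex are kept as complex identifiers.
    """
    path = Path(path)
    if dialect == "simple":
        df = pd.read_csv(path, sep="\t", dtype=str)
        lig_col, rec_col = "ligand_gene_symbol", "receptor_gene_symbol"
    elif dialect == "complex-aware":
        df = pd.read_csv(path, dtype=str)
        lig_col, rec_col = "partner_a", "partner_b"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in (lig_col, rec_col):
        if col not in df.columns:
            raise SchemaError(f"pair table {path.name} missing required column {col!r}")
    if df.empty:
        raise EmptyDatabaseError(f"pair table {path.name} contains no interactions")
    if df[lig_col].isna().any() or df[rec_col].isna().any():
        bad = rec_col if df[rec_col].isna().any() else lig_col
        raise SchemaError(f"pair table {path.name} has missing values in column {bad!r}")

    tag = source if source is not None else path.stem
    db = from_pairs(df[[lig_col, rec_col]].itertuples(index=False, name=None), source=tag)
    if dialect == "complex-aware" and complex_path is not None:
        for c in _load_complex_table(complex_path):
            db.complexes[c.complex_id] = c
    return db


def _load_complex_table(path) -> list:
    df = pd.read_csv(path, dtype=str)
    if "complex_name" not in df.columns:
        raise SchemaError("complex table missing required column 'complex_name'")
    comp_cols = [c for c in df.columns if c.startswith("component_")]
    if not comp_cols:
        raise SchemaError("complex table has no component_* columns")
    out = []
    for _, row in df.iterrows():
        comps = tuple(str(row[c]) for c in comp_cols if pd.notna(row[c]))
        out.append(ComplexDefinition(str(row["complex_name"]), comps))
    return out


def merge_databases(a: InteractionDatabase, b: InteractionDatabase) -> InteractionDatabase:
    """Union of two databases on the (ligand, receptor) key, merging source tags."""
    out = InteractionDatabase()
    for r in a:
        out.add(r)
    for r in b:
        out.add(r)
    out.complexes = {**a.complexes, **b.complexes}
    return out


def map_orthologs(db: InteractionDatabase, omap: OrthologMap,
                  expression_gene_set: Iterable[str]):
    """Rename database genes across species via an ortholog table.

    Genes with a one-to-one ortholog are renamed.  Genes absent from the map
    fall back to uppercase matching against ``expression_gene_set``.  A
    destination symbol reached from several sources becomes a synthetic
    averaged pseudo-gene (expression = mean log-normalized expression of the
    sources, materialized by :func:`contacttracing.expression.add_averaged_genes`)
    unless it is on the drop list, in which case its interactions are removed.
    Unmappable genes drop their interactions with a warning.

    Returns (mapped_db, averaged_genes, report) where ``averaged_genes`` maps the
    pseudo-gene name to its ortholog gene list and ``report`` counts genes per
    mapping class.
    """
    expr = set(expression_gene_set)
    if not expr:
        raise ValueError("expression_gene_set must be non-empty")
    by_source = omap.by_source()
    by_dest = omap.by_dest()

    averaged: dict = {}
    report = {"one_to_one": 0, "capitalized": 0, "averaged": 0,
              "dropped_multi": 0, "unmapped": 0}
    rename: dict = {}

    for gene in sorted(db.genes()):
        if gene in db.complexes:
            rename[gene] = gene  # complex ids pass through unchanged
            continue
        dests = by_source.get(gene)
        if dests is not None:
            dest = dests[0]  # first listed ortholog
            if dest in omap.drop:
                rename[gene] = None
                report["dropped_multi"] += 1
            elif len(by_dest.get(dest, [])) > 1:
                name = f"{dest}_avg"
                rename[gene] = name
                averaged[name] = sorted(by_dest[dest])
                report["averaged"] += 1
            else:
                rename[gene] = dest
                report["one_to_one"] += 1
        else:
            cap = gene.upper()
            if cap in expr:
                rename[gene] = cap
                report["capitalized"] += 1
            else:
                rename[gene] = None
                report["unmapped"] += 1
                logger.warning("gene %s unmappable; dropping its interactions", gene)

    out = InteractionDatabase(complexes=dict(db.complexes))
    for r in db:
        lig, rec = rename.get(r.ligand), rename.get(r.receptor)
        if lig is None or rec is None:
            continue
        out.add(InteractionRecord(lig, rec, r.sources))
    return out, averaged, report


def apply_complex_rule(ds, complexes: Sequence[ComplexDefinition]):
    """Append one pseudo-gene per complex to an expression dataset.

    The per-cell value of a complex is the minimum over its component genes,
    applied to both the counts and the log-normalized layer (min of a monotone
    transform equals transform of the min, so the two layers stay consistent).
    Complexes with fewer than two resolvable components are skipped.
    """
    from .expression import append_genes  # local import to avoid cycle

    names, count_cols, lognorm_cols = [], [], []
    present = set(ds.genes)
    for c in complexes:
        comps = [g for g in c.components if g in present]
        if len(comps) < 2:
            logger.warning("complex %s skipped: <2 resolvable components", c.complex_id)
            continue
        idx = [ds.gene_index(g) for g in comps]
        counts = ds.counts[:, idx].toarray() if hasattr(ds.counts, "toarray") else ds.counts[:, idx]
        lognorm = ds.lognorm[:, idx].toarray() if hasattr(ds.lognorm, "toarray") else ds.lognorm[:, idx]
        names.append(c.complex_id)
        count_cols.append(counts.min(axis=1))
        lognorm_cols.append(lognorm.min(axis=1))
    if not names:
        return ds
    return append_genes(ds, names, np.column_stack(count_cols), np.column_stack(lognorm_cols))


def filter_interactions(db: InteractionDatabase, ds, min_detect_frac: float = 0.01) -> InteractionDatabase:
    """Drop interactions whose ligand or receptor is detected in fewer than
    ``min_detect_frac`` of all cells (inclusive boundary: exactly the threshold
    is retained).  Genes absent from the dataset count as undetected.
    """
    if not 0.0 <= min_detect_frac <= 1.0:
        raise ValueError("min_detect_frac must be in [0, 1]")
    frac = ds.detection_fraction()
    def ok(gene: str) -> bool:
        return float(frac.get(gene, 0.0)) >= min_detect_frac

    out = InteractionDatabase(complexes=dict(db.complexes))
    for r in db:
        if ok(r.ligand) and ok(r.receptor):
            out.add(r)
    return out
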