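"""Reading, validation, and writing of gene-level annotation tables.

The analysis starts from three pre-digested tab-separated tables, one row per
predicted gene of a metagenome gene catalog:

``genes.tsv``
    ``gene_id`` and ``read_count`` — the number of clean reads the aligner
    assigned to the gene.  Counts are treated as opaque totals; no length
    normalization is applied.
``taxonomy.tsv``
    ``gene_id`` and ``lineage`` — a ';'-separated list of ``rank:name`` pairs
    (``d``omain down to ``g``enus).  Genes missing from this table, or whose
    lineage stops above genus, are binned as ``"unassigned"``.
``cazy.tsv``
    ``gene_id`` and ``families`` — ';'-separated CAZy family labels in the
    dbCAN overview style (e.g. ``GH5_4;CBM3``).  Extra columns (coordinates,
    e-values) are ignored; e-value thresholding is assumed to have happened
    upstream.

The joined result is a :class:`GeneCatalog` carrying the total clean read
count ``N`` of the metagenome, which is supplied independently because not
every clean read maps to a predicted gene.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger("cazcontrib")

#: Reserved genus token for genes without a genus-level assignment.
UNASSIGNED = "unassigned"

#: Valid CAZy family labels: class prefix, family number, optional subfamily.
FAMILY_PATTERN = re.compile(r"^(GH|GT|PL|CE|AA|CBM)[0-9]+(_[0-9]+)?$")

#: Rank order used in lineage strings.
LINEAGE_RANKS = ("d", "p", "c", "o", "f", "g")


class CatalogError(ValueError):
    """Raised for invalid catalog inputs (duplicate ids, bad labels, ...)."""


def family_class(family: str) -> str:
    """Return the CAZy class prefix (GH/GT/PL/CE/AA/CBM) of a family label."""
    m = FAMILY_PATTERN.match(family)
    if m is None:
        raise CatalogError(f"malformed CAZy family label: {family!r}")
    return m.group(1)


@dataclass(frozen=True)
class GeneRecord:
    """One gene of the catalog.

    Parameters
    ----------
    gene_id
        Opaque unique identifier.
    genus
        Genus name, or :data:`UNASSIGNED`.  Composite bins such as
        ``unclassified_f__Bacillaceae`` are kept verbatim as genus-level bins.
    lineage
        Ordered ``rank:name`` pairs, possibly partial.
    families
        CAZy family labels; empty for non-CAZyme genes.
    read_count
        Mapped clean reads (non-negative).
    """

    gene_id: str
    genus: str = UNASSIGNED
    lineage: tuple[str, ...] = ()
    families: frozenset[str] = frozenset()
    read_count: int = 0

    def __post_init__(self) -> None:
        if self.read_count < 0:
            raise CatalogError(
                f"negative read count for gene {self.gene_id!r}: {self.read_count}"
            )
        bad = sorted(f for f in self.families if not FAMILY_PATTERN.match(f))
        if bad:
            raise CatalogError(
                f"malformed CAZy family label(s) for gene {self.gene_id!r}: "
                + ", ".join(bad)
            )


@dataclass
class GeneCatalog:
    """A validated gene catalog plus the metagenome's total clean read count.

    ``total_reads`` (``N``) must be at least the sum of per-gene counts;
    unmapped or unannotated reads account for the difference.
    """

    records: list[GeneRecord]
    total_reads: int
    _frame: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise CatalogError(f"total_reads must be positive, got {self.total_reads}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise CatalogError(f"duplicate gene_id: {rec.gene_id!r}")
            seen.add(rec.gene_id)
        mapped = sum(r.read_count for r in self.records)
        if mapped > self.total_reads:
            raise CatalogError(
                f"sum of per-gene read counts ({mapped}) exceeds total_reads "
                f"({self.total_reads})"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    @property
    def mapped_reads(self) -> int:
        return int(self.to_frame()["read_count"].sum())

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: gene_id, genus, lineage, families (';'-joined), read_count."""
        if self._frame is None:
            self._frame = pd.DataFrame(
                {
                    "gene_id": [r.gene_id for r in self.records],
                    "genus": [r.genus for r in self.records],
                    "lineage": [";".join(r.lineage) for r in self.records],
                    "families": [";".join(sorted(r.families)) for r in self.records],
                    "read_count": [r.read_count for r in self.records],
                }
            )
        return self._frame


def parse_lineage(lineage: str) -> tuple[tuple[str, ...], str]:
    """Split a ';'-separated ``rank:name`` lineage; return (pairs, genus).

    The genus is the name at rank ``g``, or :data:`UNASSIGNED` when the
    lineage stops above genus.
    """
    pairs = tuple(p.strip() for p in lineage.split(";") if p.strip())
    genus = UNASSIGNED
    for pair in pairs:
        rank, _, name = pair.partition(":")
        if rank == "g" and name:
            genus = name
    return pairs, genus


def _split_families(cell: str) -> frozenset[str]:
    # dbCAN overview cells may carry "GH5_4(123-456)" style coordinates.
    fams = []
    for tok in str(cell).split(";"):
        tok = tok.strip()
        if not tok or tok == "-":
            continue
        fams.append(tok.split("(")[0].strip())
    return frozenset(fams)


def read_catalog(
    genes_path: str | Path,
    taxonomy_path: str | Path,
    cazy_path: str | Path,
    total_reads: int,
) -> GeneCatalog:
    """Join the three annotation tables into a validated :class:`GeneCatalog`.

    Every gene in ``genes_path`` yields one record; genes absent from the
    taxonomy table become :data:`UNASSIGNED`, genes absent from the CAZy
    table get an empty family set.

    Raises
    ------
    CatalogError
        On duplicate gene ids, negative read counts, malformed family
        labels, or annotation rows referring to unknown genes.
    """
    genes = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str})
    taxonomy = pd.read_csv(taxonomy_path, sep="\t", dtype=str).fillna("")
    cazy = pd.read_csv(cazy_path, sep="\t", dtype=str).fillna("")

    dupes = genes["gene_id"][genes["gene_id"].duplicated()]
    if not dupes.empty:
        raise CatalogError(f"duplicate gene_id: {dupes.iloc[0]!r}")
    known = set(genes["gene_id"])
    for name, table in (("taxonomy", taxonomy), ("cazy", cazy)):
        unknown = sorted(set(table["gene_id"]) - known)
        if unknown:
            raise CatalogError(f"{name} file names unknown gene(s): {unknown[:5]}")

    lineages = dict(zip(taxonomy["gene_id"], taxonomy["lineage"]))
    families = dict(zip(cazy["gene_id"], cazy["families"]))

    records = []
    for gene_id, read_count in zip(genes["gene_id"], genes["read_count"]):
        pairs, genus = parse_lineage(lineages.get(gene_id, ""))
        records.append(
            GeneRecord(
                gene_id=gene_id,
                genus=genus,
                lineage=pairs,
                families=_split_families(families.get(gene_id, "")),
                read_count=int(read_count),
            )
        )
    catalog = GeneCatalog(records=records, total_reads=int(total_reads))
    logger.info(
        "read catalog: %d genes, %d mapped reads, N=%d",
        len(catalog), catalog.mapped_reads, catalog.total_reads,
    )
    return catalog


def write_catalog(catalog: GeneCatalog, out_dir: str | Path) -> dict[str, Path]:
    """Write a catalog back to genes/taxonomy/cazy TSVs (inverse of read_catalog).

    Genes with an empty lineage or family set are omitted from the taxonomy
    and CAZy tables respectively, matching the sparse input convention.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = catalog.to_frame()
    paths = {
        "genes": out_dir / "genes.tsv",
        "taxonomy": out_dir / "taxonomy.tsv",
        "cazy": out_dir / "cazy.tsv",
    }
    frame[["gene_id", "read_count"]].to_csv(paths["genes"], sep="\t", index=False)
    tax = frame.loc[frame["lineage"] != "", ["gene_id", "lineage"]]
    tax.to_csv(paths["taxonomy"], sep="\t", index=False)
    caz = frame.loc[frame["families"] != "", ["gene_id", "families"]]
    caz.to_csv(paths["cazy"], sep="\t", index=False)
    return paths


def write_table(table: pd.DataFrame, path: str | Path, sort: bool = True) -> None:
    """Write a result table as UTF-8 TSV with a header row.

    Rows are ordered lexicographically by the first column unless ``sort``
    is disabled (for tables that define their own order).  Empty tables are
    rejected rather than silently producing header-only files.
    """
    if table is None or len(table) == 0:
        raise ValueError(f"refusing to write empty table to {path}")
    out = table.reset_index() if table.index.name is not None else table
    if sort:
        out = out.sort_values(out.columns[0], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path: str | Path, index_col: str | None = None) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    df = pd.read_csv(path, sep="\t")
    if index_col is not None:
        df = df.set_index(index_col)
    return df


def validate_catalog(catalog: GeneCatalog) -> None:
    """Re-run all catalog invariants; no-op when the catalog is valid."""
    GeneCatalog(records=catalog.records, total_reads=catalog.total_reads)
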