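"""Read-count aggregation: genus abundances and CAZyme class/family profiles.

All quantities are read-share based.  The relative abundance of a genus g is

    R_g = N_g / N

with N_g the summed mapped-read counts of the genus's genes and N the total
clean read count of the metagenome.  Class- and family-level CAZyme summaries
count a gene once per class/family it carries: multi-modular genes bring
their full read count into every family they are annotated with, so family
tallies are per-family, not per-gene, totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .annotation_io import GeneCatalog, family_class
from .function_map import FunctionMap

CAZY_CLASSES = ("AA", "CBM", "CE", "GH", "GT", "PL")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, matching conventional table formatting."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ProfileTables:
    """Class-level and family-level CAZyme aggregates.

    ``class_summary``: per CAZy class — family_count, gene_count, read_count.
    ``family_summary``: per family — gene_count, read_count.
    ``section_sums``: per summary-table section — gene_count, read_count.
    ``genus_abundance``: optional genus → R_g series.
    """

    class_summary: pd.DataFrame
    family_summary: pd.DataFrame
    section_sums: pd.DataFrame
    genus_abundance: pd.Series | None = None

    @property
    def total_cazyme_genes(self) -> int:
        return int(self.class_summary["gene_count"].sum())

    @property
    def total_cazyme_reads(self) -> int:
        return int(self.class_summary["read_count"].sum())


def genus_abundances(
    catalog: GeneCatalog, denominator: str = "total"
) -> pd.Series:
    """Per-genus relative abundance R_g = N_g / N.

    ``denominator="total"`` uses the metagenome's total clean reads N (the
    standard definition); ``"mapped"`` divides by the summed per-gene counts
    instead.  Either choice cancels in the contribution coefficient as long
    as it is applied consistently.
    """
    frame = catalog.to_frame()
    if denominator == "total":
        n = catalog.total_reads
    elif denominator == "mapped":
        n = int(frame["read_count"].sum())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if n <= 0:
        raise ValueError("cannot compute abundances with zero total reads")
    shares = frame.groupby("genus")["read_count"].sum() / n
    shares.name = "R_g"
    return shares.sort_index()


def merge_minor_genera(abundances: pd.Series, threshold: float = 0.01) -> pd.Series:
    """Report-time view merging genera below ``threshold`` into "others".

    The underlying matrices always keep every genus; this merge mirrors the
    usual composition-plot convention only when writing summary output.
    """
    major = abundances[abundances >= threshold]
    minor = abundances[abundances < threshold]
    out = major.copy()
    if len(minor):
        out.loc["others"] = float(minor.sum())
    return out.sort_values(ascending=False)


def _family_long(catalog: GeneCatalog) -> pd.DataFrame:
    """One row per (gene, family) for CAZyme genes."""
    frame = catalog.to_frame()
    caz = frame.loc[frame["families"] != "", ["gene_id", "families", "read_count"]]
    if caz.empty:
        return pd.DataFrame(columns=["gene_id", "family", "read_count"])
    long = caz.assign(family=caz["families"].str.split(";")).explode("family")
    return long[["gene_id", "family", "read_count"]]


def cazyme_profile(catalog: GeneCatalog, fmap: FunctionMap) -> ProfileTables:
    """Aggregate a catalog into class/family/section summaries.

    Genes count once per distinct family and once per distinct class; a
    bi-functional gene therefore appears fully in two family rows.  Families
    outside the function map still contribute to class totals (the class
    table spans the whole CAZyme repertoire, the section sums only its
    lignocellulolytic subset).
    """
    long = _family_long(catalog)

    fam = (
        long.groupby("family")
        .agg(gene_count=("gene_id", "nunique"), read_count=("read_count", "sum"))
        .sort_index()
    )

    by_class = long.assign(cazy_class=long["family"].map(family_class))
    per_class_gene = by_class.drop_duplicates(["gene_id", "cazy_class"])
    cls = (
        per_class_gene.groupby("cazy_class")
        .agg(gene_count=("gene_id", "nunique"), read_count=("read_count", "sum"))
        .reindex(CAZY_CLASSES, fill_value=0)
    )
    family_counts = pd.Series(
        {c: sum(1 for f in fam.index if family_class(f) == c) for c in CAZY_CLASSES}
    )
    cls.insert(0, "family_count", family_counts)
    cls.index.name = "cazy_class"

    # Section sums over the map's summary-table sections, resolving
    # subfamilies to their roll-up parent entry; one count per gene-section.
    section_of = fmap.section_of
    with_section = long.assign(
        section=long["family"].map(
            lambda f: section_of.get(fmap.resolve_family(f) or "", "")
        )
    )
    with_section = with_section.loc[with_section["section"] != ""]
    per_gene_section = with_section.drop_duplicates(["gene_id", "section"])
    sec = (
        per_gene_section.groupby("section")
        .agg(gene_count=("gene_id", "nunique"), read_count=("read_count", "sum"))
        .sort_index()
    )

    return ProfileTables(
        class_summary=cls.astype(int),
        family_summary=fam.astype(int),
        section_sums=sec.astype(int),
        genus_abundance=genus_abundances(catalog),
    )


def cazyme_read_fraction(
    profile: ProfileTables, total_reads: int | GeneCatalog
) -> float:
    """Percentage of total clean reads mapping to CAZyme genes (2 decimals).

    A gene with families in several classes would inflate the class-summary
    read total, so the fraction is computed over distinct CAZyme genes when
    a catalog is given; for fixture profiles the class totals are used.
    """
    if isinstance(total_reads, GeneCatalog):
        frame = total_reads.to_frame()
        caz_reads = int(frame.loc[frame["families"] != "", "read_count"].sum())
        n = total_reads.total_reads
    else:
        caz_reads = profile.total_cazyme_reads
        n = int(total_reads)
    if n <= 0:
        raise ValueError("cannot compute read fraction with zero total reads")
    return round_half_up(100.0 * caz_reads / n, 2)
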