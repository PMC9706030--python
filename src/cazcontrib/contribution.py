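"""Genus × function read shares, contribution coefficients, and role calls.

For a function f (a set of CAZy families with that activity), the total
function read count is

    N_f = Σ reads of genes carrying at least one family mapped to f

with each qualifying gene counted once per function even when several of its
families map to f.  The genus share of the function is R_g-f = N_g-f / N_f,
and the contribution coefficient of genus g to function f is

    CC_g,f = R_g-f / R_g .

CC > 1 means the genus supplies more function-f enzyme genes than its
overall read share would predict; CC < 1 means it under-contributes.  A
genus that persistently under-contributes across the hydrolytic functions
while consuming released sugars is a candidate "sugar cheater".

CC cells are undefined (NaN) when R_g = 0 or N_f = 0; they are reported as
blanks, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneCatalog
from .function_map import (
    HYDROLASE_CATEGORIES,
    ROLLUPS,
    FunctionMap,
    UnknownCategoryError,
)
from .profiling import _family_long

ROLE_CONTRIBUTOR = "contributor"
ROLE_CHEATER = "cheater"
ROLE_INTERMEDIATE = "intermediate"
ROLE_UNDETERMINED = "undetermined"


@dataclass
class DistributionMatrix:
    """Genus × function read shares.

    ``values``: R_g-f matrix (rows = genera, columns = functions); each
    column with N_f > 0 sums to 1 over all genera including "unassigned".
    ``counts``: integer N_g-f matrix.  ``function_reads``: N_f per function;
    zero-read functions are kept (flagged by an all-NaN share column).
    """

    values: pd.DataFrame
    counts: pd.DataFrame
    function_reads: pd.Series

    @property
    def genera(self) -> list[str]:
        return list(self.values.index)

    @property
    def functions(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CCMatrix:
    """Genus × function contribution coefficients plus optional role calls."""

    values: pd.DataFrame
    abundances: pd.Series
    calls: dict[str, str] | None = field(default=None)


def _resolve_functions(functions: Sequence[str]) -> None:
    from .function_map import CATEGORIES

    unknown = [f for f in functions if f not in CATEGORIES and f not in ROLLUPS]
    if unknown:
        raise UnknownCategoryError(f"unknown function name(s): {unknown}")


def function_distribution(
    catalog: GeneCatalog,
    fmap: FunctionMap,
    functions: Sequence[str] | None = None,
    by: str = "reads",
) -> DistributionMatrix:
    """Compute the genus × function distribution matrix.

    Parameters
    ----------
    functions
        Function categories and/or substrate roll-ups; defaults to the
        hydrolase categories.  Unknown names raise.
    by
        ``"reads"`` (default) weights genes by mapped reads — the scale all
        defined quantities use; ``"genes"`` counts genes instead, for
        comparison with gene-count share figures.
    """
    if functions is None:
        functions = list(HYDROLASE_CATEGORIES)
    _resolve_functions(functions)
    if by not in ("reads", "genes"):
        raise ValueError(f"unknown weighting {by!r}")

    frame = catalog.to_frame()
    genera = sorted(frame["genus"].unique())
    long = _family_long(catalog)
    genus_of = dict(zip(frame["gene_id"], frame["genus"]))

    # gene -> set of categories via its families (resolved through the map)
    cats = long["family"].map(fmap.categories_of)
    gene_cat = (
        long.assign(category=cats)
        .explode("category")
        .dropna(subset=["category"])
        .drop_duplicates(["gene_id", "category"])
    )
    gene_cat = gene_cat.assign(
        genus=gene_cat["gene_id"].map(genus_of),
        w=gene_cat["read_count"] if by == "reads" else 1,
    )

    counts = pd.DataFrame(0, index=genera, columns=list(functions), dtype=np.int64)
    for fn in functions:
        members = ROLLUPS.get(fn, (fn,))
        # each qualifying gene counted once, also across roll-up members
        sub = (
            gene_cat.loc[gene_cat["category"].isin(members)]
            .drop_duplicates("gene_id")
            .groupby("genus")["w"]
            .sum()
        )
        counts[fn] = sub.reindex(genera).fillna(0).astype(np.int64)
    counts.index.name = "genus"

    function_reads = counts.sum(axis=0)
    function_reads.name = "N_f"
    with np.errstate(invalid="ignore", divide="ignore"):
        values = counts / function_reads.replace(0, np.nan)
    return DistributionMatrix(
        values=values, counts=counts, function_reads=function_reads.astype(np.int64)
    )


def contribution_coefficients(
    dist: DistributionMatrix, abundances: Mapping[str, float] | pd.Series
) -> CCMatrix:
    """CC_g,f = R_g-f / R_g for every cell of the distribution matrix.

    Every genus row of ``dist`` must have a known abundance; cells with
    R_g = 0 (or an undefined function column) are NaN.
    """
    ab = pd.Series(abundances, dtype=float)
    missing = [g for g in dist.genera if g not in ab.index]
    if missing:
        raise KeyError(f"no abundance for genera: {missing}")
    ab = ab.reindex(dist.genera)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = dist.values.div(ab.replace(0, np.nan), axis=0)
    return CCMatrix(values=cc, abundances=ab)


def classify_roles(
    cc: CCMatrix,
    hydrolase_functions: Sequence[str] | None = None,
    cheater_quantile: float = 0.75,
    cheater_cutoff: float = 1.0,
    contributor_cutoff: float = 1.0,
) -> dict[str, str]:
    """Call each genus contributor / cheater / intermediate.

    A genus is a contributor when at least ``cheater_quantile`` of its
    defined CC cells over the hydrolase functions exceed
    ``contributor_cutoff``, a cheater when that fraction falls below
    ``cheater_cutoff``, and intermediate otherwise.  Genera with no defined
    cells get "undetermined".  Lignin-active AAs and esterases are excluded
    from the default function list, since cheating is defined against the
    sugar-releasing hydrolases.
    """
    if hydrolase_functions is None:
        hydrolase_functions = list(HYDROLASE_CATEGORIES)
    if not len(hydrolase_functions):
        raise ValueError("hydrolase_functions must be non-empty")
    missing = [f for f in hydrolase_functions if f not in cc.values.columns]
    if missing:
        raise KeyError(f"functions absent from CC matrix: {missing}")

    sub = cc.values[list(hydrolase_functions)]
    calls: dict[str, str] = {}
    for genus, row in sub.iterrows():
        defined = row.dropna()
        if defined.empty:
            calls[genus] = ROLE_UNDETERMINED
            continue
        frac_above = float((defined > contributor_cutoff).mean())
        frac_below = float((defined < cheater_cutoff).mean())
        if frac_above >= cheater_quantile:
            calls[genus] = ROLE_CONTRIBUTOR
        elif frac_below >= cheater_quantile:
            calls[genus] = ROLE_CHEATER
        else:
            calls[genus] = ROLE_INTERMEDIATE
    cc.calls = calls
    return calls


def export_circos_table(dist: DistributionMatrix, path: str | Path) -> None:
    """Write the integer N_g-f matrix in Circos tableviewer dialect.

    First row: function labels; first column: genus labels; cells: integer
    read counts.  Column sums reproduce N_f exactly.
    """
    if dist.counts.empty:
        raise ValueError("refusing to export an empty distribution matrix")
    out = dist.counts.copy()
    out.index.name = "genus"
    out.to_csv(path, sep="\t")


def read_circos_table(path: str | Path) -> pd.DataFrame:
    """Read back a tableviewer matrix written by :func:`export_circos_table`."""
    return pd.read_csv(path, sep="\t", index_col=0)
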