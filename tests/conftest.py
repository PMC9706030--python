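from __future__ import annotations

import numpy as np
import pytest

from cazcontrib import (
    GeneCatalog,
    GeneRecord,
    load_default_map,
)


@pytest.fixture(scope="session")
def fmap():
    return load_default_map()


@pytest.fixture
def toy_catalog():
    """Three genes: a GH10 xylanase, a non-CAZyme, and an unassigned
    bi-modular cellulase; 175 of 1000 clean reads mapped."""
    records = [
        GeneRecord("g1", genus="A", lineage=("d:Bacteria", "g:A"),
                   families=frozenset({"GH10"}), read_count=100),
        GeneRecord("g2", genus="A", lineage=("d:Bacteria", "g:A"),
                   families=frozenset(), read_count=50),
        GeneRecord("g3", families=frozenset({"GH5_4", "CBM3"}), read_count=25),
    ]
    return GeneCatalog(records=records, total_reads=1000)


def write_toy_tsvs(tmp_path, genes, taxonomy, cazy):
    """Write the three input tables from (header, rows) tuples."""
    paths = {}
    for name, (header, rows) in {
        "genes": genes, "taxonomy": taxonomy, "cazy": cazy
    }.items():
        p = tmp_path / f"{name}.tsv"
        lines = ["\t".join(header)] + ["\t".join(map(str, r)) for r in rows]
        p.write_text("\n".join(lines) + "\n")
        paths[name] = p
    return paths


def random_catalog(seed, n_genes=200, total_reads=100_000, fmap=None):
    """Small random catalog over a mix of mapped, unmapped, and no families."""
    rng = np.random.default_rng(seed)
    genera = ["Ruminiclostridium", "Thermoanaerobacterium", "Symbiobacterium",
              "unassigned"]
    pool = ["GH10", "GH5_4", "GH43_11", "GH1", "CE1", "AA6", "CBM3", "GT2",
            "GH9", "GH95", "GH78", "PL1"]
    records = []
    for i in range(n_genes):
        nfam = rng.integers(0, 3)
        fams = frozenset(rng.choice(pool, size=nfam, replace=False))
        records.append(
            GeneRecord(
                f"g{i:04d}",
                genus=str(rng.choice(genera)),
                lineage=(),
                families=fams,
                read_count=int(rng.integers(0, 500)),
            )
        )
    # fix lineage consistency for assigned genera
    records = [
        GeneRecord(r.gene_id,
                   genus=r.genus,
                   lineage=() if r.genus == "unassigned" else ("d:Bacteria", f"g:{r.genus}"),
                   families=r.families,
                   read_count=r.read_count)
        for r in records
    ]
    return GeneCatalog(records=records, total_reads=total_reads)
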