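from collections import defaultdict

import pytest

from cazcontrib import (
    GeneCatalog,
    GeneRecord,
    cazyme_profile,
    cazyme_read_fraction,
    genus_abundances,
    merge_minor_genera,
    round_half_up,
)
from cazcontrib.annotation_io import family_class

from conftest import random_catalog


def _catalog(spec, total_reads):
    """spec: list of (gene_id, genus, families, reads)."""
    return GeneCatalog(
        [
            GeneRecord(g, genus=gen,
                       lineage=() if gen == "unassigned" else (f"g:{gen}",),
                       families=frozenset(fams), read_count=n)
            for g, gen, fams, n in spec
        ],
        total_reads=total_reads,
    )


def test_genus_abundances_hand_arithmetic():
    cat = _catalog(
        [("g1", "A", [], 200), ("g2", "A", [], 100), ("g3", "B", [], 100)], 1000
    )
    ab = genus_abundances(cat)
    assert ab.to_dict() == {"A": 0.3, "B": 0.1}


def test_single_genus_holding_all_reads():
    cat = _catalog([("g1", "A", [], 600), ("g2", "A", [], 400)], 1000)
    assert genus_abundances(cat).to_dict() == {"A": 1.0}


def test_zero_total_reads_rejected():
    with pytest.raises(Exception):
        _catalog([("g1", "A", [], 0)], 0)
    cat = _catalog([("g1", "A", [], 0)], 10)
    with pytest.raises(ValueError):
        genus_abundances(cat, denominator="mapped")


def test_profile_counts_multimodular_genes_once_per_family(fmap):
    cat = _catalog(
        [
            ("g1", "A", ["GH10"], 100),
            ("g2", "A", ["GH5_4", "CBM3"], 40),
            ("g3", "B", ["GH10", "GH9"], 10),
            ("g4", "B", [], 50),
        ],
        1000,
    )
    prof = cazyme_profile(cat, fmap)
    fam = prof.family_summary
    assert fam.loc["GH10", "gene_count"] == 2
    assert fam.loc["GH10", "read_count"] == 110
    # bi-modular gene carries its full reads into both families
    assert fam.loc["GH5_4", "read_count"] == 40
    assert fam.loc["CBM3", "read_count"] == 40
    cls = prof.class_summary
    assert cls.loc["GH", "gene_count"] == 3  # g3 counted once for GH
    assert cls.loc["GH", "read_count"] == 150
    assert cls.loc["CBM", "gene_count"] == 1
    assert cls.loc["GT", "gene_count"] == 0


def test_empty_catalog_profiles_to_zero(fmap):
    cat = _catalog([("g1", "A", [], 10)], 100)
    prof = cazyme_profile(cat, fmap)
    assert prof.total_cazyme_genes == 0
    assert prof.total_cazyme_reads == 0
    assert cazyme_read_fraction(prof, cat) == 0.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_class_totals_match_brute_force(fmap, seed):
    """Family/class read totals equal a per-record re-aggregation."""
    cat = random_catalog(seed)
    prof = cazyme_profile(cat, fmap)
    fam_reads, cls_reads = defaultdict(int), defaultdict(int)
    fam_genes = defaultdict(set)
    for rec in cat:
        for f in rec.families:
            fam_reads[f] += rec.read_count
            fam_genes[f].add(rec.gene_id)
        for c in {family_class(f) for f in rec.families}:
            cls_reads[c] += rec.read_count
    for f, reads in fam_reads.items():
        assert prof.family_summary.loc[f, "read_count"] == reads
        assert prof.family_summary.loc[f, "gene_count"] == len(fam_genes[f])
    for c, reads in cls_reads.items():
        assert prof.class_summary.loc[c, "read_count"] == reads


@pytest.mark.parametrize("k", [3, 17])
def test_scaling_reads_and_total_leaves_shares_unchanged(fmap, k):
    cat = random_catalog(7)
    scaled = GeneCatalog(
        [
            GeneRecord(r.gene_id, genus=r.genus, lineage=r.lineage,
                       families=r.families, read_count=r.read_count * k)
            for r in cat
        ],
        total_reads=cat.total_reads * k,
    )
    assert genus_abundances(cat).to_dict() == pytest.approx(
        genus_abundances(scaled).to_dict()
    )
    assert cazyme_read_fraction(cazyme_profile(cat, fmap), cat) == pytest.approx(
        cazyme_read_fraction(cazyme_profile(scaled, fmap), scaled)
    )


def test_adding_reads_to_a_genus_is_monotone():
    base = [("g1", "A", [], 100), ("g2", "B", [], 100)]
    before = genus_abundances(_catalog(base, 1000))
    after = genus_abundances(
        _catalog(base + [("g3", "A", [], 50)], 1000)
    )
    assert after["A"] > before["A"]
    assert after["B"] <= before["B"]
    # with the mapped-read denominator the others strictly shrink
    before_m = genus_abundances(_catalog(base, 1000), denominator="mapped")
    after_m = genus_abundances(
        _catalog(base + [("g3", "A", [], 50)], 1000), denominator="mapped"
    )
    assert after_m["B"] < before_m["B"]


def test_minor_genera_merge_is_report_time_only():
    cat = _catalog(
        [("g1", "A", [], 900), ("g2", "B", [], 5), ("g3", "C", [], 4)], 1000
    )
    ab = genus_abundances(cat)
    merged = merge_minor_genera(ab, threshold=0.01)
    assert set(merged.index) == {"A", "others"}
    assert merged["others"] == pytest.approx(0.009)
    # underlying series keeps every genus
    assert set(ab.index) == {"A", "B", "C"}


def test_percent_rounding_is_half_up():
    assert round_half_up(5.815, 2) == 5.82
    assert round_half_up(5.8149, 2) == 5.81
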