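from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from cazcontrib import (
    GeneCatalog,
    GeneRecord,
    ROLLUPS,
    UnknownCategoryError,
    classify_roles,
    contribution_coefficients,
    export_circos_table,
    function_distribution,
    genus_abundances,
    read_circos_table,
)
from cazcontrib.contribution import CCMatrix, DistributionMatrix

from conftest import random_catalog


def _catalog(spec, total_reads):
    return GeneCatalog(
        [
            GeneRecord(g, genus=gen,
                       lineage=() if gen == "unassigned" else (f"g:{gen}",),
                       families=frozenset(fams), read_count=n)
            for g, gen, fams, n in spec
        ],
        total_reads=total_reads,
    )


def _cc_from_shares(shares: dict, abundances: dict, function="f") -> CCMatrix:
    values = pd.DataFrame({function: pd.Series(shares, dtype=float)})
    counts = (values * 1000).astype(np.int64)
    dist = DistributionMatrix(
        values=values, counts=counts,
        function_reads=counts.sum().astype(np.int64),
    )
    return contribution_coefficients(dist, abundances)


def brute_force_distribution(catalog, fmap, functions):
    """Independent per-record re-aggregation of N_f and R_g-f."""
    n_f = defaultdict(int)
    n_gf = defaultdict(lambda: defaultdict(int))
    for rec in catalog:
        cats = set()
        for fam in rec.families:
            cats |= set(fmap.categories_of(fam))
        for fn in functions:
            if cats & set(ROLLUPS.get(fn, (fn,))):
                n_f[fn] += rec.read_count
                n_gf[fn][rec.genus] += rec.read_count
    return n_f, n_gf


def test_two_gene_distribution(fmap):
    cat = _catalog(
        [("g1", "A", ["GH10"], 80), ("g2", "B", ["GH10"], 20)], 1000
    )
    dist = function_distribution(cat, fmap, ["endo_xylanase"])
    assert dist.function_reads["endo_xylanase"] == 100
    assert dist.values.loc["A", "endo_xylanase"] == pytest.approx(0.8)
    assert dist.values.loc["B", "endo_xylanase"] == pytest.approx(0.2)


def test_gene_with_two_qualifying_families_counts_once(fmap):
    # GH5_4 and GH9 both map to endoglucanase
    cat = _catalog([("g1", "A", ["GH5_4", "GH9"], 60)], 1000)
    dist = function_distribution(cat, fmap, ["endoglucanase"])
    assert dist.function_reads["endoglucanase"] == 60


def test_rollup_function_counts_gene_once_across_members(fmap):
    # GH5_4 maps to several cellulose-member categories
    cat = _catalog([("g1", "A", ["GH5_4"], 30), ("g2", "B", ["GH1"], 10)], 1000)
    dist = function_distribution(cat, fmap, ["cellulose"])
    assert dist.function_reads["cellulose"] == 40


def test_unknown_function_rejected(fmap, toy_catalog):
    with pytest.raises(UnknownCategoryError):
        function_distribution(toy_catalog, fmap, ["sugar_magic"])


def test_cc_worked_example():
    cc = _cc_from_shares({"Ruminiclostridium": 0.1998},
                         {"Ruminiclostridium": 0.4285}, function="lignin_AA")
    assert round(float(cc.values.iloc[0, 0]), 3) == 0.466


def test_cc_proportional_representation_is_one():
    cc = _cc_from_shares({"A": 0.25}, {"A": 0.25})
    assert float(cc.values.iloc[0, 0]) == pytest.approx(1.0)


def test_cc_requires_all_abundances():
    with pytest.raises(KeyError):
        _cc_from_shares({"A": 0.5, "B": 0.5}, {"A": 0.5})


def test_zero_abundance_cell_is_undefined_not_zero():
    cc = _cc_from_shares({"A": 0.8, "B": 0.2}, {"A": 0.5, "B": 0.0})
    assert np.isnan(cc.values.loc["B"].iloc[0])


@pytest.mark.parametrize("seed", [11, 12])
def test_matrix_equals_brute_force_oracle(fmap, seed):
    cat = random_catalog(seed, n_genes=300)
    functions = ["endoglucanase", "beta_xylosidase", "esterase", "cellulose"]
    dist = function_distribution(cat, fmap, functions)
    n_f, n_gf = brute_force_distribution(cat, fmap, functions)
    for fn in functions:
        assert dist.function_reads[fn] == n_f.get(fn, 0)
        for genus in dist.genera:
            assert dist.counts.loc[genus, fn] == n_gf[fn].get(genus, 0)
    # column sums to one over all genera including unassigned
    for fn in functions:
        if n_f.get(fn, 0) > 0:
            assert dist.values[fn].sum() == pytest.approx(1.0)
    # weighted identity sum_g R_g * CC_g,f = 1
    ab = genus_abundances(cat)
    cc = contribution_coefficients(dist, ab)
    for fn in functions:
        if n_f.get(fn, 0) > 0:
            assert float((ab * cc.values[fn]).sum()) == pytest.approx(1.0)


def test_cc_invariant_under_uniform_rescaling(fmap):
    cat = random_catalog(13, n_genes=150)
    k = 5
    scaled = GeneCatalog(
        [GeneRecord(r.gene_id, genus=r.genus, lineage=r.lineage,
                    families=r.families, read_count=r.read_count * k)
         for r in cat],
        total_reads=cat.total_reads * k,
    )
    f = ["endoglucanase", "esterase"]
    cc1 = contribution_coefficients(
        function_distribution(cat, fmap, f), genus_abundances(cat))
    cc2 = contribution_coefficients(
        function_distribution(scaled, fmap, f), genus_abundances(scaled))
    pd.testing.assert_frame_equal(cc1.values, cc2.values)


def test_gene_count_mode(fmap):
    cat = _catalog(
        [("g1", "A", ["GH10"], 999), ("g2", "B", ["GH10"], 1)], 2000
    )
    dist = function_distribution(cat, fmap, ["endo_xylanase"], by="genes")
    assert dist.values.loc["A", "endo_xylanase"] == pytest.approx(0.5)


def test_classify_roles_extremes_and_undetermined():
    values = pd.DataFrame(
        {
            "endoglucanase": [2.0, 0.2, 2.0, np.nan],
            "beta_xylosidase": [2.0, 0.2, 0.2, np.nan],
        },
        index=["up", "down", "mixed", "empty"],
    )
    cc = CCMatrix(values=values, abundances=pd.Series(0.25, index=values.index))
    calls = classify_roles(cc, ["endoglucanase", "beta_xylosidase"],
                           cheater_quantile=0.75)
    assert calls == {
        "up": "contributor",
        "down": "cheater",
        "mixed": "intermediate",
        "empty": "undetermined",
    }
    with pytest.raises(ValueError):
        classify_roles(cc, [])


def test_circos_export_round_trip(fmap, tmp_path):
    cat = _catalog(
        [("g1", "A", ["GH10"], 70), ("g2", "B", ["GH10"], 30),
         ("g3", "A", ["CE1"], 10)], 1000
    )
    dist = function_distribution(cat, fmap, ["endo_xylanase", "esterase"])
    path = tmp_path / "circos_input.txt"
    export_circos_table(dist, path)
    lines = path.read_text().strip().split("\n")
    assert len(lines) == 3  # header + two genus rows
    assert lines[0].split("\t")[1:] == ["endo_xylanase", "esterase"]
    back = read_circos_table(path)
    pd.testing.assert_frame_equal(back, dist.counts, check_names=False)
    assert (back.sum(axis=0) == dist.function_reads).all()
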