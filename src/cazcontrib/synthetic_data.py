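"""Synthetic consortium gene catalogs with known ground truth.

Simulation starts at the annotation layer the analysis consumes — there are
no sequences, contigs, or reads, only a gene catalog with per-gene genus,
CAZy families, and mapped-read counts.  The generator plants:

* a genus abundance profile (read shares summing to ≤ 1; the remainder is
  the "unassigned" bin),
* a genus × function allocation multiplier ``m[g][f]`` steering how many
  function-f CAZyme genes genus g carries relative to proportional
  representation (m < 1 cheater-like, m > 1 contributor-like), and
* overdispersed per-gene read counts: each gene receives a Gamma-distributed
  relative coverage weight (shape = ``dispersion``; smaller is more
  overdispersed) and reads are drawn multinomially over genes, so per-gene
  counts are marginally negative-binomial-like while conditional read noise
  still shrinks as 1/sqrt(depth).

Because every function column of the share matrix renormalizes to 1, the
expected contribution coefficient of a cell is not the raw multiplier but

    E[CC_g,f] ≈ m'_g,f / Σ_g' R_g' m'_g,f

where m' folds in cross-listing (a gene drawn for one function whose family
also carries another activity counts in both columns).  The returned ground
truth therefore includes the analytically expected CC matrix alongside the
raw multipliers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import UNASSIGNED, GeneCatalog, GeneRecord
from .function_map import (
    CATEGORIES,
    HYDROLASE_CATEGORIES,
    FunctionMap,
    load_default_map,
)
from .profiling import ProfileTables

GENERATOR_VERSION = "cazcontrib-sim-1.0"

#: Genus-level read-share profile of the emulated thermophilic consortium:
#: nine dominant genera; the remaining 10.55% falls to the unassigned bin.
TMC7_GENUS_PROFILE: dict[str, float] = {
    "Ruminiclostridium": 0.4285,
    "Thermoanaerobacterium": 0.1841,
    "Geobacillus": 0.1044,
    "unclassified_f__Bacillaceae": 0.0748,
    "Aeribacillus": 0.0265,
    "Symbiobacterium": 0.0247,
    "Desulfotomaculum": 0.0233,
    "Caldibacillus": 0.0156,
    "Clostridium": 0.0126,
}

#: Default base weight of each function category in the CAZyme gene pool.
#: Hydrolase categories are equally weighted; the lignin and binding
#: buckets are down-weighted (few AA families; CBMs ride along as extra
#: modules too).
DEFAULT_BASE_WEIGHTS: dict[str, float] = {
    **{c: 1.0 for c in HYDROLASE_CATEGORIES},
    "lignin_AA": 0.3,
    "esterase": 1.0,
    "binding_module": 0.5,
}


@dataclass
class SimConfig:
    """Parameters of one synthetic catalog.

    ``allocation`` maps genus → (function category → multiplier); missing
    genera/functions default to 1 (proportional representation).
    ``dispersion`` is the Gamma shape of per-gene coverage weights (>0;
    2.0 gives a coefficient of variation of ~0.7, a modest overdispersion).
    """

    seed: int
    n_genes: int = 5000
    total_reads: int = 1_000_000
    genus_profile: dict[str, float] = field(
        default_factory=lambda: dict(TMC7_GENUS_PROFILE)
    )
    allocation: dict[str, dict[str, float]] = field(default_factory=dict)
    dispersion: float = 2.0
    noncazyme_fraction: float = 0.70
    base_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_WEIGHTS)
    )
    extra_cbm_prob: float = 0.15

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.total_reads <= 0:
            raise ValueError("n_genes and total_reads must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.noncazyme_fraction < 1:
            raise ValueError("noncazyme_fraction must be in [0, 1)")
        if any(v < 0 for v in self.genus_profile.values()):
            raise ValueError("genus abundances must be non-negative")
        if sum(self.genus_profile.values()) > 1 + 1e-9:
            raise ValueError("genus_profile sums to more than 1")
        for per_fn in self.allocation.values():
            if any(m < 0 for m in per_fn.values()):
                raise ValueError("allocation multipliers must be non-negative")

    def multiplier(self, genus: str, function: str) -> float:
        return float(self.allocation.get(genus, {}).get(function, 1.0))


def _full_profile(cfg: SimConfig) -> dict[str, float]:
    profile = dict(cfg.genus_profile)
    rest = 1.0 - sum(profile.values())
    profile[UNASSIGNED] = profile.get(UNASSIGNED, 0.0) + max(rest, 0.0)
    return profile


def _category_universe(cfg: SimConfig) -> list[str]:
    return [c for c in CATEGORIES if cfg.base_weights.get(c, 0.0) > 0]


def _cross_matrix(fmap: FunctionMap, cats: list[str]) -> pd.DataFrame:
    """X[f_drawn, f_counted]: probability that a gene drawn for f_drawn
    (family chosen uniformly from the curated list) is counted under
    f_counted by the aggregation."""
    x = pd.DataFrame(0.0, index=cats, columns=cats)
    for fd in cats:
        fams = sorted(fmap.families_for(fd))
        for fam in fams:
            for fc in fmap.categories_of(fam):
                if fc in x.columns:
                    x.loc[fd, fc] += 1.0 / len(fams)
    return x


def expected_cc(
    cfg: SimConfig, fmap: FunctionMap | None = None
) -> pd.DataFrame:
    """Analytically expected CC per genus × catalytic function.

    Folds the function-column renormalization and family cross-listing into
    the planted multipliers; the simulation estimate converges to this
    matrix as gene number and read depth grow.
    """
    fmap = fmap or load_default_map()
    profile = _full_profile(cfg)
    cats = _category_universe(cfg)
    genera = list(profile)
    q = pd.DataFrame(
        {
            f: [profile[g] * cfg.base_weights[f] * cfg.multiplier(g, f) for g in genera]
            for f in cats
        },
        index=genera,
    )
    incidence = q.to_numpy() @ _cross_matrix(fmap, cats).to_numpy()
    inc = pd.DataFrame(incidence, index=genera, columns=cats)
    share = inc / inc.sum(axis=0)
    pi = pd.Series(profile)
    return share.div(pi, axis=0)


def simulate_catalog(
    cfg: SimConfig, fmap: FunctionMap | None = None
) -> tuple[GeneCatalog, dict]:
    """Draw one catalog; return it with its ground-truth record.

    The joint (genus, function) assignment of CAZyme genes follows
    probabilities ∝ abundance × base weight × multiplier; non-CAZyme genes
    are then allocated so each genus's overall expected read share matches
    its planted abundance.  Reproducible given ``cfg.seed``.
    """
    fmap = fmap or load_default_map()
    rng = np.random.default_rng(cfg.seed)
    profile = _full_profile(cfg)
    genera = list(profile)
    pi = np.array([profile[g] for g in genera])
    cats = _category_universe(cfg)

    n_caz = int(round(cfg.n_genes * (1 - cfg.noncazyme_fraction)))
    n_non = cfg.n_genes - n_caz

    # joint genus × function assignment probabilities for CAZyme genes
    q = np.array(
        [
            [profile[g] * cfg.base_weights[f] * cfg.multiplier(g, f) for f in cats]
            for g in genera
        ]
    )
    q_total = q.sum()
    if q_total <= 0:
        raise ValueError("allocation leaves no probability mass for CAZyme genes")
    cell_counts = rng.multinomial(n_caz, (q / q_total).ravel()).reshape(q.shape)

    # non-CAZyme genes rebalance each genus to its target overall share
    phi = n_caz / cfg.n_genes
    if n_non > 0:
        r = (pi - phi * (q.sum(axis=1) / q_total)) / (1 - phi)
        if (r < -1e-9).any():
            bad = [g for g, v in zip(genera, r) if v < -1e-9]
            raise ValueError(
                f"infeasible profile: CAZyme allocation of {bad} exceeds its "
                "total abundance; lower multipliers or noncazyme_fraction"
            )
        r = np.clip(r, 0, None)
        r /= r.sum()
        non_counts = rng.multinomial(n_non, r)
    else:
        non_counts = np.zeros(len(genera), dtype=int)

    # subfamily-resolving family choice per category
    fam_choices = {
        f: sorted(
            sub
            for fam in fmap.families_for(f)
            for sub in (fmap.subfamilies_of(fam) or [fam])
        )
        for f in cats
    }
    cbm_pool = sorted(fmap.families_for("binding_module"))

    genus_col: list[str] = []
    family_col: list[frozenset[str]] = []
    for gi, g in enumerate(genera):
        for fi, f in enumerate(cats):
            k = cell_counts[gi, fi]
            if k == 0:
                continue
            fams = rng.choice(fam_choices[f], size=k)
            extra = (
                (rng.random(k) < cfg.extra_cbm_prob)
                if (cbm_pool and f != "binding_module")
                else np.zeros(k, dtype=bool)
            )
            extra_fams = rng.choice(cbm_pool, size=k) if cbm_pool else None
            for j in range(k):
                members = {str(fams[j])}
                if extra[j]:
                    members.add(str(extra_fams[j]))
                genus_col.append(g)
                family_col.append(frozenset(members))
        genus_col.extend([g] * int(non_counts[gi]))
        family_col.extend([frozenset()] * int(non_counts[gi]))

    order = rng.permutation(len(genus_col))
    genus_col = [genus_col[i] for i in order]
    family_col = [family_col[i] for i in order]

    # overdispersed coverage weights, then multinomial read sampling
    weights = rng.gamma(shape=cfg.dispersion, scale=1.0 / cfg.dispersion, size=cfg.n_genes)
    weights /= weights.sum()
    reads = rng.multinomial(cfg.total_reads, weights)

    records = []
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        g = genus_col[i]
        lineage = ("d:Bacteria",) if g == UNASSIGNED else ("d:Bacteria", f"g:{g}")
        records.append(
            GeneRecord(
                gene_id=f"gene_{i:0{width}d}",
                genus=g,
                lineage=lineage,
                families=family_col[i],
                read_count=int(reads[i]),
            )
        )
    catalog = GeneCatalog(records=records, total_reads=cfg.total_reads)

    genus_arr = np.array(genus_col)
    struct_share = {g: float(weights[genus_arr == g].sum()) for g in genera}
    ecc = expected_cc(cfg, fmap)
    truth = {
        "generator_version": GENERATOR_VERSION,
        "seed": cfg.seed,
        "n_genes": cfg.n_genes,
        "total_reads": cfg.total_reads,
        "genus_profile": profile,
        "allocation": {
            g: {f: cfg.multiplier(g, f) for f in cats} for g in genera
        },
        "expected_genus_read_share": struct_share,
        "expected_cc": {g: dict(ecc.loc[g]) for g in ecc.index},
    }
    return catalog, truth


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


# -- the emulated consortium preset -----------------------------------------

_CLUSTER_A = (
    "endoglucanase",
    "exoglucanase",
    "beta_glucosidase",
    "endo_xylanase",
    "beta_xylosidase",
    "beta_mannanase",
)
_CLUSTER_B = (
    "arabinofuranosidase",
    "alpha_mannosidase",
    "galactosidase",
    "alpha_rhamnosidase",
    "alpha_fucosidase",
    "glucuronidase",
)

PRESET_CONTRIBUTORS = ("Ruminiclostridium", "Thermoanaerobacterium")
PRESET_CHEATERS = ("Symbiobacterium", "Desulfotomaculum")


def tmc7_preset(
    seed: int,
    n_genes: int = 50_000,
    total_reads: int = 1_000_000,
    contributor_multiplier: float = 1.2,
    cheater_multiplier: float = 0.2,
    dispersion: float = 2.0,
) -> tuple[SimConfig, dict[str, str]]:
    """The emulated-consortium study condition.

    Plants the two dominant genera as contributors (multiplier ≥ 1.2 on all
    hydrolase functions, but lignin under-representation for the most
    abundant genus), the two planted cheaters (0.2 on all hydrolase
    functions, enriched in lignin/esterase), and gives the remaining five
    genera a split division of labor (1.5 on one substrate cluster, 0.6 on
    the other) so they are neither contributors nor cheaters overall.  The
    unassigned bin is balanced per function so the abundance-weighted mean
    multiplier is ~1 and planted multipliers are recovered as CCs.

    Returns the config and the planted role of each named genus.
    """
    if contributor_multiplier < 1.2:
        raise ValueError("contributor multiplier below the planted 1.2 floor")
    profile = dict(TMC7_GENUS_PROFILE)
    neutrals = [g for g in profile if g not in PRESET_CONTRIBUTORS + PRESET_CHEATERS]

    allocation: dict[str, dict[str, float]] = {}
    for g in PRESET_CONTRIBUTORS:
        allocation[g] = {f: contributor_multiplier for f in HYDROLASE_CATEGORIES}
    allocation["Ruminiclostridium"]["lignin_AA"] = 0.45
    for g in PRESET_CHEATERS:
        allocation[g] = {f: cheater_multiplier for f in HYDROLASE_CATEGORIES}
        allocation[g]["lignin_AA"] = 1.2
        allocation[g]["esterase"] = 1.2
    for i, g in enumerate(neutrals):
        hi, lo = (_CLUSTER_A, _CLUSTER_B) if i % 2 == 0 else (_CLUSTER_B, _CLUSTER_A)
        allocation[g] = {**{f: 1.5 for f in hi}, **{f: 0.6 for f in lo}}

    # balance the unassigned bin so each hydrolase column's
    # abundance-weighted mean multiplier is ~1
    pi_unassigned = 1.0 - sum(profile.values())
    allocation[UNASSIGNED] = {}
    for f in HYDROLASE_CATEGORIES:
        named = sum(
            profile[g] * allocation.get(g, {}).get(f, 1.0) for g in profile
        )
        allocation[UNASSIGNED][f] = max((1.0 - named) / pi_unassigned, 0.05)

    roles = {g: "intermediate" for g in neutrals}
    roles.update({g: "contributor" for g in PRESET_CONTRIBUTORS})
    roles.update({g: "cheater" for g in PRESET_CHEATERS})

    cfg = SimConfig(
        seed=seed,
        n_genes=n_genes,
        total_reads=total_reads,
        genus_profile=profile,
        allocation=allocation,
        dispersion=dispersion,
        noncazyme_fraction=0.70,
    )
    return cfg, roles


# -- printed-table fixtures ---------------------------------------------------

def fixture_tables() -> ProfileTables:
    """The published class-level and family-level summary tables as fixtures.

    Class summary: six CAZy classes with family counts, gene counts, and
    read numbers.  Family summary: the lignocellulolytic families with their
    summary-table section; section sums are recomputed from the rows.
    """
    with resources.as_file(
        resources.files("cazcontrib").joinpath("data/table1_class_summary.tsv")
    ) as p1:
        t1 = pd.read_csv(p1, sep="\t").set_index("cazy_class")
    with resources.as_file(
        resources.files("cazcontrib").joinpath("data/table2_family_summary.tsv")
    ) as p2:
        t2 = pd.read_csv(p2, sep="\t")
    sections = (
        t2.groupby("section")[["gene_count", "read_count"]].sum().sort_index()
    )
    family = t2.set_index("family")
    return ProfileTables(
        class_summary=t1, family_summary=family, section_sums=sections
    )
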