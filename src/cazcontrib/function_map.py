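"""Curated CAZy family → lignocellulolytic function ontology.

The mapping connects CAZy (sub)families to the enzymatic roles they play in
lignocellulose breakdown: the three cooperating cellulase activities, the
hemicellulose main-chain hydrolases, the debranching enzymes, carbohydrate
esterases, lignin-active auxiliary activities, and carbohydrate-binding
modules.  It is shipped as a packaged, editable TSV and is a frozen curation,
not an automatic derivation from a CAZy release.

Two views of membership coexist:

* ``listed`` entries form the curated per-function family lists whose
  cardinalities are the headline counts (10 endoglucanase families, 9
  beta-xylosidase families, ...).  :meth:`FunctionMap.families_for` returns
  these by default.
* A few extra entries record activities present in a family's catalogue
  description but outside the curated lists (e.g. the beta-glucuronidase
  activity of GH1).  :meth:`FunctionMap.categories_of` includes them, and so
  does read aggregation.

Subfamily handling: when a family is mapped at parent level with a
subfamily roll-up note (GH5, GH43), subfamily labels such as ``GH5_4``
inherit the parent's categories; an explicitly mapped subfamily (``GH30_8``)
matches only exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .annotation_io import FAMILY_PATTERN, CatalogError, family_class

#: Catalytic function categories (heatmap columns).
CATALYTIC_CATEGORIES = (
    "lignin_AA",
    "endoglucanase",
    "exoglucanase",
    "beta_glucosidase",
    "endo_xylanase",
    "beta_xylosidase",
    "beta_mannanase",
    "arabinofuranosidase",
    "alpha_mannosidase",
    "galactosidase",
    "alpha_rhamnosidase",
    "alpha_fucosidase",
    "glucuronidase",
    "esterase",
)

#: Full controlled vocabulary, including the non-catalytic CBM bucket.
CATEGORIES = CATALYTIC_CATEGORIES + ("binding_module",)

#: Substrate-level roll-ups of the catalytic categories.
ROLLUPS: dict[str, tuple[str, ...]] = {
    "cellulose": ("endoglucanase", "exoglucanase", "beta_glucosidase"),
    "hemicellulose": (
        "endo_xylanase",
        "beta_xylosidase",
        "beta_mannanase",
        "arabinofuranosidase",
        "alpha_mannosidase",
        "galactosidase",
        "alpha_rhamnosidase",
        "alpha_fucosidase",
        "glucuronidase",
        "esterase",
    ),
    "lignin": ("lignin_AA",),
}

#: GH-hydrolase categories used for contributor/cheater classification.
#: Lignin-active AAs and esterases are excluded: sugar cheaters are defined
#: by under-contribution to the hydrolytic (sugar-releasing) machinery.
HYDROLASE_CATEGORIES = tuple(
    c for c in CATALYTIC_CATEGORIES if c not in ("lignin_AA", "esterase")
)


class UnknownCategoryError(KeyError):
    """Raised when a function name is outside the controlled vocabulary."""


@dataclass
class FunctionMap:
    """Many-to-many CAZy family ↔ function category mapping.

    Attributes
    ----------
    entries
        One row per (family, category) membership, with ``listed`` marking
        curated-list membership and ``section`` the summary-table section of
        the family.  Families with no lignocellulolytic category appear with
        an empty category so their class/section metadata is retained.
    """

    entries: pd.DataFrame
    _cat_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        bad = sorted(
            f for f in self.entries["family"].unique() if not FAMILY_PATTERN.match(f)
        )
        if bad:
            raise CatalogError(f"malformed family label(s) in map: {bad}")
        cats = set(self.entries.loc[self.entries["category"] != "", "category"])
        unknown = sorted(cats - set(CATEGORIES))
        if unknown:
            raise UnknownCategoryError(f"unknown categories in map: {unknown}")

    # -- family-side metadata -------------------------------------------------

    @property
    def families(self) -> frozenset[str]:
        return frozenset(self.entries["family"])

    @property
    def class_of(self) -> dict[str, str]:
        return {f: family_class(f) for f in self.families}

    @property
    def section_of(self) -> dict[str, str]:
        return dict(zip(self.entries["family"], self.entries["section"]))

    @property
    def rollup_parents(self) -> frozenset[str]:
        roll = self.entries.loc[self.entries["subfamily_rollup"] == 1, "family"]
        return frozenset(roll)

    # -- lookups --------------------------------------------------------------

    def resolve_family(self, family: str) -> str | None:
        """Map a label to the map entry it falls under, or None if unmapped.

        Exact matches win; otherwise a subfamily label (``GH5_4``) resolves
        to its parent when the parent is mapped with a subfamily roll-up.
        """
        if not FAMILY_PATTERN.match(family):
            raise CatalogError(f"malformed CAZy family label: {family!r}")
        if family in self.families:
            return family
        parent = family.split("_")[0]
        if parent in self.rollup_parents:
            return parent
        return None

    def subfamilies_of(self, family: str) -> tuple[str, ...]:
        """Known subfamily labels of a roll-up parent (empty otherwise).

        Parsed from the map's source notes, e.g. ``GH5 → (GH5_1, GH5_2, ...)``.
        """
        if family not in self.rollup_parents:
            return ()
        notes = self.entries.loc[self.entries["family"] == family, "source_note"]
        subs: list[str] = []
        for note in notes:
            for tok in str(note).split():
                if tok.startswith(family + "_") and FAMILY_PATTERN.match(tok):
                    subs.append(tok)
        return tuple(dict.fromkeys(subs))

    def categories_of(self, family: str) -> frozenset[str]:
        """All function categories of a family label (empty if unmapped)."""
        cached = self._cat_cache.get(family)
        if cached is not None:
            return cached
        entry = self.resolve_family(family)
        if entry is None:
            result = frozenset()
        else:
            rows = self.entries.loc[
                (self.entries["family"] == entry) & (self.entries["category"] != ""),
                "category",
            ]
            result = frozenset(rows)
        self._cat_cache[family] = result
        return result

    def families_for(self, category: str, listed_only: bool = True) -> frozenset[str]:
        """Families of a category or roll-up (curated lists by default).

        Roll-up names (``cellulose``, ``hemicellulose``, ``lignin``) return
        the union over their member categories.  Parent-level roll-up
        entries (GH5, GH43) count as a single family label.
        """
        if category in ROLLUPS:
            out: set[str] = set()
            for member in ROLLUPS[category]:
                out |= self.families_for(member, listed_only=listed_only)
            return frozenset(out)
        if category not in CATEGORIES:
            raise UnknownCategoryError(category)
        mask = self.entries["category"] == category
        if listed_only:
            mask &= self.entries["listed"] == 1
        return frozenset(self.entries.loc[mask, "family"])

    def category_table(self) -> pd.DataFrame:
        """Curated-list cardinality per catalytic category (sorted by name)."""
        rows = [
            {"category": c, "family_count": len(self.families_for(c))}
            for c in CATALYTIC_CATEGORIES
        ]
        return pd.DataFrame(rows).set_index("category")


def load_map(path: str | Path) -> FunctionMap:
    """Load a function map TSV (family, cazy_class, category, section,
    subfamily_rollup, listed, source_note)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df["subfamily_rollup"] = df["subfamily_rollup"].replace("", "0").astype(int)
    df["listed"] = df["listed"].replace("", "0").astype(int)
    for fam, cls in zip(df["family"], df["cazy_class"]):
        if family_class(fam) != cls:
            raise CatalogError(
                f"map entry {fam!r} declares class {cls!r} but label implies "
                f"{family_class(fam)!r}"
            )
    return FunctionMap(entries=df)


def load_default_map() -> FunctionMap:
    """Load the packaged curation shipped with the library."""
    with resources.as_file(
        resources.files("cazcontrib").joinpath("data/function_map.tsv")
    ) as path:
        return load_map(path)
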