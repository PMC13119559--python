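"""Category schemes: the ordered legend of a categorical map plus the
reclassification table that collapses fine sensor-product codes into the
Level-1 classes the analysis runs on.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Category:
    """One land-cover class: integer id, short label, long name."""

    id: int
    abbrev: str
    name: str


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered set of categories and a fine-code -> category-id map.

    Parameters
    ----------
    categories
        Categories in declaration order. Ids must be unique and are kept in
        the listed order everywhere (matrix rows/columns, tie-breaks).
    reclass_map
        Mapping from source (fine) integer codes to category ids. May be
        empty for schemes used only on already-reclassified data.
    """

    categories: tuple[Category, ...]
    reclass_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.categories]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate category ids: {ids}")
        abbrevs = [c.abbrev for c in self.categories]
        if len(set(abbrevs)) != len(abbrevs):
            raise ValueError(f"duplicate category abbreviations: {abbrevs}")
        bad = {v for v in self.reclass_map.values() if v not in set(ids)}
        if bad:
            raise ValueError(f"reclass_map targets unknown category ids: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def ids(self) -> list[int]:
        return [c.id for c in self.categories]

    @property
    def abbrevs(self) -> list[str]:
        return [c.abbrev for c in self.categories]

    def __len__(self) -> int:
        return len(self.categories)

    def id_of(self, abbrev: str) -> int:
        for c in self.categories:
            if c.abbrev == abbrev:
                return c.id
        raise KeyError(abbrev)

    def abbrev_of(self, cat_id: int) -> str:
        for c in self.categories:
            if c.id == cat_id:
                return c.abbrev
        raise KeyError(cat_id)

    def index_of(self, cat_id: int) -> int:
        """Position of a category id in declaration order."""
        try:
            return self.ids.index(cat_id)
        except ValueError:
            raise KeyError(cat_id) from None

    def subset_labels(self, labels: list[str]) -> "CategoryScheme":
        keep = [c for c in self.categories if c.abbrev in set(labels)]
        return CategoryScheme(tuple(keep), {})


def _expand(codes: list[int | tuple[int, int]]) -> list[int]:
    out: list[int] = []
    for c in codes:
        if isinstance(c, tuple):
            out.extend(range(c[0], c[1] + 1))
        else:
            out.append(c)
    return out


#: Fine-code groups of the Level-1 land-cover legend. Ranges are inclusive.
_LEVEL1_TABLE: list[tuple[int, str, str, list[int | tuple[int, int]]]] = [
    (1, "CRP", "Cropland", [10, 11, 12, 20]),
    (2, "FST", "Forest", [(51, 92)]),
    (3, "SHR", "Shrubland", [120, 121, 122]),
    (4, "GRS", "Grassland", [130]),
    (5, "TUD", "Tundra", [140]),
    (6, "WET", "Wetland", [(181, 187)]),
    (7, "IMP", "Impervious Surface", [190]),
    (8, "BAL", "Bare Area", [150, 152, 153, (200, 202)]),
    (9, "WTR", "Water Body", [210]),
    (10, "PSI", "Permanent Snow/Ice", [220]),
]


def level1_scheme() -> CategoryScheme:
    """The ten-class Level-1 land-cover scheme (CRP ... PSI).

    Aggregates the 35-class fine legend of a 30 m global land-cover product
    into ten broad classes; e.g. all evergreen/deciduous broadleaf/needleleaf
    and mixed forest codes (51-92) collapse to Forest, the seven wetland
    sub-types (181-187) to Wetland.
    """
    cats = tuple(Category(i, a, n) for i, a, n, _ in _LEVEL1_TABLE)
    reclass: dict[int, int] = {}
    for cat_id, _, _, codes in _LEVEL1_TABLE:
        for code in _expand(codes):
            reclass[code] = cat_id
    return CategoryScheme(cats, reclass)


def simple_scheme(abbrevs: list[str]) -> CategoryScheme:
    """A minimal scheme with ids 1..n and identity reclassification.

    Handy for tests and synthetic landscapes where only the labels matter.
    """
    cats = tuple(Category(i + 1, a, a) for i, a in enumerate(abbrevs))
    return CategoryScheme(cats, {c.id: c.id for c in cats})
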