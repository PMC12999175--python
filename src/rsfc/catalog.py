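"""ROI catalog: names, hemispheres, functional categories, seed/target roles.

The analyses contrast occipital "seed" regions (three secondary visual
areas plus V1) against two families of "target" regions: prefrontal
subregions (language-, math-, and executive-responsive) and primary
sensory-motor areas (A1, S1/M1).  The catalog is plain metadata; it does
not know anything about time series.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ROI",
    "ROICatalog",
    "default_catalog",
    "SEED_CATEGORIES",
    "SECONDARY_VISUAL_CATEGORIES",
    "PFC_CATEGORIES",
    "SENSORY_MOTOR_CATEGORIES",
    "CATEGORIES",
    "HEMISPHERES",
]

SECONDARY_VISUAL_CATEGORIES: tuple[str, ...] = (
    "secondary_visual_LG",
    "secondary_visual_MTH",
    "secondary_visual_EF",
)
SEED_CATEGORIES: tuple[str, ...] = SECONDARY_VISUAL_CATEGORIES + ("V1",)
PFC_CATEGORIES: tuple[str, ...] = ("PFC_LANG", "PFC_MATH", "PFC_EF")
SENSORY_MOTOR_CATEGORIES: tuple[str, ...] = ("A1", "S1M1")
CATEGORIES: tuple[str, ...] = SEED_CATEGORIES + PFC_CATEGORIES + SENSORY_MOTOR_CATEGORIES
HEMISPHERES: tuple[str, ...] = ("L", "R")


@dataclass(frozen=True)
class ROI:
    """One region of interest.

    Parameters
    ----------
    name : str
        Unique label (column header in time-series tables).
    hemisphere : {"L", "R"}
    category : str
        One of :data:`CATEGORIES`.
    role : {"seed", "target"}
        Whether the ROI acts as an occipital seed or a non-visual target.
    """

    name: str
    hemisphere: str
    category: str
    role: str

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r} for ROI {self.name!r}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for ROI {self.name!r}")
        if self.role not in ("seed", "target"):
            raise ValueError(f"unknown role {self.role!r} for ROI {self.name!r}")


class ROICatalog:
    """Ordered collection of :class:`ROI` with lookup helpers.

    Invariants enforced at construction: unique names, every ROI has
    exactly one hemisphere and category, and the seed/target sets do not
    overlap (a name cannot appear with both roles).
    """

    def __init__(self, rois: list[ROI]):
        names = [r.name for r in rois]
        if len(set(names)) != len(names):
            raise ValueError("duplicate ROI names in catalog")
        self._rois: tuple[ROI, ...] = tuple(rois)
        self._by_name = {r.name: r for r in self._rois}

    def __len__(self) -> int:
        return len(self._rois)

    def __iter__(self):
        return iter(self._rois)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> ROI:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self._rois]

    def hemisphere(self, name: str) -> str:
        return self._by_name[name].hemisphere

    def category(self, name: str) -> str:
        return self._by_name[name].category

    def by_category(self, *categories: str) -> list[str]:
        """ROI names whose category is in ``categories`` (catalog order)."""
        cats = set(categories)
        unknown = cats - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        return [r.name for r in self._rois if r.category in cats]

    def seeds(self) -> list[str]:
        return [r.name for r in self._rois if r.role == "seed"]

    def targets(self) -> list[str]:
        return [r.name for r in self._rois if r.role == "target"]

    def secondary_visual(self) -> list[str]:
        return self.by_category(*SECONDARY_VISUAL_CATEGORIES)

    def v1(self) -> list[str]:
        return self.by_category("V1")

    def pfc(self) -> list[str]:
        return self.by_category(*PFC_CATEGORIES)

    def sensory_motor(self) -> list[str]:
        return self.by_category(*SENSORY_MOTOR_CATEGORIES)

    def index_of(self, names: list[str]) -> list[int]:
        order = {n: i for i, n in enumerate(self.names)}
        return [order[n] for n in names]


def default_catalog() -> ROICatalog:
    """Bilateral catalog: 9 categories x 2 hemispheres = 18 ROIs."""
    rois = []
    for cat in CATEGORIES:
        role = "seed" if cat in SEED_CATEGORIES else "target"
        for hemi in HEMISPHERES:
            rois.append(ROI(name=f"{cat}_{hemi}", hemisphere=hemi, category=cat, role=role))
    return ROICatalog(rois)
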