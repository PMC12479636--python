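"""Species/phenostage taxonomy: the 39-class registry and label semantics.

Nine woody species are monitored with a small, species-specific set of
discrete phenological stages (phenostages). Reproductive stages carry a
rank expressing seasonal progression; ``vegetative`` (no reproductive
organs visible) is deliberately unranked and acts as a fallback label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Stage",
    "STAGE_RANK",
    "PhenostageScheme",
    "build_default_scheme",
    "most_advanced_stage",
    "load_reference_metrics",
    "SYSTEMATIC_STAGES",
]


class Stage(str, Enum):
    """The eight phenostage labels."""

    SEEDLING = "seedling"
    FLOWERING_BUD = "flowering_bud"
    FLOWERING = "flowering"
    UNRIPE_FRUIT = "unripe_fruit"
    FRUIT = "fruit"
    RIPE_FRUIT = "ripe_fruit"
    SENESCENCE = "senescence"
    VEGETATIVE = "vegetative"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Seasonal-progression rank of the reproductive stages. ``vegetative`` has
#: no rank: it means "no reproductive organs visible" and never outranks a
#: ranked stage. ``fruit`` is the undivided fruiting label used where the
#: unripe/ripe distinction is not made; it sits between unripe and ripe.
STAGE_RANK: dict[Stage, int] = {
    Stage.SEEDLING: 1,
    Stage.FLOWERING_BUD: 2,
    Stage.FLOWERING: 3,
    Stage.UNRIPE_FRUIT: 4,
    Stage.FRUIT: 5,
    Stage.RIPE_FRUIT: 6,
    Stage.SENESCENCE: 7,
}

#: Stages that systematic (protocol-driven) phenology networks report and
#: that can be aligned with opportunistic image annotations.
SYSTEMATIC_STAGES: tuple[Stage, ...] = (
    Stage.FLOWERING,
    Stage.RIPE_FRUIT,
    Stage.SENESCENCE,
)


def _canon(name: str) -> str:
    return " ".join(name.split()).casefold()


def most_advanced_stage(stages: Iterable[Stage]) -> Stage:
    """Return the most seasonally advanced stage of a non-empty set.

    Images showing several reproductive stages at once are labeled with the
    most advanced one (e.g. flowering + fruiting -> fruiting). ``vegetative``
    is returned only when no ranked stage is present.

    Raises
    ------
    ValueError
        If ``stages`` is empty.
    """
    stages = set(Stage(s) for s in stages)
    if not stages:
        raise ValueError("most_advanced_stage: empty stage set is not a valid labeling")
    ranked = [s for s in stages if s in STAGE_RANK]
    if not ranked:
        return Stage.VEGETATIVE
    return max(ranked, key=STAGE_RANK.__getitem__)


@dataclass(frozen=True)
class PhenostageScheme:
    """Registry of species and the stages recorded for each.

    The default registry has 9 species and 39 (species, stage) classes.
    Species names are exact binomials; lookup is case-insensitive and
    whitespace-normalized.
    """

    stages_by_species: Mapping[str, tuple[Stage, ...]]
    _index: dict[str, str] = field(init=False, repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {_canon(sp): sp for sp in self.stages_by_species}
        )

    @property
    def species(self) -> list[str]:
        return list(self.stages_by_species)

    @property
    def classes(self) -> list[tuple[str, Stage]]:
        """All (species, stage) pairs, in registry order."""
        return [
            (sp, st)
            for sp, stages in self.stages_by_species.items()
            for st in stages
        ]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def resolve_species(self, name: str) -> str:
        """Map a species name to its canonical binomial (or raise KeyError)."""
        key = _canon(name)
        if key not in self._index:
            raise KeyError(f"unknown species: {name!r}")
        return self._index[key]

    def stages_for(self, species: str) -> tuple[Stage, ...]:
        return self.stages_by_species[self.resolve_species(species)]

    def has_class(self, species: str, stage: Stage | str) -> bool:
        try:
            sp = self.resolve_species(species)
        except KeyError:
            return False
        return Stage(stage) in self.stages_by_species[sp]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "stages": {sp: [s.value for s in st] for sp, st in self.stages_by_species.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: Mapping) -> "PhenostageScheme":
        stages = {
            sp: tuple(Stage(s) for s in d["stages"][sp]) for sp in d["species"]
        }
        return cls(stages_by_species=stages)

    @classmethod
    def from_json(cls, path: str | Path) -> "PhenostageScheme":
        return cls.from_dict(json.loads(Path(path).read_text()))


# Which species use the undivided "fruit" label (unripe/ripe hard to tell
# apart in the field) vs. the split unripe/ripe labels is fixed in the
# registry, not inferred. "seedling" is recorded only for Fagus sylvatica.
_DEFAULT_STAGES: dict[str, tuple[Stage, ...]] = {
    "Acer platanoides": (
        Stage.FLOWERING, Stage.FRUIT, Stage.SENESCENCE, Stage.VEGETATIVE,
    ),
    "Aesculus hippocastanum": (
        Stage.FLOWERING_BUD, Stage.FLOWERING, Stage.UNRIPE_FRUIT,
        Stage.RIPE_FRUIT, Stage.VEGETATIVE,
    ),
    "Betula pendula": (
        Stage.FLOWERING, Stage.FRUIT, Stage.SENESCENCE, Stage.VEGETATIVE,
    ),
    "Cornus mas": (
        Stage.FLOWERING, Stage.UNRIPE_FRUIT, Stage.RIPE_FRUIT, Stage.VEGETATIVE,
    ),
    "Crataegus laevigata": (
        Stage.FLOWERING_BUD, Stage.FLOWERING, Stage.RIPE_FRUIT, Stage.VEGETATIVE,
    ),
    "Fagus sylvatica": (
        Stage.SEEDLING, Stage.FLOWERING, Stage.FRUIT, Stage.SENESCENCE,
        Stage.VEGETATIVE,
    ),
    "Rosa canina": (
        Stage.FLOWERING, Stage.RIPE_FRUIT, Stage.VEGETATIVE,
    ),
    "Sambucus nigra": (
        Stage.FLOWERING_BUD, Stage.FLOWERING, Stage.UNRIPE_FRUIT,
        Stage.RIPE_FRUIT, Stage.VEGETATIVE,
    ),
    "Sorbus aucuparia": (
        Stage.FLOWERING_BUD, Stage.FLOWERING, Stage.RIPE_FRUIT,
        Stage.SENESCENCE, Stage.VEGETATIVE,
    ),
}


def build_default_scheme() -> PhenostageScheme:
    """Return the default 9-species, 39-class registry."""
    return PhenostageScheme(stages_by_species=_DEFAULT_STAGES)


def load_reference_metrics() -> pd.DataFrame:
    """Load the bundled reference per-class evaluation metrics.

    These are the published operating characteristics of a 39-class
    species-phenostage classifier trained on ~2,900 curated images:
    per-class train/test image counts and F1/recall/precision. Used by
    worked examples and tests as a fixed reference table.

    Returns a DataFrame with columns
    ``species, stage, train_n, test_n, f1, recall, precision``.
    """
    with resources.files("phenotag.data").joinpath("reference_class_metrics.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    df["stage"] = df["stage"].map(Stage)
    return df
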