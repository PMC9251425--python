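"""Food-group taxonomy for plant-based diet indices.

Foods are collapsed into food groups, each assigned to one of three
categories: healthy plant foods, less-healthy plant foods, and animal foods.
The default taxonomy has 17 groups; an optional ``fermented_foods`` group
(category configurable, default healthy plant) can be appended for cuisines
where fermented products are a distinct staple.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ClassificationError, MapValidationError

HEALTHY_PLANT = "healthy_plant"
UNHEALTHY_PLANT = "unhealthy_plant"
ANIMAL = "animal"
CATEGORIES = (HEALTHY_PLANT, UNHEALTHY_PLANT, ANIMAL)

#: Default group -> category assignment (17 groups).
DEFAULT_GROUPS: dict[str, str] = {
    # healthy plant foods
    "whole_grains": HEALTHY_PLANT,
    "fruits": HEALTHY_PLANT,
    "vegetables": HEALTHY_PLANT,
    "nuts": HEALTHY_PLANT,
    "legumes": HEALTHY_PLANT,
    "tea_coffee": HEALTHY_PLANT,
    "vegetable_oils": HEALTHY_PLANT,
    # less-healthy plant foods
    "refined_grains": UNHEALTHY_PLANT,
    "potatoes": UNHEALTHY_PLANT,
    "sugary_drinks": UNHEALTHY_PLANT,
    "sweets_desserts": UNHEALTHY_PLANT,
    "preserved_foods": UNHEALTHY_PLANT,
    # animal foods
    "animal_fats": ANIMAL,
    "dairy": ANIMAL,
    "eggs": ANIMAL,
    "fish_seafood": ANIMAL,
    "meat": ANIMAL,
}


@dataclass
class FoodGroupMap:
    """Mapping of food groups to categories plus an optional item-code lookup.

    Parameters
    ----------
    groups :
        ``group_id -> category`` with category one of ``healthy_plant``,
        ``unhealthy_plant``, ``animal``.
    item_map :
        Optional ``item_code -> group_id`` lookup for item-level inputs.
    n_expected :
        Number of groups the map must contain (17 for the default scheme).
    """

    groups: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    item_map: dict[str, str] = field(default_factory=dict)
    n_expected: int = 17

    def __post_init__(self):
        if len(self.groups) != self.n_expected:
            raise MapValidationError(
                f"food-group map must contain exactly {self.n_expected} groups, "
                f"got {len(self.groups)}"
            )
        bad = {g: c for g, c in self.groups.items() if c not in CATEGORIES}
        if bad:
            raise MapValidationError(f"unknown categories: {bad}")
        orphan = set(self.item_map.values()) - set(self.groups)
        if orphan:
            raise MapValidationError(f"item codes map to unknown groups: {sorted(orphan)}")

    # -- constructors ------------------------------------------------------
    @classmethod
    def default(cls, include_fermented: bool = False,
                fermented_category: str = HEALTHY_PLANT) -> "FoodGroupMap":
        groups = dict(DEFAULT_GROUPS)
        n = 17
        if include_fermented:
            groups["fermented_foods"] = fermented_category
            n = 18
        return cls(groups=groups, n_expected=n)

    @classmethod
    def from_yaml(cls, path) -> "FoodGroupMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            groups=dict(raw["groups"]),
            item_map=dict(raw.get("item_map", {})),
            n_expected=int(raw.get("n_expected", len(raw["groups"]))),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"groups": self.groups, "item_map": self.item_map,
                 "n_expected": self.n_expected},
                fh, sort_keys=False,
            )

    # -- queries -----------------------------------------------------------
    @property
    def group_ids(self) -> list[str]:
        return list(self.groups)

    def groups_in(self, category: str) -> list[str]:
        return [g for g, c in self.groups.items() if c == category]

    @property
    def plant_groups(self) -> list[str]:
        return [g for g, c in self.groups.items() if c != ANIMAL]

    def classify(self, item_code) -> str:
        """Map an item code to its food group; unmapped codes raise."""
        try:
            return self.item_map[item_code]
        except KeyError:
            raise ClassificationError(item_code) from None


def classify_food_item(item_code, food_group_map: FoodGroupMap) -> str:
    """Return the group id for ``item_code`` under ``food_group_map``."""
    return food_group_map.classify(item_code)
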