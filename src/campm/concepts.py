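"""Visual-concept vocabulary and its generative structure.

A *visual concept* is a boolean annotation attached to a wearable-camera
photograph, indicating a microenvironment or activity relevant to fine
particulate (PM2.5) exposure: cooking-related concepts, travel modes,
occupational settings, non-cooking combustion, and coarse indoor/outdoor
location.  Concepts are non-exclusive within a photograph: a participant can
be in the kitchen while a biomass stove burns and someone smokes.

For simulation we impose a generative structure the annotation data alone do
not have: *base states* are mutually exclusive microenvironments visited one
at a time (kitchen, road, agricultural field, office/shop, industry, other
indoor), while *overlay* concepts (smoking, stoves, flame, food preparation,
eating) are episodic events that can co-occur with compatible base states.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Concept name -> category.  The five categories group concepts the way the
#: annotation protocol does; location concepts are excluded from regression
#: (collinear with activities) but kept for descriptives.
DEFAULT_CATEGORIES: dict[str, str] = {
    "biomass_cooking_unit": "cooking",
    "lpg_stove": "cooking",
    "other_cooking_unit": "cooking",
    "food_preparation": "cooking",
    "eating": "cooking",
    "kitchen": "cooking",
    "travel_bus": "travel",
    "travel_bicycle": "travel",
    "travel_auto_rickshaw": "travel",
    "travel_motorcycle": "travel",
    "travel_car": "travel",
    "road": "travel",
    "office_shop": "occupation",
    "work_field": "occupation",
    "industry": "occupation",
    "informal_work": "occupation",
    "diesel_generator": "other_combustion",
    "smoking": "other_combustion",
    "visible_flame_smoke": "other_combustion",
    "indoors": "location",
    "in_vehicle": "location",
    "mixed": "location",
}

#: Mutually exclusive simulator base states.
BASE_STATES: tuple[str, ...] = (
    "kitchen",
    "road",
    "work_field",
    "office_shop",
    "industry",
    "indoors_other",
)

#: Episodic overlay concepts that attach to compatible base states.
OVERLAY_CONCEPTS: tuple[str, ...] = (
    "smoking",
    "lpg_stove",
    "biomass_cooking_unit",
    "visible_flame_smoke",
    "food_preparation",
    "eating",
)

#: Base state -> visual concepts implied while in that state.  ``indoors_other``
#: is not itself a concept; it only implies the location concept "indoors".
STATE_CONCEPTS: dict[str, tuple[str, ...]] = {
    "kitchen": ("kitchen", "indoors"),
    "road": ("road",),
    "work_field": ("work_field",),
    "office_shop": ("office_shop", "indoors"),
    "industry": ("industry",),
    "indoors_other": ("indoors",),
}

#: Overlay concept -> base states it may co-occur with.
DEFAULT_COMPATIBILITY: dict[str, tuple[str, ...]] = {
    "smoking": BASE_STATES,
    "lpg_stove": ("kitchen", "indoors_other"),
    "biomass_cooking_unit": ("kitchen", "indoors_other"),
    "visible_flame_smoke": ("kitchen", "road", "industry", "indoors_other"),
    "food_preparation": ("kitchen", "indoors_other"),
    "eating": ("kitchen", "indoors_other", "office_shop"),
}


@dataclass(frozen=True)
class ConceptVocabulary:
    """The concept list, its category grouping and simulator structure."""

    categories: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CATEGORIES))
    base_states: tuple[str, ...] = BASE_STATES
    overlays: tuple[str, ...] = OVERLAY_CONCEPTS
    state_concepts: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(STATE_CONCEPTS)
    )
    compatibility: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COMPATIBILITY)
    )

    @property
    def concepts(self) -> tuple[str, ...]:
        return tuple(self.categories)

    @property
    def location_concepts(self) -> tuple[str, ...]:
        return tuple(c for c, cat in self.categories.items() if cat == "location")

    def category_of(self, concept: str) -> str:
        try:
            return self.categories[concept]
        except KeyError:
            raise KeyError(f"unknown concept: {concept!r}") from None

    def validate(self) -> None:
        for state, implied in self.state_concepts.items():
            if state not in self.base_states:
                raise ValueError(f"state_concepts key {state!r} is not a base state")
            for c in implied:
                self.category_of(c)
        for overlay, states in self.compatibility.items():
            if overlay not in self.overlays:
                raise ValueError(f"compatibility key {overlay!r} is not an overlay")
            for s in states:
                if s not in self.base_states:
                    raise ValueError(f"{overlay!r} compatible with unknown state {s!r}")


DEFAULT_VOCABULARY = ConceptVocabulary()
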