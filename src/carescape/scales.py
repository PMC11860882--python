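"""The demand indicator system: three primary indicators, eleven items.

The battery measures what older residents want from community elder-care
facilities.  Each item is answered on a five-point Likert scale (1 = not
needed ... 5 = very needed) plus a companion walking-time question coded
1 (<=5 min), 2 (5-10 min), 3 (10-15 min).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError


@dataclass(frozen=True)
class ScaleDefinition:
    """One primary indicator and the ordered items that measure it."""

    scale_name: str
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.item_ids) < 2:
            raise ConfigurationError(
                f"scale {self.scale_name!r} needs at least 2 items"
            )
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ConfigurationError(
                f"scale {self.scale_name!r} has duplicate item ids"
            )


LIFE_CARE = ScaleDefinition(
    "life_care",
    ("bathing_assistance", "daytime_care", "canteen", "night_care"),
)
MEDICAL_SECURITY = ScaleDefinition(
    "medical_security",
    ("rehabilitation_nursing", "healthcare", "spiritual_consolation"),
)
CULTURAL_ENTERTAINMENT = ScaleDefinition(
    "cultural_entertainment",
    ("chess_cards", "sports_activities", "art_activities", "university"),
)

DEFAULT_SCALES: tuple[ScaleDefinition, ...] = (
    LIFE_CARE,
    MEDICAL_SECURITY,
    CULTURAL_ENTERTAINMENT,
)

ALL_ITEMS: tuple[str, ...] = tuple(
    item for scale in DEFAULT_SCALES for item in scale.item_ids
)

#: walking-time companion column for a Likert item
def walk_column(item_id: str) -> str:
    return f"walk_{item_id}"


WALK_ITEMS: tuple[str, ...] = tuple(walk_column(i) for i in ALL_ITEMS)

#: binary demand indicator column written by the synthetic generator
def need_column(scale_name: str) -> str:
    return f"need_{scale_name}"


def scales_by_name(
    scales: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
) -> dict[str, ScaleDefinition]:
    return {s.scale_name: s for s in scales}
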