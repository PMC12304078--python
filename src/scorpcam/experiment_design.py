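"""Stage 2: choosing experimental background greys by Weber contrast.

The choice arena uses three printed grey backgrounds. The *medium* grey is
the patch of a calibrated grey scale with the smallest absolute Weber
contrast to the luminance of a medium-grey-adapted scorpionfish (the study
achieved 0.03). The *light* and *dark* greys are the patches whose Weber
contrast against the light-/dark-adapted fish comes closest to +0.33 and
-0.33 respectively — clearly lighter and darker than the fish can render
itself. The starting zone takes the geometric mean of the two backgrounds
in play (intermediate on the log-luminance scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rnl import weber_contrast

__all__ = [
    "GreyPatch",
    "GreyScale",
    "BackgroundDesign",
    "select_medium",
    "select_extremes",
    "starting_zone",
    "design_backgrounds",
]

DEFAULT_EXTREME_CONTRAST = 0.33


@dataclass(frozen=True)
class GreyPatch:
    label: str
    luminance: float


@dataclass(frozen=True)
class GreyScale:
    """Grey patches ordered by luminance (observer catch units)."""

    patches: tuple[GreyPatch, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if any(p.luminance <= 0 for p in self.patches):
            raise ValueError("grey patch luminances must be positive")
        ordered = tuple(sorted(self.patches, key=lambda p: p.luminance))
        object.__setattr__(self, "patches", ordered)

    def __len__(self) -> int:
        return len(self.patches)


@dataclass(frozen=True)
class BackgroundDesign:
    """The three selected backgrounds with achieved contrasts and zones."""

    dark: GreyPatch
    medium: GreyPatch
    light: GreyPatch
    achieved_contrasts: dict[str, float]
    starting_zone_luminance: dict[str, float]

    def __post_init__(self) -> None:
        if not self.dark.luminance < self.medium.luminance < self.light.luminance:
            raise ValueError("backgrounds must be ordered dark < medium < light in luminance")


def select_medium(fish_lum_medium_adapted: float, greys: GreyScale) -> tuple[GreyPatch, float]:
    """Patch minimising |Weber contrast| to the medium-adapted fish.

    Ties break toward the darker patch. Returns (patch, achieved signed
    contrast).
    """
    if len(greys) == 0:
        raise ValueError("empty grey scale")
    best = None
    for patch in greys.patches:  # ascending luminance: first win = darker tie-break
        c = weber_contrast(patch.luminance, fish_lum_medium_adapted)
        if best is None or abs(c) < abs(best[1]) - 1e-15:
            best = (patch, c)
    return best


def select_extremes(
    fish_lum_light_adapted: float,
    fish_lum_dark_adapted: float,
    greys: GreyScale,
    target: float = DEFAULT_EXTREME_CONTRAST,
) -> tuple[tuple[GreyPatch, float], tuple[GreyPatch, float]]:
    """Light and dark background patches at +-``target`` Weber contrast.

    The light background is the patch whose contrast against the
    light-adapted fish is closest to ``+target`` (lighter than the fish);
    the dark background targets ``-target`` against the dark-adapted fish.
    Returns ((light_patch, contrast), (dark_patch, contrast)).
    """
    if len(greys) == 0:
        raise ValueError("empty grey scale")

    def closest(fish_lum: float, wanted: float) -> tuple[GreyPatch, float]:
        best = None
        for patch in greys.patches:
            c = weber_contrast(patch.luminance, fish_lum)
            if best is None or abs(c - wanted) < abs(best[1] - wanted) - 1e-15:
                best = (patch, c)
        return best

    light = closest(fish_lum_light_adapted, +target)
    dark = closest(fish_lum_dark_adapted, -target)
    return light, dark


def starting_zone(bg_a_lum: float, bg_b_lum: float) -> float:
    """Intermediate (geometric-mean) luminance for the starting zone.

    Strictly between the two backgrounds whenever they differ; intermediacy
    on the log scale matches the perceptual (Weber/log) spacing used
    throughout.
    """
    if bg_a_lum <= 0 or bg_b_lum <= 0:
        raise ValueError("background luminances must be positive")
    return float(np.sqrt(bg_a_lum * bg_b_lum))


def design_backgrounds(
    fish_lum_dark_adapted: float,
    fish_lum_medium_adapted: float,
    fish_lum_light_adapted: float,
    greys: GreyScale,
    target: float = DEFAULT_EXTREME_CONTRAST,
) -> BackgroundDesign:
    """Full background design: three greys, contrasts, per-treatment zones."""
    medium, c_medium = select_medium(fish_lum_medium_adapted, greys)
    (light, c_light), (dark, c_dark) = select_extremes(
        fish_lum_light_adapted, fish_lum_dark_adapted, greys, target
    )
    zones = {
        "dark_light": starting_zone(dark.luminance, light.luminance),
        "medium_light": starting_zone(medium.luminance, light.luminance),
        "medium_dark": starting_zone(medium.luminance, dark.luminance),
    }
    return BackgroundDesign(
        dark=dark,
        medium=medium,
        light=light,
        achieved_contrasts={"dark": c_dark, "medium": c_medium, "light": c_light},
        starting_zone_luminance=zones,
    )
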