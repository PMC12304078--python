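"""Wavelength grids, spectra, visual pigment templates and observer presets.

The package models two fish observers:

* the scorpionfish *Scorpaena porcus* — a dichromat with cone sensitivities
  peaking at 455 and 530 nm, a 1:1 cone ratio, and the luminance channel
  defined as the long-wavelength (530 nm) cone;
* the prey triplefin *Tripterygion delaisi* — a trichromat peaking at 468,
  517 and 530 nm with a 0.25:1:1 cone ratio, luminance defined as the mean
  catch of the two longer-wavelength cones.

Both use a Weber fraction of 0.05 anchored on the most abundant cone class.
Pigment absorbance curves are built from the Govardovskii et al. (2000)
A1 alpha-band template, the standard nomogram for fish visual pigments; the
beta band is negligible above ~430 nm for these peaks and is off by default.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "VisualSystem",
    "DEFAULT_GRID",
    "pigment_template",
    "build_visual_system",
    "load_illuminant",
    "load_spectrum_csv",
    "make_depth_illuminant",
    "OBSERVER_PRESETS",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres (endpoints inclusive)."""

    start: float = 300.0
    stop: float = 700.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"grid start {self.start} must be < stop {self.stop}")
        if self.step <= 0:
            raise ValueError(f"grid step must be positive, got {self.step}")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1


DEFAULT_GRID = WavelengthGrid(300.0, 700.0, 1.0)


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed non-negative function on a :class:`WavelengthGrid`.

    ``kind`` tags the physical quantity: surface ``reflectance`` (bounded by
    1), an ``illuminant`` spectrum, or a receptor ``sensitivity`` curve.
    """

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.grid),):
            raise ValueError(
                f"values length {values.shape} does not match grid length {len(self.grid)}"
            )
        if np.any(values < 0):
            raise ValueError("spectrum values must be non-negative")
        if self.kind == "reflectance" and np.any(values > 1.0 + 1e-9):
            raise ValueError("reflectance values must be <= 1")
        if self.kind not in {"reflectance", "illuminant", "sensitivity"}:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.grid, self.values * factor, self.kind)


@dataclass(frozen=True)
class VisualSystem:
    """An observer: receptor peaks, relative cone abundances, noise, luminance.

    ``luminance_indices`` names the receptor(s) whose mean catch defines the
    achromatic (luminance) channel; a single index means a single-cone channel.
    """

    name: str
    peaks: tuple[float, ...]
    abundances: tuple[float, ...]
    weber_fraction: float
    luminance_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.peaks) != len(self.abundances):
            raise ValueError("peaks and abundances must have equal length")
        if any(b <= a for a, b in zip(self.peaks, self.peaks[1:])):
            raise ValueError("receptor peaks must be strictly ascending")
        if any(a <= 0 for a in self.abundances):
            raise ValueError("abundances must be positive")
        if self.weber_fraction <= 0:
            raise ValueError("Weber fraction must be positive")
        if any(i < 0 or i >= len(self.peaks) for i in self.luminance_indices):
            raise ValueError("luminance receptor index out of range")

    @property
    def n_receptors(self) -> int:
        return len(self.peaks)

    def sensitivities(self, grid: WavelengthGrid = DEFAULT_GRID, *, beta_band: bool = False) -> list[Spectrum]:
        """Pigment sensitivity curve for each receptor on ``grid``."""
        return [pigment_template(p, grid, beta_band=beta_band) for p in self.peaks]


# Named observer parameter sets. Weber fraction 0.05 refers to the most
# abundant cone class and the luminance channel in both species.
OBSERVER_PRESETS: dict[str, VisualSystem] = {
    "scorpaena_porcus": VisualSystem(
        name="scorpaena_porcus",
        peaks=(455.0, 530.0),
        abundances=(1.0, 1.0),
        weber_fraction=0.05,
        luminance_indices=(1,),  # long-wavelength cone
    ),
    "tripterygion_delaisi": VisualSystem(
        name="tripterygion_delaisi",
        peaks=(468.0, 517.0, 530.0),
        abundances=(0.25, 1.0, 1.0),
        weber_fraction=0.05,
        luminance_indices=(1, 2),  # mean of the two longer-wavelength cones
    ),
}


def build_visual_system(preset_name: str) -> VisualSystem:
    """Return a named observer preset.

    Available presets: ``scorpaena_porcus`` (dichromat scorpionfish viewer)
    and ``tripterygion_delaisi`` (trichromat prey viewer).
    """
    try:
        return OBSERVER_PRESETS[preset_name]
    except KeyError:
        raise KeyError(
            f"unknown observer preset {preset_name!r}; "
            f"available: {sorted(OBSERVER_PRESETS)}"
        ) from None


def pigment_template(
    lambda_max: float,
    grid: WavelengthGrid = DEFAULT_GRID,
    *,
    beta_band: bool = False,
) -> Spectrum:
    """Govardovskii A1 visual-pigment absorbance template.

    Alpha band: ``S(x) = 1 / (exp[A(a-x)] + exp[B(b-x)] + exp[C(c-x)] + D)``
    with ``x = lambda_max / lambda``, A=69.7, B=28, b=0.922, C=-14.9,
    c=1.104, D=0.674 and ``a = 0.8795 + 0.0459 exp(-(lambda_max-300)^2/11940)``.
    With ``beta_band=True`` the short-wavelength beta band of the same paper
    is added and the curve renormalised to unit maximum.

    Parameters
    ----------
    lambda_max:
        Peak wavelength in nm; must lie in [330, 600] (template validity).
    """
    if not 330.0 <= lambda_max <= 600.0:
        raise ValueError(f"lambda_max {lambda_max} nm outside supported range [330, 600]")
    lam = grid.wavelengths
    x = lambda_max / lam
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    values = alpha
    if beta_band:
        a_beta = 0.26
        lam_beta = 189.0 + 0.315 * lambda_max
        b_beta = -40.5 + 0.195 * lambda_max
        beta = a_beta * np.exp(-(((lam - lam_beta) / b_beta) ** 2))
        values = alpha + beta
        values = values / values.max()
    return Spectrum(grid, values, kind="sensitivity")


def load_spectrum_csv(
    path: str | Path,
    grid: WavelengthGrid = DEFAULT_GRID,
    *,
    kind: str = "reflectance",
    normalise: bool = False,
) -> Spectrum:
    """Read a two-column ``wavelength_nm,value`` CSV and resample to ``grid``.

    Wavelengths must cover the grid; values are linearly interpolated.
    """
    table = pd.read_csv(path)
    cols = [c.strip() for c in table.columns]
    if len(cols) < 2:
        raise ValueError(f"spectrum file {path} must have two columns")
    wl = np.asarray(table.iloc[:, 0], dtype=float)
    val = np.asarray(table.iloc[:, 1], dtype=float)
    order = np.argsort(wl)
    wl, val = wl[order], val[order]
    lam = grid.wavelengths
    if wl[0] > lam[0] + 1e-9 or wl[-1] < lam[-1] - 1e-9:
        raise ValueError(
            f"spectrum file covers {wl[0]:g}-{wl[-1]:g} nm but the grid requires "
            f"{lam[0]:g}-{lam[-1]:g} nm"
        )
    values = np.interp(lam, wl, val)
    if normalise:
        values = values / values.max()
    return Spectrum(grid, values, kind=kind)


def load_illuminant(source: str | Path, grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Load an illuminant by builtin name (``"d65"``) or from a spectrum file.

    The result is resampled to ``grid`` by linear interpolation and normalised
    to unit maximum (only relative spectral power matters for contrast).
    """
    if isinstance(source, str) and source.lower() == "d65":
        ref = importlib.resources.files("scorpcam.data").joinpath("d65.csv")
        with importlib.resources.as_file(ref) as p:
            return load_spectrum_csv(p, grid, kind="illuminant", normalise=True)
    return load_spectrum_csv(source, grid, kind="illuminant", normalise=True)


def make_depth_illuminant(
    depth_m: float = 6.0,
    grid: WavelengthGrid = DEFAULT_GRID,
) -> Spectrum:
    """Synthetic depth-attenuated daylight for coastal water.

    A stand-in spectrum (not a field measurement): D65 multiplied by a
    wavelength-dependent Beer-Lambert attenuation with a clear-coastal
    absorption minimum near 480 nm, giving the blue-green shifted light
    typical of a few metres' depth. Normalised to unit maximum.
    """
    d65 = load_illuminant("d65", grid)
    lam = grid.wavelengths
    # crude diffuse attenuation coefficient (1/m), minimum in the blue-green
    k = 0.04 + 0.9 * ((lam - 480.0) / 220.0) ** 2
    values = d65.values * np.exp(-k * depth_m)
    return Spectrum(grid, values / values.max(), kind="illuminant")
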