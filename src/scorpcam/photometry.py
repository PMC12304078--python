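"""Quantum catches, grey-standard normalisation and camera-to-cone mapping.

Two routes produce observer cone catches:

1. the direct spectral route — ``Q_i = sum_lambda R(lambda) I(lambda)
   S_i(lambda) dlambda`` from a reflectance spectrum, an illuminant and the
   observer's pigment sensitivities; and
2. an image route — linear camera channel means inside a region of interest
   are normalised against a grey standard of known reflectance (von Kries
   style) and pushed through a least-squares linear map from camera-channel
   catches to observer cone catches.

The image route is a deliberately simple linear stand-in for full
multispectral camera calibration; inputs are assumed linear-encoded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectral import DEFAULT_GRID, Spectrum, VisualSystem, WavelengthGrid

__all__ = [
    "ConeCatch",
    "ROIMeasurement",
    "GreyStandard",
    "ChannelToConeMap",
    "quantum_catch",
    "catch_from_values",
    "luminance",
    "normalize_to_standard",
    "normalize_two_point",
    "roi_mean",
    "fit_channel_to_cone_map",
    "read_roi_table",
    "write_catch_table",
    "read_catch_table",
]


@dataclass(frozen=True)
class ConeCatch:
    """Per-receptor quantum catches and derived luminance for one stimulus."""

    catches: np.ndarray
    luminance: float
    observer: str
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "catches", np.asarray(self.catches, dtype=float))
        if np.any(self.catches < 0):
            raise ValueError("quantum catches must be non-negative")


@dataclass(frozen=True)
class ROIMeasurement:
    """Mean linear camera values over one region of interest."""

    photo_id: str
    label: str
    channel_means: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel_means", np.asarray(self.channel_means, dtype=float))
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


@dataclass(frozen=True)
class GreyStandard:
    """A grey patch of known nominal reflectance with its measured values."""

    nominal_reflectance: float
    measured_values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "measured_values", np.asarray(self.measured_values, dtype=float))
        if not 0.0 < self.nominal_reflectance < 1.0:
            raise ValueError("nominal reflectance must be in (0, 1)")


def _luminance_from_catches(catches: np.ndarray, observer: VisualSystem) -> float:
    idx = list(observer.luminance_indices)
    if max(idx) >= catches.shape[-1]:
        raise ValueError("luminance receptor index out of range for these catches")
    return float(np.mean(catches[..., idx], axis=-1))


def luminance(catch: ConeCatch, observer: VisualSystem) -> float:
    """Luminance-channel signal per the observer's definition.

    A single named receptor (scorpionfish: the long-wavelength cone) or the
    arithmetic mean of named receptors (triplefin: the two longer-wavelength
    cones).
    """
    if len(catch.catches) != observer.n_receptors:
        raise ValueError(
            f"catch has {len(catch.catches)} receptors, observer "
            f"{observer.name!r} expects {observer.n_receptors}"
        )
    return _luminance_from_catches(catch.catches, observer)


def catch_from_values(
    values: Sequence[float],
    observer: VisualSystem,
    label: str = "",
) -> ConeCatch:
    """Wrap raw per-receptor catch values, filling luminance from the observer."""
    arr = np.asarray(values, dtype=float)
    if arr.shape != (observer.n_receptors,):
        raise ValueError(
            f"expected {observer.n_receptors} catch values, got {arr.shape}"
        )
    return ConeCatch(arr, _luminance_from_catches(arr, observer), observer.name, label)


def quantum_catch(
    reflectance: Spectrum,
    illuminant: Spectrum,
    observer: VisualSystem,
    *,
    label: str = "",
    beta_band: bool = False,
) -> ConeCatch:
    """Observer cone catches of a reflectance spectrum under an illuminant.

    ``Q_i = sum R(lambda) I(lambda) S_i(lambda) dlambda`` on the common grid;
    linear in reflectance. Luminance follows the observer's channel
    definition.
    """
    if reflectance.grid != illuminant.grid:
        raise ValueError("reflectance and illuminant are on different grids")
    grid = reflectance.grid
    sens = observer.sensitivities(grid, beta_band=beta_band)
    q = np.array(
        [float(np.sum(reflectance.values * illuminant.values * s.values) * grid.step) for s in sens]
    )
    return ConeCatch(q, _luminance_from_catches(q, observer), observer.name, label)


def normalize_to_standard(measurement: ROIMeasurement, standard: GreyStandard) -> ROIMeasurement:
    """One-point grey-standard normalisation to reflectance estimates.

    Each channel is rescaled so the standard maps to its nominal reflectance:
    ``value_c = mean_c / standard_c * nominal``.
    """
    std = standard.measured_values
    if std.shape != measurement.channel_means.shape:
        raise ValueError("grey standard channel count does not match measurement")
    if np.any(std <= 0):
        raise ValueError("grey standard channel values must be positive")
    values = measurement.channel_means / std * standard.nominal_reflectance
    return ROIMeasurement(measurement.photo_id, measurement.label, values, measurement.n_pixels)


def normalize_two_point(
    measurement: ROIMeasurement,
    standard_low: GreyStandard,
    standard_high: GreyStandard,
) -> ROIMeasurement:
    """Two-point linear normalisation through two grey standards.

    Fits, per channel, the straight line mapping the two measured standard
    values (e.g. 12% and 72% greys) to their nominal reflectances and applies
    it to the measurement. Falls back on nothing: two distinct standards are
    required.
    """
    lo, hi = standard_low, standard_high
    if lo.nominal_reflectance >= hi.nominal_reflectance:
        lo, hi = hi, lo
    dv = hi.measured_values - lo.measured_values
    if np.any(np.abs(dv) <= 0):
        raise ValueError("grey standards have identical measured values in a channel")
    slope = (hi.nominal_reflectance - lo.nominal_reflectance) / dv
    values = lo.nominal_reflectance + slope * (measurement.channel_means - lo.measured_values)
    return ROIMeasurement(measurement.photo_id, measurement.label, values, measurement.n_pixels)


def roi_mean(
    image: np.ndarray,
    mask: np.ndarray,
    *,
    photo_id: str = "",
    label: str = "",
) -> ROIMeasurement:
    """Per-channel arithmetic mean of a linear image over a boolean mask.

    ``image`` is (rows, cols) or (rows, cols, channels), row-major with
    0-based pixel coordinates; ``mask`` is a same-shape-in-plane boolean map
    (nonzero = inside the ROI).
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if image.ndim == 2:
        image = image[..., None]
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape does not match image plane")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty ROI: mask selects no pixels")
    means = image[mask].mean(axis=0)
    return ROIMeasurement(photo_id, label, means, n)


@dataclass(frozen=True)
class ChannelToConeMap:
    """Linear least-squares map from camera-channel catches to cone catches."""

    matrix: np.ndarray  # (n_camera_channels, n_receptors)
    observer: str
    rms_relative_error: float

    def apply(self, channel_values: Sequence[float], observer: VisualSystem, label: str = "") -> ConeCatch:
        v = np.asarray(channel_values, dtype=float)
        if v.shape != (self.matrix.shape[0],):
            raise ValueError("channel count does not match the fitted map")
        q = v @ self.matrix
        q = np.clip(q, 0.0, None)
        return ConeCatch(q, _luminance_from_catches(q, observer), observer.name, label)


def fit_channel_to_cone_map(
    training_reflectances: Sequence[Spectrum],
    camera_sensitivities: Sequence[Spectrum],
    observer: VisualSystem,
    illuminant: Spectrum,
) -> ChannelToConeMap:
    """Fit the linear camera-to-observer catch transform on training spectra.

    Camera catches C and observer catches Q are computed for each training
    reflectance by the direct spectral route; the map M minimising
    ``||C M - Q||_F`` is found by least squares. The training RMS relative
    error (over entries of Q) is reported so gamut coverage problems are
    visible.
    """
    if len(training_reflectances) < 10:
        raise ValueError(
            f"need >= 10 training spectra spanning the gamut, got {len(training_reflectances)}"
        )
    grid = illuminant.grid
    cam = np.array(
        [
            [float(np.sum(r.values * illuminant.values * s.values) * grid.step) for s in camera_sensitivities]
            for r in training_reflectances
        ]
    )
    obs = np.array(
        [quantum_catch(r, illuminant, observer).catches for r in training_reflectances]
    )
    rank = np.linalg.matrix_rank(cam)
    if rank < cam.shape[1]:
        raise ValueError(
            f"training set is rank-deficient (rank {rank} < {cam.shape[1]} channels)"
        )
    matrix, *_ = np.linalg.lstsq(cam, obs, rcond=None)
    pred = cam @ matrix
    rel = (pred - obs) / np.where(obs == 0, 1.0, obs)
    rmse = float(np.sqrt(np.mean(rel**2)))
    return ChannelToConeMap(matrix, observer.name, rmse)


# ---------------------------------------------------------------------------
# Image and tabular I/O

def read_image(path: str | Path) -> np.ndarray:
    """Read a linear-encoded 16-bit TIFF/PNG as a float array.

    No gamma decoding is applied: inputs are declared linear. Returns
    (rows, cols) or (rows, cols, channels).
    """
    import imageio.v3 as iio

    return np.asarray(iio.imread(path), dtype=float)


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit mask image; nonzero pixels are inside the ROI."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr.max(axis=-1)
    return arr != 0


def read_roi_table(path: str | Path) -> list[ROIMeasurement]:
    """Read a ROI table CSV: photo_id,label,channel_1..channel_k,n_pixels."""
    table = pd.read_csv(path)
    chan_cols = [c for c in table.columns if c.startswith("channel_")]
    if not chan_cols:
        raise ValueError(f"{path}: no channel_* columns found")
    out = []
    for _, row in table.iterrows():
        out.append(
            ROIMeasurement(
                str(row["photo_id"]),
                str(row["label"]),
                row[chan_cols].to_numpy(dtype=float),
                int(row.get("n_pixels", 1)),
            )
        )
    return out


def write_catch_table(catches: Sequence[ConeCatch], path: str | Path, *, extra: pd.DataFrame | None = None) -> None:
    """Write cone catches as CSV with Q1..Qk and luminance columns."""
    k = len(catches[0].catches)
    rows = {
        "label": [c.label for c in catches],
        **{f"Q{i+1}": [c.catches[i] for c in catches] for i in range(k)},
        "luminance": [c.luminance for c in catches],
        "observer": [c.observer for c in catches],
    }
    frame = pd.DataFrame(rows)
    if extra is not None:
        frame = pd.concat([extra.reset_index(drop=True), frame], axis=1)
    frame.to_csv(path, index=False)


def read_catch_table(path: str | Path, observer: VisualSystem) -> pd.DataFrame:
    """Read a catch CSV (columns Q1..Qk plus metadata), recomputing luminance."""
    frame = pd.read_csv(path)
    qcols = sorted(
        (c for c in frame.columns if c.startswith("Q") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if len(qcols) != observer.n_receptors:
        raise ValueError(
            f"{path}: found {len(qcols)} catch columns, observer expects {observer.n_receptors}"
        )
    q = frame[qcols].to_numpy(dtype=float)
    frame["luminance"] = q[:, list(observer.luminance_indices)].mean(axis=1)
    return frame
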