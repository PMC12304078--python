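"""Receptor-noise-limited (RNL) contrasts, Weber contrast, JND thresholds.

Perceptual distances follow the Vorobyev-Osorio receptor-noise-limited model
with log-transformed receptor signals ``f_i = ln Q_i``. Channel noise is
``e_i = w * sqrt(eta_max / eta_i)`` so the stated Weber fraction ``w``
anchors the most abundant cone class. Chromatic distance uses the closed
dichromat / trichromat forms; the achromatic distance is the log luminance
ratio in Weber-fraction units, ``|ln(L_a/L_b)| / w``.

Distances are in Just Noticeable Difference (JND) units: values below 1 are
considered indistinguishable under ideal viewing; 3 JND is the conservative
detection threshold under natural conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .photometry import ConeCatch
from .spectral import VisualSystem

__all__ = [
    "ReceptorNoise",
    "ContrastResult",
    "receptor_noise",
    "log_receptor_contrast",
    "chromatic_jnd",
    "achromatic_jnd",
    "achromatic_jnd_from_luminance",
    "weber_contrast",
    "classify_jnd",
]


@dataclass(frozen=True)
class ReceptorNoise:
    """Per-receptor noise-to-signal ratios e_i."""

    e: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "e", np.asarray(self.e, dtype=float))
        if np.any(self.e <= 0):
            raise ValueError("receptor noise values must be positive")


@dataclass(frozen=True)
class ContrastResult:
    """Chromatic and achromatic JND for one (unordered) stimulus pair."""

    pair: tuple[str, str]
    chromatic_jnd: float
    achromatic_jnd: float


def receptor_noise(observer: VisualSystem) -> ReceptorNoise:
    """Noise per channel: ``e_i = w * sqrt(eta_max / eta_i)``.

    The Weber fraction applies to the most abundant class; rarer cones are
    noisier in proportion to the square root of their relative abundance.
    """
    eta = np.asarray(observer.abundances, dtype=float)
    e = observer.weber_fraction * np.sqrt(eta.max() / eta)
    return ReceptorNoise(e)


def _catch_values(c: ConeCatch | Sequence[float]) -> np.ndarray:
    if isinstance(c, ConeCatch):
        return c.catches
    return np.asarray(c, dtype=float)


def log_receptor_contrast(a: ConeCatch | Sequence[float], b: ConeCatch | Sequence[float]) -> np.ndarray:
    """Log receptor signals ``df_i = ln(Q_i,a / Q_i,b)`` (antisymmetric)."""
    qa, qb = _catch_values(a), _catch_values(b)
    if qa.shape != qb.shape:
        raise ValueError("stimuli have different receptor counts")
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise ValueError("log receptor contrast requires strictly positive catches")
    return np.log(qa / qb)


def chromatic_jnd(
    a: ConeCatch | Sequence[float],
    b: ConeCatch | Sequence[float],
    noise: ReceptorNoise,
) -> float:
    """RNL chromatic distance in JND for a di- or trichromatic observer.

    Dichromat: ``|df1 - df2| / sqrt(e1^2 + e2^2)``. Trichromat:
    ``sqrt[(e1^2 (df3-df2)^2 + e2^2 (df3-df1)^2 + e3^2 (df1-df2)^2) /
    ((e1 e2)^2 + (e1 e3)^2 + (e2 e3)^2)]``. Zero iff all df_i are equal
    (a pure luminance shift is invisible to the chromatic channel).
    """
    qa, qb = _catch_values(a), _catch_values(b)
    # canonical pair order makes the distance bit-exactly symmetric
    if tuple(qb) < tuple(qa):
        qa, qb = qb, qa
    df = log_receptor_contrast(qa, qb)
    e = noise.e
    if df.shape != e.shape:
        raise ValueError("noise vector length does not match receptor count")
    if len(df) == 2:
        return float(abs(df[0] - df[1]) / np.hypot(e[0], e[1]))
    if len(df) == 3:
        num = (
            e[0] ** 2 * (df[2] - df[1]) ** 2
            + e[1] ** 2 * (df[2] - df[0]) ** 2
            + e[2] ** 2 * (df[0] - df[1]) ** 2
        )
        den = (e[0] * e[1]) ** 2 + (e[0] * e[2]) ** 2 + (e[1] * e[2]) ** 2
        return float(np.sqrt(num / den))
    raise ValueError(f"unsupported observer arity: {len(df)} receptors (need 2 or 3)")


def achromatic_jnd_from_luminance(
    lum_a: float,
    lum_b: float,
    weber_fraction: float,
    *,
    form: str = "log",
) -> float:
    """Achromatic JND between two luminance-channel signals.

    ``form="log"`` (default): ``|ln(L_a / L_b)| / w``, scale-invariant and
    consistent with the log-signal chromatic channel. ``form="linear"``: the
    symmetric mean-referenced Weber ratio ``|L_a - L_b| / (w * mean(L))``.
    """
    if lum_a <= 0 or lum_b <= 0:
        raise ValueError("luminances must be strictly positive")
    if form == "log":
        hi, lo = max(lum_a, lum_b), min(lum_a, lum_b)  # bit-exact symmetry
        return float(np.log(hi / lo) / weber_fraction)
    if form == "linear":
        return float(abs(lum_a - lum_b) / (weber_fraction * 0.5 * (lum_a + lum_b)))
    raise ValueError(f"unknown achromatic form {form!r}")


def achromatic_jnd(
    a: ConeCatch,
    b: ConeCatch,
    observer: VisualSystem,
    *,
    form: str = "log",
) -> float:
    """Achromatic JND between two stimuli via the observer's luminance channel."""
    return achromatic_jnd_from_luminance(
        a.luminance, b.luminance, observer.weber_fraction, form=form
    )


def weber_contrast(lum: float, lum_ref: float) -> float:
    """Signed Weber contrast ``(L - L_ref) / L_ref`` against a reference.

    Positive means lighter than the reference, negative darker.
    """
    if lum_ref <= 0:
        raise ValueError("reference luminance must be positive")
    return (lum - lum_ref) / lum_ref


def classify_jnd(x: float) -> str:
    """Classify a JND value against the 1 and 3 JND detection thresholds.

    Boundaries go to the more detectable class: exactly 1 is ``above_1``,
    exactly 3 is ``above_3`` (conservative detection claims).
    """
    if x < 0:
        raise ValueError("JND values are non-negative")
    if x < 1.0:
        return "indistinguishable"
    if x < 3.0:
        return "above_1"
    return "above_3"
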