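"""Seeded generators emulating the study's field and behavioural data.

Nothing here is measured data: the generators produce inputs with the same
*structure* and realistic magnitudes so every pipeline stage can run and be
tested without downloads.

* ``gen_substrate_library`` — six substrate types with the study's photo
  census (12, 9, 9, 3, 5, 5). Each type has a mean reflectance built from a
  baseline plus Gaussian spectral bumps; photos vary by multiplicative
  lognormal jitter of the baseline (achromatic) and of each bump
  (chromatic). Catches come from the direct spectral route under D65.
* ``gen_choice_experiment`` — two species (23 + 27 fish), three binary
  treatments, per-treatment expected-success probabilities (defaults 0.9,
  0.8, 0.15 mirroring the direction of the study's choices), a configurable
  fraction of never-settling fish (default: five of the 27 *S. porcus*),
  and event streams with stop-and-go decoy pauses (< 5 s), sub-minute
  bouts, and exactly one qualifying >= 60 s bout for settlers.
* ``gen_fish_population`` / ``gen_pattern_experiment`` — per-fish bar
  luminances that respond to the adaptation background with a gain on the
  log scale, a species-specific internal bar contrast (in JND), and eight
  lognormal background samples per experimental background.
* ``gen_greyscale`` — a log-spaced grey scale for the design stage.

All generators are deterministic given (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .behaviour import (
    EXPECTED_BACKGROUND,
    TREATMENT_BACKGROUNDS,
    TREATMENTS,
    ChoiceRecord,
    EthogramEvent,
)
from .experiment_design import GreyPatch, GreyScale
from .pattern import N_BACKGROUND_SAMPLES, BackgroundSampleSet, BarMeasurement
from .photometry import ConeCatch, catch_from_values, quantum_catch
from .spectral import DEFAULT_GRID, Spectrum, VisualSystem, build_visual_system, load_illuminant
from .substrate_analysis import SUBSTRATE_TYPES, SubstratePhoto

__all__ = [
    "SpeciesParams",
    "SimulationConfig",
    "gen_substrate_library",
    "gen_fish_population",
    "gen_choice_experiment",
    "gen_pattern_experiment",
    "gen_greyscale",
]

TRIAL_HORIZON_S = 600.0

# (baseline reflectance, [(centre nm, width nm, amplitude), ...]) per type.
# Chosen once to look like the named substrates: bright broadband sand, green
# seagrass, dark stems and turf, yellow algae, red sponge.
SUBSTRATE_SPECTRA: dict[str, tuple[float, list[tuple[float, float, float]]]] = {
    "rubble_sand": (0.30, [(580.0, 160.0, 0.20)]),
    "seagrass_leaves": (0.06, [(550.0, 55.0, 0.22)]),
    "seagrass_stems": (0.04, [(620.0, 90.0, 0.10)]),
    "turf_algae": (0.035, [(555.0, 60.0, 0.09), (650.0, 60.0, 0.05)]),
    "yellow_algae": (0.10, [(575.0, 70.0, 0.28), (640.0, 80.0, 0.12)]),
    "red_sponge": (0.05, [(650.0, 55.0, 0.30)]),
}

DEFAULT_PHOTO_CENSUS: dict[str, int] = {
    "rubble_sand": 12,
    "seagrass_leaves": 9,
    "turf_algae": 9,
    "red_sponge": 3,
    "yellow_algae": 5,
    "seagrass_stems": 5,
}


@dataclass(frozen=True)
class SpeciesParams:
    """Generator parameters for one scorpionfish species.

    ``dark_bar_luminance`` is the dark bar's luminance catch when adapted to
    the medium background; ``internal_contrast_jnd`` the mean dark-to-light
    bar contrast in achromatic JND; ``gain`` the fraction of a log-luminance
    background shift that the bars track (0 = no adjustment, 1 = full).
    """

    dark_bar_luminance: float = 0.8
    internal_contrast_jnd: float = 10.0
    gain: float = 0.6
    log_sd_fish: float = 0.15
    log_sd_noise: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for every generator."""

    seed: int = 0
    photo_census: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PHOTO_CENSUS))
    substrate_achromatic_log_sd: float = 0.22
    substrate_chromatic_log_sd: float = 0.12
    n_fish: dict[str, int] = field(default_factory=lambda: {"maderensis": 23, "porcus": 27})
    never_settle_rate: dict[str, float] = field(
        default_factory=lambda: {"maderensis": 0.0, "porcus": 5.0 / 27.0}
    )
    choice_probabilities: dict[str, float] = field(
        default_factory=lambda: {"dark_light": 0.9, "medium_light": 0.8, "medium_dark": 0.15}
    )
    background_luminance: dict[str, float] = field(
        default_factory=lambda: {"dark": 0.5, "medium": 1.0, "light": 2.0}
    )
    background_sample_log_sd: float = 0.08
    species_params: dict[str, SpeciesParams] = field(
        default_factory=lambda: {
            "maderensis": SpeciesParams(internal_contrast_jnd=14.0),
            "porcus": SpeciesParams(internal_contrast_jnd=7.0),
        }
    )

    def __post_init__(self) -> None:
        for t, n in self.photo_census.items():
            if n < 1:
                raise ValueError(f"photo census for {t!r} must be >= 1")
            if t not in SUBSTRATE_TYPES:
                raise ValueError(f"unknown substrate type {t!r}")
        for p in self.choice_probabilities.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("choice probabilities must be in [0, 1]")
        for r in self.never_settle_rate.values():
            if not 0.0 <= r <= 1.0:
                raise ValueError("never-settle rates must be in [0, 1]")


# ---------------------------------------------------------------------------
# Stage 1 inputs


def _type_reflectance(
    substrate: str,
    grid,
    baseline_factor: float = 1.0,
    bump_factors: Sequence[float] | None = None,
) -> Spectrum:
    baseline, bumps = SUBSTRATE_SPECTRA[substrate]
    lam = grid.wavelengths
    values = np.full_like(lam, baseline * baseline_factor, dtype=float)
    for i, (centre, width, amp) in enumerate(bumps):
        f = 1.0 if bump_factors is None else bump_factors[i]
        values = values + amp * f * np.exp(-(((lam - centre) / width) ** 2))
    return Spectrum(grid, np.clip(values, 1e-4, 1.0), kind="reflectance")


def gen_substrate_library(
    config: SimulationConfig,
    observer: VisualSystem | None = None,
    *,
    return_spectra: bool = False,
):
    """Per-photo substrate cone catches with the study's census.

    Returns a list of :class:`SubstratePhoto` (and, when requested, the
    underlying reflectance spectra). Jitter: the whole spectrum scales by a
    lognormal factor (achromatic variation between photos) and each spectral
    bump by its own lognormal factor (chromatic variation).
    """
    rng = np.random.default_rng(config.seed)
    observer = observer or build_visual_system("scorpaena_porcus")
    illuminant = load_illuminant("d65")
    photos, spectra = [], []
    for substrate in sorted(config.photo_census):
        n_bumps = len(SUBSTRATE_SPECTRA[substrate][1])
        for i in range(config.photo_census[substrate]):
            base_f = float(np.exp(rng.normal(0.0, config.substrate_achromatic_log_sd)))
            bump_f = np.exp(
                rng.normal(0.0, config.substrate_chromatic_log_sd, n_bumps)
            ) * base_f
            refl = _type_reflectance(substrate, DEFAULT_GRID, base_f, bump_f)
            photo_id = f"{substrate}_{i + 1:02d}"
            catch = quantum_catch(refl, illuminant, observer, label=photo_id)
            photos.append(SubstratePhoto(substrate, photo_id, catch))
            spectra.append(refl)
    if return_spectra:
        return photos, spectra
    return photos


# ---------------------------------------------------------------------------
# Stage 2 inputs


def gen_greyscale(
    n_patches: int = 64,
    lum_range: tuple[float, float] = (0.2, 3.2),
) -> GreyScale:
    """Log-spaced grey scale: constant luminance ratio between neighbours."""
    if n_patches < 2:
        raise ValueError("a grey scale needs at least 2 patches")
    lo, hi = lum_range
    lums = np.geomspace(lo, hi, n_patches)
    patches = tuple(GreyPatch(f"g{i + 1:02d}", float(v)) for i, v in enumerate(lums))
    return GreyScale(patches, source="synthetic log-spaced scale")


# ---------------------------------------------------------------------------
# Stage 3 inputs


def _fish_ids(config: SimulationConfig) -> list[tuple[str, str]]:
    out = []
    for species in sorted(config.n_fish):
        for i in range(config.n_fish[species]):
            out.append((f"{species[:3]}_{i + 1:02d}", species))
    return out


def gen_choice_experiment(
    config: SimulationConfig,
) -> tuple[list[EthogramEvent], pd.DataFrame]:
    """Event streams plus the generator's intended choice per trial.

    Never-settling fish (a per-species rate; the realised count is
    ``round(rate * n)`` fish drawn at random) produce only movement and
    stop-and-go pauses shorter than 5 s in every treatment. Settling fish
    produce decoy pauses (< 5 s), possibly a sub-minute bout, then one
    qualifying >= 60 s bout on the chosen background, all within the
    10-minute trial.
    """
    rng = np.random.default_rng(config.seed)
    events: list[EthogramEvent] = []
    intent_rows = []
    for species in sorted(config.n_fish):
        n = config.n_fish[species]
        rate = config.never_settle_rate.get(species, 0.0)
        n_never = int(round(rate * n))
        never_idx = set(rng.choice(n, size=n_never, replace=False)) if n_never else set()
        for i in range(n):
            fish_id = f"{species[:3]}_{i + 1:02d}"
            for treatment in TREATMENTS:
                backgrounds = TREATMENT_BACKGROUNDS[treatment]
                if i in never_idx:
                    intended = None
                else:
                    expected = EXPECTED_BACKGROUND[treatment]
                    other = backgrounds[0] if backgrounds[1] == expected else backgrounds[1]
                    p = config.choice_probabilities[treatment]
                    intended = expected if rng.uniform() < p else other
                events.extend(
                    _trial_events(rng, fish_id, species, treatment, backgrounds, intended)
                )
                intent_rows.append(
                    {
                        "fish_id": fish_id,
                        "species": species,
                        "treatment": treatment,
                        "intended_choice": intended,
                    }
                )
    return events, pd.DataFrame(intent_rows)


def _trial_events(rng, fish_id, species, treatment, backgrounds, intended):
    """One trial's event stream; round-trips exactly through the scoring rules."""
    evs = []
    t = 0.0

    def add(state, duration):
        nonlocal t
        evs.append(EthogramEvent(fish_id, species, treatment, state, t, duration))
        t += duration

    n_decoys = int(rng.integers(1, 4))
    for _ in range(n_decoys):
        add("moving", float(rng.uniform(5.0, 20.0)))
        add(str(rng.choice(backgrounds)), float(rng.uniform(1.0, 4.5)))  # stop-and-go
    if intended is None:
        # never-settler: keep pausing < 5 s until the trial ends
        while t < TRIAL_HORIZON_S - 30.0:
            add("moving", float(rng.uniform(10.0, 40.0)))
            add(str(rng.choice(backgrounds)), float(rng.uniform(1.0, 4.5)))
        return evs
    if rng.uniform() < 0.5:
        # a settled-but-sub-minute bout, possibly on the other background
        add("moving", float(rng.uniform(3.0, 10.0)))
        add(str(rng.choice(backgrounds)), float(rng.uniform(6.0, 45.0)))
    add("moving", float(rng.uniform(3.0, 10.0)))
    add(intended, float(rng.uniform(60.0, min(180.0, TRIAL_HORIZON_S - t - 1.0))))
    return evs


# ---------------------------------------------------------------------------
# Stage 4 inputs


def gen_fish_population(
    config: SimulationConfig,
    *,
    observer: VisualSystem | None = None,
) -> pd.DataFrame:
    """Per-fish bar luminances under each adaptation background.

    Log dark-bar luminance = log(species base) + gain * (log L_bg - log
    L_medium) + fish effect + noise; the light bar sits a species-specific
    internal contrast (in JND, converted via the Weber fraction) above the
    dark bar, so light > dark always holds.
    """
    observer = observer or build_visual_system("tripterygion_delaisi")
    rng = np.random.default_rng(config.seed + 1)
    w = observer.weber_fraction
    lm = config.background_luminance["medium"]
    rows = []
    for fish_id, species in _fish_ids(config):
        par = config.species_params[species]
        fish_effect = rng.normal(0.0, par.log_sd_fish)
        contrast_fish = par.internal_contrast_jnd * float(np.exp(rng.normal(0.0, 0.15)))
        for background, lbg in sorted(config.background_luminance.items()):
            noise = rng.normal(0.0, par.log_sd_noise)
            log_dark = (
                np.log(par.dark_bar_luminance)
                + par.gain * (np.log(lbg) - np.log(lm))
                + fish_effect
                + noise
            )
            dark = float(np.exp(log_dark))
            light = float(dark * np.exp(w * contrast_fish))
            rows.append(
                {
                    "fish_id": fish_id,
                    "species": species,
                    "background": background,
                    "dark_bar": dark,
                    "light_bar": light,
                }
            )
    return pd.DataFrame(rows)


def _grey_catch(luminance: float, observer: VisualSystem, label: str = "") -> ConeCatch:
    # spectrally flat stimulus: every receptor catch equals the luminance signal
    return catch_from_values(np.full(observer.n_receptors, luminance), observer, label)


def gen_pattern_experiment(
    config: SimulationConfig,
    choices: Sequence[ChoiceRecord],
    *,
    observer: VisualSystem | None = None,
) -> tuple[list[BarMeasurement], dict[str, BackgroundSampleSet]]:
    """Bar measurements for every settled trial plus background sample sets.

    Bars use the fish-population model evaluated at the chosen background as
    the adaptation state; backgrounds get eight lognormally jittered grey
    samples around their design luminance.
    """
    observer = observer or build_visual_system("tripterygion_delaisi")
    population = gen_fish_population(config, observer=observer)
    lookup = population.set_index(["fish_id", "background"])
    rng = np.random.default_rng(config.seed + 2)
    bars = []
    for rec in choices:
        if rec.first_settled is None:
            continue
        row = lookup.loc[(rec.fish_id, rec.first_settled)]
        for bar, lum in (("dark_bar", row["dark_bar"]), ("light_bar", row["light_bar"])):
            bars.append(
                BarMeasurement(
                    rec.fish_id,
                    rec.species,
                    rec.treatment,
                    rec.first_settled,
                    bar,
                    _grey_catch(float(lum), observer, f"{rec.fish_id}_{bar}"),
                )
            )
    samples = {}
    for background, lbg in sorted(config.background_luminance.items()):
        lums = lbg * np.exp(
            rng.normal(0.0, config.background_sample_log_sd, N_BACKGROUND_SAMPLES)
        )
        samples[background] = BackgroundSampleSet(
            background,
            tuple(_grey_catch(float(v), observer, f"{background}_s{j + 1}") for j, v in enumerate(lums)),
        )
    return bars, samples
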