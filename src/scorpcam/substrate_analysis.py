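"""Stage 1: perceptual contrasts between and within natural substrate types.

Six substrate types (rubble and sand, seagrass leaves, seagrass stems, turf
algae, yellow algae, red sponge) are compared pairwise from the scorpionfish
viewer's perspective. Every photo of one type is compared against every
photo of the other (within-type: all unordered pairs of distinct photos),
giving 21 comparison categories for 6 types. Chromatic and achromatic JND
are then modelled with Gamma log-link GLMMs — comparison as the fixed
effect, first photo ID as the random intercept — and summarised as medians
with 95% compatibility intervals from 10,000 posterior draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement
from typing import Sequence

import numpy as np
import pandas as pd

from .mixedmodels import ModelFit, ModelSpec, PosteriorSummary, fit_glmm, posterior_draws, predict_levels
from .photometry import ConeCatch
from .rnl import achromatic_jnd, chromatic_jnd, classify_jnd, receptor_noise
from .spectral import VisualSystem

__all__ = [
    "SubstratePhoto",
    "SUBSTRATE_TYPES",
    "pairwise_contrasts",
    "substrate_models",
]

SUBSTRATE_TYPES = (
    "rubble_sand",
    "seagrass_leaves",
    "seagrass_stems",
    "turf_algae",
    "yellow_algae",
    "red_sponge",
)


@dataclass(frozen=True)
class SubstratePhoto:
    """One calibrated photo of a substrate: its per-photo mean cone catch."""

    substrate: str
    photo_id: str
    mean_catch: ConeCatch


def comparison_label(type_a: str, type_b: str) -> str:
    """Order-free label for a substrate pair (self-pairs allowed)."""
    a, b = sorted((type_a, type_b))
    return f"{a} vs {b}"


def pairwise_contrasts(
    photos: Sequence[SubstratePhoto],
    observer: VisualSystem,
    *,
    types: Sequence[str] = SUBSTRATE_TYPES,
) -> pd.DataFrame:
    """All between- and within-type photo-level contrasts.

    Between types A and B every A-photo is paired with every B-photo
    (n_A x n_B rows); within a type all unordered pairs of distinct photos
    (n(n-1)/2 rows). Returns a table with columns ``comparison, photo_a,
    photo_b, chromatic_jnd, achromatic_jnd``.
    """
    for p in photos:
        if p.substrate not in types:
            raise ValueError(f"unknown substrate label {p.substrate!r}")
    by_type: dict[str, list[SubstratePhoto]] = {t: [] for t in types}
    for p in photos:
        by_type[p.substrate].append(p)
    noise = receptor_noise(observer)
    rows = []
    for type_a, type_b in combinations_with_replacement(sorted(types), 2):
        if type_a == type_b:
            pairs = combinations(by_type[type_a], 2)
        else:
            pairs = ((pa, pb) for pa in by_type[type_a] for pb in by_type[type_b])
        label = comparison_label(type_a, type_b)
        for pa, pb in pairs:
            rows.append(
                {
                    "comparison": label,
                    "photo_a": pa.photo_id,
                    "photo_b": pb.photo_id,
                    "chromatic_jnd": chromatic_jnd(pa.mean_catch, pb.mean_catch, noise),
                    "achromatic_jnd": achromatic_jnd(pa.mean_catch, pb.mean_catch, observer),
                }
            )
    return pd.DataFrame(rows, columns=["comparison", "photo_a", "photo_b", "chromatic_jnd", "achromatic_jnd"])


def substrate_models(
    table: pd.DataFrame,
    *,
    n_draws: int = 10000,
    seed: int | None = None,
) -> dict[str, tuple[ModelFit, list[PosteriorSummary]]]:
    """Fit the two Gamma contrast models and summarise per comparison.

    One model per response (``chromatic_jnd``, ``achromatic_jnd``), each with
    comparison as fixed effect and ``photo_a`` as the random intercept.
    Summaries carry a JND-threshold class for the median
    (``indistinguishable`` / ``above_1`` / ``above_3``) in ``jnd_class``.
    """
    if table.empty:
        raise ValueError("empty comparison table")
    present = set(table["comparison"])
    types = sorted({t for label in present for t in label.split(" vs ")})
    expected = {comparison_label(a, b) for a, b in combinations_with_replacement(types, 2)}
    missing = sorted(expected - present)
    if missing:
        raise ValueError(f"comparison labels without rows: {missing}")
    out: dict[str, tuple[ModelFit, list[PosteriorSummary]]] = {}
    levels = pd.DataFrame({"comparison": sorted(table["comparison"].unique())})
    for i, response in enumerate(("chromatic_jnd", "achromatic_jnd")):
        spec = ModelSpec(response, "gamma_log", ("comparison",), "photo_a")
        fit = fit_glmm(table, spec)
        draws = posterior_draws(fit, n_draws, None if seed is None else seed + i)
        summaries = predict_levels(fit, draws, levels)
        out[response] = (fit, summaries)
    return out


def summaries_frame(summaries: Sequence[PosteriorSummary]) -> pd.DataFrame:
    """Posterior summaries as a table, annotated with the JND class."""
    return pd.DataFrame(
        {
            "level": [s.level for s in summaries],
            "median": [s.median for s in summaries],
            "ci_low": [s.ci_low for s in summaries],
            "ci_high": [s.ci_high for s in summaries],
            "jnd_class": [classify_jnd(s.median) for s in summaries],
        }
    )
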