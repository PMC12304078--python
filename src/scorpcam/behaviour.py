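"""Stage 3: ethogram scoring and the binomial background-choice model.

Each 10-minute trial yields a stream of timed behavioural states (moving, or
stationary on one of the two backgrounds). Scoring applies two rules:

* *duration settled* — only stationary bouts of at least 5 s count
  (shorter "stop-and-go" pauses are not choices);
* *first settled* — the background of the earliest stationary bout lasting
  at least 60 s; fish with no such bout never settled.

First-settled choices are re-encoded against the a-priori expectation per
treatment (dark over light, medium over light, medium over dark) as a
success/failure variable, and modelled with a binomial logit GLMM with
species x treatment fixed effects and fish ID as random intercept. Fish
that never settled in any treatment are excluded before fitting. Median
choice proportions per species x treatment with 95% compatibility intervals
come from 10,000 posterior draws; an interval excluding 0.5 flags a
non-random choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mixedmodels import ModelFit, ModelSpec, PosteriorSummary, fit_glmm, posterior_draws, predict_levels

__all__ = [
    "EthogramEvent",
    "ChoiceRecord",
    "TREATMENT_BACKGROUNDS",
    "EXPECTED_BACKGROUND",
    "settled_bouts",
    "first_settled",
    "encode_success",
    "score_events",
    "choice_analysis",
    "read_event_table",
]

SPECIES = ("maderensis", "porcus")
TREATMENTS = ("dark_light", "medium_light", "medium_dark")

# backgrounds present in each binary choice treatment
TREATMENT_BACKGROUNDS: dict[str, tuple[str, str]] = {
    "dark_light": ("dark", "light"),
    "medium_light": ("medium", "light"),
    "medium_dark": ("medium", "dark"),
}

# a-priori expected (success) background per treatment
EXPECTED_BACKGROUND: dict[str, str] = {
    "dark_light": "dark",
    "medium_light": "medium",
    "medium_dark": "medium",
}

MIN_BOUT_S = 5.0
MIN_SETTLE_S = 60.0
TRIAL_HORIZON_S = 600.0


@dataclass(frozen=True)
class EthogramEvent:
    """One timed behavioural state within a trial."""

    fish_id: str
    species: str
    treatment: str
    state: str  # background label or "moving"
    start_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("event duration must be positive")
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")


@dataclass(frozen=True)
class ChoiceRecord:
    """Scored outcome of one fish x treatment trial."""

    fish_id: str
    species: str
    treatment: str
    first_settled: str | None
    durations: dict[str, float]
    success: int | None

    def __post_init__(self) -> None:
        if (self.success is None) != (self.first_settled is None):
            raise ValueError("success is defined iff the fish first settled somewhere")


def _check_events(events: Sequence[EthogramEvent]) -> list[EthogramEvent]:
    ordered = sorted(events, key=lambda e: e.start_s)
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.start_s + prev.duration_s > nxt.start_s + 1e-9:
            raise ValueError(
                f"overlapping events for fish {prev.fish_id!r}: "
                f"[{prev.start_s}, {prev.start_s + prev.duration_s}) and [{nxt.start_s}, ...)"
            )
    return ordered


def settled_bouts(
    events: Sequence[EthogramEvent],
    min_bout_s: float = MIN_BOUT_S,
) -> dict[str, float]:
    """Total settled time per background, counting only bouts >= 5 s.

    Stop-and-go pauses shorter than ``min_bout_s`` are excluded; the
    boundary (exactly 5 s) counts.
    """
    durations: dict[str, float] = {}
    for ev in _check_events(events):
        if ev.state == "moving":
            continue
        durations.setdefault(ev.state, 0.0)
        if ev.duration_s >= min_bout_s:
            durations[ev.state] += ev.duration_s
    return durations


def first_settled(
    events: Sequence[EthogramEvent],
    min_settle_s: float = MIN_SETTLE_S,
) -> str | None:
    """Background of the earliest stationary bout lasting >= 1 minute.

    Returns None when the fish never settled that long anywhere.
    """
    for ev in _check_events(events):
        if ev.state != "moving" and ev.duration_s >= min_settle_s:
            return ev.state
    return None


def encode_success(choice: str, treatment: str) -> int:
    """Success/failure code for a first-settled background.

    Expected (1): dark in dark-light, medium in medium-light, medium in
    medium-dark; the opposite background codes 0.
    """
    backgrounds = TREATMENT_BACKGROUNDS.get(treatment)
    if backgrounds is None:
        raise ValueError(f"unknown treatment {treatment!r}")
    if choice not in backgrounds:
        raise ValueError(f"background {choice!r} is not part of treatment {treatment!r}")
    return int(choice == EXPECTED_BACKGROUND[treatment])


def score_events(events: Iterable[EthogramEvent]) -> list[ChoiceRecord]:
    """Score a full event table into one ChoiceRecord per fish x treatment."""
    by_trial: dict[tuple[str, str, str], list[EthogramEvent]] = {}
    for ev in events:
        by_trial.setdefault((ev.fish_id, ev.species, ev.treatment), []).append(ev)
    records = []
    for (fish_id, species, treatment), evs in sorted(by_trial.items()):
        durations = settled_bouts(evs)
        choice = first_settled(evs)
        success = None if choice is None else encode_success(choice, treatment)
        records.append(ChoiceRecord(fish_id, species, treatment, choice, durations, success))
    return records


def records_frame(records: Sequence[ChoiceRecord]) -> pd.DataFrame:
    rows = [
        {
            "fish_id": r.fish_id,
            "species": r.species,
            "treatment": r.treatment,
            "first_settled": r.first_settled,
            "success": r.success,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def choice_analysis(
    records: Sequence[ChoiceRecord],
    *,
    n_draws: int = 10000,
    seed: int | None = None,
) -> tuple[ModelFit, list[PosteriorSummary], dict[str, bool]]:
    """Binomial choice model with species x treatment effects.

    Fish that never settled in any treatment are excluded entirely;
    remaining trials without a settled choice are dropped. Returns the fit,
    a posterior summary of the expected-choice proportion per species x
    treatment, and non-random flags (CI excludes the 0.5 chance level).
    """
    frame = records_frame(records)
    settled_any = frame.groupby("fish_id")["success"].transform(lambda s: s.notna().any())
    frame = frame[settled_any]
    frame = frame.dropna(subset=["success"]).copy()
    frame["success"] = frame["success"].astype(float)

    cells = frame.groupby(["species", "treatment"]).size()
    expected_cells = [(s, t) for s in sorted(frame["species"].unique()) for t in TREATMENTS]
    missing = [c for c in expected_cells if c not in cells.index]
    if frame.empty or missing:
        raise ValueError(f"species x treatment cells without data: {missing or 'all'}")

    spec = ModelSpec("success", "binomial_logit", ("species * treatment",), "fish_id")
    fit = fit_glmm(frame, spec)
    draws = posterior_draws(fit, n_draws, seed)
    levels = pd.DataFrame(expected_cells, columns=["species", "treatment"])
    summaries = predict_levels(fit, draws, levels)
    non_random = {s.level: s.excludes(0.5) for s in summaries}
    return fit, summaries, non_random


def read_event_table(path: str | Path) -> list[EthogramEvent]:
    """Read a BORIS-style event CSV:
    fish_id,species,treatment,state,start_s,duration_s."""
    frame = pd.read_csv(path)
    required = {"fish_id", "species", "treatment", "state", "start_s", "duration_s"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        EthogramEvent(
            str(r.fish_id), str(r.species), str(r.treatment), str(r.state),
            float(r.start_s), float(r.duration_s),
        )
        for r in frame.itertuples()
    ]


def write_event_table(events: Sequence[EthogramEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "fish_id": [e.fish_id for e in events],
            "species": [e.species for e in events],
            "treatment": [e.treatment for e in events],
            "state": [e.state for e in events],
            "start_s": [e.start_s for e in events],
            "duration_s": [e.duration_s for e in events],
        }
    ).to_csv(path, index=False)
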