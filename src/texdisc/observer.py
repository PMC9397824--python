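"""Simulated observers for the triangle discrimination task.

An observer answers each triangle trial correctly with a probability that
depends on the trial's stimulus intensity x (the difference ratio) through
a logistic law with known ground-truth parameters — the generative
counterpart of the fitted psychometric function, which makes parameter
recovery by the analysis chain well-posed.  Two response models are
provided:

``plain_logistic``
    p(x) = 1 / (1 + exp(−(α + β x))).  With the default α = −ln 2 the
    chance level 1/3 of the triangle test holds exactly at x = 0.
``guess_floored``
    p(x) = 1/3 + (2/3) / (1 + exp(−(α + β x))): a high-threshold reading
    in which the logistic describes detection and misses fall back to a
    1-in-3 guess, so p(0) ≥ 1/3 by construction.

Observers are stateless across trials; training-induced improvement is
modelled by supplying a second observer with a steeper slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .stimuli import Block, TrialSpec
from .psychometrics import TrialRecord

FLOOR_MODES = ("plain_logistic", "guess_floored")


@dataclass(frozen=True)
class ObserverModel:
    """Ground-truth sensitivity of a simulated participant.

    ``alpha_true`` / ``beta_true`` are the logistic intercept and slope
    (per unit difference ratio).  Per-side overrides allow asymmetric
    sensitivity to coarser vs. finer comparisons.
    """

    alpha_true: float = -math.log(2.0)
    beta_true: float = 10.0
    floor_mode: str = "plain_logistic"
    side_overrides: Optional[dict] = None   # e.g. {"less_coarse": {"beta_true": 12}}

    def __post_init__(self) -> None:
        if self.beta_true < 0:
            raise ValueError("beta_true must be >= 0")
        if self.floor_mode not in FLOOR_MODES:
            raise ValueError(f"floor_mode must be one of {FLOOR_MODES}")

    @classmethod
    def zero_sensitivity(cls) -> "ObserverModel":
        """An observer who guesses uniformly: p(x) = 1/3 for all x."""
        return cls(alpha_true=-math.log(2.0), beta_true=0.0)

    def _params_for(self, side: Optional[str]) -> tuple[float, float]:
        alpha, beta = self.alpha_true, self.beta_true
        if side and self.side_overrides and side in self.side_overrides:
            ov = self.side_overrides[side]
            alpha = ov.get("alpha_true", alpha)
            beta = ov.get("beta_true", beta)
        return alpha, beta

    def trained(self, beta_gain: float) -> "ObserverModel":
        """A copy with the slope scaled by ``beta_gain`` (post-training state)."""
        return replace(self, beta_true=self.beta_true * beta_gain)


def p_correct(
    observer: ObserverModel, difference_ratio: float, side: Optional[str] = None
) -> float:
    """Probability of a correct triangle response at intensity x ≥ 0."""
    if difference_ratio < 0:
        raise ValueError("difference ratio must be >= 0")
    alpha, beta = observer._params_for(side)
    logistic = 1.0 / (1.0 + math.exp(-(alpha + beta * difference_ratio)))
    if observer.floor_mode == "guess_floored":
        return 1.0 / 3.0 + (2.0 / 3.0) * logistic
    return logistic


def simulate_trial_response(
    trial: TrialSpec, observer: ObserverModel, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw the observer's response to one trial.

    Returns ``(response_index, correct)``.  A correct response picks the
    odd position; an incorrect one picks uniformly between the two
    non-odd positions.
    """
    side = (
        "more_coarse"
        if trial.comparison.spatial_frequency < trial.standard.spatial_frequency
        else "less_coarse"
    )
    p = p_correct(observer, trial.difference_ratio, side)
    if rng.random() < p:
        return trial.odd_index, 1
    others = [i for i in range(3) if i != trial.odd_index]
    return others[int(rng.integers(2))], 0


def simulate_phase(
    block: Block,
    observer: ObserverModel,
    rng: np.random.Generator,
    participant: str = "sim",
    session: int = 1,
    condition: str = "active",
    phase: Optional[str] = None,
    trial_offset: int = 0,
    seed: int = 0,
) -> list[TrialRecord]:
    """Simulate one block and return its trial records in presentation order."""
    phase = phase or block.phase_label
    records = []
    for idx, trial in enumerate(block.trials):
        response, _ = simulate_trial_response(trial, observer, rng)
        records.append(
            TrialRecord(
                participant=participant,
                session=session,
                phase=phase,
                condition=condition,
                trial_idx=trial_offset + idx,
                f_st=trial.standard.spatial_frequency,
                f_co=trial.comparison.spatial_frequency,
                combination=trial.combination,
                odd_index=trial.odd_index,
                response_index=response,
                seed=seed,
            )
        )
    return records
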