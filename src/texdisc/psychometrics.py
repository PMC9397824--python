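"""Psychometric analysis: correct-response probability, logistic fits, PSE.

The discrimination data of one participant and phase are Bernoulli
outcomes Y_i over the stimulus-intensity axis x = |f_Co − f_St| / f_St.
Two logistic psychometric functions

    F(x | α, β) = 1 / (1 + exp(−(α + β x)))

are fitted by maximum likelihood, one per coarseness side (comparisons
below vs. above the standard frequency).  The point of subjective equality
(PSE) is the intensity at which the fitted probability crosses 0.50,
i.e. −α/β.  A fit only counts as converged when the estimate is finite,
the slope positive, and the PSE lies within the range of intensities
actually presented at baseline; non-convergence is a data state, not an
error.  The PSE drives the participant-specific construction of training
stimulus sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .stimuli import Stimulus, StimulusSet, difference_ratio

#: intensity range spanned by the default assessment set: 16/164 .. 64/164.
#: (printed elsewhere to 2–3 s.f. as 0.098 and 0.39)
RATIO_MIN = 16.0 / 164.0
RATIO_MAX = 64.0 / 164.0

SIDES = ("more_coarse", "less_coarse")
PHASES = ("familiarization", "iBL", "BL", "training", "RT")
CONDITIONS = ("active", "passive")


@dataclass(frozen=True)
class TrialRecord:
    """One completed triangle trial.

    ``correct`` is 1 iff the response index equals the odd-texture index.
    """

    participant: str
    session: int
    phase: str
    condition: str
    trial_idx: int
    f_st: float
    f_co: float
    combination: str
    odd_index: int
    response_index: int
    seed: int = 0

    @property
    def x(self) -> float:
        """Difference ratio (stimulus intensity) of this trial."""
        return difference_ratio(self.f_co, self.f_st)

    @property
    def correct(self) -> int:
        return int(self.response_index == self.odd_index)

    @property
    def side(self) -> str:
        return "more_coarse" if self.f_co < self.f_st else "less_coarse"


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "participant": r.participant,
            "session": r.session,
            "phase": r.phase,
            "condition": r.condition,
            "trial_idx": r.trial_idx,
            "f_st": r.f_st,
            "f_co": r.f_co,
            "diff_ratio": r.x,
            "combination": r.combination,
            "odd_idx": r.odd_index,
            "response_idx": r.response_index,
            "correct": r.correct,
            "seed": r.seed,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic fit for one coarseness side."""

    side: str
    alpha: float
    beta: float
    pse: Optional[float]
    converged: bool
    n_trials: int


def probability_correct(
    records: Sequence[TrialRecord],
    expected_comparisons: Optional[Sequence[float]] = None,
) -> tuple[dict[float, float], float]:
    """Per-stimulus proportions correct p_i and their unweighted mean.

    p_i is the number of correct responses to comparison stimulus i divided
    by the number of its presentations; the phase score averages the p_i
    over the comparison stimuli (the eight of the default set).  When
    ``expected_comparisons`` is given, every listed frequency must appear
    in the records.
    """
    if not records:
        raise ValueError("no trial records given")
    by_stim: dict[float, list[int]] = {}
    for r in records:
        by_stim.setdefault(r.f_co, []).append(r.correct)
    if expected_comparisons is not None:
        absent = sorted(set(expected_comparisons) - set(by_stim))
        if absent:
            raise ValueError(f"missing comparison stimuli in records: {absent}")
    p_i = {f: float(np.mean(v)) for f, v in sorted(by_stim.items())}
    return p_i, float(np.mean(list(p_i.values())))


def check_convergence(
    pse: Optional[float],
    ratio_min: float = RATIO_MIN,
    ratio_max: float = RATIO_MAX,
) -> bool:
    """A fit counts as converged iff its PSE lies within the assessed range."""
    if pse is None or not math.isfinite(pse):
        return False
    return ratio_min <= pse <= ratio_max


def fit_psychometric(
    records: Sequence[TrialRecord],
    side: Optional[str] = None,
    ratio_min: float = RATIO_MIN,
    ratio_max: float = RATIO_MAX,
) -> PsychometricFit:
    """Maximum-likelihood logistic fit of correctness against intensity.

    Fits only the records of one coarseness side (taken from ``side`` or,
    if omitted, inferred — the records must then be single-sided; pooling
    sides is never done here).  Perfect separation, non-finite estimates,
    a non-positive slope, or a PSE outside the assessed intensity range all
    yield ``converged=False``.
    """
    if side is not None:
        records = [r for r in records if r.side == side]
    else:
        sides = {r.side for r in records}
        if len(sides) > 1:
            raise ValueError("records span both sides; pass side= explicitly")
        side = sides.pop() if sides else "more_coarse"
    if not records:
        raise ValueError(f"no records for side {side!r}")

    x = np.array([r.x for r in records])
    y = np.array([r.correct for r in records])
    n = len(records)
    alpha = beta = math.nan

    if 0 < y.sum() < n and len(np.unique(x)) >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.Logit(y, sm.add_constant(x))
                res = model.fit(disp=0, maxiter=200)
            if res.mle_retvals.get("converged", False) and np.all(
                np.isfinite(res.params)
            ):
                alpha, beta = float(res.params[0]), float(res.params[1])
        except (PerfectSeparationError, np.linalg.LinAlgError):
            pass

    pse: Optional[float] = None
    if math.isfinite(beta) and beta > 0:
        pse = -alpha / beta
    converged = check_convergence(pse, ratio_min, ratio_max)
    return PsychometricFit(
        side=side, alpha=alpha, beta=beta, pse=pse, converged=converged, n_trials=n
    )


def pse_outcome(
    records: Sequence[TrialRecord],
    all_correct_rule: str = "phase",
    require_both_sides: bool = True,
    ratio_min: float = RATIO_MIN,
    ratio_max: float = RATIO_MAX,
) -> Optional[float]:
    """Phase-level PSE score of one participant-phase, or None if unusable.

    The score is the mean of the two per-side PSEs.  When the participant
    answered every trial of the phase correctly, the score is set directly
    to the minimum assessed difference ratio (``all_correct_rule="phase"``,
    the default; ``"side"`` applies the floor per all-correct side
    instead).  With ``require_both_sides`` (default) the score is None
    whenever either side lacks a usable PSE — downstream analyses then
    exclude the paired case.
    """
    if all_correct_rule not in ("phase", "side"):
        raise ValueError("all_correct_rule must be 'phase' or 'side'")
    if not records:
        return None
    if all_correct_rule == "phase" and all(r.correct for r in records):
        return ratio_min

    side_pses: list[Optional[float]] = []
    for side in SIDES:
        side_recs = [r for r in records if r.side == side]
        if not side_recs:
            side_pses.append(None)
            continue
        if all_correct_rule == "side" and all(r.correct for r in side_recs):
            side_pses.append(ratio_min)
            continue
        fit = fit_psychometric(side_recs, side, ratio_min, ratio_max)
        side_pses.append(fit.pse if fit.converged else None)

    available = [p for p in side_pses if p is not None]
    if not available:
        return None
    if require_both_sides and len(available) < len(SIDES):
        return None
    return float(np.mean(available))


def adapt_training_set(
    pse_mc: Optional[float],
    pse_lc: Optional[float],
    baseline_set: StimulusSet,
    converged_mc: bool,
    converged_lc: bool,
    resolution: float = 2e-5,
) -> StimulusSet:
    """Build the participant-specific training stimulus set from baseline PSEs.

    For each converged side, four comparison intensities are placed
    symmetrically around that side's PSE with the baseline inter-stimulus
    spacing Δ retained: {PSE − 1.5Δ, PSE − 0.5Δ, PSE + 0.5Δ, PSE + 1.5Δ}.
    Intensities are clipped below at one robot-resolution step above zero
    and above at the baseline maximum; after clipping, coincident values
    are separated by one resolution step so frequencies stay strictly
    ordered.  Intensities map back to frequencies as f_St(1 − r) on the
    more-coarse side and f_St(1 + r) on the less-coarse side.  A side whose
    baseline fit did not converge keeps its baseline comparisons; if
    neither converged the baseline set is returned unchanged.

    This construction is a reconstruction of the adaptive procedure from
    its stated inputs (per-side PSEs, baseline spacing, assessed range); it
    is isolated here so an alternative rule can be swapped in.
    """
    if not (converged_mc or converged_lc):
        return baseline_set

    f_st = baseline_set.standard.spatial_frequency
    base_ratios_mc = sorted(
        difference_ratio(s.spatial_frequency, f_st) for s in baseline_set.more_coarse
    )
    delta = base_ratios_mc[1] - base_ratios_mc[0] if len(base_ratios_mc) > 1 else RATIO_MIN
    r_floor = resolution * f_st
    r_ceil = max(
        difference_ratio(s.spatial_frequency, f_st)
        for s in baseline_set.comparisons
    )

    def side_ratios(pse: float) -> list[float]:
        raw = [pse + delta * c for c in (-1.5, -0.5, 0.5, 1.5)]
        clipped = [min(max(r, r_floor), r_ceil) for r in raw]
        # separate any values that collided at a clip boundary
        for i in range(len(clipped) - 2, -1, -1):
            if clipped[i] >= clipped[i + 1] - resolution * f_st / 2:
                clipped[i] = clipped[i + 1] - resolution * f_st
        return clipped

    if converged_mc and pse_mc is not None:
        mc = tuple(
            Stimulus(f_st * (1.0 - r)) for r in sorted(side_ratios(pse_mc), reverse=True)
        )
    else:
        mc = baseline_set.more_coarse
    if converged_lc and pse_lc is not None:
        lc = tuple(Stimulus(f_st * (1.0 + r)) for r in sorted(side_ratios(pse_lc)))
    else:
        lc = baseline_set.less_coarse
    return StimulusSet(standard=baseline_set.standard, more_coarse=mc, less_coarse=lc)
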