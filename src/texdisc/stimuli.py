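"""Grating stimuli and triangle-test trial construction.

A texture stimulus is a sinusoidal grating characterised by its spatial
frequency f (m^-1); its spatial period is 1/f (m).  Discrimination trials
follow the triangle test: three textures are presented, two share the same
frequency, and the respondent must identify the odd one.  Assessment blocks
follow the method of constant stimuli: a fixed set of comparison stimuli
(Co), each judged against a fixed standard (St), presented repeatedly in
randomised order.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: the six equiprobable triplet arrangements of the triangle test
COMBINATIONS = (
    "St/St/Co",
    "St/Co/St",
    "Co/St/St",
    "Co/Co/St",
    "Co/St/Co",
    "St/Co/Co",
)

ROLES = ("standard", "comparison")


def spatial_period(frequency: float) -> float:
    """Spatial period (m) of a grating, the reciprocal of its frequency (m^-1)."""
    if frequency <= 0:
        raise ValueError(f"spatial frequency must be positive, got {frequency}")
    return 1.0 / frequency


def difference_ratio(comparison_frequency: float, standard_frequency: float) -> float:
    """Stimulus intensity |f_Co - f_St| / f_St (dimensionless).

    This is the abscissa of the psychometric function: 0 for identical
    gratings, growing with discriminability.
    """
    if comparison_frequency <= 0 or standard_frequency <= 0:
        raise ValueError(
            "spatial frequencies must be positive, got "
            f"({comparison_frequency}, {standard_frequency})"
        )
    return abs(comparison_frequency - standard_frequency) / standard_frequency


@dataclass(frozen=True)
class Stimulus:
    """A single grating stimulus.

    Parameters
    ----------
    spatial_frequency
        Gratings per meter (m^-1), strictly positive.
    role
        ``"standard"`` (the fixed reference) or ``"comparison"``.
    """

    spatial_frequency: float
    role: str = "comparison"

    def __post_init__(self) -> None:
        if self.spatial_frequency <= 0:
            raise ValueError(
                f"spatial_frequency must be > 0, got {self.spatial_frequency}"
            )
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    @property
    def spatial_period(self) -> float:
        """Crest-to-crest distance in meters."""
        return spatial_period(self.spatial_frequency)


@dataclass(frozen=True)
class StimulusSet:
    """A standard stimulus with its two flanking comparison pools.

    ``more_coarse`` holds the four comparisons with frequency below the
    standard (coarser gratings: longer period), ``less_coarse`` the four
    above.  The default experimental set keeps the comparisons evenly
    spaced and centred on the standard; adapted training sets may break
    those properties, in which case a warning is logged.
    """

    standard: Stimulus
    more_coarse: tuple[Stimulus, ...]
    less_coarse: tuple[Stimulus, ...]

    def __post_init__(self) -> None:
        f_st = self.standard.spatial_frequency
        mc = [s.spatial_frequency for s in self.more_coarse]
        lc = [s.spatial_frequency for s in self.less_coarse]
        if not mc or not lc:
            raise ValueError("both comparison pools must be non-empty")
        if not all(f < f_st for f in mc):
            raise ValueError("all more_coarse frequencies must be below the standard")
        if not all(f > f_st for f in lc):
            raise ValueError("all less_coarse frequencies must be above the standard")
        for side, freqs in (("more_coarse", mc), ("less_coarse", lc)):
            if not all(b > a for a, b in zip(freqs, freqs[1:])):
                raise ValueError(f"{side} frequencies must be strictly increasing")
            gaps = np.diff(freqs)
            if len(gaps) and not np.allclose(gaps, gaps[0]):
                logger.warning(
                    "%s comparison spacing is not constant: %s", side, list(gaps)
                )
        if not np.isclose(np.mean(mc + lc), f_st):
            logger.warning(
                "standard frequency %.4g is not the mean of the comparisons (%.4g)",
                f_st,
                np.mean(mc + lc),
            )

    @property
    def comparisons(self) -> tuple[Stimulus, ...]:
        """All comparison stimuli, more-coarse first, ascending frequency."""
        return self.more_coarse + self.less_coarse

    @property
    def difference_ratios(self) -> list[float]:
        f_st = self.standard.spatial_frequency
        return [difference_ratio(s.spatial_frequency, f_st) for s in self.comparisons]

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "standard_frequency": self.standard.spatial_frequency,
            "more_coarse": [s.spatial_frequency for s in self.more_coarse],
            "less_coarse": [s.spatial_frequency for s in self.less_coarse],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSet":
        return cls(
            standard=Stimulus(float(d["standard_frequency"]), role="standard"),
            more_coarse=tuple(
                Stimulus(float(f)) for f in sorted(d["more_coarse"])
            ),
            less_coarse=tuple(
                Stimulus(float(f)) for f in sorted(d["less_coarse"])
            ),
        )

    def to_file(self, path) -> None:
        """Write the set as YAML (or JSON if the suffix is .json)."""
        text = (
            json.dumps(self.to_dict(), indent=2)
            if str(path).endswith(".json")
            else yaml.safe_dump(self.to_dict())
        )
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def from_file(cls, path) -> "StimulusSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_default_stimulus_set() -> StimulusSet:
    """The default experimental stimulus set.

    Standard at 164 m^-1, four more-coarse comparisons {100, 116, 132, 148}
    and four less-coarse {180, 196, 212, 228}, i.e. 16 m^-1 spacing on each
    side with the standard equal to the mean of all eight comparisons.
    """
    return StimulusSet(
        standard=Stimulus(164.0, role="standard"),
        more_coarse=tuple(Stimulus(f) for f in (100.0, 116.0, 132.0, 148.0)),
        less_coarse=tuple(Stimulus(f) for f in (180.0, 196.0, 212.0, 228.0)),
    )


@dataclass(frozen=True)
class TrialSpec:
    """One triangle-test triplet.

    Exactly two of the three presented textures share a frequency; the
    third sits at ``odd_index``.  The ``combination`` label records which
    positions carried the standard (St) and which the comparison (Co).
    """

    triplet: tuple[Stimulus, Stimulus, Stimulus]
    odd_index: int
    combination: str
    standard: Stimulus
    comparison: Stimulus

    def __post_init__(self) -> None:
        if self.combination not in COMBINATIONS:
            raise ValueError(f"unknown combination label {self.combination!r}")
        if self.odd_index not in (0, 1, 2):
            raise ValueError(f"odd_index must be 0, 1 or 2, got {self.odd_index}")
        freqs = [s.spatial_frequency for s in self.triplet]
        counts = {f: freqs.count(f) for f in set(freqs)}
        if sorted(counts.values()) != [1, 2]:
            raise ValueError("triplet must contain exactly two equal frequencies")
        odd_freq = min(counts, key=counts.get)
        if freqs[self.odd_index] != odd_freq:
            raise ValueError("odd_index does not point at the odd texture")
        labels = self.combination.split("/")
        for lab, stim in zip(labels, self.triplet):
            expect = self.standard if lab == "St" else self.comparison
            if stim.spatial_frequency != expect.spatial_frequency:
                raise ValueError("combination label inconsistent with triplet")

    @property
    def difference_ratio(self) -> float:
        return difference_ratio(
            self.comparison.spatial_frequency, self.standard.spatial_frequency
        )


@dataclass
class Block:
    """An ordered list of triangle trials for one protocol phase."""

    trials: list[TrialSpec]
    phase_label: str

    def __len__(self) -> int:
        return len(self.trials)

    def comparison_frequencies(self) -> list[float]:
        return [t.comparison.spatial_frequency for t in self.trials]


def make_triangle_trial(
    standard: Stimulus, comparison: Stimulus, rng: np.random.Generator
) -> TrialSpec:
    """Draw one triangle trial, choosing uniformly among the six arrangements.

    In St/St/Co-type arrangements the odd texture is the comparison; in
    Co/Co/St-type arrangements it is the standard.
    """
    if standard.spatial_frequency == comparison.spatial_frequency:
        raise ValueError("standard and comparison frequencies are equal; no odd texture")
    combination = COMBINATIONS[rng.integers(len(COMBINATIONS))]
    labels = combination.split("/")
    triplet = tuple(standard if lab == "St" else comparison for lab in labels)
    minority = "Co" if labels.count("Co") == 1 else "St"
    odd_index = labels.index(minority)
    return TrialSpec(
        triplet=triplet,
        odd_index=odd_index,
        combination=combination,
        standard=standard,
        comparison=comparison,
    )


def make_constant_stimuli_block(
    stimulus_set: StimulusSet,
    repetitions: int,
    phase_label: str,
    rng: np.random.Generator,
) -> Block:
    """A constant-stimuli assessment block.

    Each comparison stimulus appears exactly ``repetitions`` times (the
    protocol default of 5 over 8 comparisons gives the 40-trial block);
    presentation order is a seeded permutation of the multiset.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    comparisons = list(stimulus_set.comparisons) * repetitions
    order = rng.permutation(len(comparisons))
    trials = [
        make_triangle_trial(stimulus_set.standard, comparisons[i], rng) for i in order
    ]
    return Block(trials=trials, phase_label=phase_label)


def make_training_blocks(
    training_set: StimulusSet,
    rng: np.random.Generator,
    n_blocks: int = 3,
    repetitions: int = 5,
) -> list[Block]:
    """The training phase: ``n_blocks`` blocks sharing one comparison order.

    The comparison-stimulus sequence is randomised once for the first block
    and repeated verbatim in the remaining blocks; the triplet arrangement
    (odd-texture position) is re-drawn independently per trial so that
    positions cannot be memorised across blocks.
    """
    first = make_constant_stimuli_block(training_set, repetitions, "training", rng)
    blocks = [first]
    for _ in range(n_blocks - 1):
        trials = [
            make_triangle_trial(training_set.standard, t.comparison, rng)
            for t in first.trials
        ]
        blocks.append(Block(trials=trials, phase_label="training"))
    return blocks
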