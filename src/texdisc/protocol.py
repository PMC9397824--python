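"""The three-session study protocol as a seeded simulation, plus session-log IO.

Protocol structure (per participant):

- Session 1: a single familiarization trial, then two initial baselines
  (iBL) of 40 trials each — one active, one passive, order counterbalanced
  across participants.
- Sessions 2 and 3: baseline (BL, 40 trials), three training blocks of 40
  trials with participant-specific comparison stimuli adapted to the BL
  psychometric fits, and retention (RT, 40 trials).  Half the participants
  do session 2 passively and session 3 actively; the other half the
  reverse (crossover).

Human participants are replaced by simulated observers with known
sensitivity; the post-training retention block uses an observer with a
steeper psychometric slope, emulating short-term training gains.  All
randomness descends from one master seed through spawned child streams,
so a study is byte-reproducible.

Session logs are tidy CSV, one row per trial; kinematic traces (optional,
they are not needed for the score/PSE/reliability analyses) are sibling
CSVs keyed by participant, session and trial.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import haptics, outcomes, psychometrics, stats, stimuli
from .observer import ObserverModel, simulate_phase
from .psychometrics import (
    TrialRecord,
    adapt_training_set,
    fit_psychometric,
    pse_outcome,
    probability_correct,
    records_to_frame,
)
from .stimuli import Block, StimulusSet, TrialSpec, build_default_stimulus_set

logger = logging.getLogger(__name__)

LOG_COLUMNS = [
    "participant", "session", "phase", "condition", "trial_idx",
    "f_st", "f_co", "diff_ratio", "combination", "odd_idx",
    "response_idx", "correct", "seed",
]

SCHEMA_VERSION = 1

#: familiarization triplet frequencies (m^-1): two fine textures and one
#: clearly coarser odd texture.
FAMILIARIZATION_TRIPLET = (228.0, 228.0, 100.0)


@dataclass
class ProtocolConfig:
    """Study-level configuration.

    ``baseline_beta_range`` is the between-subject spread of the true
    psychometric slope (uniform draw per participant);
    ``training_beta_gain`` scales the slope of the post-training observer
    used for retention blocks.  ``n_participants`` must be even so both
    counterbalancing splits are exact halves.
    """

    n_participants: int = 10
    repetitions: int = 5
    n_training_blocks: int = 3
    baseline_alpha: float = -math.log(2.0)
    baseline_beta_range: tuple[float, float] = (5.0, 20.0)
    training_beta_gain: float = 1.5
    floor_mode: str = "plain_logistic"
    between_day_jitter: float = 0.0   # sd of day-to-day slope noise (0 = identical)
    simulate_traces: bool = False
    traces_per_phase: int = 1         # traces per assessment phase when enabled
    stimulus_set: StimulusSet = field(default_factory=build_default_stimulus_set)
    haptic_params: haptics.HapticParams = field(default_factory=haptics.HapticParams)

    def validate(self) -> None:
        if self.n_participants < 2 or self.n_participants % 2:
            raise ValueError("n_participants must be an even number >= 2")
        if self.repetitions < 1 or self.n_training_blocks < 1:
            raise ValueError("repetitions and n_training_blocks must be >= 1")
        lo, hi = self.baseline_beta_range
        if not (0 <= lo <= hi):
            raise ValueError("baseline_beta_range must be 0 <= lo <= hi")
        if self.training_beta_gain <= 0:
            raise ValueError("training_beta_gain must be > 0")

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("stimulus_set", "haptic_params")
        }
        d["baseline_beta_range"] = list(self.baseline_beta_range)
        d["stimulus_set"] = self.stimulus_set.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        sset = d.pop("stimulus_set", None)
        d.pop("haptic_params", None)
        if "baseline_beta_range" in d:
            d["baseline_beta_range"] = tuple(d["baseline_beta_range"])
        cfg = cls(**d)
        if sset:
            cfg.stimulus_set = StimulusSet.from_dict(sset)
        return cfg

    @classmethod
    def from_file(cls, path) -> "ProtocolConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SessionLog:
    """Ordered trial records of one simulated study (or one slice of it)."""

    records: list[TrialRecord]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def write_session_log(path, log: SessionLog) -> None:
    df = log.to_frame()
    df = df[LOG_COLUMNS] if len(df) else pd.DataFrame(columns=LOG_COLUMNS)
    df.to_csv(path, index=False)


def read_session_log(path) -> SessionLog:
    """Read a session-log CSV; malformed rows raise with their line number."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in LOG_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown session-log columns: {unknown}")
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session log {path} is missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        try:
            records.append(
                TrialRecord(
                    participant=str(row.participant),
                    session=int(row.session),
                    phase=str(row.phase),
                    condition=str(row.condition),
                    trial_idx=int(row.trial_idx),
                    f_st=float(row.f_st),
                    f_co=float(row.f_co),
                    combination=str(row.combination),
                    odd_index=int(row.odd_idx),
                    response_index=int(row.response_idx),
                    seed=int(row.seed),
                )
            )
            if int(row.correct) != records[-1].correct:
                raise ValueError("correct flag inconsistent with response/odd index")
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return SessionLog(records=records)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _familiarization_trial(sset: StimulusSet) -> TrialSpec:
    """The fixed single familiarization triplet (two fine, one coarse texture)."""
    fa, fb, fc = FAMILIARIZATION_TRIPLET
    dup = stimuli.Stimulus(fa, role="standard")
    odd = stimuli.Stimulus(fc)
    return TrialSpec(
        triplet=(dup, stimuli.Stimulus(fb, role="standard"), odd),
        odd_index=2,
        combination="St/St/Co",
        standard=dup,
        comparison=odd,
    )


def run_protocol_simulation(
    config: ProtocolConfig,
    seed: int,
    out_dir: Optional[Path] = None,
) -> SessionLog:
    """Simulate the full study and (optionally) write it to ``out_dir``.

    Returns the combined SessionLog.  When ``out_dir`` is given, writes
    ``study_log.csv``, ``config.json``, and — if trace simulation is
    enabled — per-trial kinematic trace CSVs under ``traces/``.
    """
    config.validate()
    master = np.random.SeedSequence(seed)
    study_rng = np.random.default_rng(master.spawn(1)[0])
    n = config.n_participants

    # counterbalancing: iBL condition order and day-2 condition
    ibl_active_first = np.zeros(n, dtype=bool)
    ibl_active_first[study_rng.permutation(n)[: n // 2]] = True
    day2_passive = np.zeros(n, dtype=bool)
    day2_passive[study_rng.permutation(n)[: n // 2]] = True

    all_records: list[TrialRecord] = []
    traces: list[tuple[str, int, str, haptics.KinematicTrace]] = []
    lo, hi = config.baseline_beta_range

    participant_seeds = master.spawn(n)
    for p in range(n):
        pid = f"P{p + 1:03d}"
        prng = np.random.default_rng(participant_seeds[p])
        beta_p = float(prng.uniform(lo, hi))
        base_obs = ObserverModel(
            alpha_true=config.baseline_alpha,
            beta_true=beta_p,
            floor_mode=config.floor_mode,
        )
        trained_obs = base_obs.trained(config.training_beta_gain)

        def day_observer(obs: ObserverModel) -> ObserverModel:
            if config.between_day_jitter > 0:
                noisy = max(0.0, obs.beta_true + prng.normal(0, config.between_day_jitter))
                return ObserverModel(obs.alpha_true, noisy, obs.floor_mode)
            return obs

        # ---- session 1: familiarization + two iBLs -----------------------
        fam = _familiarization_trial(config.stimulus_set)
        fam_records = simulate_phase(
            Block([fam], "familiarization"),
            base_obs, prng, participant=pid, session=1,
            condition="active", seed=seed,
        )
        all_records.extend(fam_records)

        first = "active" if ibl_active_first[p] else "passive"
        second = "passive" if first == "active" else "active"
        for cond in (first, second):
            block = stimuli.make_constant_stimuli_block(
                config.stimulus_set, config.repetitions, "iBL", prng
            )
            recs = simulate_phase(
                block, day_observer(base_obs), prng, participant=pid,
                session=1, condition=cond, seed=seed,
            )
            all_records.extend(recs)
            traces.extend(_maybe_traces(config, pid, 1, cond, block))

        # ---- sessions 2 and 3: BL -> training -> RT ----------------------
        for session in (2, 3):
            if session == 2:
                cond = "passive" if day2_passive[p] else "active"
            else:
                cond = "active" if day2_passive[p] else "passive"

            bl_block = stimuli.make_constant_stimuli_block(
                config.stimulus_set, config.repetitions, "BL", prng
            )
            bl_obs = day_observer(base_obs)
            bl_records = simulate_phase(
                bl_block, bl_obs, prng, participant=pid,
                session=session, condition=cond, seed=seed,
            )
            all_records.extend(bl_records)
            traces.extend(_maybe_traces(config, pid, session, cond, bl_block))

            # adapt the training comparisons to the BL psychometric fits
            fit_mc = fit_psychometric(bl_records, "more_coarse")
            fit_lc = fit_psychometric(bl_records, "less_coarse")
            training_set = adapt_training_set(
                fit_mc.pse, fit_lc.pse, config.stimulus_set,
                fit_mc.converged, fit_lc.converged,
            )

            offset = 0
            for tb in stimuli.make_training_blocks(
                training_set, prng,
                n_blocks=config.n_training_blocks,
                repetitions=config.repetitions,
            ):
                all_records.extend(
                    simulate_phase(
                        tb, bl_obs, prng, participant=pid, session=session,
                        condition=cond, phase="training",
                        trial_offset=offset, seed=seed,
                    )
                )
                offset += len(tb)

            rt_block = stimuli.make_constant_stimuli_block(
                config.stimulus_set, config.repetitions, "RT", prng
            )
            all_records.extend(
                simulate_phase(
                    rt_block, day_observer(trained_obs), prng, participant=pid,
                    session=session, condition=cond, seed=seed,
                )
            )
            traces.extend(_maybe_traces(config, pid, session, cond, rt_block))

    log = SessionLog(
        records=all_records,
        metadata={"seed": seed, "schema_version": SCHEMA_VERSION,
                  "n_participants": n},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_session_log(out_dir / "study_log.csv", log)
        with open(out_dir / "config.json", "w") as fh:
            json.dump({**config.to_dict(), "seed": seed,
                       "schema_version": SCHEMA_VERSION}, fh, indent=2)
        if traces:
            tdir = out_dir / "traces"
            tdir.mkdir(exist_ok=True)
            for pid, session, cond, trace_obj in traces:
                trace_obj[1].to_csv(
                    tdir / f"{pid}_s{session}_{cond}_{trace_obj[0]}.csv"
                )
    return log


def _maybe_traces(config, pid, session, cond, block):
    """Simulate exploration traces for the first trials of an assessment block."""
    if not config.simulate_traces:
        return []
    out = []
    for i, trial in enumerate(block.trials[: config.traces_per_phase]):
        trace = haptics.simulate_trial_exploration(
            trial, mode=cond, params=config.haptic_params
        )
        out.append((pid, session, cond, (f"{block.phase_label}_t{i}", trace)))
    return out


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


def analyze_study(
    study: "SessionLog | Path | str",
    traces_dir: Optional[Path] = None,
) -> dict[str, pd.DataFrame]:
    """Study-level analysis of a simulated (or recorded) session log.

    Returns a dict of tidy tables:

    - ``scores``: per participant × session × phase × condition — the
      mean proportion correct over the comparison stimuli and the PSE
      outcome (NaN where no usable PSE).
    - ``reliability``: ICC(2,k) of day-1 iBL vs day-2 BL per condition
      group (participants grouped by their day-2 condition) for both
      metrics, with CI, p-value and qualitative band.
    - ``bland_altman``: limits of agreement for the same pairings.
    - ``kinematics`` (only when traces are supplied): per-trace outcome
      measures.

    Familiarization trials are excluded from every table.
    """
    if not isinstance(study, SessionLog):
        path = Path(study)
        log_path = path / "study_log.csv" if path.is_dir() else path
        if traces_dir is None and path.is_dir() and (path / "traces").is_dir():
            traces_dir = path / "traces"
        study = read_session_log(log_path)

    records = [r for r in study.records if r.phase != "familiarization"]
    if not records:
        raise ValueError("no analyzable trial records (familiarization only?)")

    df = records_to_frame(records)
    expected_phases = {"iBL", "BL", "RT"}
    present = set(df["phase"].unique())
    missing_phases = expected_phases - present
    if missing_phases:
        warnings.warn(f"phases missing from the log: {sorted(missing_phases)}; "
                      "producing partial output")

    # ---- per participant × session × phase × condition scores ------------
    rows = []
    keys = ["participant", "session", "phase", "condition"]
    grouped: dict[tuple, list[TrialRecord]] = {}
    for r in records:
        grouped.setdefault((r.participant, r.session, r.phase, r.condition), []).append(r)
    for (pid, session, phase, cond), recs in sorted(grouped.items()):
        _, score = probability_correct(recs)
        pse = pse_outcome(recs) if phase in ("iBL", "BL", "RT") else None
        rows.append(
            {
                "participant": pid, "session": session, "phase": phase,
                "condition": cond, "n_trials": len(recs),
                "p_correct": score,
                "pse": pse if pse is not None else np.nan,
            }
        )
    scores = pd.DataFrame(rows)

    # ---- reliability: iBL (day 1) vs BL (day 2), grouped by day-2 condition
    rel_rows, ba_rows = [], []
    day2 = scores[(scores["session"] == 2) & (scores["phase"] == "BL")]
    for cond in ("active", "passive"):
        members = day2[day2["condition"] == cond]["participant"]
        ibl = scores[
            (scores["phase"] == "iBL") & (scores["condition"] == cond)
            & scores["participant"].isin(members)
        ].set_index("participant")
        bl = day2[day2["condition"] == cond].set_index("participant")
        common = ibl.index.intersection(bl.index)
        for metric in ("p_correct", "pse"):
            x1 = ibl.loc[common, metric].to_numpy(float)
            x2 = bl.loc[common, metric].to_numpy(float)
            ok = np.isfinite(x1) & np.isfinite(x2)   # paired exclusion
            if ok.sum() < 3:
                warnings.warn(
                    f"too few paired cases for ICC ({cond}/{metric}): {int(ok.sum())}"
                )
                continue
            icc = stats.icc_2k(np.column_stack([x1[ok], x2[ok]]))
            rel_rows.append(
                {
                    "condition": cond, "metric": metric,
                    "icc": icc.icc_value, "ci_low": icc.ci_low,
                    "ci_high": icc.ci_high, "p_value": icc.p_value,
                    "n": icc.n_subjects,
                    "classification": icc.classification,
                }
            )
            ba = stats.bland_altman(x1[ok], x2[ok])
            ba_rows.append(
                {
                    "condition": cond, "metric": metric,
                    "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
                    "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                    "n_outside": ba.n_outside, "n": ok.sum(),
                }
            )
    result = {
        "scores": scores,
        "reliability": pd.DataFrame(rel_rows),
        "bland_altman": pd.DataFrame(ba_rows),
    }

    if traces_dir is not None and Path(traces_dir).is_dir():
        krows = []
        for f in sorted(Path(traces_dir).glob("*.csv")):
            trace = haptics.KinematicTrace.from_csv(f)
            kin = outcomes.compute_kinematics(trace)
            krows.append(
                {
                    "trace": f.stem,
                    "scanning_duration_s": kin.scanning_duration,
                    "path_length_m": kin.path_length,
                    "mean_scanning_speed_mps": kin.mean_scanning_speed,
                }
            )
        result["kinematics"] = pd.DataFrame(krows)
    return result
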