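"""End-to-end in-silico trial: enroll, randomize, train, assess, assemble.

``run_trial`` produces a :class:`TrialDataset` with a long-format visit table
(one row per participant-week), a per-participant table, and the allocation
list.  ``apply_locf`` adds the last-observation-carried-forward variant used
by the sensitivity analysis; ``responder_flags`` derives the ≥50%-reduction
clinical-responder indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .config import TrialConfig
from .participants import (
    VISITS,
    ClinicalProfile,
    default_trajectory_model,
    sample_participant,
    simulate_adherence,
    simulate_trajectory,
)
from .randomization import permuted_block_sequence
from .responders import ResponderModel
from .task_engine import SessionResult, next_session_start, run_session

__all__ = ["TrialDataset", "run_trial", "apply_locf", "responder_flags",
           "ITEM_COLS", "LONG_COLUMNS"]

ITEM_COLS = [f"hamd_item_{i}" for i in range(1, 18)]
LONG_COLUMNS = (["participant_id", "arm", "week", "hamd_total", *ITEM_COLS,
                 "bdi", "sessions_this_week", "sessions_cum", "status",
                 "itt", "mitt"])


@dataclass
class TrialDataset:
    """Long visit-level records plus participant-level and allocation tables."""

    long: pd.DataFrame
    participants: pd.DataFrame
    allocation: pd.DataFrame
    locf: Optional[pd.DataFrame] = None
    config: Optional[TrialConfig] = None
    seed: Optional[int] = None

    @property
    def mitt_ids(self) -> list[str]:
        return list(self.participants.loc[self.participants["mitt"], "participant_id"])

    def arm_of(self) -> pd.Series:
        return self.participants.set_index("participant_id")["arm"]


def _likert(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), 1, 5))


def _train_participant(profile: ClinicalProfile, sessions_by_week, cfg: TrialConfig,
                       rng: np.random.Generator) -> tuple[float, int]:
    """Run the attended training sessions through the task engine; returns
    (mean N across sessions, final session count)."""
    modality = "face" if profile.group == "EFMT" else "shape"
    responder = ResponderModel(capacity=profile.capacity)
    policy = cfg.task.policy()
    spec = cfg.task.block_spec()
    prev: Optional[SessionResult] = None
    mean_ns: list[float] = []
    idx = 0
    for week_sessions in sessions_by_week:
        for _ in range(week_sessions):
            idx += 1
            start = 1 if idx == 1 else next_session_start(prev, policy)
            prev = run_session(idx, start, responder, policy, rng,
                               spec_template=spec, modality=modality)
            mean_ns.append(prev.mean_n)
    return (float(np.mean(mean_ns)) if mean_ns else float("nan"), idx)


def run_trial(config: TrialConfig, rng: np.random.Generator,
              seed: Optional[int] = None, model=None) -> TrialDataset:
    """Simulate one complete trial under ``config``.

    All randomness flows through ``rng``; identical config + generator state
    reproduce the dataset exactly.  ``model`` overrides the default trajectory
    model (e.g. a null model with identical arm curves for calibration runs).
    """
    if model is None:
        model = default_trajectory_model(residual_sd=config.residual_sd,
                                         rho=config.residual_rho,
                                         dose_effect=config.dose_effect,
                                         attendance_prob=config.attendance_prob)
    allocation = permuted_block_sequence(config.n_participants, rng)
    long_rows: list[dict] = []
    part_rows: list[dict] = []
    for a in allocation:
        profile = sample_participant(a.arm, rng, config.cohort, participant_id=a.participant_id)
        adher = simulate_adherence(rng, config.attendance_prob,
                                   n_weeks=config.n_weeks,
                                   sessions_per_week=config.sessions_per_week)
        if config.simulate_sessions:
            mean_n, _ = _train_participant(profile, adher.sessions_by_week, config, rng)
        else:
            mean_n = float("nan")
        records = simulate_trajectory(profile, model, adher.sessions_by_week, rng,
                                      discontinuation_week=adher.discontinuation_week)
        # m-ITT: randomized, >=1 week of training completed, >=1 post-baseline Ham-D
        mitt = len(records) > 1
        cum = 0
        for rec in records:
            cum += rec.sessions_this_week
            row = {"participant_id": rec.participant_id, "arm": a.arm,
                   "week": rec.week, "hamd_total": rec.hamd_total,
                   "bdi": rec.bdi, "sessions_this_week": rec.sessions_this_week,
                   "sessions_cum": cum, "status": rec.status,
                   "itt": True, "mitt": mitt}
            row.update({c: v for c, v in zip(ITEM_COLS, rec.hamd_items)})
            long_rows.append(row)
        lk = config.likert
        completer = not adher.discontinued
        part_rows.append({
            "participant_id": a.participant_id, "arm": a.arm,
            "baseline_hamd": profile.baseline_hamd, "baseline_bdi": profile.baseline_bdi,
            "baseline_wais": profile.baseline_wais,
            "outcome_wais": profile.baseline_wais + rng.normal(config.wais_gain_mean,
                                                               config.wais_gain_sd),
            "episode_duration_months": profile.episode_duration_months,
            "capacity": profile.capacity, "mean_n": mean_n,
            "sessions_total": adher.total_sessions,
            "discontinued": adher.discontinued,
            "discontinuation_week": adher.discontinuation_week,
            "completer": completer, "itt": True, "mitt": mitt,
            "accept_baseline": _likert(rng, *lk.accept_baseline[a.arm]),
            "accept_outcome": _likert(rng, *lk.accept_outcome[a.arm]),
            "help_attention": _likert(rng, *lk.help_attention[a.arm]),
            "help_thoughts": _likert(rng, *lk.help_thoughts[a.arm]),
            "help_mood": _likert(rng, *lk.help_mood[a.arm]),
            "help_memory": _likert(rng, *lk.help_memory[a.arm]),
        })
    long = pd.DataFrame(long_rows, columns=LONG_COLUMNS)
    participants = pd.DataFrame(part_rows)
    alloc = pd.DataFrame([vars(x) for x in allocation])
    return TrialDataset(long=long, participants=participants, allocation=alloc,
                        config=config, seed=seed)


def apply_locf(dataset: TrialDataset) -> TrialDataset:
    """Return the dataset with an LOCF-completed long table attached.

    Every m-ITT participant gets a row at every week 0..6; missing Ham-D
    totals, item scores and BDI are carried forward from the last observed
    visit, with an ``imputed`` flag on carried rows.  Non-m-ITT participants
    (no post-baseline observation to carry) keep only observed rows.
    Idempotent: applying it to an already-complete table changes nothing.
    """
    src = dataset.locf if dataset.locf is not None else dataset.long
    carry_cols = ["hamd_total", *ITEM_COLS, "bdi"]
    out = []
    for pid, g in src.groupby("participant_id", sort=False):
        g = g.sort_values("week")
        if "imputed" not in g.columns:
            g = g.assign(imputed=False)
        if not bool(g["mitt"].iloc[0]):
            out.append(g)
            continue
        have = set(g["week"])
        last = g.iloc[-1]
        rows = [g]
        for w in range(VISITS):
            if w in have:
                continue
            r = last.copy()
            r["week"] = w
            r["sessions_this_week"] = 0
            r["imputed"] = True
            rows.append(r.to_frame().T)
        gg = pd.concat(rows, ignore_index=True).sort_values("week")
        gg[carry_cols] = gg[carry_cols].astype(float).ffill()
        out.append(gg)
    locf = pd.concat(out, ignore_index=True)
    locf = locf.astype({c: src[c].dtype for c in carry_cols} | {"imputed": bool})
    return replace(dataset, locf=locf)


def responder_flags(dataset: TrialDataset, week: int = VISITS - 1) -> pd.DataFrame:
    """Clinical-responder flags: at least 50% Ham-D reduction from baseline.

    The outcome value is the week-6 observation, or its LOCF imputation when
    :func:`apply_locf` has been run.  Participants with no usable outcome
    (not in m-ITT) get a missing flag, reported in the ``defined`` column;
    summary counts treat them as non-responders.
    """
    src = dataset.locf if dataset.locf is not None else dataset.long
    rows = []
    for pid, g in src.groupby("participant_id", sort=False):
        g = g.sort_values("week")
        base = g.loc[g["week"] == 0, "hamd_total"]
        outc = g.loc[g["week"] == week, "hamd_total"]
        if base.empty or base.iloc[0] <= 0:
            raise ValueError(f"participant {pid} lacks a positive baseline")
        b = float(base.iloc[0])
        if outc.empty:
            rows.append({"participant_id": pid, "arm": g["arm"].iloc[0],
                         "baseline": b, "outcome": np.nan,
                         "responder": pd.NA, "defined": False})
        else:
            o = float(outc.iloc[0])
            rows.append({"participant_id": pid, "arm": g["arm"].iloc[0],
                         "baseline": b, "outcome": o,
                         "responder": bool((b - o) / b >= 0.5), "defined": True})
    return pd.DataFrame(rows)
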