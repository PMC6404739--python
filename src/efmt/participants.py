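"""Simulated clinical cohort: baselines, weekly symptom trajectories, adherence.

The generator reproduces the statistical structure a two-arm 6-week depression
training trial's analysis assumes: moderate baseline severity (17-item Ham-D in
[16, 27]), clinician-rated weekly totals whose group-mean trajectories diverge
in favour of the active arm, within-participant correlation across visits, a
dose effect of sessions completed in the active arm, per-item decompositions
that respect the instrument's item ranges, and the protocol's two
discontinuation rules (fewer than two sessions in any week, or more than three
missed overall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "HAMD_ITEM_MAX",
    "HAMD_MAX_TOTAL",
    "ClinicalProfile",
    "TrajectoryModel",
    "TrajectoryRecord",
    "AdherenceRecord",
    "CohortConfig",
    "sample_participant",
    "simulate_adherence",
    "simulate_trajectory",
    "decompose_hamd_items",
    "simulate_cohort_totals",
    "wais_composite",
    "default_trajectory_model",
    "compound_symmetry_cov",
]

# 17-item Ham-D item maxima: nine items rated 0-4 (depressed mood, guilt,
# suicide, work/activities, retardation, agitation, psychic anxiety, somatic
# anxiety, hypochondriasis) and eight rated 0-2; total maximum 52.
HAMD_ITEM_MAX: tuple[int, ...] = (4, 4, 4, 2, 2, 2, 4, 4, 4, 4, 4, 2, 2, 2, 4, 2, 2)
HAMD_MAX_TOTAL = sum(HAMD_ITEM_MAX)  # 52

N_WEEKS = 6                     # training weeks; visits at weeks 0..6
SESSIONS_PER_WEEK = 3
VISITS = N_WEEKS + 1


@dataclass(frozen=True)
class ClinicalProfile:
    participant_id: str
    group: str                  # "EFMT" | "CT"
    baseline_hamd: int
    baseline_bdi: int
    baseline_wais: float        # mean scaled score of DSF, DSB, LNS
    episode_duration_months: float
    capacity: float = 3.0       # latent N-back capacity for the task engine

    def __post_init__(self) -> None:
        if not (16 <= self.baseline_hamd <= 27):
            raise ValueError("baseline Ham-D must respect the eligibility window [16, 27]")


@dataclass
class TrajectoryModel:
    """Arm-specific weekly mean curves plus residual structure.

    ``weekly_means[arm]`` has one Ham-D value per visit (weeks 0..6);
    ``residual_cov`` is the 7x7 positive-definite within-participant
    covariance; ``dose_effect`` (active arm only) shifts a participant's curve
    by ``dose_effect * (cumulative sessions - expected cumulative sessions)``
    so the configured means stay the realized means; ``item_profile`` gives
    the 17 allocation weights used to split totals into items.
    """

    weekly_means: dict[str, np.ndarray]
    residual_cov: np.ndarray
    dose_effect: float = 0.0
    dose_arm: str = "EFMT"
    expected_sessions_per_week: float = SESSIONS_PER_WEEK
    item_profile: np.ndarray = field(
        default_factory=lambda: np.asarray(HAMD_ITEM_MAX, float) / HAMD_MAX_TOTAL)
    bdi_link: dict[str, tuple[float, float]] = field(default_factory=dict)  # arm -> (intercept, slope)
    bdi_noise_sd: float = 3.0
    dropout_week_hazard: float = 0.0   # extrinsic dropout on top of protocol rules

    def __post_init__(self) -> None:
        self.residual_cov = np.asarray(self.residual_cov, float)
        if self.residual_cov.shape != (VISITS, VISITS):
            raise ValueError(f"residual_cov must be {VISITS}x{VISITS}")
        if not np.allclose(self.residual_cov, self.residual_cov.T):
            raise ValueError("residual_cov must be symmetric")
        eig = np.linalg.eigvalsh(self.residual_cov)
        if eig.min() < -1e-10:
            raise ValueError("residual_cov must be positive semi-definite")
        for arm, mu in self.weekly_means.items():
            mu = np.asarray(mu, float)
            if mu.shape != (VISITS,):
                raise ValueError(f"weekly_means[{arm!r}] must have {VISITS} entries")
            self.weekly_means[arm] = mu
        self.item_profile = np.asarray(self.item_profile, float)
        if self.item_profile.shape != (17,) or (self.item_profile < 0).any():
            raise ValueError("item_profile must be 17 non-negative weights")


@dataclass(frozen=True)
class TrajectoryRecord:
    participant_id: str
    week: int
    hamd_total: int
    hamd_items: tuple[int, ...]
    bdi: int
    sessions_this_week: int
    status: str                 # "active" | "discontinued" | "completed"

    def __post_init__(self) -> None:
        if sum(self.hamd_items) != self.hamd_total:
            raise ValueError("Ham-D items must sum to the total")


@dataclass(frozen=True)
class AdherenceRecord:
    sessions_by_week: tuple[int, ...]      # attended sessions, weeks 1..6
    discontinued: bool
    discontinuation_week: Optional[int]    # 1-based week the rule fired, else None

    @property
    def total_sessions(self) -> int:
        return sum(self.sessions_by_week)


@dataclass
class CohortConfig:
    """Baseline sampling parameters, per arm where relevant."""

    hamd_mean: dict[str, float] = field(default_factory=lambda: {"EFMT": 19.25, "CT": 19.48})
    hamd_sd: dict[str, float] = field(default_factory=lambda: {"EFMT": 2.55, "CT": 2.64})
    hamd_lo: int = 16
    hamd_hi: int = 27
    wais_mean: float = 10.9
    wais_sd: float = 0.8
    episode_months_mean: dict[str, float] = field(default_factory=lambda: {"EFMT": 18.6, "CT": 11.0})
    capacity_mean: dict[str, float] = field(default_factory=lambda: {"EFMT": 3.4, "CT": 4.4})
    capacity_sd: dict[str, float] = field(default_factory=lambda: {"EFMT": 1.7, "CT": 2.0})
    bdi_baseline_mean: dict[str, float] = field(default_factory=lambda: {"EFMT": 31.28, "CT": 28.71})
    attendance_prob: float = 0.88


from functools import lru_cache


@lru_cache(maxsize=64)
def _calibrated_truncnorm(mean: float, sd: float, lo: float, hi: float) -> stats.rv_continuous:
    """Truncated normal on [lo, hi] whose *truncated* mean equals ``mean``.

    Truncating a normal at the eligibility bounds shifts its mean (by ~+0.5
    Ham-D points for the default window), so the latent location is solved so
    that the distribution actually sampled has the configured mean.
    """
    if sd == 0:
        raise ValueError("sd must be > 0 for the calibrated truncated normal")

    def trunc_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    loc = optimize.brentq(trunc_mean, lo - 10 * sd, hi + 10 * sd)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


def sample_participant(group: str, rng: np.random.Generator,
                       config: CohortConfig | None = None,
                       participant_id: str = "P000") -> ClinicalProfile:
    """Draw one participant's baseline profile for the given arm.

    Baseline Ham-D is a rounded truncated normal confined to the eligibility
    window [16, 27] (calibrated so the sampled mean matches the configured
    arm mean); the working-memory composite is Normal(wais_mean, wais_sd).
    With ``hamd_sd = 0`` every baseline equals the rounded arm mean.
    """
    cfg = config or CohortConfig()
    mu, sd = cfg.hamd_mean[group], cfg.hamd_sd[group]
    if sd == 0:
        hamd = int(round(mu))
        if not (cfg.hamd_lo <= hamd <= cfg.hamd_hi):
            raise ValueError("degenerate config mean outside eligibility window")
    else:
        dist = _calibrated_truncnorm(mu, sd, cfg.hamd_lo - 0.499, cfg.hamd_hi + 0.499)
        hamd = int(np.clip(round(float(dist.rvs(random_state=rng))), cfg.hamd_lo, cfg.hamd_hi))
    bdi = max(0, int(round(rng.normal(cfg.bdi_baseline_mean[group], 4.0))))
    wais = float(rng.normal(cfg.wais_mean, cfg.wais_sd))
    months = float(rng.gamma(2.0, cfg.episode_months_mean[group] / 2.0))
    capacity = float(np.clip(rng.normal(cfg.capacity_mean[group], cfg.capacity_sd[group]), 1.0, 12.0))
    return ClinicalProfile(participant_id=participant_id, group=group,
                           baseline_hamd=hamd, baseline_bdi=bdi, baseline_wais=wais,
                           episode_duration_months=months, capacity=capacity)


def simulate_adherence(rng: np.random.Generator,
                       attendance_prob: float = 0.88,
                       n_weeks: int = N_WEEKS,
                       sessions_per_week: int = SESSIONS_PER_WEEK) -> AdherenceRecord:
    """Simulate attended sessions per week and apply the discontinuation rules.

    Each scheduled session is attended independently with ``attendance_prob``.
    A participant is discontinued in the first week where either rule fires:
    fewer than two sessions completed that week, or more than three sessions
    missed cumulatively.  Weeks after discontinuation have zero sessions.
    """
    sessions = [0] * n_weeks
    missed = 0
    disc_week: Optional[int] = None
    for w in range(n_weeks):
        s = int(rng.binomial(sessions_per_week, attendance_prob))
        sessions[w] = s
        missed += sessions_per_week - s
        if s < 2 or missed > 3:
            disc_week = w + 1
            for later in range(w + 1, n_weeks):
                sessions[later] = 0
            break
    return AdherenceRecord(sessions_by_week=tuple(sessions),
                           discontinued=disc_week is not None,
                           discontinuation_week=disc_week)


def compound_symmetry_cov(sd: float = 4.9, rho: float = 0.5,
                          n: int = VISITS) -> np.ndarray:
    """Compound-symmetry covariance stored as a dense matrix, so downstream
    models that assume an unstructured covariance are genuinely exercised."""
    cov = np.full((n, n), rho * sd * sd)
    np.fill_diagonal(cov, sd * sd)
    return cov


# Printed anchor geometry of the trial: CT declines linearly 19.48 -> 14.71;
# the CT-minus-EFMT difference is anchored at baseline/week-3/week-6
# (0.2283, 3.1462, 3.8681) and linearly interpolated between anchors.
_CT_ANCHORS = (19.48, 14.71)
_DIFF_ANCHORS = {0: 0.2283, 3: 3.1462, 6: 3.8681}
_BDI_ANCHORS = {"EFMT": (31.28, 20.0), "CT": (28.71, 25.29)}


def default_weekly_means() -> dict[str, np.ndarray]:
    weeks = np.arange(VISITS, dtype=float)
    ct = np.interp(weeks, [0, N_WEEKS], _CT_ANCHORS)
    diff = np.interp(weeks, sorted(_DIFF_ANCHORS), [_DIFF_ANCHORS[k] for k in sorted(_DIFF_ANCHORS)])
    return {"CT": ct, "EFMT": ct - diff}


def default_trajectory_model(residual_sd: float = 4.9, rho: float = 0.5,
                             dose_effect: float = -0.7,
                             attendance_prob: float = 0.88) -> TrajectoryModel:
    """Default generating model anchored to the trial's printed group curves."""
    means = default_weekly_means()
    bdi_link = {}
    for arm, (b0, b6) in _BDI_ANCHORS.items():
        h0, h6 = means[arm][0], means[arm][N_WEEKS]
        slope = (b0 - b6) / (h0 - h6)
        bdi_link[arm] = (b0 - slope * h0, slope)
    return TrajectoryModel(
        weekly_means=means,
        residual_cov=compound_symmetry_cov(residual_sd, rho),
        dose_effect=dose_effect,
        expected_sessions_per_week=SESSIONS_PER_WEEK * attendance_prob,
        bdi_link=bdi_link,
    )


def simulate_trajectory(profile: ClinicalProfile, model: TrajectoryModel,
                        sessions_by_week: Sequence[int], rng: np.random.Generator,
                        discontinuation_week: Optional[int] = None,
                        ) -> list[TrajectoryRecord]:
    """Simulate one participant's weekly Ham-D/BDI records.

    Weekly total = arm mean + centred dose term (active arm) + correlated
    residual, rounded and clipped to the instrument range [0, 52].  The
    week-0 residual is replaced so the baseline equals the sampled eligible
    baseline.  Records stop before ``discontinuation_week`` (a participant
    discontinued in week w misses the week-w assessment onward).
    """
    mu = model.weekly_means[profile.group].copy()
    pd_ok = np.linalg.eigvalsh(model.residual_cov).min() > 1e-10
    resid = rng.multivariate_normal(np.zeros(VISITS), model.residual_cov,
                                    method="cholesky" if pd_ok else "svd")
    cum = np.concatenate([[0], np.cumsum(sessions_by_week)])
    if profile.group == model.dose_arm and model.dose_effect != 0.0:
        expected = model.expected_sessions_per_week * np.arange(VISITS)
        mu = mu + model.dose_effect * (cum - expected)
    totals = np.clip(np.round(mu + resid), 0, HAMD_MAX_TOTAL).astype(int)
    totals[0] = profile.baseline_hamd

    last_week = VISITS - 1 if discontinuation_week is None else discontinuation_week - 1
    records = []
    for w in range(last_week + 1):
        items = decompose_hamd_items(int(totals[w]), model.item_profile, rng)
        icpt, slope = model.bdi_link.get(profile.group, (0.0, 1.0))
        bdi = int(np.clip(round(icpt + slope * totals[w] + rng.normal(0, model.bdi_noise_sd)), 0, 63))
        if w == 0:
            bdi = profile.baseline_bdi
        if discontinuation_week is not None and w == last_week:
            status = "discontinued"
        elif w == VISITS - 1:
            status = "completed"
        else:
            status = "active"
        records.append(TrajectoryRecord(
            participant_id=profile.participant_id, week=w,
            hamd_total=int(totals[w]), hamd_items=tuple(items), bdi=bdi,
            sessions_this_week=0 if w == 0 else int(sessions_by_week[w - 1]),
            status=status))
    return records


def decompose_hamd_items(total: int, item_profile: Sequence[float],
                         rng: np.random.Generator) -> np.ndarray:
    """Split a Ham-D total into 17 item scores.

    Multinomial allocation proportional to ``item_profile`` with stochastic
    redistribution of any points exceeding an item's maximum; the result
    always re-sums to ``total`` and respects each item's range.
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    if total > HAMD_MAX_TOTAL:
        raise ValueError(f"total {total} exceeds the instrument maximum {HAMD_MAX_TOTAL}")
    w = np.asarray(item_profile, float)
    if w.sum() <= 0:
        raise ValueError("item_profile must have positive mass")
    items = rng.multinomial(total, w / w.sum())
    caps = np.asarray(HAMD_ITEM_MAX)
    for _ in range(64):
        over = np.maximum(items - caps, 0)
        if not over.any():
            break
        items = np.minimum(items, caps)
        room = caps - items
        free = w * (room > 0)
        if free.sum() == 0:
            free = (room > 0).astype(float)
        extra = rng.multinomial(int(over.sum()), free / free.sum())
        items = items + extra
    return items.astype(int)


def simulate_cohort_totals(n_by_arm: dict[str, int], model: TrajectoryModel,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Vectorized totals-only cohort draw for calibration studies.

    Same generative law as :func:`simulate_trajectory` (arm weekly means +
    correlated residuals, rounded, clipped to the instrument range) with full
    attendance and no item decomposition, so thousands of complete cohorts
    can be drawn cheaply for Monte-Carlo parameter-recovery and type-I-error
    studies of the longitudinal models.
    """
    rows = []
    offset = 0
    for arm, n in n_by_arm.items():
        mu = model.weekly_means[arm]
        resid = rng.multivariate_normal(np.zeros(VISITS), model.residual_cov,
                                        size=n, method="cholesky")
        totals = np.clip(np.round(mu + resid), 0, HAMD_MAX_TOTAL).astype(int)
        for i in range(n):
            pid = f"S{offset + i:04d}"
            for w in range(VISITS):
                rows.append((pid, arm, w, totals[i, w]))
        offset += n
    return pd.DataFrame(rows, columns=["participant_id", "arm", "week", "hamd_total"])


def wais_composite(dsf: float, dsb: float, lns: float) -> float:
    """Working-memory composite: mean scaled score of Digit-Span Forward,
    Digit-Span Backward and Letter-Number Sequencing."""
    return (dsf + dsb + lns) / 3.0
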