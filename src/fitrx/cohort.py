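"""Synthetic cohorts of male-student fitness records and two-arm trial datasets.

The simulator emulates the statistical structure the downstream pipeline
assumes: a four-class WHO BMI distribution heavily skewed toward normal
weight, a monotone dependence of the four fitness tests on weight status,
and a late-lap fatigue signal in the 3,000 m run whose slope grows with
BMI category. Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

N_LAPS = 15
METRICS = ("run_3000m", "pull_ups", "sit_ups", "shuttle")

COHORT_COLUMNS = (
    ["subject_id"]
    + [f"lap_{i:02d}" for i in range(1, N_LAPS + 1)]
    + ["pull_ups", "sit_ups", "shuttle_s", "bmi", "category"]
)


class BMICategory(enum.IntEnum):
    """WHO weight-status class, ordinal in BMI."""

    underweight = 0
    normal = 1
    overweight = 2
    obese = 3


def assign_bmi_category(bmi: float) -> BMICategory:
    """Classify a BMI (kg/m^2) into the WHO category.

    Boundaries are half-open with the lower bound inclusive —
    [18.5, 25) normal, [25, 30) overweight, >= 30 obese — so every
    positive BMI maps to exactly one category.
    """
    if not math.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be positive and finite, got {bmi!r}")
    if bmi < 18.5:
        return BMICategory.underweight
    if bmi < 25.0:
        return BMICategory.normal
    if bmi < 30.0:
        return BMICategory.overweight
    return BMICategory.obese


@dataclass(frozen=True)
class FitnessRecord:
    """One subject's four-test battery plus BMI and category label.

    lap_times are the fifteen 200 m splits of the 3,000 m run in seconds;
    their sum is the total run time. shuttle_time is the 30x2 shuttle-run
    total in seconds.
    """

    subject_id: str
    lap_times: tuple[float, ...]
    pull_ups: int
    sit_ups: int
    shuttle_time: float
    bmi: float
    category: BMICategory

    def __post_init__(self) -> None:
        if len(self.lap_times) != N_LAPS:
            raise ValueError(f"expected {N_LAPS} lap times, got {len(self.lap_times)}")
        if any(t <= 0 for t in self.lap_times):
            raise ValueError("lap times must be positive")
        if self.pull_ups < 0 or self.sit_ups < 0:
            raise ValueError("repetition counts must be non-negative")
        if self.category != assign_bmi_category(self.bmi):
            raise ValueError("category inconsistent with BMI")

    @property
    def run_total(self) -> float:
        return float(sum(self.lap_times))


# Base level and spread of each test in the reference (normal-weight) class,
# anchored to the trial cohort's baseline means/SDs: pull-ups 10.2 +/- 3.1,
# 3,000 m 14.2 +/- 1.1 min (=> ~56.8 s per 200 m lap), shuttle 32.4 +/- 2.3 s.
METRIC_BASE = {
    "pace": (55.5, 2.5),      # s per 200 m lap, subject-level
    "pull_ups": (10.5, 3.1),
    "sit_ups": (40.0, 6.0),
    "shuttle": (32.0, 2.3),
}

# Mean shift of each metric per category (underweight, normal, overweight,
# obese) in units of that metric's SD. Counts fall and times rise from
# normal -> obese; underweight sits slightly below normal on every test.
DEFAULT_EFFECT_SIZES = {
    "pace": (0.4, 0.0, 0.9, 2.2),
    "pull_ups": (-0.5, 0.0, -1.0, -2.0),
    "sit_ups": (-0.4, 0.0, -0.9, -1.8),
    "shuttle": (0.4, 0.0, 0.9, 2.0),
}

# Late-lap slowdown in s per lap index; grows with weight status so the
# fatigue signature separates the classes in the lap sequence itself.
DEFAULT_FATIGUE_SLOPE = (0.10, 0.20, 0.40, 0.60)

# BMI sampling windows per category (mean, sd, low, high); truncated normal.
_BMI_WINDOWS = (
    (17.4, 0.7, 15.0, 18.5),
    (21.5, 1.6, 18.5, 25.0),
    (26.7, 1.2, 25.0, 30.0),
    (31.5, 1.3, 30.0, 40.0),
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort draw.

    class_proportions default to the development-cohort prevalence
    (5.3 / 74.5 / 19.0 / 1.2 %); counts are fixed by largest-remainder
    rounding so they always sum to n.
    """

    n: int
    class_proportions: tuple[float, float, float, float] = (0.053, 0.745, 0.190, 0.012)
    fatigue_slope_by_category: tuple[float, float, float, float] = DEFAULT_FATIGUE_SLOPE
    metric_effect_sizes: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    lap_noise_sd: float = 1.2
    seed: int = 42

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("class proportions must be non-negative")
        n_positive = sum(1 for p in self.class_proportions if p > 0)
        if self.n < n_positive:
            raise ValueError(
                f"n={self.n} too small to place every positive-proportion category"
            )


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Integer class counts summing to n via largest-remainder rounding.

    Ties in the fractional remainders are broken by lower class index,
    which makes the allocation deterministic.
    """
    quotas = [n * p for p in proportions]
    counts = [int(math.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    shortfall = n - sum(counts)
    order = sorted(range(len(proportions)), key=lambda i: (-remainders[i], i))
    for i in order[:shortfall]:
        counts[i] += 1
    return counts


def _truncated_normal(rng: np.random.Generator, mean, sd, low, high, size) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out >= high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out >= high)
    return out


def generate_cohort(spec: CohortSpec) -> list[FitnessRecord]:
    """Draw a cohort of FitnessRecords reproducible from spec.seed.

    Per subject: BMI from the category's truncated-normal window; a
    lognormal base lap pace shifted by the category pace effect; lap t =
    base pace + fatigue_slope * (t-1) + Gaussian split noise; counts and
    shuttle time from shifted normals, counts rounded and floored at 0.
    """
    counts = largest_remainder_counts(spec.n, spec.class_proportions)
    rng = np.random.default_rng(spec.seed)
    records: list[FitnessRecord] = []
    sid = 0
    for cat in BMICategory:
        k = counts[cat]
        if k == 0:
            continue
        bmi = _truncated_normal(rng, *_BMI_WINDOWS[cat], size=k)
        pace_mu, pace_sd = METRIC_BASE["pace"]
        eff = spec.metric_effect_sizes
        center = pace_mu + eff["pace"][cat] * pace_sd
        # lognormal base pace: subject-level variation multiplicative in pace
        base_pace = center * np.exp(rng.normal(0.0, pace_sd / pace_mu, size=k))
        slope = spec.fatigue_slope_by_category[cat]
        laps = (
            base_pace[:, None]
            + slope * np.arange(N_LAPS)[None, :]
            + rng.normal(0.0, spec.lap_noise_sd, size=(k, N_LAPS))
        )
        laps = np.maximum(laps, 1.0)
        pu_mu, pu_sd = METRIC_BASE["pull_ups"]
        su_mu, su_sd = METRIC_BASE["sit_ups"]
        sh_mu, sh_sd = METRIC_BASE["shuttle"]
        pull_ups = np.maximum(
            0, np.rint(rng.normal(pu_mu + eff["pull_ups"][cat] * pu_sd, pu_sd, size=k))
        ).astype(int)
        sit_ups = np.maximum(
            0, np.rint(rng.normal(su_mu + eff["sit_ups"][cat] * su_sd, su_sd, size=k))
        ).astype(int)
        shuttle = np.maximum(
            5.0, rng.normal(sh_mu + eff["shuttle"][cat] * sh_sd, sh_sd, size=k)
        )
        for i in range(k):
            records.append(
                FitnessRecord(
                    subject_id=f"S{sid:05d}",
                    lap_times=tuple(float(x) for x in laps[i]),
                    pull_ups=int(pull_ups[i]),
                    sit_ups=int(sit_ups[i]),
                    shuttle_time=float(shuttle[i]),
                    bmi=float(bmi[i]),
                    category=cat,
                )
            )
            sid += 1
    return records


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def cohort_to_frame(records: Sequence[FitnessRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id}
        row.update({f"lap_{i + 1:02d}": r.lap_times[i] for i in range(N_LAPS)})
        row.update(
            pull_ups=r.pull_ups,
            sit_ups=r.sit_ups,
            shuttle_s=r.shuttle_time,
            bmi=r.bmi,
            category=r.category.name,
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[FitnessRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            FitnessRecord(
                subject_id=str(row["subject_id"]),
                lap_times=tuple(float(row[f"lap_{i:02d}"]) for i in range(1, N_LAPS + 1)),
                pull_ups=int(row["pull_ups"]),
                sit_ups=int(row["sit_ups"]),
                shuttle_time=float(row["shuttle_s"]),
                bmi=float(row["bmi"]),
                category=BMICategory[str(row["category"])],
            )
        )
    return records


def write_cohort_csv(records: Sequence[FitnessRecord], path, spec: CohortSpec | None = None) -> None:
    """Write one row per subject; if a spec is given, a JSON sidecar
    records the generating parameters for provenance."""
    cohort_to_frame(records).to_csv(path, index=False)
    if spec is not None:
        sidecar = str(path) + ".spec.json"
        with open(sidecar, "w", encoding="utf-8") as fh:
            json.dump(asdict(spec), fh, indent=2)


def read_cohort_csv(path) -> list[FitnessRecord]:
    return frame_to_cohort(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Randomized trial
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialRecord:
    """Paired baseline/post measurements for one trial participant."""

    subject_id: str
    arm: str  # "intervention" | "control"
    baseline: FitnessRecord
    post: FitnessRecord
    adherence_fraction: float
    completed: bool

    def __post_init__(self) -> None:
        if self.baseline.subject_id != self.post.subject_id:
            raise ValueError("baseline and post must share subject_id")
        if not 0.0 <= self.adherence_fraction <= 1.0:
            raise ValueError("adherence must be in [0, 1]")


# Twelve-week mean changes per arm, anchored to the trial's reported
# within-group deltas: intervention +4.5 pull-ups, -1.4 min on 3,000 m,
# -3.3 s shuttle; control +1.5 / -0.5 min / -1.3 s. Sit-up changes are not
# tabulated; modest defaults. The BMI effect is per baseline category
# (under, normal, over, obese) because the prescription targets the
# heaviest deficits hardest; the intervention values are calibrated so the
# expected transition rates match the reported 68.3% overweight->normal
# and 41.2% obese->overweight.
DEFAULT_TRIAL_EFFECTS = {
    "intervention": {
        "pull_ups": 4.5,
        "run_total_s": -84.0,  # -1.4 min
        "shuttle_s": -3.3,
        "sit_ups": 5.0,
        "bmi": (0.3, -0.8, -2.6, -1.55),
    },
    "control": {
        "pull_ups": 1.5,
        "run_total_s": -30.0,  # -0.5 min
        "shuttle_s": -1.3,
        "sit_ups": 2.0,
        "bmi": (0.1, -0.2, -0.5, -0.3),
    },
}

# Between-subject SD of each 12-week change score.
DEFAULT_CHANGE_SD = {
    "pull_ups": 1.6,
    "run_total_s": 20.0,
    "shuttle_s": 1.4,
    "sit_ups": 2.5,
    "bmi": 0.9,
}

DEFAULT_ATTRITION = {"intervention": 0.132, "control": 0.141}
ADHERENCE_MEAN, ADHERENCE_SD = 0.785, 0.123


def _shift_record(rec: FitnessRecord, deltas: dict[str, float], rng: np.random.Generator,
                  change_sd: dict[str, float]) -> FitnessRecord:
    def d(key):
        sd = change_sd[key]
        delta = deltas[key]
        if isinstance(delta, (tuple, list)):  # per baseline category
            delta = delta[int(rec.category)]
        return delta + (rng.normal(0.0, sd) if sd > 0 else 0.0)

    run_delta = d("run_total_s")
    laps = tuple(max(t + run_delta / N_LAPS, 1.0) for t in rec.lap_times)
    bmi = max(rec.bmi + d("bmi"), 12.0)
    # half-up rounding keeps a +4.5 mean effect deterministic (+4 or +5)
    half_up = lambda x: int(math.floor(x + 0.5))
    return FitnessRecord(
        subject_id=rec.subject_id,
        lap_times=laps,
        pull_ups=max(0, half_up(rec.pull_ups + d("pull_ups"))),
        sit_ups=max(0, half_up(rec.sit_ups + d("sit_ups"))),
        shuttle_time=max(5.0, rec.shuttle_time + d("shuttle_s")),
        bmi=bmi,
        category=assign_bmi_category(bmi),
    )


def generate_trial(
    n_per_arm: int,
    effects: dict[str, dict[str, float]] | None = None,
    attrition: dict[str, float] | None = None,
    change_sd: dict[str, float] | None = None,
    seed: int = 42,
    baseline_spec: CohortSpec | None = None,
) -> list[TrialRecord]:
    """Simulate a two-arm trial with permuted-block randomization.

    Post metrics are baseline plus the arm effect plus subject-level
    change noise; completion flags are missing-at-random Bernoulli draws
    at 1 - attrition.
    """
    if n_per_arm < 2:
        raise ValueError("need at least 2 subjects per arm")
    effects = effects if effects is not None else DEFAULT_TRIAL_EFFECTS
    attrition = attrition if attrition is not None else DEFAULT_ATTRITION
    change_sd = change_sd if change_sd is not None else DEFAULT_CHANGE_SD
    for arm, frac in attrition.items():
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"attrition for {arm} must be in [0, 1)")

    n = 2 * n_per_arm
    # trial recruits skew heavier than the development cohort: weight the
    # overweight/obese classes up so category transitions are observable
    spec = baseline_spec or CohortSpec(n=n, class_proportions=(0.04, 0.56, 0.32, 0.08),
                                       seed=seed)
    baseline = generate_cohort(spec)
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(n)
    arms_seq = randomize_blocks(n, block_size=4, seed=seed + 2)

    records = []
    for pos, idx in enumerate(order):
        rec = baseline[idx]
        arm = arms_seq[pos]
        post = _shift_record(rec, effects[arm], rng, change_sd)
        adherence = float(np.clip(rng.normal(ADHERENCE_MEAN, ADHERENCE_SD), 0.0, 1.0))
        completed = bool(rng.random() >= attrition[arm])
        records.append(
            TrialRecord(
                subject_id=rec.subject_id,
                arm=arm,
                baseline=rec,
                post=post,
                adherence_fraction=adherence,
                completed=completed,
            )
        )
    return records


def randomize_blocks(n: int, block_size: int = 4, seed: int = 42) -> list[str]:
    """Permuted-block allocation to two arms.

    Every complete block contains exactly block_size/2 of each arm; a
    trailing partial block is a truncated permuted block, so the overall
    imbalance never exceeds block_size/2.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if block_size < 2 or block_size % 2 != 0:
        raise ValueError("block size must be even and >= 2")
    rng = np.random.default_rng(seed)
    half = block_size // 2
    template = np.array([0] * half + [1] * half)
    out: list[str] = []
    while len(out) < n:
        block = rng.permutation(template)
        out.extend("intervention" if b == 0 else "control" for b in block)
    return out[:n]


def trial_to_frame(records: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "arm": r.arm,
            "adherence": r.adherence_fraction,
            "completed": r.completed,
        }
        for tag, rec in (("base", r.baseline), ("post", r.post)):
            row[f"{tag}_run_total_s"] = rec.run_total
            row[f"{tag}_pull_ups"] = rec.pull_ups
            row[f"{tag}_sit_ups"] = rec.sit_ups
            row[f"{tag}_shuttle_s"] = rec.shuttle_time
            row[f"{tag}_bmi"] = rec.bmi
            row[f"{tag}_category"] = rec.category.name
        rows.append(row)
    return pd.DataFrame(rows)
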