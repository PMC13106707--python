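"""Shapley attribution over the four fitness metrics and the rule-based
exercise-prescription layer.

Attribution is exact: with only four features the full coalition lattice
has 2^4 = 16 cells, so Shapley values are enumerated without sampling,
with absent features imputed by the background mean. Deficiencies (metrics
pushing the prediction toward a less healthy category) map onto the weekly
training template — HIIT 5x30 min, aerobic 3x30 min, strength 2x30 min,
>= 300 min/week — via emphasis rules, and longitudinal adjustment applies
progressive overload with an acute:chronic load-ratio (FRBI) deload guard.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, replace
from datetime import date, timedelta
from typing import Callable, Sequence

import numpy as np

from .cohort import BMICategory

METRIC_ORDER = ("run_3000m", "pull_ups", "sit_ups", "shuttle")


# ---------------------------------------------------------------------------
# Exact Shapley attribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapAttribution:
    """Signed per-metric contributions (log-odds units) to the predicted class."""

    contributions: dict[str, float]
    base_value: float
    predicted_class: BMICategory
    model_output: float  # log-odds margin at the full coalition

    @property
    def additivity_gap(self) -> float:
        return abs(self.base_value + sum(self.contributions.values()) - self.model_output)


def _log_odds(p: np.ndarray, cls: int) -> float:
    pc = float(np.clip(p[cls], 1e-12, 1 - 1e-12))
    return math.log(pc / (1.0 - pc))


def metric_shap(
    pipeline: Callable[[np.ndarray], np.ndarray],
    x: Sequence[float],
    background: np.ndarray,
) -> ShapAttribution:
    """Exact Shapley values of the four metric summaries.

    `pipeline` maps an (N, 4) matrix of metric summaries to (N, 4) class
    probabilities and must be deterministic (checked by a repeated
    evaluation). The coalition value v(S) is the log-odds of the predicted
    class when features outside S are replaced by the background mean.
    """
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    if x.shape != (4,):
        raise ValueError("x must hold exactly 4 metric summaries")
    if background.ndim != 2 or background.shape[1] != 4 or len(background) == 0:
        raise ValueError("background must be a non-empty (B, 4) sample")
    ref = background.mean(axis=0)

    # build all 16 coalition inputs in one batch
    coalitions = list(itertools.product((0, 1), repeat=4))
    grid = np.array([np.where(np.array(c, bool), x, ref) for c in coalitions])
    probs = np.asarray(pipeline(grid), dtype=float)
    probs2 = np.asarray(pipeline(grid), dtype=float)
    if not np.array_equal(probs, probs2):
        raise ValueError("pipeline is not deterministic; attribution undefined")
    full = coalitions.index((1, 1, 1, 1))
    cls = int(np.argmax(probs[full]))
    v = {c: _log_odds(probs[i], cls) for i, c in enumerate(coalitions)}

    phi = np.zeros(4)
    fact = math.factorial
    for m in range(4):
        for c in coalitions:
            if c[m] == 1:
                continue
            s = sum(c)
            weight = fact(s) * fact(4 - s - 1) / fact(4)
            c_with = tuple(1 if j == m else cj for j, cj in enumerate(c))
            phi[m] += weight * (v[c_with] - v[c])
    return ShapAttribution(
        contributions=dict(zip(METRIC_ORDER, phi.tolist())),
        base_value=v[(0, 0, 0, 0)],
        predicted_class=BMICategory(cls),
        model_output=v[(1, 1, 1, 1)],
    )


def rank_deficiencies(attr: ShapAttribution, second_fraction: float = 0.5) -> list[str]:
    """Top 1-2 metrics whose positive contributions drove an unhealthy prediction.

    Returns the metric with the largest positive contribution, plus the
    runner-up iff its contribution is at least `second_fraction` of the
    leader's. A normal-weight prediction, or no positive contribution,
    yields an empty list. Ties break by the fixed metric order.
    """
    if attr.predicted_class == BMICategory.normal:
        return []
    positive = [
        (m, c) for m, c in attr.contributions.items() if c > 0
    ]
    if not positive:
        return []
    order = {m: i for i, m in enumerate(METRIC_ORDER)}
    positive.sort(key=lambda mc: (-mc[1], order[mc[0]]))
    out = [positive[0][0]]
    if len(positive) > 1 and positive[1][1] >= second_fraction * positive[0][1]:
        out.append(positive[1][0])
    return out


# ---------------------------------------------------------------------------
# Weekly plan template and emphasis mapping
# ---------------------------------------------------------------------------

HIIT_PROTOCOL = "5 cycles of 20-s maximal sprint + 40-s rest"

# deficiency -> (modality to emphasize, tag)
EMPHASIS_RULES = {
    "pull_ups": ("strength", "upper-body strength"),
    "run_3000m": ("aerobic", "aerobic conditioning"),
    "sit_ups": ("strength", "core strength"),
    "shuttle": ("HIIT", "anaerobic power"),
}

STATIC_PLAN_NOTES = (
    "Diet: 2,500-3,000 kcal/day adjusted to BMI; protein >= 84 g/day; "
    "carbohydrate 300-400 g/day (whole grains); fat 50-70 g/day; fiber >= 25 g/day; "
    "minimize high-sugar foods. Mental health: stress-management activity >= 1x/week; "
    ">= 30 min daily outdoor activity."
)


@dataclass(frozen=True)
class Session:
    modality: str          # "HIIT" | "aerobic" | "strength"
    frequency: int         # sessions per week
    minutes: float         # minutes per session
    load: float = 1.0      # load multiplier


@dataclass(frozen=True)
class WeeklyPlan:
    sessions: tuple[Session, ...]
    emphasis: tuple[str, ...] = ()
    deload_days: int = 0
    notes: str = STATIC_PLAN_NOTES

    @property
    def total_weekly_minutes(self) -> float:
        return sum(s.frequency * s.minutes for s in self.sessions)

    def session(self, modality: str) -> Session:
        for s in self.sessions:
            if s.modality == modality:
                return s
        raise KeyError(modality)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": 1,
                "sessions": [
                    {"modality": s.modality, "freq": s.frequency,
                     "minutes": s.minutes, "load": s.load}
                    for s in self.sessions
                ],
                "emphasis": list(self.emphasis),
                "deload_days": self.deload_days,
                "total_weekly_minutes": self.total_weekly_minutes,
                "hiit_protocol": HIIT_PROTOCOL,
                "notes": self.notes,
            },
            indent=2,
        )

    def to_markdown(self) -> str:
        lines = ["| Modality | Sessions/wk | Minutes | Load |", "|---|---|---|---|"]
        for s in self.sessions:
            lines.append(f"| {s.modality} | {s.frequency} | {s.minutes} | {s.load:.3f} |")
        lines.append("")
        lines.append(f"Total weekly minutes: {self.total_weekly_minutes}")
        if self.emphasis:
            lines.append("Emphasis: " + ", ".join(self.emphasis))
        if self.deload_days:
            lines.append(f"Deload active for {self.deload_days} days")
        lines.append(f"HIIT protocol: {HIIT_PROTOCOL}")
        lines.append(self.notes)
        return "\n".join(lines)


def plan_from_json(text: str) -> WeeklyPlan:
    obj = json.loads(text)
    return WeeklyPlan(
        sessions=tuple(
            Session(s["modality"], int(s["freq"]), float(s["minutes"]), float(s["load"]))
            for s in obj["sessions"]
        ),
        emphasis=tuple(obj.get("emphasis", ())),
        deload_days=int(obj.get("deload_days", 0)),
        notes=obj.get("notes", STATIC_PLAN_NOTES),
    )


def baseline_plan() -> WeeklyPlan:
    """The unmodified weekly template: 10 sessions, 300 minutes."""
    return WeeklyPlan(
        sessions=(
            Session("HIIT", 5, 30),
            Session("aerobic", 3, 30),
            Session("strength", 2, 30),
        )
    )


def map_prescription(
    deficiencies: Sequence[str],
    emphasis_load: float = 1.2,
) -> WeeklyPlan:
    """Instantiate the weekly template with deficiency-driven emphasis.

    Each deficiency adds one weekly session of its mapped modality and
    raises that modality's load multiplier to `emphasis_load`. Total
    minutes can only grow, so the >= 300 min floor is preserved.
    """
    plan = baseline_plan()
    sessions = {s.modality: s for s in plan.sessions}
    tags: list[str] = []
    for d in deficiencies:
        if d not in EMPHASIS_RULES:
            raise ValueError(f"unknown deficiency tag {d!r}")
        modality, tag = EMPHASIS_RULES[d]
        s = sessions[modality]
        sessions[modality] = replace(
            s, frequency=s.frequency + 1, load=max(s.load, emphasis_load)
        )
        tags.append(tag)
    out = WeeklyPlan(
        sessions=tuple(sessions[m] for m in ("HIIT", "aerobic", "strength")),
        emphasis=tuple(tags),
    )
    assert out.total_weekly_minutes >= 300
    return out


# ---------------------------------------------------------------------------
# Load monitoring and longitudinal adjustment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoadHistory:
    """Dated session loads (RPE x minutes, arbitrary units)."""

    entries: tuple[tuple[date, float], ...]

    def __post_init__(self) -> None:
        for _, load in self.entries:
            if load < 0:
                raise ValueError("loads must be non-negative")
        dates = [d for d, _ in self.entries]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("dates must be strictly increasing")


def compute_frbi(
    history: LoadHistory, acute_window: int = 7, chronic_window: int = 28
) -> float:
    """Fatigue-recovery balance index: acute:chronic mean daily load ratio.

    Mean daily load over the trailing `acute_window` days divided by the
    mean over the trailing `chronic_window` days (windows end at the last
    recorded date; days without sessions count as zero load). Steady
    loading gives exactly 1.0; values above ~1.2 flag overtraining risk.
    """
    if not history.entries:
        raise ValueError("empty load history")
    last = history.entries[-1][0]
    first = history.entries[0][0]
    if (last - first).days + 1 < chronic_window:
        raise ValueError(
            f"history spans {(last - first).days + 1} days; needs >= {chronic_window} "
            "(pad explicitly with zero-load days if intended)"
        )

    def daily_mean(window: int) -> float:
        start = last - timedelta(days=window - 1)
        total = sum(load for d, load in history.entries if d >= start)
        return total / window

    chronic = daily_mean(chronic_window)
    if chronic == 0:
        raise ZeroDivisionError("zero chronic load; FRBI undefined")
    return daily_mean(acute_window) / chronic


@dataclass(frozen=True)
class AdjustmentPolicy:
    frbi_threshold: float = 1.2
    deload_fraction: float = 0.175   # midpoint of the 15-20% band
    deload_days: int = 4             # midpoint of 3-5 days
    improvement_threshold: float = 0.02
    volume_increment: float = 0.075  # midpoint of the 5-10% weekly band


def adjust_prescription(
    plan: WeeklyPlan,
    progress: dict[str, float],
    frbi: float,
    policy: AdjustmentPolicy = AdjustmentPolicy(),
) -> WeeklyPlan:
    """Biweekly reassessment step.

    If FRBI exceeds the threshold, every modality's load multiplier is cut
    by the deload fraction for `deload_days` days and nothing is intensified.
    Otherwise each metric whose fractional improvement (positive = better)
    falls below the improvement threshold has its mapped modality's volume
    raised by the progressive-overload increment; improving metrics leave
    the plan untouched.
    """
    if frbi > policy.frbi_threshold:
        sessions = tuple(
            replace(s, load=s.load * (1.0 - policy.deload_fraction))
            for s in plan.sessions
        )
        return replace(plan, sessions=sessions, deload_days=policy.deload_days)

    sessions = {s.modality: s for s in plan.sessions}
    for metric, change in progress.items():
        if metric not in EMPHASIS_RULES:
            raise ValueError(f"unknown metric {metric!r}")
        if change >= policy.improvement_threshold:
            continue
        modality, _ = EMPHASIS_RULES[metric]
        s = sessions[modality]
        sessions[modality] = replace(s, minutes=s.minutes * (1.0 + policy.volume_increment))
    return replace(
        plan,
        sessions=tuple(sessions[s.modality] for s in plan.sessions),
        deload_days=0,
    )
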