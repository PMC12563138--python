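"""Break-even estimation for graft substitution.

During healing of a grafted site, the fraction of the evaluated tissue area
occupied by newly formed bone rises while the fraction occupied by residual
graft particles falls.  The *break-even point* is the moment at which the two
fractions are equal — a measurable proxy for the regenerative equilibrium
between bone apposition and graft resorption.  With histomorphometric data at
two healing times, the estimate is the intersection of two straight lines:
an ascending one through the bone observations and a descending one through
the graft observations.

The estimator is deliberately linear.  Bone healing is not — it accelerates
and plateaus — so the companion :mod:`breakeven.sim` module quantifies the
bias this approximation incurs under nonlinear ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Status",
    "BreakEvenConfig",
    "TimepointObservation",
    "HealingSeries",
    "LinearTrend",
    "BreakEvenResult",
    "DimensionLossResult",
    "ValidationError",
    "fit_segment_trends",
    "select_segment",
    "estimate_break_even",
    "dimension_loss",
    "analyze_series",
    "compare_materials",
]

#: statuses rendered "NA" in reports (no trustworthy crossing coordinates)
NON_CONVERGENT = frozenset({"not_reached", "divergent"})


class ValidationError(ValueError):
    """Invalid input data (out-of-range percentage, bad series, unknown time)."""


class Status(str, Enum):
    """Classification of an estimated crossing relative to the fitted segment.

    - ``within_interval``: the crossing falls inside the observed segment —
      an interpolation, the most trustworthy case.
    - ``extrapolated``: the crossing falls beyond the last observation but
      within ``max_extrapolation_factor`` times it; reported with a caveat.
    - ``not_reached``: the projected crossing is so far beyond the data that
      the linear extrapolation is considered unjustified; rendered NA.
    - ``already_crossed``: bone already exceeded graft before the first
      observation; neither interpolation nor forward extrapolation applies.
    - ``divergent``: the lines are parallel or separating (bone slope not
      greater than graft slope); no meaningful crossing exists; rendered NA.
    """

    WITHIN_INTERVAL = "within_interval"
    EXTRAPOLATED = "extrapolated"
    NOT_REACHED = "not_reached"
    ALREADY_CROSSED = "already_crossed"
    DIVERGENT = "divergent"

    @property
    def convergent(self) -> bool:
        return self in (Status.WITHIN_INTERVAL, Status.EXTRAPOLATED)


@dataclass(frozen=True)
class BreakEvenConfig:
    """Tunable knobs of the estimator.

    Parameters
    ----------
    max_extrapolation_factor
        A projected crossing at time t* with last observation at t_end is
        accepted (status ``extrapolated``) only while t* <= factor * t_end.
        Beyond that the series is classified ``not_reached``.  Default 1.5.
    report_decimals
        Decimal places used by report renderers.  Internal values are never
        rounded.
    """

    max_extrapolation_factor: float = 1.5
    report_decimals: int = 1

    def __post_init__(self) -> None:
        if self.max_extrapolation_factor < 1.0:
            raise ValidationError("max_extrapolation_factor must be >= 1")


@dataclass(frozen=True)
class TimepointObservation:
    """One histomorphometric measurement.

    ``new_bone_pct`` and ``residual_graft_pct`` are fractions of the evaluated
    tissue area, in percent; they are compositional, so their sum cannot
    exceed 100.  ``animal_id`` is None for group means.  ``total_area`` (mm²)
    feeds the dimension-loss computation when available.
    """

    time_days: float
    new_bone_pct: float
    residual_graft_pct: float
    animal_id: str | None = None
    total_area: float | None = None

    def __post_init__(self) -> None:
        if not self.time_days > 0:
            raise ValidationError(f"time_days must be > 0, got {self.time_days}")
        for name in ("new_bone_pct", "residual_graft_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name} must be in [0, 100], got {v}")
        if self.new_bone_pct + self.residual_graft_pct > 100.0 + 1e-9:
            raise ValidationError(
                "new_bone_pct + residual_graft_pct exceeds 100% "
                f"({self.new_bone_pct} + {self.residual_graft_pct})"
            )


@dataclass(frozen=True)
class HealingSeries:
    """Ordered observations for one material in one study.

    Replicate (per-animal) observations may share a time point; the estimator
    aggregates them to arithmetic group means via :meth:`aggregate` before
    trend fitting.  At least two distinct times are required.
    """

    study_label: str
    material: str
    observations: tuple[TimepointObservation, ...]

    def __init__(
        self,
        study_label: str,
        material: str,
        observations: Iterable[TimepointObservation],
    ) -> None:
        obs = tuple(
            sorted(observations, key=lambda o: (o.time_days, o.animal_id or ""))
        )
        if len({o.time_days for o in obs}) < 2:
            raise ValidationError(
                f"series {study_label!r}/{material!r} needs >= 2 distinct time points"
            )
        object.__setattr__(self, "study_label", study_label)
        object.__setattr__(self, "material", material)
        object.__setattr__(self, "observations", obs)

    @property
    def times(self) -> tuple[float, ...]:
        """Distinct observation times, ascending."""
        return tuple(sorted({o.time_days for o in self.observations}))

    @property
    def has_replicates(self) -> bool:
        return any(o.animal_id is not None for o in self.observations)

    def aggregate(self) -> "HealingSeries":
        """Collapse replicates to per-time-point arithmetic means."""
        if not self.has_replicates and len(self.observations) == len(self.times):
            return self
        rows = []
        for t in self.times:
            group = [o for o in self.observations if o.time_days == t]
            areas = [o.total_area for o in group if o.total_area is not None]
            rows.append(
                TimepointObservation(
                    time_days=t,
                    new_bone_pct=sum(o.new_bone_pct for o in group) / len(group),
                    residual_graft_pct=sum(o.residual_graft_pct for o in group)
                    / len(group),
                    total_area=sum(areas) / len(areas) if areas else None,
                )
            )
        return HealingSeries(self.study_label, self.material, rows)

    def observation_at(self, time_days: float) -> TimepointObservation:
        """Group-mean observation at an exact time point."""
        agg = self.aggregate()
        for o in agg.observations:
            if o.time_days == time_days:
                return o
        raise ValidationError(
            f"time {time_days} not observed in series "
            f"{self.study_label!r}/{self.material!r} (have {agg.times})"
        )


@dataclass(frozen=True)
class LinearTrend:
    """A straight line in (percent vs. days) space, fitted over one segment.

    The two-point fit is exact: evaluating at ``t_start``/``t_end`` returns
    the anchoring observations.
    """

    slope: float  # percent per day
    intercept: float  # percent at day 0
    t_start: float
    t_end: float

    def __call__(self, t: float) -> float:
        return self.slope * t + self.intercept

    @classmethod
    def through_points(
        cls, t1: float, y1: float, t2: float, y2: float
    ) -> "LinearTrend":
        if t1 == t2:
            raise ValidationError(f"degenerate segment: t1 == t2 == {t1}")
        slope = (y2 - y1) / (t2 - t1)
        return cls(slope=slope, intercept=y1 - slope * t1, t_start=t1, t_end=t2)


@dataclass(frozen=True)
class BreakEvenResult:
    """The estimated crossing and its validity classification.

    ``time_days``/``level_pct`` hold the projected intersection even for
    ``not_reached``, ``already_crossed`` and non-parallel ``divergent``
    geometry (useful for diagnostics and for re-classification under a
    different extrapolation bound); they are None only for parallel lines,
    where no intersection exists.  Report renderers print NA for
    ``not_reached`` and ``divergent``.
    """

    time_days: float | None
    level_pct: float | None
    status: Status
    segment: tuple[float, float]
    extrapolation_factor: float | None = None
    study_label: str | None = None
    material: str | None = None

    def to_dict(self) -> dict:
        """JSON-compatible record; non-convergent coordinates rendered None."""
        convergent = self.status.convergent
        return {
            "study": self.study_label,
            "material": self.material,
            "segment_start_days": self.segment[0],
            "segment_end_days": self.segment[1],
            "time_days": self.time_days if convergent else None,
            "level_pct": self.level_pct if convergent else None,
            "status": self.status.value,
            "extrapolation_factor": self.extrapolation_factor,
        }


@dataclass(frozen=True)
class DimensionLossResult:
    """Percent reduction of total augmented area between two healing periods."""

    loss_pct: float
    period: tuple[float, float]


def fit_segment_trends(
    series: HealingSeries, segment: tuple[float, float]
) -> tuple[LinearTrend, LinearTrend]:
    """Fit exact two-point lines to bone and graft over one segment.

    Parameters
    ----------
    series
        The healing series; replicates are aggregated to group means first.
    segment
        ``(t1, t2)`` in days; both must be observed times, and distinct.

    Returns
    -------
    (bone, graft)
        Ascending bone trend and (typically) descending graft trend.
    """
    t1, t2 = segment
    if t1 == t2:
        raise ValidationError(f"segment times must be distinct, got {segment}")
    o1, o2 = series.observation_at(t1), series.observation_at(t2)
    bone = LinearTrend.through_points(t1, o1.new_bone_pct, t2, o2.new_bone_pct)
    graft = LinearTrend.through_points(
        t1, o1.residual_graft_pct, t2, o2.residual_graft_pct
    )
    return bone, graft


def select_segment(series: HealingSeries) -> tuple[float, float]:
    """Choose the two time points closest to the anticipated crossing.

    Scans adjacent time-point pairs of the aggregated series and returns the
    earliest pair across which the sign of (bone − graft) changes or touches
    zero.  If the difference never changes sign, the crossing is anticipated
    beyond the data and the last pair is returned.
    """
    agg = series.aggregate()
    times = agg.times
    diffs = [
        o.new_bone_pct - o.residual_graft_pct for o in agg.observations
    ]
    for i in range(len(times) - 1):
        if diffs[i] == 0.0 or diffs[i] * diffs[i + 1] <= 0.0:
            return (times[i], times[i + 1])
    return (times[-2], times[-1])


def estimate_break_even(
    bone: LinearTrend,
    graft: LinearTrend,
    config: BreakEvenConfig | None = None,
) -> BreakEvenResult:
    """Intersect the two trend lines and classify the crossing.

    The closed form is ``t* = (c_g − c_b) / (m_b − m_g)`` for lines
    ``y = m t + c``; the level is either line evaluated at ``t*``.  All
    degenerate geometries map to statuses rather than exceptions: parallel or
    separating lines are ``divergent``, a crossing before the segment is
    ``already_crossed``, and a crossing beyond
    ``max_extrapolation_factor × t_end`` is ``not_reached``.
    """
    config = config or BreakEvenConfig()
    segment = (bone.t_start, bone.t_end)
    if (bone.t_start, bone.t_end) != (graft.t_start, graft.t_end):
        raise ValidationError(
            "bone and graft trends must be fitted on the same segment"
        )
    if bone.slope == graft.slope:
        return BreakEvenResult(None, None, Status.DIVERGENT, segment)

    t_star = (graft.intercept - bone.intercept) / (bone.slope - graft.slope)
    t_start, t_end = segment
    # snap to an observed endpoint when the crossing lands there up to
    # rounding, so an observed bone == graft equality is reported exactly
    for anchor in (t_start, t_end):
        if t_star != anchor and math.isclose(
            t_star, anchor, rel_tol=1e-12, abs_tol=1e-12
        ):
            t_star = anchor
    level = bone(t_star)
    factor = t_star / t_end if t_star > t_end else None

    if bone.slope < graft.slope:
        # geometric intersection exists but the bone trend is falling
        # relative to the graft trend: no forward convergence
        return BreakEvenResult(t_star, level, Status.DIVERGENT, segment, factor)
    if t_star < t_start:
        status = Status.ALREADY_CROSSED
    elif t_star <= t_end:
        status = Status.WITHIN_INTERVAL
    elif t_star <= config.max_extrapolation_factor * t_end:
        status = Status.EXTRAPOLATED
    else:
        status = Status.NOT_REACHED
    return BreakEvenResult(t_star, level, status, segment, factor)


def dimension_loss(
    area_t1: float, area_t2: float, t1: float, t2: float
) -> DimensionLossResult:
    """Percent reduction of total augmented area between two periods.

    ``loss = (area_t1 − area_t2) / area_t1 × 100``; a gain comes out
    negative.  Distinct from the graft-fraction change: it tracks the whole
    augmented region shrinking, not the graft's share of it.
    """
    if not area_t1 > 0:
        raise ValidationError(f"baseline area must be > 0, got {area_t1}")
    if not t2 > t1:
        raise ValidationError(f"period must be ordered, got ({t1}, {t2})")
    return DimensionLossResult(
        loss_pct=(area_t1 - area_t2) / area_t1 * 100.0, period=(t1, t2)
    )


def analyze_series(
    series: HealingSeries, config: BreakEvenConfig | None = None
) -> BreakEvenResult:
    """End-to-end estimate for one series: select segment, fit, intersect."""
    agg = series.aggregate()
    segment = select_segment(agg)
    bone, graft = fit_segment_trends(agg, segment)
    result = estimate_break_even(bone, graft, config)
    return replace(result, study_label=series.study_label, material=series.material)


def compare_materials(
    series_collection: Sequence[HealingSeries],
    config: BreakEvenConfig | None = None,
) -> pd.DataFrame:
    """Break-even comparison across materials.

    One row per series, sorted ascending by estimated crossing time with
    non-convergent (``not_reached``/``divergent``) rows last.  Columns carry
    unrounded values; rendering to a report rounds and inserts NA.
    """
    rows = []
    for s in series_collection:
        r = analyze_series(s, config)
        rows.append(
            {
                "study": s.study_label,
                "material": s.material,
                "segment_start_days": r.segment[0],
                "segment_end_days": r.segment[1],
                "time_days": r.time_days,
                "level_pct": r.level_pct,
                "status": r.status.value,
                "extrapolated": r.status is Status.EXTRAPOLATED,
                "extrapolation_factor": r.extrapolation_factor,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "study",
            "material",
            "segment_start_days",
            "segment_end_days",
            "time_days",
            "level_pct",
            "status",
            "extrapolated",
            "extrapolation_factor",
        ],
    )
    if df.empty:
        return df
    df["_na"] = df["status"].isin(NON_CONVERGENT)
    df["_t"] = df["time_days"].where(~df["_na"], other=math.inf)
    df = (
        df.sort_values(["_na", "_t"], kind="stable")
        .drop(columns=["_na", "_t"])
        .reset_index(drop=True)
    )
    return df
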