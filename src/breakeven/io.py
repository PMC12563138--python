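"""Reading, reporting and plotting for break-even analyses.

Input is tidy CSV: one row per (study, material, time point), columns
``study, material, time_value, time_unit, new_bone_pct, residual_graft_pct``
with optional ``animal_id`` and ``total_area_mm2``.  Times are converted to
days on read (week × 7, month × 30).  A bundled dataset of six graft
materials from four rabbit sinus-floor-elevation studies ships with the
package for worked examples and regression tests.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import (
    BreakEvenConfig,
    BreakEvenResult,
    HealingSeries,
    Status,
    TimepointObservation,
    ValidationError,
    NON_CONVERGENT,
    fit_segment_trends,
)

__all__ = [
    "UNIT_DAYS",
    "StudyTable",
    "read_study_table",
    "write_study_table",
    "load_rabbit_sinus_lift",
    "render_report",
    "plot_crossing",
]

UNIT_DAYS = {"day": 1.0, "week": 7.0, "month": 30.0}

REQUIRED_COLUMNS = (
    "study",
    "material",
    "time_value",
    "time_unit",
    "new_bone_pct",
    "residual_graft_pct",
)
OPTIONAL_COLUMNS = ("animal_id", "total_area_mm2")


@dataclass(frozen=True)
class StudyTable:
    """Validated tidy table of histomorphometric observations.

    ``frame`` keeps the original columns plus a derived ``time_days``; row
    order is preserved from the source file so round-trips are faithful.
    """

    frame: pd.DataFrame

    def to_series(self) -> list[HealingSeries]:
        """Group rows into one :class:`HealingSeries` per (study, material)."""
        out = []
        seen = []
        for _, row in self.frame.iterrows():
            key = (row["study"], row["material"])
            if key not in seen:
                seen.append(key)
        for study, material in seen:
            sub = self.frame[
                (self.frame["study"] == study)
                & (self.frame["material"] == material)
            ]
            obs = [
                TimepointObservation(
                    time_days=r["time_days"],
                    new_bone_pct=r["new_bone_pct"],
                    residual_graft_pct=r["residual_graft_pct"],
                    animal_id=r.get("animal_id"),
                    total_area=r.get("total_area_mm2"),
                )
                for _, r in sub.iterrows()
            ]
            out.append(HealingSeries(study, material, obs))
        return out

    def __len__(self) -> int:
        return len(self.frame)


def _validate_rows(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{source}: missing column(s) {missing}")
    df = df.copy()
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = None
    df["animal_id"] = df["animal_id"].where(pd.notna(df["animal_id"]), None)
    df["total_area_mm2"] = df["total_area_mm2"].where(
        pd.notna(df["total_area_mm2"]), None
    )

    time_days = []
    for i, row in df.iterrows():
        where = f"{source}: row {i + 2}"  # +2: header line and 1-based count
        unit = str(row["time_unit"]).strip().lower()
        if unit not in UNIT_DAYS:
            raise ValidationError(
                f"{where}: unknown time_unit {row['time_unit']!r} "
                f"(expected one of {sorted(UNIT_DAYS)})"
            )
        try:
            t = float(row["time_value"]) * UNIT_DAYS[unit]
            bone = float(row["new_bone_pct"])
            graft = float(row["residual_graft_pct"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{where}: non-numeric value ({exc})") from exc
        if t <= 0:
            raise ValidationError(f"{where}: time must be positive, got {t} days")
        for name, v in (("new_bone_pct", bone), ("residual_graft_pct", graft)):
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"{where}: {name} = {v} outside [0, 100]"
                )
        if bone + graft > 100.0 + 1e-9:
            raise ValidationError(
                f"{where}: new_bone_pct + residual_graft_pct = "
                f"{bone + graft} exceeds 100%"
            )
        time_days.append(t)
    df["time_days"] = time_days
    return df


def read_study_table(path) -> StudyTable:
    """Read and validate a tidy study CSV; converts times to days.

    Raises :class:`~breakeven.core.ValidationError` naming the offending row
    (1-based, counting the header) on any malformed value.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype={"study": str, "material": str})
    return StudyTable(_validate_rows(df, str(path)))


def write_study_table(table: StudyTable, path) -> None:
    """Write a study table back to CSV with the original input columns."""
    cols = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in table.frame]
    out = table.frame[cols]
    # drop all-empty optional columns so round-trips are field-identical
    for col in OPTIONAL_COLUMNS:
        if col in out.columns and out[col].isna().all():
            out = out.drop(columns=[col])
    out.to_csv(path, index=False)


def load_rabbit_sinus_lift() -> StudyTable:
    """The bundled rabbit sinus-floor-elevation dataset.

    Six graft materials (autogenous bone chips, Bio-Oss in two studies,
    Bio-Oss Collagen, Maxresorb granules and paste, Gen-Os) from four
    published rabbit studies, as group means at two healing times each.
    """
    ref = resources.files("breakeven.data").joinpath("rabbit_sinus_lift.csv")
    with resources.as_file(ref) as p:
        return read_study_table(p)


def _fmt(value: float | None, decimals: int, status: str, marker: str = "") -> str:
    if value is None or status in NON_CONVERGENT:
        return "NA"
    return f"{value:.{decimals}f}{marker}"


def render_report(
    comparison: pd.DataFrame,
    fmt: str = "text",
    config: BreakEvenConfig | None = None,
) -> str:
    """Render a material comparison as pretty text or CSV.

    Non-convergent rows print ``NA`` for both coordinates; rows estimated by
    extrapolation beyond the last observation carry an ``a`` footnote marker
    on their day and level values.  Values are rounded to
    ``config.report_decimals`` (default 1); internal values stay unrounded.
    """
    config = config or BreakEvenConfig()
    d = config.report_decimals
    rows = []
    for _, r in comparison.iterrows():
        marker = " a" if r.get("extrapolated") else ""
        seg = f"{r['segment_start_days']:g}-{r['segment_end_days']:g} d"
        rows.append(
            {
                "study": r["study"],
                "material": r["material"],
                "segment": seg,
                "days": _fmt(r["time_days"], d, r["status"], marker),
                "level_pct": _fmt(r["level_pct"], d, r["status"], marker),
                "status": r["status"],
            }
        )
    out = pd.DataFrame(
        rows, columns=["study", "material", "segment", "days", "level_pct", "status"]
    )
    if fmt == "csv":
        buf = _io.StringIO()
        out.to_csv(buf, index=False)
        return buf.getvalue()
    if fmt == "text":
        if out.empty:
            return "  ".join(out.columns)
        widths = {
            c: max(len(c), *(len(str(v)) for v in out[c])) for c in out.columns
        }
        lines = ["  ".join(c.ljust(widths[c]) for c in out.columns)]
        for _, r in out.iterrows():
            lines.append("  ".join(str(r[c]).ljust(widths[c]) for c in out.columns))
        note = "a extrapolated beyond the last observation point"
        if any("a" in str(v) for v in out["days"]):
            lines.append(note)
        return "\n".join(lines)
    raise ValidationError(f"unknown report format {fmt!r}")


def plot_crossing(
    series: HealingSeries,
    result: BreakEvenResult,
    path,
    config: BreakEvenConfig | None = None,
) -> None:
    """Two-line crossing plot: ascending bone, descending graft.

    Solid lines over the fitted segment; dashed continuation to the crossing
    when it lies beyond the data (extrapolated); a marker at the intersection
    whenever the status permits one.  Writes PNG or SVG by file extension.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    agg = series.aggregate()
    bone, graft = fit_segment_trends(agg, result.segment)
    t1, t2 = result.segment

    fig, ax = plt.subplots(figsize=(6, 4))
    for trend, label, color in (
        (bone, "new bone", "tab:blue"),
        (graft, "residual graft", "tab:orange"),
    ):
        ax.plot([t1, t2], [trend(t1), trend(t2)], color=color, label=label)
    times = agg.times
    ax.plot(times, [o.new_bone_pct for o in agg.observations], "o", color="tab:blue")
    ax.plot(
        times,
        [o.residual_graft_pct for o in agg.observations],
        "s",
        color="tab:orange",
    )
    if result.status is Status.EXTRAPOLATED:
        t_star = result.time_days
        for trend, color in ((bone, "tab:blue"), (graft, "tab:orange")):
            ax.plot([t2, t_star], [trend(t2), trend(t_star)], "--", color=color)
    if result.status.convergent:
        ax.plot(
            [result.time_days],
            [result.level_pct],
            "k*",
            markersize=12,
            label=f"break-even {result.time_days:.1f} d / {result.level_pct:.1f}%",
        )
    ax.set_xlabel("healing time (days)")
    ax.set_ylabel("% of evaluated tissue area")
    ax.set_title(f"{series.material} ({series.study_label})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
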