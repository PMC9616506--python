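"""Preclinical tumor-volume response classification.

Caliper measurements convert to volumes with V = pi*l*s^2/6 (l the long
side, s the short side, in mm). Per-mouse response over the treatment
window follows the Pediatric Preclinical Testing Program (PPTP) classes,
evaluated on the volume relative to baseline (randomization):

* CR  — the tumor drops below the measurable minimum (default 100 mm^3);
* MCR — CR maintained at the last in-window observation;
* PR  — >= 50% regression without reaching CR;
* PD  — >= 25% growth without ever regressing past 50%;
* SD  — everything else.

A relapse is regrowth above ``relapse_min`` (default 200 mm^3) after a CR
was reached or after surgical resection. The exact PPTP parameterization
used in any given study may differ; every threshold here is a config key
echoed into the output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)


def volume_from_caliper(l: float, s: float) -> float:
    """Ellipsoid tumor volume V = pi*l*s^2/6 (mm^3).

    ``l`` is defined as the long side; swapped operands are corrected
    with a logged warning.
    """
    if l < 0 or s < 0:
        raise ValueError("caliper measurements must be non-negative")
    if l < s:
        logger.warning("caliper long side %.3g < short side %.3g; swapping", l, s)
        l, s = s, l
    return math.pi * l * s * s / 6.0


@dataclass(frozen=True)
class ResponseThresholds:
    """PPTP-style classification thresholds (all config-overridable)."""

    pd_min_relative: float = 1.25   # >= 25% volume increase
    pr_max_relative: float = 0.5    # >= 50% regression
    measurable_min: float = 100.0   # mm^3; below this the tumor counts as CR
    relapse_min: float = 200.0      # mm^3; regrowth above this is a relapse


@dataclass
class VolumeSeries:
    """One mouse's tumor-volume trajectory (days strictly increasing)."""

    mouse_id: str
    group: str
    days: list[int]
    volumes: list[float]
    window: tuple[int, int] = (0, 42)
    surgery_day: int | None = None

    def __post_init__(self) -> None:
        if len(self.days) != len(self.volumes):
            raise ValueError("days and volumes must align")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(v < 0 for v in self.volumes):
            raise ValueError("volumes must be non-negative")


@dataclass(frozen=True)
class ResponseCall:
    mouse_id: str
    group: str
    response: str  # PD | SD | PR | CR | MCR
    relapse: bool
    min_relative: float
    max_relative: float
    min_volume: float
    baseline_volume: float
    thresholds: ResponseThresholds = field(default=ResponseThresholds())


def classify_response(
    series: VolumeSeries, thresholds: ResponseThresholds = ResponseThresholds()
) -> ResponseCall:
    """Classify one mouse's response; see the module docstring for rules.

    The baseline is the first observation at or after the start of the
    treatment window; the response class is evaluated on in-window
    observations, while relapse scans all later observations.
    """
    start, end = series.window
    try:
        b = next(i for i, d in enumerate(series.days) if d >= start)
    except StopIteration:
        raise ValueError("no observation at or after the randomization day")
    baseline = series.volumes[b]
    if baseline <= 0:
        raise ValueError("baseline volume must be positive")
    in_window = [
        (d, v) for d, v in zip(series.days[b:], series.volumes[b:]) if d <= end
    ]
    if len(in_window) < 2:
        raise ValueError("need at least two in-window observations")
    rel = [v / baseline for _, v in in_window]
    min_rel, max_rel = min(rel), max(rel)
    min_vol = min(v for _, v in in_window)

    if min_vol < thresholds.measurable_min:
        final_vol = in_window[-1][1]
        response = "MCR" if final_vol < thresholds.measurable_min else "CR"
    elif min_rel <= thresholds.pr_max_relative:
        response = "PR"
    elif max_rel >= thresholds.pd_min_relative:
        response = "PD"
    else:
        response = "SD"

    relapse = False
    cr_day: float | None = None
    if response in ("CR", "MCR"):
        cr_day = next(d for d, v in in_window if v < thresholds.measurable_min)
    if series.surgery_day is not None:
        cr_day = min(cr_day, series.surgery_day) if cr_day is not None \
            else series.surgery_day
    if cr_day is not None:
        relapse = any(
            v > thresholds.relapse_min
            for d, v in zip(series.days, series.volumes)
            if d > cr_day
        )

    return ResponseCall(
        mouse_id=series.mouse_id, group=series.group, response=response,
        relapse=relapse, min_relative=min_rel, max_relative=max_rel,
        min_volume=min_vol, baseline_volume=baseline, thresholds=thresholds,
    )


RESPONSE_CLASSES = ("PD", "SD", "PR", "CR", "MCR")


def tally_outcomes(calls: Sequence[ResponseCall], group: str) -> pd.DataFrame:
    """Counts and integer-rounded percentages per response class + relapse."""
    in_group = [c for c in calls if c.group == group]
    if not in_group:
        raise ValueError(f"no calls in group {group!r}")
    n = len(in_group)
    rows = []
    for cls in RESPONSE_CLASSES:
        count = sum(c.response == cls for c in in_group)
        rows.append({"group": group, "outcome": cls, "count": count,
                     "percent": round(100.0 * count / n)})
    relapsed = sum(c.relapse for c in in_group)
    rows.append({"group": group, "outcome": "relapse", "count": relapsed,
                 "percent": round(100.0 * relapsed / n)})
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[ResponseCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "mouse_id": c.mouse_id, "group": c.group, "response": c.response,
            "relapse": c.relapse, "min_relative": c.min_relative,
            "max_relative": c.max_relative, "min_volume": c.min_volume,
            "baseline_volume": c.baseline_volume,
        }
        for c in calls
    ])


def read_volumes_tsv(path, window=(0, 42)) -> list[VolumeSeries]:
    """TSV with columns mouse_id, group, day and either volume or l + s."""
    df = pd.read_csv(path, sep="\t")
    series = []
    for (mouse, group), grp in df.groupby(["mouse_id", "group"], sort=True):
        grp = grp.sort_values("day")
        if "volume" in grp.columns and grp["volume"].notna().all():
            vols = [float(v) for v in grp["volume"]]
        else:
            vols = [volume_from_caliper(float(r.l), float(r.s))
                    for r in grp.itertuples()]
        surgery = None
        if "surgery_day" in grp.columns and grp["surgery_day"].notna().any():
            surgery = int(grp["surgery_day"].dropna().iloc[0])
        series.append(VolumeSeries(
            mouse_id=str(mouse), group=str(group),
            days=[int(d) for d in grp["day"]], volumes=vols,
            window=window, surgery_day=surgery,
        ))
    return series
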