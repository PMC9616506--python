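"""Intratumor heterogeneity metrics and fish-plot data export.

Three statistics summarize the clonal composition of a tumor:

* CNAB, the copy-number aberration burden: the frequency-weighted sum of
  absolute copy deviations from a diploid cell, restricted to aberrations
  not in the model's stem clone (so models can be compared on what they
  accumulated beyond their shared starting material);
* Simpson's index of diversity Ds = 1 - sum(f^2) over clone frequencies
  (0 = monoclonal; approaches 1 when every cell is its own clone);
* the private-aberration fraction: the share of a tumor's non-stem clones
  (or events) observed in no other tumor of the same model — a measure
  of inter-tumor heterogeneity.

Fish-plot export validates parent-child nesting of clone prevalences over
time and emits the time grid, trajectories and parent map as plain data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

FREQ_TOL = 1e-6


class Aberration(NamedTuple):
    """A copy-number aberration carried by a clone.

    ``copy`` is the total copy number of the affected span; the burden
    contribution is |copy - reference| (reference 2 = diploid cell).
    """

    chrom: str
    start: int
    end: int
    copy: int

    def deviation(self, reference_ploidy: int = 2) -> int:
        return abs(self.copy - reference_ploidy)

    @property
    def direction(self) -> str:
        return "gain" if self.copy > 2 else "loss"


@dataclass
class CloneFrequencyTable:
    """Clone frequencies (disjoint, summing to 1) for one tumor at one time."""

    tumor_id: str
    time: int
    frequencies: dict[str, float]
    clone_events: dict[str, frozenset[Aberration]]
    stem: frozenset[Aberration] = frozenset()

    def check_normalized(self) -> None:
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > FREQ_TOL:
            raise ValueError(
                f"clone frequencies of {self.tumor_id}@{self.time} sum to {total}"
            )

    def non_stem_events(self, clone: str) -> frozenset[Aberration]:
        return self.clone_events[clone] - self.stem


def cnab(table: CloneFrequencyTable, reference_ploidy: int = 2) -> float:
    """Copy-number aberration burden, stem-excluded.

    CNAB = sum over clones of f(clone) * sum over that clone's non-stem
    aberrations of |copy deviation from the reference ploidy|.
    """
    if not table.frequencies:
        raise ValueError("tumor has no clones")
    table.check_normalized()
    total = 0.0
    for clone, f in table.frequencies.items():
        burden = sum(
            e.deviation(reference_ploidy) for e in table.non_stem_events(clone)
        )
        total += f * burden
    return total


def simpson_diversity(frequencies: Sequence[float]) -> float:
    """Simpson's index of diversity Ds = 1 - sum(f^2)."""
    arr = np.asarray(frequencies, dtype=float)
    if arr.size == 0 or abs(arr.sum() - 1.0) > FREQ_TOL:
        raise ValueError("clone frequencies must sum to 1")
    return float(1.0 - np.sum(arr ** 2))


def _events_match(a: Aberration, b: Aberration, min_reciprocal: float = 0.5) -> bool:
    if a.chrom != b.chrom or a.direction != b.direction:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov > 0 and ov >= min_reciprocal * (a.end - a.start) \
        and ov >= min_reciprocal * (b.end - b.start)


def private_aberration_fraction(
    tables: Sequence[CloneFrequencyTable],
    unit: str = "clones",
) -> dict[str, float]:
    """Fraction of each tumor's non-stem units found in no other tumor.

    ``unit="clones"`` (default) compares clones by exact event-set
    equality; ``unit="events"`` compares individual aberrations by the
    convergence rule (same chromosome and direction, reciprocal overlap
    >= 50%). Tumors observed at several times contribute the union of
    their clones. Tumors with no non-stem units get fraction 0.
    """
    by_tumor: dict[str, list[CloneFrequencyTable]] = {}
    for t in tables:
        by_tumor.setdefault(t.tumor_id, []).append(t)
    if len(by_tumor) < 2:
        raise ValueError("private-aberration fraction needs >= 2 tumors")

    if unit == "clones":
        units: dict[str, set[frozenset[Aberration]]] = {}
        for tumor, tabs in by_tumor.items():
            units[tumor] = {
                evs - tab.stem
                for tab in tabs
                for evs in tab.clone_events.values()
                if evs - tab.stem
            }
        out = {}
        for tumor, mine in units.items():
            others = set().union(*(u for t2, u in units.items() if t2 != tumor))
            if not mine:
                out[tumor] = 0.0
            else:
                private = [u for u in mine if u not in others]
                out[tumor] = len(private) / len(mine)
        return out
    if unit == "events":
        ev_units: dict[str, list[Aberration]] = {}
        for tumor, tabs in by_tumor.items():
            seen: list[Aberration] = []
            for tab in tabs:
                for evs in tab.clone_events.values():
                    for e in evs - tab.stem:
                        if e not in seen:
                            seen.append(e)
            ev_units[tumor] = seen
        out = {}
        for tumor, mine in ev_units.items():
            others = [e for t2, evs in ev_units.items() if t2 != tumor for e in evs]
            if not mine:
                out[tumor] = 0.0
            else:
                private = [
                    e for e in mine if not any(_events_match(e, o) for o in others)
                ]
                out[tumor] = len(private) / len(mine)
        return out
    raise ValueError(f"unknown unit {unit!r}")


# ---------------------------------------------------------------------------
# Fish-plot data

class NestingViolationError(ValueError):
    pass


@dataclass
class FishplotData:
    """Validated clone-prevalence trajectories for fish-plot rendering."""

    times: list[int]
    trajectories: dict[str, list[float]]  # prevalence per time point
    parents: dict[str, str | None]
    emergence_time: dict[str, float]
    interpolation: str = "linear"

    def to_json(self) -> str:
        return json.dumps({
            "times": self.times,
            "trajectories": self.trajectories,
            "parents": self.parents,
            "emergence_time": self.emergence_time,
            "interpolation": self.interpolation,
        }, indent=1, sort_keys=True)


def to_prevalence(
    frequencies: Mapping[str, float], parents: Mapping[str, str | None]
) -> dict[str, float]:
    """Convert disjoint clone fractions to cellular prevalence.

    The prevalence of a clone is its own fraction plus that of all its
    descendants — the quantity fish plots nest.
    """
    children: dict[str | None, list[str]] = {}
    for clone, parent in parents.items():
        children.setdefault(parent, []).append(clone)

    def prev(clone: str) -> float:
        return frequencies.get(clone, 0.0) + sum(
            prev(c) for c in children.get(clone, [])
        )

    return {clone: prev(clone) for clone in parents}


def fishplot_data(
    prevalences_by_time: Mapping[int, Mapping[str, float]],
    parents: Mapping[str, str | None],
    tol: float = FREQ_TOL,
) -> FishplotData:
    """Validate and assemble fish-plot trajectories for one tumor.

    Input prevalences are on the nested (clone + descendants) scale; at
    every time point the prevalences of a clone's children must sum to at
    most the clone's own prevalence. Clones absent at a time point get
    prevalence 0; values between observed times interpolate linearly, and
    a clone's emergence is placed at the midpoint before its first
    nonzero observation (standard fish-plot convention).
    """
    times = sorted(prevalences_by_time)
    if not times:
        raise ValueError("no time points supplied")
    children: dict[str | None, list[str]] = {}
    for clone, parent in parents.items():
        children.setdefault(parent, []).append(clone)

    for t in times:
        prev = prevalences_by_time[t]
        for clone, p in prev.items():
            if clone not in parents:
                raise ValueError(f"clone {clone!r} missing from the parent map")
            if not (-tol <= p <= 1.0 + tol):
                raise ValueError(f"prevalence {p} of {clone!r} outside [0, 1]")
        for parent_clone in parents:
            kids = children.get(parent_clone, [])
            kid_sum = sum(prev.get(k, 0.0) for k in kids)
            if kid_sum > prev.get(parent_clone, 0.0) + tol:
                raise NestingViolationError(
                    f"at time {t}, children {kids} of {parent_clone!r} sum to "
                    f"{kid_sum:.6g} > parent prevalence "
                    f"{prev.get(parent_clone, 0.0):.6g}"
                )

    trajectories = {
        clone: [float(prevalences_by_time[t].get(clone, 0.0)) for t in times]
        for clone in parents
    }
    emergence: dict[str, float] = {}
    for clone, traj in trajectories.items():
        first = next((k for k, v in enumerate(traj) if v > 0), None)
        if first is None or first == 0:
            emergence[clone] = float(times[0])
        else:
            emergence[clone] = (times[first - 1] + times[first]) / 2.0
    return FishplotData(times, trajectories, dict(parents), emergence)


# ---------------------------------------------------------------------------
# Tabular I/O

def tables_to_frame(tables: Sequence[CloneFrequencyTable]) -> pd.DataFrame:
    rows = []
    for t in tables:
        for clone, f in t.frequencies.items():
            events = ";".join(
                f"{e.chrom}:{e.start}-{e.end}:{e.copy}"
                for e in sorted(t.clone_events[clone])
            )
            rows.append({
                "tumor_id": t.tumor_id, "time": t.time, "clone_id": clone,
                "frequency": f, "events": events,
            })
    return pd.DataFrame(rows)


def frame_to_tables(
    df: pd.DataFrame, stem: frozenset[Aberration] = frozenset()
) -> list[CloneFrequencyTable]:
    def parse_events(s: str) -> frozenset[Aberration]:
        if not s or pd.isna(s):
            return frozenset()
        out = []
        for token in str(s).split(";"):
            loc, copy = token.rsplit(":", 1)
            chrom, span = loc.split(":")
            start, end = span.split("-")
            out.append(Aberration(chrom, int(start), int(end), int(copy)))
        return frozenset(out)

    tables = []
    for (tumor, time), grp in df.groupby(["tumor_id", "time"], sort=True):
        tables.append(CloneFrequencyTable(
            tumor_id=str(tumor), time=int(time),
            frequencies={str(r.clone_id): float(r.frequency)
                         for r in grp.itertuples()},
            clone_events={str(r.clone_id): parse_events(r.events)
                          for r in grp.itertuples()},
            stem=stem,
        ))
    return tables
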