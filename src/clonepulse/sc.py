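"""Single-cell CNA event calling and clone identification.

Input is an integer copy-number matrix on ~1-Mb genomic bins (rows) by
single cells (columns), as produced by low-pass scDNA-seq copy-number
callers. Events are maximal runs of consecutive same-chromosome bins at a
constant copy state deviating from the baseline ploidy. Two run-length
cutoffs curate candidate runs into events:

* imbalances (ordinary gains/losses) require >= 5 consecutive bins;
* high-grade amplifications (MYCN-level, far above single-copy gain)
  require only >= 2 consecutive bins.

Cells with identical event sets form a clone; event-free cells form the
designated "baseline" clone.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import chrom_sort_key

BASELINE_CLONE = "baseline"


@dataclass
class CellBinMatrix:
    """Integer copy states per (bin, cell); bins in BED 0-based half-open."""

    bins: list[tuple[str, int, int]]
    cells: list[str]
    copy_state: np.ndarray  # shape (n_bins, n_cells), int
    baseline_ploidy: int | Mapping[str, int] = 2

    def __post_init__(self) -> None:
        self.copy_state = np.asarray(self.copy_state, dtype=int)
        if self.copy_state.shape != (len(self.bins), len(self.cells)):
            raise ValueError("copy_state shape must be (n_bins, n_cells)")
        if (self.copy_state < 0).any():
            raise ValueError("copy states must be non-negative")
        keys = [(chrom_sort_key(c), s) for c, s, _ in self.bins]
        if keys != sorted(keys):
            raise ValueError("bins must be sorted by chromosome then start")
        prev: dict[str, int] = {}
        for chrom, start, end in self.bins:
            if start < prev.get(chrom, -1):
                raise ValueError(f"overlapping bins on {chrom}")
            prev[chrom] = end

    def baseline_for(self, cell: str) -> int:
        if isinstance(self.baseline_ploidy, Mapping):
            return self.baseline_ploidy.get(cell, 2)
        return self.baseline_ploidy

    def profile(self, cell: str) -> np.ndarray:
        try:
            j = self.cells.index(cell)
        except ValueError:
            raise KeyError(f"unknown cell {cell!r}") from None
        return self.copy_state[:, j]


@dataclass(frozen=True, order=True)
class CNAEvent:
    """A curated copy-number event: a constant-state run of bins.

    Events compare (and hash) by chromosome, bin span, direction and copy
    state; the grade follows from state and run length under the cutoffs.
    """

    chrom: str
    start_bin_index: int
    end_bin_index: int
    direction: Literal["gain", "loss"]
    copy_state: int
    grade: Literal["imbalance", "high_grade_amplification"] = field(
        default="imbalance", compare=False
    )

    @property
    def n_bins(self) -> int:
        return self.end_bin_index - self.start_bin_index + 1

    def genomic_span(self, bins: Sequence[tuple[str, int, int]]) -> tuple[str, int, int]:
        c0, s0, _ = bins[self.start_bin_index]
        c1, _, e1 = bins[self.end_bin_index]
        assert c0 == c1 == self.chrom
        return (self.chrom, s0, e1)


@dataclass
class CloneAssignment:
    cell_to_clone: dict[str, str]
    clone_events: dict[str, frozenset[CNAEvent]]
    clone_sizes: dict[str, int]

    @property
    def clones(self) -> list[str]:
        return list(self.clone_events)

    @property
    def frequencies(self) -> dict[str, float]:
        total = sum(self.clone_sizes.values())
        return {c: n / total for c, n in self.clone_sizes.items()}

    def is_singleton(self, clone: str) -> bool:
        return self.clone_sizes[clone] == 1


def _runs(profile: np.ndarray, baseline: int, chrom_of: np.ndarray) -> Iterable[tuple[int, int, int]]:
    """Maximal runs (start, end, state) of constant non-baseline state that
    never cross a chromosome boundary."""
    n = len(profile)
    i = 0
    while i < n:
        state = profile[i]
        if state == baseline:
            i += 1
            continue
        j = i
        while (
            j + 1 < n
            and profile[j + 1] == state
            and chrom_of[j + 1] == chrom_of[i]
        ):
            j += 1
        yield i, j, int(state)
        i = j + 1


def call_cell_events(
    matrix: CellBinMatrix,
    cell: str,
    min_imbalance_bins: int = 5,
    min_amplification_bins: int = 2,
    amplification_state_threshold: int | None = None,
    max_gap_bins: int = 0,
) -> list[CNAEvent]:
    """Call CNA events for one cell from its bin copy-state profile.

    Runs of length >= ``min_imbalance_bins`` become imbalances; runs at a
    state >= ``amplification_state_threshold`` (default baseline + 3) of
    length >= ``min_amplification_bins`` become high-grade amplifications.
    A run qualifying for both grades is emitted once, as an amplification.
    A single dissenting bin breaks a run unless ``max_gap_bins`` > 0, in
    which case same-state runs separated by at most that many bins are
    merged (the gap bins are absorbed into the run).
    """
    profile = matrix.profile(cell)
    baseline = matrix.baseline_for(cell)
    if amplification_state_threshold is None:
        amplification_state_threshold = baseline + 3
    chrom_of = pd.factorize(np.array([c for c, _, _ in matrix.bins]))[0]

    runs = list(_runs(profile, baseline, chrom_of))
    if max_gap_bins > 0:
        # merge same-state runs separated by at most max_gap_bins dissenting
        # bins (the gap is absorbed into the merged run)
        by_state: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for start, end, state in runs:
            by_state.setdefault((int(chrom_of[start]), state), []).append((start, end))
        merged: list[tuple[int, int, int]] = []
        for (_, state), spans in by_state.items():
            spans.sort()
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s - cur_e - 1 <= max_gap_bins:
                    cur_e = e
                else:
                    merged.append((cur_s, cur_e, state))
                    cur_s, cur_e = s, e
            merged.append((cur_s, cur_e, state))
        runs = sorted(merged)

    events: list[CNAEvent] = []
    for start, end, state in runs:
        length = end - start + 1
        direction = "gain" if state > baseline else "loss"
        chrom = matrix.bins[start][0]
        if state >= amplification_state_threshold and length >= min_amplification_bins:
            grade = "high_grade_amplification"
        elif length >= min_imbalance_bins:
            grade = "imbalance"
        else:
            continue
        events.append(CNAEvent(chrom, start, end, direction, state, grade))
    return events


def call_all_cells(matrix: CellBinMatrix, **kwargs) -> dict[str, frozenset[CNAEvent]]:
    return {
        cell: frozenset(call_cell_events(matrix, cell, **kwargs))
        for cell in matrix.cells
    }


def canonicalize_events(
    events_per_cell: Mapping[str, frozenset[CNAEvent]],
    tolerance_bins: int,
) -> dict[str, frozenset[CNAEvent]]:
    """Snap near-identical events onto shared canonical representatives.

    Events with the same chromosome, direction and copy state whose span
    boundaries differ by at most ``tolerance_bins`` are treated as the
    same event; the representative is the variant carried by the most
    cells (ties toward the genomically first). This emulates the
    curation step that a handful of noise-perturbed boundary bins should
    not split a clone.
    """
    counts: dict[CNAEvent, int] = defaultdict(int)
    for events in events_per_cell.values():
        for e in events:
            counts[e] += 1
    reps: list[CNAEvent] = []
    mapping: dict[CNAEvent, CNAEvent] = {}
    for e in sorted(counts, key=lambda e: (-counts[e], _event_sort_key(e))):
        match = next(
            (r for r in reps
             if r.chrom == e.chrom and r.direction == e.direction
             and r.copy_state == e.copy_state
             and abs(r.start_bin_index - e.start_bin_index) <= tolerance_bins
             and abs(r.end_bin_index - e.end_bin_index) <= tolerance_bins),
            None,
        )
        if match is None:
            reps.append(e)
            mapping[e] = e
        else:
            mapping[e] = match
    return {
        cell: frozenset(mapping[e] for e in events)
        for cell, events in events_per_cell.items()
    }


def group_cells_into_clones(
    events_per_cell: Mapping[str, frozenset[CNAEvent]],
    match_tolerance_bins: int = 0,
) -> CloneAssignment:
    """Partition cells into clones by event-set equality.

    Events compare exactly (chromosome, bin span, direction, state) by
    default; a positive ``match_tolerance_bins`` first snaps events whose
    boundaries differ by at most that many bins onto a common
    representative (see :func:`canonicalize_events`), for noisy data.
    Clones are labelled C1, C2, ... by decreasing size, ties broken by the
    lexicographically smallest member cell id; event-free cells form the
    "baseline" clone, which keeps its designated label.
    """
    if not events_per_cell:
        raise ValueError("no cells supplied")
    if match_tolerance_bins > 0:
        events_per_cell = canonicalize_events(events_per_cell, match_tolerance_bins)
    groups: dict[frozenset[CNAEvent], list[str]] = defaultdict(list)
    for cell, events in events_per_cell.items():
        groups[frozenset(events)].append(cell)

    ordered = sorted(
        groups.items(), key=lambda kv: (-len(kv[1]), min(kv[1]))
    )
    cell_to_clone: dict[str, str] = {}
    clone_events: dict[str, frozenset[CNAEvent]] = {}
    clone_sizes: dict[str, int] = {}
    k = 0
    for events, cells in ordered:
        if len(events) == 0:
            label = BASELINE_CLONE
        else:
            k += 1
            label = f"C{k}"
        clone_events[label] = events
        clone_sizes[label] = len(cells)
        for cell in cells:
            cell_to_clone[cell] = label
    return CloneAssignment(cell_to_clone, clone_events, clone_sizes)


@dataclass
class EventMatrix:
    """Binary events-by-columns matrix with per-column cell-count weights."""

    data: pd.DataFrame  # rows: event keys, columns: cells or clones, {0,1}
    events: list[CNAEvent]
    weights: pd.Series  # per column

    def __post_init__(self) -> None:
        if not self.data.isin([0, 1]).all().all():
            raise ValueError("event matrix entries must be binary")

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def column_event_sets(self) -> dict[str, frozenset[CNAEvent]]:
        out = {}
        for col in self.data.columns:
            mask = self.data[col].to_numpy().astype(bool)
            out[col] = frozenset(e for e, m in zip(self.events, mask) if m)
        return out


def _event_sort_key(e: CNAEvent):
    return (chrom_sort_key(e.chrom), e.start_bin_index, e.end_bin_index,
            e.direction, e.copy_state)


def build_event_matrix(
    assignment: CloneAssignment, columns: Literal["cells", "clones"] = "clones"
) -> EventMatrix:
    """Binary event matrix over the union of called events.

    Rows are events in genomic order; columns are clone labels (weighted
    by cell count) or cell ids (weight 1 each), in sorted order.
    """
    all_events = sorted(
        {e for evs in assignment.clone_events.values() for e in evs},
        key=_event_sort_key,
    )
    if columns == "clones":
        col_labels = sorted(assignment.clone_events)
        col_sets = assignment.clone_events
        weights = {c: assignment.clone_sizes[c] for c in col_labels}
    else:
        col_labels = sorted(assignment.cell_to_clone)
        col_sets = {
            cell: assignment.clone_events[assignment.cell_to_clone[cell]]
            for cell in col_labels
        }
        weights = {c: 1 for c in col_labels}
    mat = np.zeros((len(all_events), len(col_labels)), dtype=int)
    for j, col in enumerate(col_labels):
        evs = col_sets[col]
        for i, e in enumerate(all_events):
            if e in evs:
                mat[i, j] = 1
    index = [
        f"{e.chrom}:{e.start_bin_index}-{e.end_bin_index}:{e.direction}{e.copy_state}"
        for e in all_events
    ]
    data = pd.DataFrame(mat, index=index, columns=col_labels)
    return EventMatrix(data, all_events, pd.Series(weights, dtype=float))


# ---------------------------------------------------------------------------
# Tabular I/O

def read_cell_matrix(bins_bed, matrix_tsv, baseline_ploidy: int = 2) -> CellBinMatrix:
    """Load bins from a BED file and copy states from a bins-by-cells TSV."""
    bed = pd.read_csv(bins_bed, sep="\t", header=None,
                      names=["chrom", "start", "end"], usecols=[0, 1, 2])
    bins = [(str(r.chrom), int(r.start), int(r.end)) for r in bed.itertuples()]
    mat = pd.read_csv(matrix_tsv, sep="\t", index_col=0)
    return CellBinMatrix(bins, list(mat.columns), mat.to_numpy(), baseline_ploidy)


def events_to_frame(
    events_per_cell: Mapping[str, frozenset[CNAEvent]],
    bins: Sequence[tuple[str, int, int]],
) -> pd.DataFrame:
    rows = []
    for cell in sorted(events_per_cell):
        for e in sorted(events_per_cell[cell], key=_event_sort_key):
            chrom, start, end = e.genomic_span(bins)
            rows.append({
                "cell": cell, "chrom": chrom, "start": start, "end": end,
                "start_bin": e.start_bin_index, "end_bin": e.end_bin_index,
                "direction": e.direction, "copy_state": e.copy_state,
                "grade": e.grade,
            })
    return pd.DataFrame(rows)
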