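"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here, with the truth
record returned alongside: clone trees with per-branch CNA events, bulk
allele-specific segments at known purity, single-cell bin matrices,
expression matrices with group-structured signatures linked to survival,
and tumor-volume trajectories for each treatment-response archetype.

All generators are pure functions of (seed, parameters): regeneration
with the same arguments is bit-identical. Default noise levels
(sigma_log2r = 0.02, flip_noise = 0.01, volume noise 0.05) are visibly
nontrivial yet recoverable by the corresponding estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import bulk, sc
from .bulk import AllelicSegment, forward_log2r, forward_mbaf
from .diversity import Aberration, CloneFrequencyTable
from .genome import AUTOSOME_MB, MB
from .response import VolumeSeries
from .sc import CellBinMatrix, CloneAssignment, CNAEvent
from .signatures import SurvivalCohort

DEFAULT_GENOME: dict[str, int] = dict(AUTOSOME_MB)  # chrom -> n 1-Mb bins


class SimEvent(NamedTuple):
    """A planted CNA: ``delta`` copies gained (+) or lost (-) over a bin span."""

    chrom: str
    start_bin: int  # chromosome-local, 0-based
    n_bins: int
    delta: int

    @property
    def end_bin(self) -> int:
        return self.start_bin + self.n_bins - 1

    def to_aberration(self, baseline: int = 2) -> Aberration:
        return Aberration(
            self.chrom, self.start_bin * MB, (self.end_bin + 1) * MB,
            baseline + self.delta,
        )


@dataclass
class SimulatedCloneTree:
    """Ground-truth clone tree: parents, per-branch events, baseline ploidy."""

    seed: int
    parents: dict[str, str | None]  # clone -> parent clone ("C0" is the root)
    branch_events: dict[str, tuple[SimEvent, ...]]
    baseline_ploidy: int = 2
    genome: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENOME))

    @property
    def clones(self) -> list[str]:
        return list(self.parents)

    def event_set(self, clone: str) -> frozenset[SimEvent]:
        """All events on the lineage from the root down to ``clone``."""
        events: set[SimEvent] = set()
        node: str | None = clone
        while node is not None:
            events.update(self.branch_events[node])
            node = self.parents[node]
        return frozenset(events)

    @property
    def stem_events(self) -> frozenset[SimEvent]:
        return frozenset(self.branch_events["C0"])

    @property
    def all_events(self) -> list[SimEvent]:
        return [e for clone in self.clones for e in self.branch_events[clone]]

    def carriers(self, event: SimEvent) -> frozenset[str]:
        return frozenset(c for c in self.clones if event in self.event_set(c))


def simulate_clone_tree(
    seed: int,
    n_clones: int = 4,
    events_per_branch: int = 2,
    genome_model: Mapping[str, int] | None = None,
    stem_wgd: bool = False,
    event_bins: tuple[int, int] = (8, 30),
    event_delta_choices: Sequence[int] = (1, 1, -1, 2),
    max_tries: int = 200,
) -> SimulatedCloneTree:
    """Random rooted clone tree with per-branch events.

    Clone C0 is the founder; every other clone attaches to a uniformly
    drawn existing clone. Each branch acquires ``events_per_branch``
    events whose spans never overlap any event already on the lineage
    (so per-bin copy states are well defined). ``stem_wgd`` doubles the
    baseline ploidy at the stem.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    genome = dict(genome_model) if genome_model is not None else dict(DEFAULT_GENOME)
    rng = np.random.default_rng(seed)
    chroms = list(genome)

    parents: dict[str, str | None] = {"C0": None}
    for k in range(1, n_clones):
        parents[f"C{k}"] = f"C{rng.integers(0, k)}"

    branch_events: dict[str, tuple[SimEvent, ...]] = {}

    def lineage_events(clone: str) -> list[SimEvent]:
        out = []
        node: str | None = clone
        while node is not None:
            out.extend(branch_events.get(node, ()))
            node = parents[node]
        return out

    for clone in parents:
        taken = lineage_events(clone)
        new: list[SimEvent] = []
        for _ in range(events_per_branch):
            for _attempt in range(max_tries):
                chrom = chroms[rng.integers(0, len(chroms))]
                lo, hi = event_bins
                n_bins = int(rng.integers(lo, min(hi, genome[chrom]) + 1))
                start = int(rng.integers(0, genome[chrom] - n_bins + 1))
                delta = int(event_delta_choices[
                    rng.integers(0, len(event_delta_choices))
                ])
                cand = SimEvent(chrom, start, n_bins, delta)
                clash = any(
                    e.chrom == chrom
                    and not (cand.end_bin < e.start_bin or cand.start_bin > e.end_bin)
                    for e in taken + new
                )
                if not clash:
                    new.append(cand)
                    break
            else:
                raise ValueError(
                    "could not place events without within-lineage overlap; "
                    "reduce events_per_branch or enlarge the genome model"
                )
        branch_events[clone] = tuple(new)

    return SimulatedCloneTree(
        seed=seed, parents=parents, branch_events=branch_events,
        baseline_ploidy=4 if stem_wgd else 2, genome=genome,
    )


def random_clone_frequencies(
    tree: SimulatedCloneTree, seed: int, concentration: float = 2.0
) -> dict[str, float]:
    """Dirichlet clone frequencies (disjoint, summing to 1)."""
    rng = np.random.default_rng(seed)
    f = rng.dirichlet([concentration] * len(tree.clones))
    return dict(zip(tree.clones, map(float, f)))


def sweep_frequencies(
    frequencies: Mapping[str, float], winner: str, strength: float
) -> dict[str, float]:
    """Rescale frequencies toward ``winner`` (a selective-sweep bottleneck).

    ``strength`` in [0, 1]: 0 leaves the mixture unchanged, 1 fixes the
    winning clone.
    """
    if winner not in frequencies:
        raise KeyError(winner)
    out = {c: f * (1 - strength) for c, f in frequencies.items()}
    out[winner] += strength
    return out


# ---------------------------------------------------------------------------
# Bulk segments

def _allelic_composition(delta: int) -> tuple[int, int]:
    """(n_minor, n_major) in aberrant cells for a copy change of ``delta``.

    Gains add copies of one (the major) allele; a single-copy loss removes
    one allele entirely.
    """
    if delta >= 1:
        return 1, 1 + delta
    if delta == -1:
        return 0, 1
    raise ValueError(f"unsupported copy change {delta} for bulk simulation")


def simulate_bulk_segments(
    tree: SimulatedCloneTree,
    clone_freqs: Mapping[str, float],
    purity: float,
    sigma_log2r: float = 0.02,
    sigma_baf: float = 0.01,
    seed: int = 0,
    sample_id: str = "S1",
    markers_per_mb: float = 60.0,
    fail_filter_fraction: float = 0.0,
) -> tuple[list[AllelicSegment], pd.DataFrame]:
    """Noisy allele-specific segments from a clone mixture at known purity.

    Each planted event becomes one segment whose true MSF is
    purity * (summed frequency of the carrying clones); log2R and mBAF
    follow the forward mixture models plus Gaussian noise (mBAF noise is
    mirrored back into [0.5, 1]). A ``fail_filter_fraction`` of extra
    decoy segments is planted below the curation filter (short span or
    low marker count). Returns the segments and a per-segment truth table.
    """
    total = sum(clone_freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("clone frequencies must sum to 1")
    if tree.baseline_ploidy != 2:
        raise ValueError("bulk segment simulation assumes a diploid background")
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    segments: list[AllelicSegment] = []
    truth_rows = []
    np_bg = tree.baseline_ploidy

    def emit(event: SimEvent, msf_true: float, below_filter: bool) -> None:
        n_minor, n_major = _allelic_composition(event.delta)
        n_total = np_bg + event.delta
        start = event.start_bin * MB + 1
        end = (event.end_bin + 1) * MB
        markers = max(1, int(round((end - start + 1) / MB * markers_per_mb)))
        if below_filter:
            if rng.random() < 0.5:
                end = start + int(rng.integers(5_000, 45_000))  # < 50 kbp
            markers = int(rng.integers(5, 50))
        log2r = forward_log2r(msf_true, n_total, np_bg) + rng.normal(0, sigma_log2r)
        mbaf_clean = forward_mbaf(msf_true, n_minor, n_major)
        mbaf = mbaf_clean + rng.normal(0, sigma_baf)
        mbaf = min(1.0, 0.5 + abs(mbaf - 0.5))  # mirror into [0.5, 1]
        kind = "gain" if event.delta > 0 else "loss"
        segments.append(AllelicSegment(
            sample_id=sample_id, chrom=event.chrom, start=start, end=end,
            kind=kind, log2r=log2r, mbaf=mbaf, n_minor=n_minor,
            n_major=n_major, marker_count=markers, background_ploidy=np_bg,
        ))
        truth_rows.append({
            "sample_id": sample_id, "chrom": event.chrom, "start": start,
            "end": end, "msf_true": msf_true, "delta": event.delta,
            "below_filter": below_filter,
        })

    events = tree.all_events
    for event in events:
        msf_true = purity * sum(
            clone_freqs.get(c, 0.0) for c in tree.carriers(event)
        )
        if msf_true <= 0:
            continue
        emit(event, msf_true, below_filter=False)
    n_decoys = int(round(fail_filter_fraction * len(events)))
    for _ in range(n_decoys):
        event = events[rng.integers(0, len(events))]
        msf_true = purity * sum(
            clone_freqs.get(c, 0.0) for c in tree.carriers(event)
        )
        emit(event, msf_true, below_filter=True)
    return segments, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Single-cell matrices

def _bin_grid_for(genome: Mapping[str, int]) -> list[tuple[str, int, int]]:
    return [
        (chrom, i * MB, (i + 1) * MB)
        for chrom in genome
        for i in range(genome[chrom])
    ]


def simulate_cell_matrix(
    tree: SimulatedCloneTree,
    n_cells: int,
    clone_mixture: Mapping[str, float],
    flip_noise: float = 0.01,
    seed: int = 0,
) -> tuple[CellBinMatrix, CloneAssignment]:
    """Single-cell copy-state matrix drawn from a clone mixture.

    Cells are assigned to clones by the mixture; each cell's per-bin copy
    state is the clone's lineage profile, then each (bin, cell) entry is
    independently perturbed by +/-1 with probability ``flip_noise``
    (clipped at 0). Returns the matrix and the ground-truth assignment
    (with the true per-clone event sets expressed as curated CNA events).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if abs(sum(clone_mixture.values()) - 1.0) > 1e-6:
        raise ValueError("clone mixture must sum to 1")
    rng = np.random.default_rng(seed)
    bins = _bin_grid_for(tree.genome)
    chrom_offset: dict[str, int] = {}
    off = 0
    for chrom, n in tree.genome.items():
        chrom_offset[chrom] = off
        off += n
    n_bins = off

    clone_names = list(clone_mixture)
    probs = np.array([clone_mixture[c] for c in clone_names])
    draws = rng.choice(len(clone_names), size=n_cells, p=probs)
    cells = [f"cell{i + 1:03d}" for i in range(n_cells)]

    profiles: dict[str, np.ndarray] = {}
    for clone in clone_names:
        prof = np.full(n_bins, tree.baseline_ploidy, dtype=int)
        for e in tree.event_set(clone):
            o = chrom_offset[e.chrom]
            prof[o + e.start_bin: o + e.end_bin + 1] += e.delta
        profiles[clone] = np.clip(prof, 0, None)

    mat = np.stack([profiles[clone_names[d]] for d in draws], axis=1)
    if flip_noise > 0:
        flips = rng.random(mat.shape) < flip_noise
        signs = rng.choice([-1, 1], size=mat.shape)
        mat = np.clip(mat + flips * signs, 0, None)

    matrix = CellBinMatrix(bins, cells, mat, tree.baseline_ploidy)

    def clone_events(clone: str) -> frozenset[CNAEvent]:
        out = []
        for e in tree.event_set(clone):
            o = chrom_offset[e.chrom]
            state = tree.baseline_ploidy + e.delta
            direction = "gain" if e.delta > 0 else "loss"
            grade = ("high_grade_amplification" if state >= tree.baseline_ploidy + 3
                     else "imbalance")
            out.append(CNAEvent(e.chrom, o + e.start_bin, o + e.end_bin,
                                direction, state, grade))
        return frozenset(out)

    by_clone: dict[str, list[str]] = {}
    for cell, d in zip(cells, draws):
        by_clone.setdefault(clone_names[d], []).append(cell)
    cell_to_clone = {}
    events_map = {}
    sizes = {}
    for clone, members in by_clone.items():
        label = "baseline" if not tree.event_set(clone) else clone
        events_map[label] = clone_events(clone)
        sizes[label] = len(members)
        for cell in members:
            cell_to_clone[cell] = label
    truth = CloneAssignment(cell_to_clone, events_map, sizes)
    return matrix, truth


# ---------------------------------------------------------------------------
# Expression + survival

#: Mean score gap between the > median and <= median halves of a standard
#: normal score: 2 * E[Z | Z > 0] = 2 * sqrt(2/pi).
_HALVES_GAP = 2.0 * math.sqrt(2.0 / math.pi)


def beta_for_halves_hazard_ratio(hazard_ratio: float) -> float:
    """Log-hazard slope giving ``hazard_ratio`` between score halves.

    Under hazard exp(beta * score) with a standard-normal score, the
    average hazard ratio between the above-median and below-median halves
    is exp(beta * 2*sqrt(2/pi)).
    """
    return math.log(hazard_ratio) / _HALVES_GAP


def simulate_expression_cohort(
    seed: int,
    n_genes: int = 500,
    n_samples: int = 20,
    n_patients: int = 300,
    n_signature_genes: int = 20,
    group_shift: float = 1.0,
    beta: float = 0.0,
    gene_loading_sd: float = 0.4,
    censoring_rate: float = 0.3,
    baseline_hazard: float = 1.0 / 1000.0,
) -> dict:
    """Expression matrix with a planted group signature + a linked survival cohort.

    The expression matrix holds two equal sample groups (A/B); signature
    genes are shifted by ``group_shift`` in group B. The survival cohort
    draws a latent per-patient score s ~ N(0, 1); signature genes load on
    s (plus N(0, gene_loading_sd) noise), other genes are independent
    N(0, 1), and survival times are exponential with hazard
    baseline_hazard * exp(beta * s). Censoring is exponential with rate
    chosen so that roughly ``censoring_rate`` of patients are censored at
    beta = 0.

    Returns a dict with keys ``expression``, ``groups``, ``cohort`` and
    ``truth`` (signature genes, beta, group shift).
    """
    if n_signature_genes > n_genes:
        raise ValueError("signature cannot exceed the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    signature_genes = sorted(
        rng.choice(n_genes, size=n_signature_genes, replace=False)
    )
    signature_genes = [genes[i] for i in signature_genes]
    sig_mask = np.isin(genes, signature_genes)

    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    groups = pd.Series(
        ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2),
        index=samples, name="group",
    )
    gene_means = rng.normal(0, 1, size=n_genes)
    expr = rng.normal(0, 1, size=(n_genes, n_samples)) + gene_means[:, None]
    expr[np.ix_(sig_mask, (groups == "B").to_numpy())] += group_shift
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    score = rng.normal(0, 1, size=n_patients)
    pexpr = rng.normal(0, 1, size=(n_genes, n_patients)) + gene_means[:, None]
    pexpr[sig_mask] = (
        gene_means[sig_mask][:, None]
        + score[None, :]
        + rng.normal(0, gene_loading_sd, size=(sig_mask.sum(), n_patients))
    )
    hazard = baseline_hazard * np.exp(beta * score)
    t_event = rng.exponential(1.0 / hazard)
    if censoring_rate > 0:
        c_rate = baseline_hazard * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=n_patients)
    else:
        t_cens = np.full(n_patients, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)
    patients = [f"P{i + 1:04d}" for i in range(n_patients)]
    cohort = SurvivalCohort(
        time, event, pd.DataFrame(pexpr, index=genes, columns=patients)
    )
    return {
        "expression": expression,
        "groups": groups,
        "cohort": cohort,
        "score": score,
        "truth": {
            "signature_genes": signature_genes,
            "beta": beta,
            "group_shift": group_shift,
        },
    }


# ---------------------------------------------------------------------------
# Volume trajectories

ARCHETYPES = (
    "PD", "SD", "PR", "CR", "CR_relapse", "surgery_cured", "surgery_relapse",
)

#: Expected (response class, relapse flag) per archetype under default
#: thresholds, used by recovery experiments.
ARCHETYPE_EXPECTATION = {
    "PD": ("PD", False),
    "SD": ("SD", False),
    "PR": ("PR", False),
    "CR": ("CR", False),
    "CR_relapse": ("CR", True),
    "surgery_cured": ("MCR", False),
    "surgery_relapse": ("MCR", True),
}


def _trajectory(archetype: str, days: np.ndarray, v0: float):
    """Noise-free volume trajectory and surgery day for one archetype."""
    v = np.empty_like(days, dtype=float)
    surgery_day = None
    if archetype == "PD":
        v = v0 * np.exp(0.02 * days)
    elif archetype == "SD":
        v = np.full(days.shape, v0, dtype=float)
    elif archetype == "PR":
        rate = math.log(0.35) / 42.0
        v = v0 * np.exp(rate * np.minimum(days, 42))
    elif archetype == "CR":
        nadir_day, nadir = 28.0, 60.0
        down = math.log(nadir / v0) / nadir_day
        up = math.log(150.0 / nadir) / (42.0 - nadir_day)
        v = np.where(
            days <= nadir_day,
            v0 * np.exp(down * days),
            np.where(days <= 42, nadir * np.exp(up * (days - nadir_day)), 160.0),
        )
    elif archetype == "CR_relapse":
        nadir_day, nadir = 30.0, 40.0
        down = math.log(nadir / v0) / nadir_day
        v = np.where(
            days <= nadir_day,
            v0 * np.exp(down * days),
            np.minimum(nadir * np.exp(0.15 * (days - nadir_day)), 900.0),
        )
    elif archetype in ("surgery_cured", "surgery_relapse"):
        resect, target = 25.0, 200.0
        down = math.log(target / v0) / resect
        surgery_day = int(resect)
        v = np.where(days <= resect, v0 * np.exp(down * days), 0.0)
        if archetype == "surgery_relapse":
            regrow = 20.0 * np.exp(0.15 * (days - 50.0))
            v = np.where(days > 50, np.minimum(regrow, 900.0), v)
    else:
        raise ValueError(f"unknown archetype {archetype!r}")
    return v, surgery_day


def simulate_volume_series(
    seed: int,
    archetype: str,
    noise: float = 0.05,
    mouse_id: str = "m1",
    group: str = "sim",
    v0: float = 500.0,
    window: tuple[int, int] = (0, 42),
    every: int = 3,
    last_day: int = 69,
) -> tuple[VolumeSeries, dict]:
    """One mouse's volume trajectory for a response archetype.

    Piecewise-exponential growth/regression shapes with multiplicative
    log-normal noise (sd ``noise`` on the log scale). The truth record
    carries the archetype and its expected response call.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    rng = np.random.default_rng(seed)
    days = np.arange(0, last_day + 1, every)
    clean, surgery_day = _trajectory(archetype, days.astype(float), v0)
    noisy = clean * np.exp(rng.normal(0, noise, size=clean.shape))
    noisy = np.where(clean == 0.0, 0.0, noisy)
    series = VolumeSeries(
        mouse_id=mouse_id, group=group, days=[int(d) for d in days],
        volumes=[float(v) for v in noisy], window=window,
        surgery_day=surgery_day,
    )
    expected_response, expected_relapse = ARCHETYPE_EXPECTATION[archetype]
    truth = {
        "archetype": archetype,
        "expected_response": expected_response,
        "expected_relapse": expected_relapse,
    }
    return series, truth


def simulate_volume_group(
    seed: int,
    archetype_counts: Mapping[str, int],
    group: str,
    noise: float = 0.05,
) -> tuple[list[VolumeSeries], list[dict]]:
    """A treatment group assembled from per-archetype mouse counts."""
    series, truths = [], []
    i = 0
    for archetype in sorted(archetype_counts):
        for _ in range(archetype_counts[archetype]):
            i += 1
            s, t = simulate_volume_series(
                seed + i, archetype, noise=noise,
                mouse_id=f"{group}-m{i:02d}", group=group,
            )
            series.append(s)
            truths.append(t)
    return series, truths


# ---------------------------------------------------------------------------
# Clone-frequency tables from a simulated tree

def clone_frequency_table(
    tree: SimulatedCloneTree,
    frequencies: Mapping[str, float],
    tumor_id: str,
    time: int = 0,
) -> CloneFrequencyTable:
    """Package simulated clone frequencies as a diversity-module table."""
    events = {
        c: frozenset(e.to_aberration(tree.baseline_ploidy)
                     for e in tree.event_set(c))
        for c in frequencies
    }
    stem = frozenset(
        e.to_aberration(tree.baseline_ploidy) for e in tree.stem_events
    )
    return CloneFrequencyTable(
        tumor_id=tumor_id, time=time,
        frequencies=dict(frequencies), clone_events=events, stem=stem,
    )
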