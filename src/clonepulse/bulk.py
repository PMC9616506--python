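"""Allele-specific bulk clonality: MSF, TCF and MCF estimation.

A curated copy-number segment in one tumor sample carries two measurements
from the SNP array: the log2 median probe-intensity ratio (log2R) and the
mirrored B-allele frequency (mBAF), together with the inferred allelic
composition of the aberrant cells (N_A minor copies, N_B major copies,
total ploidy N_t) on a background of N_p copies (2 for diploid stroma).

Inverting the two-population mixture model gives the mutated sample
fraction (MSF), the fraction of all cells in the sample carrying the
aberration:

    MSF = (N_p * 2**log2R - N_p) / (N_t - N_p)                (intensity)
    MSF = (1 - 2*mBAF) / (mBAF * (N_A + N_B - 2) - N_B + 1)   (allelic)

The purity, or tumor cell fraction (TCF), is the mean MSF of the
aberrations designated clonal; the mutated clone fraction (MCF) is
MSF / TCF, set to exactly 1 when the MSF falls inside the interval of
clonal events TCF +/- 2*SD_MSF.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Absolute tolerance outside [0, 1] within which MSF values are clamped
#: rather than flagged as out of range.
CLAMP_TOL = 0.05

SegmentKind = Literal["gain", "loss", "cnni", "high_grade_amplification"]


class NonIdentifiableError(ValueError):
    """The measurement carries no information about the mixture fraction."""


@dataclass
class AllelicSegment:
    """One curated copy-number aberration in one sample (1-based inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    kind: SegmentKind
    log2r: float
    mbaf: float | None
    n_minor: int
    n_major: int
    marker_count: int
    background_ploidy: int = 2

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end < start for segment {self.sample_id}:{self.chrom}")
        if self.background_ploidy < 1:
            raise ValueError("background_ploidy must be >= 1")
        if self.n_minor < 0 or self.n_major < 0:
            raise ValueError("allele copy numbers must be non-negative")
        if self.n_minor > self.n_major:
            logger.warning(
                "segment %s:%s:%d-%d has n_minor > n_major; swapping to the "
                "major-allele orientation", self.sample_id, self.chrom,
                self.start, self.end,
            )
            self.n_minor, self.n_major = self.n_major, self.n_minor
        if self.mbaf is not None and not (0.5 <= self.mbaf <= 1.0):
            raise ValueError(f"mbaf {self.mbaf} outside [0.5, 1]")
        if self.kind == "cnni" and self.n_minor + self.n_major != self.background_ploidy:
            raise ValueError("cnni segments must be copy-neutral (N_A + N_B = N_p)")

    @property
    def n_total(self) -> int:
        """Total ploidy N_t of the alteration in aberrant cells."""
        return self.n_minor + self.n_major

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PurityEstimate:
    """Tumor cell fraction with the interval of clonal events on the MSF scale."""

    sample_id: str
    tcf: float
    sd_msf: float
    clonal_msf_interval: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.clonal_msf_interval
        if lo > hi or not (lo <= self.tcf <= hi):
            raise ValueError("TCF must lie inside an ordered clonal interval")


@dataclass(frozen=True)
class ClonalityCall:
    segment: AllelicSegment
    msf: float
    mcf: float
    status: Literal["clonal", "subclonal"]
    out_of_range: bool = False


def filter_segments(
    segments: Sequence[AllelicSegment],
    min_length_bp: int = 50_000,
    min_markers: int = 50,
) -> list[AllelicSegment]:
    """Apply the curation inclusion filter: >=50 kbp and >=50 markers.

    Both boundaries are inclusive; input order is preserved.
    """
    return [
        s for s in segments
        if s.length >= min_length_bp and s.marker_count >= min_markers
    ]


def _finish_msf(raw: float, tol: float, with_flag: bool):
    out_of_range = not (-tol <= raw <= 1.0 + tol)
    value = raw if out_of_range else min(1.0, max(0.0, raw))
    if with_flag:
        return value, out_of_range
    return value


def msf_from_log2r(
    log2r: float,
    n_total: int,
    background_ploidy: int = 2,
    *,
    tol: float = CLAMP_TOL,
    with_flag: bool = False,
) -> float | tuple[float, bool]:
    """MSF from the probe-intensity ratio: (N_p * 2**log2R - N_p) / (N_t - N_p).

    Values within ``tol`` of [0, 1] are clamped into the unit interval;
    values beyond the tolerance band are returned unclamped (flagged when
    ``with_flag`` is set), signalling a mis-specified allelic composition
    rather than measurement noise.

    Raises :class:`NonIdentifiableError` for copy-neutral events
    (N_t = N_p), whose intensity ratio is flat; use :func:`msf_from_mbaf`.
    """
    if n_total == background_ploidy:
        raise NonIdentifiableError(
            "copy-neutral event: MSF is not identifiable from log2R "
            "(use msf_from_mbaf)"
        )
    raw = (background_ploidy * 2.0 ** log2r - background_ploidy) / (
        n_total - background_ploidy
    )
    return _finish_msf(raw, tol, with_flag)


def msf_from_mbaf(
    mbaf: float,
    n_minor: int,
    n_major: int,
    *,
    tol: float = CLAMP_TOL,
    with_flag: bool = False,
) -> float | tuple[float, bool]:
    """MSF from the mirrored B-allele frequency.

        MSF = (1 - 2*mBAF) / (mBAF * (N_A + N_B - 2) - N_B + 1)

    N_B is the major allele in aberrant cells (N_A <= N_B; arguments are
    swapped with a warning otherwise), and mBAF is the frequency of that
    allele mirrored into [0.5, 1]. With this orientation the formula is
    the exact inverse of the diploid-background allele-mixture model.
    """
    if not (0.5 <= mbaf <= 1.0):
        raise ValueError(f"mbaf {mbaf} outside [0.5, 1]")
    if n_minor > n_major:
        logger.warning("n_minor > n_major; swapping to major-allele orientation")
        n_minor, n_major = n_major, n_minor
    if n_minor == n_major:
        raise NonIdentifiableError(
            "allelically balanced genotype: mBAF stays 0.5 at any mixture fraction"
        )
    denom = mbaf * (n_minor + n_major - 2) - n_major + 1
    if denom == 0.0:
        raise NonIdentifiableError("degenerate mBAF denominator")
    raw = (1.0 - 2.0 * mbaf) / denom
    return _finish_msf(raw, tol, with_flag)


def forward_log2r(msf: float, n_total: int, background_ploidy: int = 2) -> float:
    """Noise-free forward mixture model inverted by :func:`msf_from_log2r`."""
    mean_copy = msf * n_total + (1.0 - msf) * background_ploidy
    return math.log2(mean_copy / background_ploidy)


def forward_mbaf(msf: float, n_minor: int, n_major: int) -> float:
    """Noise-free major-allele frequency of an msf mixture on diploid background."""
    num = msf * n_major + (1.0 - msf) * 1.0
    den = msf * (n_minor + n_major) + (1.0 - msf) * 2.0
    return num / den


def estimate_tcf(clonal_msfs: Sequence[float], sample_id: str) -> PurityEstimate:
    """Purity = mean of the clonal MSF values; interval = TCF +/- 2*SD_MSF.

    The standard deviation is the sample SD (ddof=1), zero for a single
    value. The interval of clonal events is expressed on the MSF scale;
    dividing both bounds by TCF gives the equivalent MCF-scale interval.
    """
    if len(clonal_msfs) == 0:
        raise ValueError("at least one clonal MSF value is required")
    arr = np.asarray(clonal_msfs, dtype=float)
    tcf = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return PurityEstimate(
        sample_id=sample_id,
        tcf=tcf,
        sd_msf=sd,
        clonal_msf_interval=(tcf - 2.0 * sd, tcf + 2.0 * sd),
    )


def designate_clonal_auto(msfs: Sequence[float], window: float = 0.1) -> list[int]:
    """Automated proxy for the manual clonal designation.

    Returns indices of the densest cluster of MSF values inside a
    ``window``-wide interval that contains the maximum MSF. Ties between
    equally dense windows are broken toward the window closest to the
    maximum.
    """
    if len(msfs) == 0:
        raise ValueError("no MSF values to designate")
    arr = np.asarray(msfs, dtype=float)
    top = float(arr.max())
    starts = sorted({float(v) for v in arr if v >= top - window} | {top - window})
    best: list[int] | None = None
    best_key = (-1, -np.inf)
    for lo in starts:
        if lo + window < top:
            continue
        members = [i for i, v in enumerate(arr) if lo <= v <= lo + window]
        key = (len(members), lo)
        if key > best_key:
            best_key = key
            best = members
    assert best is not None
    return best


def classify_clonality(
    segment: AllelicSegment,
    msf: float,
    purity: PurityEstimate,
    *,
    out_of_range: bool = False,
) -> ClonalityCall:
    """Clonal if MSF falls inside the interval of clonal events (bounds
    inclusive), in which case MCF is set to exactly 1; otherwise subclonal
    with MCF = MSF / TCF clamped into [0, 1]."""
    if purity.tcf <= 0:
        raise ValueError("purity must be positive")
    lo, hi = purity.clonal_msf_interval
    if lo <= msf <= hi:
        return ClonalityCall(segment, msf, 1.0, "clonal", out_of_range)
    mcf = min(1.0, max(0.0, msf / purity.tcf))
    return ClonalityCall(segment, msf, mcf, "subclonal", out_of_range)


def segment_msf(segment: AllelicSegment, *, tol: float = CLAMP_TOL) -> tuple[float, bool]:
    """MSF for a segment, routed by kind.

    Copy-neutral imbalances use mBAF; everything else uses log2R (falling
    back to mBAF if the composition is copy-neutral relative to background).
    """
    if segment.kind == "cnni" or segment.n_total == segment.background_ploidy:
        if segment.mbaf is None:
            raise NonIdentifiableError(
                f"copy-neutral segment {segment.chrom}:{segment.start} without mBAF"
            )
        return msf_from_mbaf(
            segment.mbaf, segment.n_minor, segment.n_major, tol=tol, with_flag=True
        )
    return msf_from_log2r(
        segment.log2r, segment.n_total, segment.background_ploidy,
        tol=tol, with_flag=True,
    )


# ---------------------------------------------------------------------------
# Pipeline + tabular I/O

SEGMENT_COLUMNS = [
    "sample_id", "chrom", "start", "end", "kind", "log2r", "mbaf",
    "n_minor", "n_major", "background_ploidy", "marker_count",
]


def read_segments_tsv(path) -> list[AllelicSegment]:
    df = pd.read_csv(path, sep="\t")
    segments = []
    for row in df.itertuples(index=False):
        mbaf = getattr(row, "mbaf", None)
        if mbaf is not None and pd.isna(mbaf):
            mbaf = None
        segments.append(AllelicSegment(
            sample_id=str(row.sample_id), chrom=str(row.chrom),
            start=int(row.start), end=int(row.end), kind=str(row.kind),
            log2r=float(row.log2r), mbaf=mbaf,
            n_minor=int(row.n_minor), n_major=int(row.n_major),
            marker_count=int(row.marker_count),
            background_ploidy=int(getattr(row, "background_ploidy", 2)),
        ))
    return segments


def calls_to_frame(calls: Sequence[ClonalityCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        s = c.segment
        rows.append({
            "sample_id": s.sample_id, "chrom": s.chrom, "start": s.start,
            "end": s.end, "kind": s.kind, "log2r": s.log2r, "mbaf": s.mbaf,
            "n_minor": s.n_minor, "n_major": s.n_major,
            "background_ploidy": s.background_ploidy,
            "marker_count": s.marker_count,
            "msf": c.msf, "mcf": c.mcf, "status": c.status,
        })
    return pd.DataFrame(rows)


def call_sample(
    segments: Sequence[AllelicSegment],
    clonal_designation: Sequence[bool] | None = None,
    *,
    min_length_bp: int = 50_000,
    min_markers: int = 50,
) -> tuple[list[ClonalityCall], PurityEstimate]:
    """End-to-end clonality calling for one sample.

    Filters segments, computes MSF per segment, estimates purity from the
    designated clonal aberrations (an explicit boolean mask aligned with
    the *filtered* segments, or the automated densest-cluster proxy when
    absent), then classifies every aberration as clonal or subclonal.
    """
    kept = filter_segments(segments, min_length_bp, min_markers)
    if not kept:
        raise ValueError("no segments pass the curation filter")
    sample_ids = {s.sample_id for s in kept}
    if len(sample_ids) != 1:
        raise ValueError("call_sample expects segments from a single sample")
    msfs, flags = zip(*(segment_msf(s) for s in kept))
    if clonal_designation is None:
        clonal_idx = designate_clonal_auto(msfs)
    else:
        if len(clonal_designation) != len(kept):
            raise ValueError("clonal designation length mismatch after filtering")
        clonal_idx = [i for i, d in enumerate(clonal_designation) if d]
    purity = estimate_tcf([msfs[i] for i in clonal_idx], sample_ids.pop())
    calls = [
        classify_clonality(s, m, purity, out_of_range=f)
        for s, m, f in zip(kept, msfs, flags)
    ]
    return calls, purity
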