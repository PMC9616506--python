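"""Gene-signature scoring and survival-filtered signature integration.

A signature is a directional gene set (e.g. adrenergic vs mesenchymal-like
neuroblastoma cell states). Samples are scored by the average z score over
the signature's genes; candidate merged signatures are built as provenance
-tracked unions of published gene sets; and an integrated signature keeps
only the genes whose expression splits a patient cohort into different
overall-survival arms (median cut, log-rank test) at FDR < 0.05.

The Kaplan-Meier/log-rank machinery is implemented from its standard
definition so the whole filtering chain is self-contained and can be
checked against permutation and external oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class DegenerateSplitError(ValueError):
    """Median split produced an arm with fewer than two patients."""


@dataclass
class GeneSignature:
    """A named gene set with per-gene provenance (contributing source lists)."""

    name: str
    genes: dict[str, list[str]]  # gene -> provenance tags
    prognosis: Literal["favorable", "adverse", None] = None
    dropped: dict[str, str] = field(default_factory=dict)  # gene -> reason

    @property
    def members(self) -> list[str]:
        return list(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_genes(cls, name: str, genes: Sequence[str],
                   prognosis=None) -> "GeneSignature":
        return cls(name, {g: [name] for g in dict.fromkeys(genes)}, prognosis)


@dataclass
class SurvivalCohort:
    """Patients with follow-up time (days), death indicator and expression."""

    time: np.ndarray
    event: np.ndarray
    expression: pd.DataFrame  # genes x patients, variance-stabilized scale

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if (self.time <= 0).any():
            raise ValueError("follow-up times must be positive")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if self.expression.shape[1] != len(self.time):
            raise ValueError("expression columns must match patients")

    @property
    def n_patients(self) -> int:
        return len(self.time)


def zscore_matrix(expr: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Standardize each gene (row) to mean 0, sd 1 across samples.

    Constant genes come out as NaN rows; callers drop them with a warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("z scores need at least two samples")
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=ddof)
    return expr.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)


def zscore_signature_score(
    expr: pd.DataFrame, signature: GeneSignature
) -> tuple[pd.Series, int]:
    """Average z score over the signature's genes, per sample.

    Returns the per-sample score and the number of signature genes
    actually used (present in the matrix and non-constant).
    """
    present = [g for g in signature.members if g in expr.index]
    if not present:
        raise ValueError(
            f"signature {signature.name!r} shares no genes with the matrix"
        )
    z = zscore_matrix(expr.loc[present])
    constant = z.index[z.isna().all(axis=1)]
    if len(constant):
        logger.warning(
            "dropping %d constant gene(s) from signature %s",
            len(constant), signature.name,
        )
        z = z.drop(index=constant)
    if z.empty:
        raise ValueError("all signature genes are constant in the matrix")
    return z.mean(axis=0), int(z.shape[0])


def top_variable_genes(expr: pd.DataFrame, n: int = 1000) -> list[str]:
    """The n genes with the largest expression variance across samples.

    Sample variance (ddof=1), descending; ties broken toward the
    lexicographically smaller gene identifier. Saturates with a warning
    when the matrix has fewer than n genes.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if expr.empty:
        raise ValueError("empty expression matrix")
    var = expr.var(axis=1, ddof=1)
    ranked = sorted(var.index, key=lambda g: (-var[g], g))
    if n > len(ranked):
        logger.warning("requested %d genes but matrix has only %d", n, len(ranked))
        return ranked
    return ranked[:n]


def merge_signatures(
    sources: Sequence[GeneSignature],
    opposing: Sequence[GeneSignature] | None = None,
    name: str | None = None,
) -> GeneSignature:
    """Union of source gene sets with provenance tracking.

    A gene also present in the opposing side is assigned to whichever
    side has more supporting source lists; ties are dropped from both
    (recorded in ``dropped`` and logged).
    """
    if not sources:
        raise ValueError("at least one source signature is required")
    merged: dict[str, list[str]] = {}
    for sig in sources:
        for gene, tags in sig.genes.items():
            merged.setdefault(gene, []).extend(tags)
    result = GeneSignature(
        name or "+".join(s.name for s in sources),
        merged,
        prognosis=sources[0].prognosis,
    )
    if opposing:
        counts_opp: dict[str, int] = {}
        for sig in opposing:
            for gene, tags in sig.genes.items():
                counts_opp[gene] = counts_opp.get(gene, 0) + len(tags)
        for gene in list(result.genes):
            n_here = len(result.genes[gene])
            n_there = counts_opp.get(gene, 0)
            if n_there == 0:
                continue
            if n_here > n_there:
                continue
            if n_here == n_there:
                reason = f"tie: {n_here} sources on each side"
            else:
                reason = f"majority opposing: {n_here} vs {n_there}"
            logger.info("dropping %s from %s (%s)", gene, result.name, reason)
            result.dropped[gene] = reason
            del result.genes[gene]
    return result


def logrank_median_split(
    time: np.ndarray,
    event: np.ndarray,
    values: np.ndarray,
    tie_arm: Literal["low", "high"] = "low",
) -> tuple[float, float, str]:
    """Two-sample log-rank test after splitting patients at the median.

    Patients with value > median form the high arm; ties at the median go
    to the low arm (the common "median cut" convention; flip with
    ``tie_arm="high"``). Returns the 1-df chi-square statistic, its
    p-value and which arm fares worse ("high_worse" when the high arm has
    more deaths than expected, "low_worse" otherwise, "none" at exact
    balance).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    high = values > med if tie_arm == "low" else values >= med
    if high.sum() < 2 or (~high).sum() < 2:
        raise DegenerateSplitError(
            f"median split left arms of size {int(high.sum())} and "
            f"{int((~high).sum())}"
        )
    death_times = np.unique(time[event == 1])
    observed = 0.0
    expected = 0.0
    variance = 0.0
    for t in death_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & high).sum()
        deaths = ((time == t) & (event == 1))
        d = deaths.sum()
        d1 = (deaths & high).sum()
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0, 1.0, "none"
    statistic = (observed - expected) ** 2 / variance
    p = float(stats.chi2.sf(statistic, df=1))
    if observed > expected:
        direction = "high_worse"
    elif observed < expected:
        direction = "low_worse"
    else:
        direction = "none"
    return float(statistic), p, direction


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, input order preserved."""
    arr = np.asarray(pvalues, dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def integrate_signature(
    signature: GeneSignature,
    cohort: SurvivalCohort,
    fdr_threshold: float = 0.05,
    direction_filter: bool = True,
) -> tuple[GeneSignature, pd.DataFrame]:
    """Filter a signature's genes by overall-survival association.

    Each gene is tested by a median-cut log-rank test on its expression in
    the cohort; p-values are BH-adjusted across the signature's genes and
    genes with q < ``fdr_threshold`` are retained. When
    ``direction_filter`` is on and the signature declares a prognosis,
    only genes whose worse-survival arm matches it are kept (a
    "favorable" signature expects high expression in longer survivors,
    i.e. the low arm fares worse).
    """
    present = [g for g in signature.members if g in cohort.expression.index]
    if not present:
        raise ValueError("signature shares no genes with the cohort")
    rows = []
    for gene in present:
        values = cohort.expression.loc[gene].to_numpy()
        try:
            statistic, p, direction = logrank_median_split(
                cohort.time, cohort.event, values
            )
        except DegenerateSplitError:
            statistic, p, direction = 0.0, 1.0, "none"
        rows.append({"gene": gene, "statistic": statistic, "p": p,
                     "direction": direction})
    result = pd.DataFrame(rows).set_index("gene")
    result["q"] = bh_fdr(result["p"].to_numpy())
    retained = result["q"] < fdr_threshold
    if direction_filter and signature.prognosis is not None:
        wanted = "low_worse" if signature.prognosis == "favorable" else "high_worse"
        retained &= result["direction"] == wanted
    result["retained"] = retained
    filtered = GeneSignature(
        name=f"integrated_{signature.name}",
        genes={g: signature.genes[g] for g in result.index[retained]},
        prognosis=signature.prognosis,
    )
    return filtered, result


# ---------------------------------------------------------------------------
# Tabular I/O

def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_cohort_tsv(path) -> SurvivalCohort:
    """TSV with columns patient, time_days, event, then one column per gene."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    expr = df.drop(columns=["time_days", "event"]).T
    return SurvivalCohort(df["time_days"].to_numpy(), df["event"].to_numpy(), expr)


def signature_to_frame(sig: GeneSignature) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": g, "sources": ";".join(tags)} for g, tags in sig.genes.items()]
    )
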