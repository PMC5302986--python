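"""Inverse-correlation inference of predicted functional miRNA targets.

The screen couples two expression readouts across a small panel of cell-line
conditions (one parental line plus several derived resistant lines): miRNA
abundance measured as qPCR Cp, and gene expression as log2 microarray values.
Replicates are first summarized to one value per condition.  Because Cp is
inversely proportional to template abundance while a repressing miRNA is
expected to vary inversely with its targets, the Pearson correlation between
a miRNA's Cp profile and a target's expression profile is *positive* for a
genuine repressive edge; correlations are therefore negated so that strong
inverse regulation appears as r close to -1.

A miRNA-gene pair becomes a predicted functional target when its negated
correlation passes a threshold (default r <= -0.8) AND the pair is supported
by a minimum number of independent computational target predictors (default
>= 2 of 6).  With only four condition means, r <= -0.8 is a screening
heuristic, not a calibrated significance test; the module refuses to
correlate fewer than three conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConditionMeans",
    "CorrelationMatrix",
    "FunctionalTargetSet",
    "condition_means",
    "correlate",
    "prediction_support",
    "infer_functional_targets",
    "regulation_coverage",
]

DEFAULT_R_THRESHOLD = -0.8
DEFAULT_MIN_SUPPORT = 2


@dataclass
class ConditionMeans:
    """Feature x condition matrix of replicate means.

    ``incomplete`` lists features missing (too few detected replicates) in at
    least one condition; they are excluded from correlation.
    """

    values: pd.DataFrame
    incomplete: list[str] = field(default_factory=list)

    @property
    def complete(self) -> pd.DataFrame:
        return self.values.drop(index=self.incomplete)


def condition_means(
    values: pd.DataFrame,
    condition_map: dict[str, str],
    min_detected: int = 2,
) -> ConditionMeans:
    """Average replicates to one value per (feature, condition).

    A (feature, condition) mean over fewer than ``min_detected`` detected
    replicates is treated as missing, and the feature is flagged incomplete.
    Conditions with zero mapped samples raise an error.
    """
    conditions = sorted(set(condition_map.values()))
    cols = {}
    for cond in conditions:
        samples = [s for s in values.columns if condition_map.get(s) == cond]
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples in the matrix")
        sub = values[samples]
        n_det = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        mean[n_det < min_detected] = np.nan
        cols[cond] = mean
    out = pd.DataFrame(cols)
    incomplete = out.index[out.isna().any(axis=1)].tolist()
    return ConditionMeans(values=out, incomplete=incomplete)


@dataclass
class CorrelationMatrix:
    """miRNA x gene matrix of negated Pearson correlations over conditions."""

    values: pd.DataFrame
    n_conditions: int
    n_dropped_mirnas: int = 0
    n_dropped_genes: int = 0


def correlate(
    mirna_means: ConditionMeans,
    gene_means: ConditionMeans,
    candidates: list[str] | None = None,
) -> CorrelationMatrix:
    """Negated Pearson correlation of miRNA Cp vs. gene expression profiles.

    Profiles are the per-condition means over the shared condition set
    (>= 3 required).  ``candidates`` restricts the miRNA rows (typically the
    output of the fold-change candidate filter).  Zero-variance profiles
    yield NaN entries and are excluded downstream.
    """
    m = mirna_means.complete
    g = gene_means.complete
    if candidates is not None:
        m = m.loc[[c for c in candidates if c in m.index]]
    shared = [c for c in m.columns if c in g.columns]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared conditions, got {len(shared)}")
    mv = m[shared].to_numpy(dtype=float)
    gv = g[shared].to_numpy(dtype=float)
    k = len(shared)
    mc = mv - mv.mean(axis=1, keepdims=True)
    gc = gv - gv.mean(axis=1, keepdims=True)
    mnorm = np.sqrt((mc**2).sum(axis=1))
    gnorm = np.sqrt((gc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (mc @ gc.T) / np.outer(mnorm, gnorm)
    corr[~np.isfinite(corr)] = np.nan
    values = pd.DataFrame(-corr, index=m.index, columns=g.index)
    return CorrelationMatrix(
        values=values,
        n_conditions=k,
        n_dropped_mirnas=int((mnorm == 0).sum()) + len(mirna_means.incomplete),
        n_dropped_genes=int((gnorm == 0).sum()) + len(gene_means.incomplete),
    )


def prediction_support(predictions: pd.DataFrame) -> pd.Series:
    """Distinct-predictor support count per (mirna, gene) pair.

    ``predictions`` holds unique (mirna, gene, predictor) triples.
    """
    required = {"mirna", "gene", "predictor"}
    if not required.issubset(predictions.columns):
        raise ValueError(f"prediction table needs columns {sorted(required)}")
    return predictions.groupby(["mirna", "gene"])["predictor"].nunique()


@dataclass
class FunctionalTargetSet:
    """Inferred high-confidence inverse-correlated targets per miRNA.

    ``table`` columns: mirna, gene, r (negated correlation), support; sorted
    by miRNA id then ascending r (strongest inverse evidence first).
    """

    table: pd.DataFrame
    r_threshold: float = DEFAULT_R_THRESHOLD
    min_support: int = DEFAULT_MIN_SUPPORT

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["mirna"], self.table["gene"]))

    def targets_of(self, mirna: str) -> list[str]:
        return self.table.loc[self.table["mirna"] == mirna, "gene"].tolist()

    @property
    def mirnas(self) -> list[str]:
        return self.table["mirna"].unique().tolist()


def infer_functional_targets(
    corr: CorrelationMatrix,
    predictions: pd.DataFrame,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> FunctionalTargetSet:
    """Gate the correlation screen by multi-predictor support.

    A pair is kept iff its negated correlation is <= ``r_threshold`` (i.e.
    strong inverse association) and at least ``min_support`` distinct
    predictors list it.  Both comparisons are inclusive.
    """
    support = prediction_support(predictions)
    rows = []
    cv = corr.values
    mask = cv.le(r_threshold)
    for mirna in cv.index:
        hits = cv.columns[mask.loc[mirna].fillna(False)]
        for gene in hits:
            sup = support.get((mirna, gene), 0)
            if sup >= min_support:
                rows.append((mirna, gene, float(cv.at[mirna, gene]), int(sup)))
    table = pd.DataFrame(rows, columns=["mirna", "gene", "r", "support"])
    table = table.sort_values(["mirna", "r"], kind="mergesort").reset_index(drop=True)
    return FunctionalTargetSet(table=table, r_threshold=r_threshold, min_support=min_support)


@dataclass
class CoverageResult:
    """Fraction of DE genes accounted for by DE-miRNA regulation, plus the
    2x2 (DE vs not) x (targeted vs not) contingency table over the gene
    universe."""

    fraction: float | None
    table: np.ndarray  # [[de & targeted, de & not], [not-de & targeted, not-de & not]]
    n_de_genes: int
    n_targeted: int


def regulation_coverage(
    de_genes: set[str],
    fts: FunctionalTargetSet,
    de_mirnas: set[str],
    gene_universe: list[str],
) -> CoverageResult:
    """How many differentially expressed genes have >= 1 DE regulator miRNA.

    ``fraction`` is undefined (None) when the DE gene set is empty.
    """
    targeted = {
        g
        for m, g in fts.pairs
        if m in de_mirnas
    }
    universe = set(gene_universe)
    de = de_genes & universe
    a = len(de & targeted)
    b = len(de - targeted)
    c = len((universe - de) & targeted)
    d = len(universe - de - targeted)
    fraction = a / len(de) if de else None
    return CoverageResult(
        fraction=fraction,
        table=np.array([[a, b], [c, d]], dtype=int),
        n_de_genes=len(de),
        n_targeted=len(targeted & universe),
    )
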