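"""Moderated two-group differential expression and the cross-line consistency signature.

Each contrast (one resistant condition versus the parental reference) is
tested per feature with a two-sample t statistic whose pooled variance is
shrunk toward the across-feature mean variance — a light-weight moderation in
the spirit of empirical-Bayes variance shrinkage, with a fixed prior weight
of two pseudo-replicates.  For Cp matrices the sign is flipped so that a
positive log2 fold change always means higher abundance in the resistant
condition (lower Cp = more template).

The consistency signature collects features that are significant with the
same sign in every contrast, which is how a resistance-associated signature
shared by several independently derived resistant lines is defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEResult",
    "ConsistentSignature",
    "de_test",
    "de_counts",
    "bh_adjust",
    "consistent_signature",
    "select_candidates",
]

PRIOR_DF = 2.0  # pseudo-replicates of shrinkage toward the mean variance
DEFAULT_ALPHA = 0.05
DEFAULT_LFC_THRESHOLD = 0.7


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Returns monotone adjusted p-values capped at 1, in the input order.
    NaN entries are ignored and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pv = p[mask]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


@dataclass
class DEResult:
    """Per-feature differential-expression table for one contrast.

    ``table`` columns: log2fc, t, pvalue, padj (index = feature ids).
    ``skipped`` lists features that could not be tested (insufficient
    detected replicates, or all-zero counts).
    """

    contrast: tuple[str, str]  # (resistant, reference)
    table: pd.DataFrame
    skipped: list[str] = field(default_factory=list)

    @classmethod
    def from_reported(cls, log2fc: pd.Series, contrast: tuple[str, str]) -> "DEResult":
        """Wrap externally reported fold changes whose features all passed
        a published adjusted-p cutoff; the exact p-values are not available,
        so padj is stored as 0.0 to encode the significance call."""
        table = pd.DataFrame(
            {
                "log2fc": log2fc.astype(float),
                "t": np.nan,
                "pvalue": np.nan,
                "padj": 0.0,
            }
        )
        return cls(contrast=contrast, table=table)


def _group_samples(condition_map: dict[str, str], columns, condition: str) -> list[str]:
    samples = [s for s in columns if condition_map.get(s) == condition]
    return samples


def _moderated_t(
    values: pd.DataFrame,
    res_samples: list[str],
    ref_samples: list[str],
    negate: bool,
    min_detected: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    rows = {}
    skipped: list[str] = []
    stats_rows = []
    for feature, row in values.iterrows():
        x = row[res_samples].to_numpy(dtype=float)
        y = row[ref_samples].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        y = y[np.isfinite(y)]
        if len(x) < min_detected or len(y) < min_detected:
            skipped.append(feature)
            continue
        stats_rows.append((feature, x, y))
    if not stats_rows:
        return pd.DataFrame(columns=["log2fc", "t", "pvalue", "padj"]), skipped
    diffs, s2s, dfs, inv_ns = [], [], [], []
    for _, x, y in stats_rows:
        n1, n2 = len(x), len(y)
        diff = float(x.mean() - y.mean())
        df = n1 + n2 - 2
        s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
        diffs.append(diff)
        s2s.append(s2)
        dfs.append(df)
        inv_ns.append(1.0 / n1 + 1.0 / n2)
    diffs = np.asarray(diffs)
    s2s = np.asarray(s2s)
    dfs = np.asarray(dfs, dtype=float)
    inv_ns = np.asarray(inv_ns)
    mean_var = float(s2s.mean())
    s2_mod = (PRIOR_DF * mean_var + dfs * s2s) / (PRIOR_DF + dfs)
    se = np.sqrt(s2_mod * inv_ns)
    sign = -1.0 if negate else 1.0
    lfc = sign * diffs
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    # the shrunken variance has the spread of a chi-square with
    # (d0 + d)^2 / d degrees of freedom (moment matching), not d0 + d
    df_eff = (PRIOR_DF + dfs) ** 2 / dfs
    p = 2.0 * stats.t.sf(np.abs(t), df_eff)
    table = pd.DataFrame(
        {"log2fc": lfc, "t": t, "pvalue": p, "padj": bh_adjust(p)},
        index=[f for f, _, _ in stats_rows],
    )
    return table, skipped


def de_test(
    values: pd.DataFrame,
    condition_map: dict[str, str],
    contrast: tuple[str, str],
    kind: str = "expr",
) -> DEResult:
    """Moderated two-sample t test of one contrast on a log-scale matrix.

    ``kind="cp"`` negates differences so that a positive log2 fold change
    means the miRNA is more abundant in the resistant condition.  Features
    with fewer than 2 detected replicates on either side are skipped.
    """
    resistant, reference = contrast
    res_samples = _group_samples(condition_map, values.columns, resistant)
    ref_samples = _group_samples(condition_map, values.columns, reference)
    if not res_samples:
        raise ValueError(f"contrast condition {resistant!r} has no samples")
    if not ref_samples:
        raise ValueError(f"contrast condition {reference!r} has no samples")
    if len(res_samples) < 2 or len(ref_samples) < 2:
        raise ValueError("each side of the contrast needs >= 2 replicates")
    table, skipped = _moderated_t(values, res_samples, ref_samples, negate=(kind == "cp"))
    return DEResult(contrast=contrast, table=table, skipped=skipped)


def de_counts(
    counts: pd.DataFrame,
    factors: pd.Series,
    condition_map: dict[str, str],
    contrast: tuple[str, str],
) -> DEResult:
    """Differential expression on size-factor-normalized counts.

    The moderated t runs on log2(normalized count + 0.5); the reported log2
    fold change comes from the normalized group means.  All-zero features are
    untested and listed in ``skipped``.
    """
    norm = counts.div(factors.reindex(counts.columns), axis=1)
    nonzero = norm.loc[(norm > 0).any(axis=1)]
    allzero = [f for f in counts.index if f not in nonzero.index]
    logm = np.log2(nonzero + 0.5)
    result = de_test(logm, condition_map, contrast, kind="expr")
    resistant, reference = contrast
    res_samples = _group_samples(condition_map, counts.columns, resistant)
    ref_samples = _group_samples(condition_map, counts.columns, reference)
    mean_res = norm.loc[result.table.index, res_samples].mean(axis=1)
    mean_ref = norm.loc[result.table.index, ref_samples].mean(axis=1)
    result.table["log2fc"] = np.log2((mean_res + 0.5) / (mean_ref + 0.5))
    result.skipped = result.skipped + allzero
    return result


@dataclass
class ConsistentSignature:
    """Features significant with the same sign in every contrast."""

    up: list[str]
    down: list[str]
    log2fc: pd.DataFrame  # members x contrasts

    @property
    def members(self) -> list[str]:
        return self.up + self.down


def consistent_signature(
    results: list[DEResult],
    alpha: float = DEFAULT_ALPHA,
) -> ConsistentSignature:
    """Sign-consistent significant features across >= 3 contrasts.

    A feature is in the up (down) set when its adjusted p is below ``alpha``
    and its log2 fold change is positive (negative) in *every* contrast;
    mixed-sign features are excluded.
    """
    if len(results) < 3:
        raise ValueError(f"need >= 3 contrasts, got {len(results)}")
    common = results[0].table.index
    for r in results[1:]:
        common = common.intersection(r.table.index)
    lfc = pd.DataFrame(
        {r.contrast[0]: r.table.loc[common, "log2fc"] for r in results}
    )
    sig = pd.DataFrame(
        {r.contrast[0]: r.table.loc[common, "padj"] < alpha for r in results}
    )
    all_sig = sig.all(axis=1)
    up = lfc.index[(all_sig) & (lfc > 0).all(axis=1)].tolist()
    down = lfc.index[(all_sig) & (lfc < 0).all(axis=1)].tolist()
    return ConsistentSignature(up=up, down=down, log2fc=lfc.loc[up + down])


def select_candidates(
    results: list[DEResult],
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> list[str]:
    """Features with |log2FC| >= threshold in at least one contrast.

    No p-value criterion is applied: this is the permissive candidate filter
    feeding the inverse-correlation screen.
    """
    if not results:
        raise ValueError("need at least one contrast")
    selected: set[str] = set()
    for r in results:
        hits = r.table.index[r.table["log2fc"].abs() >= lfc_threshold]
        selected.update(hits)
    ordered = []
    for r in results:
        for f in r.table.index:
            if f in selected and f not in ordered:
                ordered.append(f)
    return ordered
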