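"""Small-RNA read processing: 3' trimming, exact-match quantification, size factors.

Reads from small-RNA libraries (18-30 nt inserts) are quality-trimmed at the
3' end, collapsed to unique sequences, and matched exactly against a mature
miRNA reference.  No mismatches or gaps are allowed; a read counts for a
reference entry when one sequence is a substring of the other.  Reads that hit
more than one distinct reference sequence are discarded as multi-mapped.

Mature miRNAs with byte-identical sequences (paralog families such as the
miR-519 cluster) are collapsed into a single :class:`SequenceGroup` before
matching, so that reads hitting such a family are counted once for the group
rather than discarded as multi-mappers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReadRecord",
    "SequenceGroup",
    "trim_read",
    "dedupe_reads",
    "group_reference",
    "match_reads",
    "quantify_sample",
    "size_factors",
    "normalize_counts",
]


@dataclass
class ReadRecord:
    """A single sequencing read: id, uppercase ACGTN sequence, Phred scores."""

    id: str
    sequence: str
    quality: np.ndarray  # Phred scores, same length as sequence

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.quality = np.asarray(self.quality, dtype=int)
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceGroup:
    """Mature miRNA ids sharing one identical sequence."""

    group_id: str
    members: tuple[str, ...]
    sequence: str


def remove_adapter(sequence: str, adapter: str, min_overlap: int = 3) -> str:
    """Strip a 3' adapter by prefix matching.

    The leftmost position where the remaining suffix of the read equals a
    prefix of the adapter (overlap >= ``min_overlap``) marks the insert end.
    """
    n = len(sequence)
    for i in range(0, n - min_overlap + 1):
        suffix = sequence[i:]
        k = min(len(suffix), len(adapter))
        if suffix[:k] == adapter[:k]:
            return sequence[:i]
    return sequence


def trim_read(
    read: ReadRecord,
    quality_cutoff: int = 20,
    min_len: int = 15,
    adapter: str | None = None,
) -> ReadRecord | None:
    """Trim the 3' end of a read; drop it if shorter than ``min_len`` after.

    Adapter removal (prefix match of the read's 3' suffix against the adapter,
    if given) runs first, then quality trimming by the running-sum rule: the
    read is cut after the position maximising ``sum(cutoff - q)`` over the
    removed suffix, when that maximum is positive.  Returns ``None`` for
    dropped reads.
    """
    seq, qual = read.sequence, read.quality
    if adapter:
        trimmed_seq = remove_adapter(seq, adapter)
        qual = qual[: len(trimmed_seq)]
        seq = trimmed_seq
    if len(seq) == 0:
        return None
    # running-sum 3' quality trim (BWA-style)
    deficit = quality_cutoff - qual[::-1].astype(float)
    running = np.cumsum(deficit)
    best = float(running.max(initial=0.0))
    if best > 0:
        cut = int(np.argmax(running)) + 1  # bases removed from the 3' end
        seq = seq[:-cut]
        qual = qual[:-cut]
    if len(seq) < min_len:
        return None
    return ReadRecord(read.id, seq, qual)


def dedupe_reads(reads: list[ReadRecord]) -> dict[str, int]:
    """Collapse reads to a unique-sequence -> copy-number table."""
    return dict(Counter(r.sequence for r in reads))


def group_reference(reference: dict[str, str]) -> list[SequenceGroup]:
    """Collapse reference entries with identical sequences into groups.

    Group ids are the member ids joined by ``|`` (sorted), so a singleton
    group keeps its miRNA id unchanged.
    """
    by_seq: dict[str, list[str]] = {}
    for mid, seq in reference.items():
        by_seq.setdefault(seq.upper().replace("U", "T"), []).append(mid)
    groups = []
    for seq, members in by_seq.items():
        members = sorted(members)
        groups.append(SequenceGroup("|".join(members), tuple(members), seq))
    groups.sort(key=lambda g: g.group_id)
    return groups


@dataclass
class MatchResult:
    """Per-group counts plus the discard/unmatched tallies for one sample."""

    counts: dict[str, int]
    multi_mapped: int
    unmatched: int
    assigned: int


def match_reads(unique_reads: dict[str, int], groups: list[SequenceGroup]) -> MatchResult:
    """Assign unique read sequences to reference groups by exact containment.

    A read matches a group when the read equals the group sequence, or one is
    an exact substring of the other.  Reads matching more than one group are
    discarded as multi-mapped (copies counted in the tally); reads matching
    none are tallied as unmatched.
    """
    counts = {g.group_id: 0 for g in groups}
    multi = 0
    unmatched = 0
    assigned = 0
    for seq, copies in unique_reads.items():
        hits = [g for g in groups if seq == g.sequence or seq in g.sequence or g.sequence in seq]
        if len(hits) == 1:
            counts[hits[0].group_id] += copies
            assigned += copies
        elif len(hits) > 1:
            multi += copies
        else:
            unmatched += copies
    return MatchResult(counts=counts, multi_mapped=multi, unmatched=unmatched, assigned=assigned)


def quantify_sample(
    reads: list[ReadRecord],
    groups: list[SequenceGroup],
    quality_cutoff: int = 20,
    min_len: int = 15,
    adapter: str | None = None,
) -> tuple[MatchResult, dict[str, int]]:
    """Trim, collapse and match one sample's reads.

    Returns the match result and a QC tally (input, surviving, dropped,
    unique, assigned, multi_mapped, unmatched).
    """
    trimmed = [trim_read(r, quality_cutoff, min_len, adapter) for r in reads]
    surviving = [r for r in trimmed if r is not None]
    unique = dedupe_reads(surviving)
    result = match_reads(unique, groups)
    qc = {
        "input_reads": len(reads),
        "surviving_reads": len(surviving),
        "dropped_reads": len(reads) - len(surviving),
        "unique_sequences": len(unique),
        "assigned": result.assigned,
        "multi_mapped": result.multi_mapped,
        "unmatched": result.unmatched,
    }
    return result, qc


def counts_to_matrix(per_sample: dict[str, MatchResult]) -> pd.DataFrame:
    """Stack per-sample match results into a group x sample count matrix."""
    return pd.DataFrame({s: pd.Series(r.counts) for s, r in per_sample.items()}).fillna(0).astype(int)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference is the per-feature geometric mean over samples, computed on
    features with all-positive counts; each sample's factor is the median
    ratio of its counts to the reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 samples")
    positive = counts.loc[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no feature has positive counts in every sample")
    log_geo = np.log(positive.to_numpy(dtype=float)).mean(axis=1)
    ratios = np.log(positive.to_numpy(dtype=float)) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    return counts.div(factors.reindex(counts.columns), axis=1)
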