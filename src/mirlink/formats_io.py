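"""Readers and writers for the on-disk formats of the pipeline.

Matrices travel as TSV with a header row of sample ids and feature ids in
the first column; undetected qPCR assays are encoded as ``NA``.  The
sample-to-condition mapping lives in a separate two-column TSV so the
matrices stay standard.  Sequences use FASTA / 4-line FASTQ (Phred+33) via
Biopython; RNA alphabets are normalized to DNA (U -> T) on input.  All
writers are deterministic: row and column order is preserved from the
in-memory objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .qpcr_normalization import MeltCurve
from .smallrna_quant import ReadRecord

__all__ = [
    "CpMatrix",
    "ExprMatrix",
    "CountMatrix",
    "read_matrix",
    "write_matrix",
    "read_condition_map",
    "write_condition_map",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_predictions",
    "write_predictions",
    "read_cohorts",
    "write_cohorts",
    "read_melt_curves",
    "write_melt_curves",
    "load_config",
    "DEFAULT_THRESHOLDS",
]

NA_TOKEN = "NA"
CP_MAX = 45.0

DEFAULT_THRESHOLDS = {
    "lfc_threshold": 0.7,
    "r_threshold": -0.8,
    "min_support": 2,
    "alpha": 0.05,
}


@dataclass
class CpMatrix:
    """miRNA x sample crossing-point matrix; lower Cp = higher abundance."""

    values: pd.DataFrame
    sample_conditions: dict[str, str]
    reference_condition: str

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (np.any(finite <= 0) or np.any(finite > CP_MAX)):
            raise ValueError(f"Cp values must lie in (0, {CP_MAX}] or be missing")
        missing = [s for s in self.values.columns if s not in self.sample_conditions]
        if missing:
            raise ValueError(f"samples without condition assignment: {missing}")
        if self.reference_condition not in set(self.sample_conditions.values()):
            raise ValueError(
                f"reference condition {self.reference_condition!r} not present in map"
            )

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            c = self.sample_conditions[s]
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def contrasts(self) -> list[tuple[str, str]]:
        """(resistant, reference) pairs, in condition order."""
        return [(c, self.reference_condition) for c in self.conditions if c != self.reference_condition]


@dataclass
class ExprMatrix:
    """Gene x sample log2 expression matrix (RMA-style scale)."""

    values: pd.DataFrame
    sample_conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression matrix must be finite")


@dataclass
class CountMatrix:
    """miRNA x sample matrix of non-negative integer read counts."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if np.any(vals < 0) or not np.all(np.equal(np.mod(vals, 1), 0)):
            raise ValueError("counts must be non-negative integers")
        self.values = self.values.astype(int)


def _read_tsv_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dups}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise ValueError(
                f"{path}: non-numeric cells in column {col!r}: {bad.head().to_dict()}"
            )
    return df.astype(float)


def read_matrix(
    path,
    kind: str,
    condition_map: dict[str, str] | None = None,
    reference_condition: str | None = None,
):
    """Read a typed feature x sample matrix from TSV.

    ``kind`` is one of ``cp``, ``expr`` or ``count``; invariants of the
    corresponding type are enforced.  ``cp`` requires a condition map.
    """
    df = _read_tsv_matrix(path)
    if kind == "cp":
        if condition_map is None:
            raise ValueError("Cp matrices need a sample-to-condition map")
        ref = reference_condition or next(iter(condition_map.values()))
        return CpMatrix(values=df, sample_conditions=condition_map, reference_condition=ref)
    if kind == "expr":
        return ExprMatrix(values=df, sample_conditions=condition_map or {})
    if kind == "count":
        return CountMatrix(values=df)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="feature")


def read_condition_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: condition map needs two columns (sample, condition)")
    sample_col, cond_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in condition map")
    return dict(zip(df[sample_col], df[cond_col]))


def write_condition_map(condition_map: dict[str, str], path) -> None:
    pd.DataFrame(
        {"sample": list(condition_map), "condition": list(condition_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """FASTA -> id -> uppercase DNA sequence (U normalized to T)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=mid, description="") for mid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[ReadRecord]:
    """4-line FASTQ (Phred+33) -> list of reads; malformed records raise
    with the offending record number."""
    reads: list[ReadRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            reads.append(
                ReadRecord(
                    id=rec.id,
                    sequence=str(rec.seq).upper().replace("U", "T"),
                    quality=np.asarray(rec.letter_annotations["phred_quality"], dtype=int),
                )
            )
    except ValueError as exc:
        raise ValueError(
            f"{path}: malformed FASTQ near record {len(reads) + 1} "
            f"(approx. line {4 * len(reads) + 1}): {exc}"
        ) from exc
    return reads


def write_fastq(reads: list[ReadRecord], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quality]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["mirna", "gene", "predictor"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"{path}: prediction table needs columns {required}")
    if df.duplicated().any():
        raise ValueError(f"{path}: duplicate (mirna, gene, predictor) triples")
    return df


def write_predictions(predictions: pd.DataFrame, path) -> None:
    predictions.to_csv(path, sep="\t", index=False)


def read_cohorts(path) -> list:
    """Cohort TSV (sample, cohort, label, one column per miRNA) -> datasets."""
    from .outcome_classification import CohortDataset

    df = pd.read_csv(path, sep="\t")
    required = {"sample", "cohort", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: cohort table needs columns {sorted(required)}")
    mirna_cols = [c for c in df.columns if c not in required]
    cohorts = []
    for cid in df["cohort"].unique():
        sub = df[df["cohort"] == cid].set_index("sample")
        cohorts.append(
            CohortDataset(
                cohort_id=str(cid),
                expression=sub[mirna_cols].astype(float),
                labels=sub["label"].astype(int),
            )
        )
    return cohorts


def write_cohorts(cohorts: list, path) -> None:
    frames = []
    for c in cohorts:
        df = c.expression.copy()
        df.insert(0, "label", c.labels)
        df.insert(0, "cohort", c.cohort_id)
        df.insert(0, "sample", df.index)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_melt_curves(path) -> list[MeltCurve]:
    """Long-format TSV (assay, temperature, fluorescence) -> curves."""
    df = pd.read_csv(path, sep="\t")
    required = {"assay", "temperature", "fluorescence"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: melt table needs columns {sorted(required)}")
    curves = []
    for assay, sub in df.groupby("assay", sort=False):
        sub = sub.sort_values("temperature")
        curves.append(
            MeltCurve(
                assay_id=str(assay),
                temperatures=sub["temperature"].to_numpy(dtype=float),
                fluorescence=sub["fluorescence"].to_numpy(dtype=float),
            )
        )
    return curves


def write_melt_curves(curves: list[MeltCurve], path) -> None:
    rows = []
    for c in curves:
        for t, f in zip(c.temperatures, c.fluorescence):
            rows.append((c.assay_id, t, f))
    pd.DataFrame(rows, columns=["assay", "temperature", "fluorescence"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def load_config(path=None) -> dict:
    """Pipeline thresholds from a YAML file, merged over the defaults
    (lfc 0.7, r -0.8, support 2, alpha 0.05)."""
    import yaml

    config = dict(DEFAULT_THRESHOLDS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(loaded) - set(config)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config.update(loaded)
    return config
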