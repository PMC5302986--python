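"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: one parental
cell line plus three independently derived resistant lines, each profiled in
biological triplicate on a miRNA qPCR panel and a gene expression array,
with a planted miRNA -> target regulatory network coupling the two layers
inversely.  Every stage of the pipeline therefore has a recoverable target:

* regulatory edges (for the inverse-correlation screen),
* per-condition miRNA shifts (for differential expression and signatures),
* a smooth signal-dependent per-sample Cp bias (for the normalization),
* per-miRNA read draws (for the small-RNA quantification),
* outcome effects on marker miRNAs (for the cohort classifiers).

Gene expression follows ``baseline - sum(strength * centered miRNA condition
abundance) + noise``; miRNA Cp follows ``intercept - slope * log2 abundance +
bias + noise`` with slope > 0, so abundance and Cp are anti-monotone.  The
planted per-sample biases are smooth low-order polynomials of the signal,
centered across samples so that the panel consensus is bias-free.

By default each target gene is regulated by at most one miRNA: a pairwise
correlation screen cannot attribute a co-regulated gene to either of its
regulators, so the default planted network is the identifiable one.  Shared
targets can be enabled to stress the screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .outcome_classification import CohortDataset
from .qpcr_normalization import MeltCurve
from .smallrna_quant import ReadRecord

__all__ = [
    "SimulationConfig",
    "RegulatoryTruth",
    "ExpressionSim",
    "ReadSim",
    "simulate_truth",
    "simulate_expression",
    "simulate_predictions",
    "simulate_reference",
    "simulate_reads",
    "simulate_cohorts",
    "simulate_melt_curves",
    "evaluate_recovery",
    "generate_all",
]

# stream offsets so each operation draws from its own reproducible stream
_STREAM_TRUTH = 0
_STREAM_EXPR = 1
_STREAM_PRED = 2
_STREAM_REF = 3
_STREAM_READS = 4
_STREAM_COHORT = 5
_STREAM_MELT = 6

PREDICTOR_NAMES = ("miRanda", "miRDB", "miRWalk", "PICTAR5", "RNA22", "Targetscan")
MARKER_MIRNAS = ("miR-190b", "miR-29b", "miR-516a-5p", "miR-203")


@dataclass
class SimulationConfig:
    """All generator knobs; the defaults are the study conditions.

    Sizes mirror the screening design (a few dozen panel miRNAs, a few
    hundred genes, triplicates of one parental and three resistant
    conditions).  Noise levels are typical replicate scatter for LNA qPCR
    panels (~0.2 Cp) and RMA-summarized arrays (~0.2 log2 units); condition
    shifts of 1-3 log2 units match the magnitude of the published
    resistance signatures.  Cohort sizes and prevalences follow the
    three-cohort clinical design (52, 60 and 40 patients with roughly half
    recurring).
    """

    n_mirnas: int = 30
    n_genes: int = 200
    n_edges: int = 150
    n_conditions: int = 4  # one parental + (n_conditions - 1) resistant
    replicates: int = 3
    de_fraction: float = 1.0  # fraction of miRNAs with condition shifts
    shift_low: float = 1.0  # log2 units
    shift_high: float = 3.0
    strength_low: float = 0.5  # unitless repression strength
    strength_high: float = 1.5
    shared_targets: bool = False  # allow a gene to have several regulators
    cp_noise_sd: float = 0.2  # Cp units
    expr_noise_sd: float = 0.2  # log2 units
    cp_slope: float = 1.0
    cp_intercept: float = 35.0
    cp_bias_amplitude: float = 1.0  # max |bias| in Cp units
    cp_bias_degree: int = 3
    decoy_rate: float = 0.05
    n_predictors: int = 6
    decoy_continue_prob: float = 0.3  # geometric tail: P(support = k+1 | >= k)
    n_reads: int = 10_000  # per sample
    read_adapter: str | None = None
    read_length: int | None = None
    reference_duplicate_fraction: float = 0.05
    cohort_sizes: tuple[int, ...] = (52, 60, 40)
    cohort_prevalence: tuple[float, ...] = (0.5, 0.5, 0.475)
    marker_mirnas: tuple[str, ...] = MARKER_MIRNAS
    marker_betas: tuple[float, ...] = (1.2, -0.8, 1.0, 0.6)
    n_cohort_mirnas: int = 20
    cohort_batch_sd: float = 0.25  # per-(cohort, miRNA) mean shift, log2 units
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirnas", "n_genes", "n_conditions", "replicates", "n_predictors", "n_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_edges < 0:
            raise ValueError("n_edges must be >= 0")
        if self.n_conditions < 4:
            raise ValueError("need >= 4 conditions (1 parental + >= 3 resistant)")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if len(self.cohort_sizes) != len(self.cohort_prevalence):
            raise ValueError("cohort_sizes and cohort_prevalence must align")
        if len(self.marker_mirnas) != len(self.marker_betas):
            raise ValueError("marker_mirnas and marker_betas must align")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), stream])

    @property
    def conditions(self) -> list[str]:
        return ["parental"] + [f"resistant_{i}" for i in range(1, self.n_conditions)]


@dataclass
class RegulatoryTruth:
    """The planted network and condition effects behind a simulation."""

    mirna_ids: list[str]
    gene_ids: list[str]
    edges: dict[tuple[str, str], float]  # (miRNA, gene) -> repression strength
    de_mirnas: dict[str, dict[str, float]]  # miRNA -> condition -> log2 shift
    conditions: list[str]

    def __post_init__(self) -> None:
        mset, gset = set(self.mirna_ids), set(self.gene_ids)
        for (m, g), strength in self.edges.items():
            if m not in mset or g not in gset:
                raise ValueError(f"edge ({m}, {g}) references undeclared ids")
            if strength <= 0:
                raise ValueError(f"edge ({m}, {g}) has non-positive strength")
        if len(self.conditions) < 4:
            raise ValueError("need >= 4 conditions")

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def to_dict(self) -> dict:
        return {
            "mirna_ids": self.mirna_ids,
            "gene_ids": self.gene_ids,
            "edges": [[m, g, s] for (m, g), s in self.edges.items()],
            "de_mirnas": self.de_mirnas,
            "conditions": self.conditions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegulatoryTruth":
        return cls(
            mirna_ids=list(d["mirna_ids"]),
            gene_ids=list(d["gene_ids"]),
            edges={(m, g): float(s) for m, g, s in d["edges"]},
            de_mirnas={m: {c: float(v) for c, v in cv.items()} for m, cv in d["de_mirnas"].items()},
            conditions=list(d["conditions"]),
        )


def simulate_truth(config: SimulationConfig) -> RegulatoryTruth:
    """Sample the planted regulatory network and per-condition miRNA shifts.

    Edges are sampled without replacement; with ``shared_targets`` disabled
    (default) target genes are drawn without replacement too, so each gene
    has at most one regulator.  Shifted miRNAs get one sign each and an
    independent magnitude per resistant condition; both signs are
    represented whenever at least two miRNAs shift.
    """
    rng = config.rng(_STREAM_TRUTH)
    mirnas = [f"miR-sim-{i + 1:03d}" for i in range(config.n_mirnas)]
    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    if config.shared_targets:
        n_pairs = config.n_mirnas * config.n_genes
        if config.n_edges > n_pairs:
            raise ValueError(f"cannot place {config.n_edges} edges among {n_pairs} pairs")
        flat = rng.choice(n_pairs, size=config.n_edges, replace=False)
        pairs = [(mirnas[i // config.n_genes], genes[i % config.n_genes]) for i in flat]
    else:
        if config.n_edges > config.n_genes:
            raise ValueError(
                f"cannot place {config.n_edges} single-regulator edges among "
                f"{config.n_genes} genes (set shared_targets=True)"
            )
        target_genes = rng.choice(config.n_genes, size=config.n_edges, replace=False)
        regulators = rng.integers(0, config.n_mirnas, size=config.n_edges)
        pairs = [(mirnas[m], genes[g]) for m, g in zip(regulators, target_genes)]
    strengths = rng.uniform(config.strength_low, config.strength_high, size=config.n_edges)
    edges = {pair: float(s) for pair, s in zip(pairs, strengths)}

    n_de = int(round(config.de_fraction * config.n_mirnas))
    de_idx = rng.choice(config.n_mirnas, size=n_de, replace=False)
    signs = np.where(rng.random(n_de) < 0.5, 1.0, -1.0)
    if n_de >= 2:  # guarantee both signs represented
        if np.all(signs > 0):
            signs[0] = -1.0
        elif np.all(signs < 0):
            signs[0] = 1.0
    resistant = config.conditions[1:]
    de_mirnas: dict[str, dict[str, float]] = {}
    for j, idx in enumerate(sorted(de_idx)):
        mags = rng.uniform(config.shift_low, config.shift_high, size=len(resistant))
        de_mirnas[mirnas[idx]] = {c: float(signs[j] * m) for c, m in zip(resistant, mags)}
    return RegulatoryTruth(
        mirna_ids=mirnas,
        gene_ids=genes,
        edges=edges,
        de_mirnas=de_mirnas,
        conditions=config.conditions,
    )


@dataclass
class ExpressionSim:
    """Simulated paired Cp / expression matrices plus their ground truth.

    ``cp`` carries the planted per-sample signal-dependent bias; ``cp_nobias``
    is the same draw without it (identical noise), so the two differ exactly
    by the planted bias and a normalization method can be scored against it.
    """

    cp: pd.DataFrame
    cp_nobias: pd.DataFrame
    expr: pd.DataFrame
    condition_map: dict[str, str]
    abundance: pd.DataFrame  # miRNA x condition log2 abundance
    reference_condition: str = "parental"


def _sample_names(config: SimulationConfig) -> tuple[list[str], dict[str, str]]:
    samples, cmap = [], {}
    for cond in config.conditions:
        for r in range(1, config.replicates + 1):
            name = f"{cond}_r{r}"
            samples.append(name)
            cmap[name] = cond
    return samples, cmap


def simulate_expression(truth: RegulatoryTruth, config: SimulationConfig) -> ExpressionSim:
    """Generate the coupled Cp and expression matrices.

    miRNA log2 abundance is a per-miRNA baseline plus the planted condition
    shift.  Gene log2 expression subtracts, for each regulating edge, the
    strength times the *centered* miRNA condition profile, realizing the
    inverse miRNA-target coupling at the condition-mean level.  Cp is affine
    in abundance with negative dependence, plus the per-sample smooth bias
    and Gaussian noise.
    """
    rng = config.rng(_STREAM_EXPR)
    mirnas, genes = truth.mirna_ids, truth.gene_ids
    conditions = truth.conditions
    samples, cmap = _sample_names(config)

    baseline_m = rng.uniform(4.0, 12.0, size=len(mirnas))
    abundance = pd.DataFrame(
        np.tile(baseline_m[:, None], (1, len(conditions))), index=mirnas, columns=conditions
    )
    for m, shifts in truth.de_mirnas.items():
        for cond, shift in shifts.items():
            abundance.at[m, cond] += shift

    baseline_g = rng.uniform(6.0, 10.0, size=len(genes))
    gene_cond = pd.DataFrame(
        np.tile(baseline_g[:, None], (1, len(conditions))), index=genes, columns=conditions
    )
    centered = abundance.sub(abundance.mean(axis=1), axis=0)
    for (m, g), strength in truth.edges.items():
        gene_cond.loc[g] -= strength * centered.loc[m]

    cond_of = [cmap[s] for s in samples]
    expr = gene_cond[cond_of].to_numpy() + rng.normal(0, config.expr_noise_sd, (len(genes), len(samples)))
    expr = pd.DataFrame(expr, index=genes, columns=samples)

    cp_clean = config.cp_intercept - config.cp_slope * abundance[cond_of].to_numpy()
    noise = rng.normal(0, config.cp_noise_sd, cp_clean.shape)
    bias = _planted_bias_matrix(cp_clean, config, rng)
    cp = pd.DataFrame(cp_clean + bias + noise, index=mirnas, columns=samples)
    cp_nobias = pd.DataFrame(cp_clean + noise, index=mirnas, columns=samples)
    return ExpressionSim(
        cp=cp,
        cp_nobias=cp_nobias,
        expr=expr,
        condition_map=cmap,
        abundance=abundance,
    )


def _planted_bias_matrix(
    cp_clean: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Smooth per-sample polynomial bias of the clean signal, centered across
    samples and scaled so the largest absolute distortion equals the
    configured amplitude."""
    n_samples = cp_clean.shape[1]
    degree = config.cp_bias_degree
    coeffs = rng.normal(0, 1.0, size=(n_samples, degree + 1))
    coeffs -= coeffs.mean(axis=0, keepdims=True)  # consensus across samples is bias-free
    lo, hi = cp_clean.min(), cp_clean.max()
    span = max(hi - lo, 1e-9)
    x01 = (cp_clean - lo) / span
    powers = np.stack([x01**k for k in range(degree + 1)], axis=-1)  # (feat, sample, deg+1)
    bias = np.einsum("fsk,sk->fs", powers, coeffs)
    peak = np.abs(bias).max()
    if peak > 0 and config.cp_bias_amplitude > 0:
        bias *= config.cp_bias_amplitude / peak
    else:
        bias = np.zeros_like(bias)
    return bias


def simulate_predictions(truth: RegulatoryTruth, config: SimulationConfig) -> pd.DataFrame:
    """Emulated multi-tool target-prediction table.

    Every true edge receives 2..n_predictors distinct supporting predictors,
    so no planted edge is lost at the support gate.  Decoy (non-edge) pairs
    enter at ``decoy_rate``; their support count follows a truncated
    geometric, so most decoys have support 1 (below the default >= 2 gate)
    but some pass it and stress the correlation filter.
    """
    if config.n_predictors < 2:
        raise ValueError("need >= 2 predictors")
    rng = config.rng(_STREAM_PRED)
    predictors = list(PREDICTOR_NAMES[: config.n_predictors])
    while len(predictors) < config.n_predictors:
        predictors.append(f"predictor{len(predictors) + 1}")
    rows: list[tuple[str, str, str]] = []
    for m, g in sorted(truth.edges):
        support = int(rng.integers(2, config.n_predictors + 1))
        chosen = rng.choice(config.n_predictors, size=support, replace=False)
        rows.extend((m, g, predictors[i]) for i in sorted(chosen))
    edge_set = truth.edge_set
    q = config.decoy_continue_prob
    for m in truth.mirna_ids:
        genes = np.asarray(truth.gene_ids)
        mask = rng.random(len(genes)) < config.decoy_rate
        for g in genes[mask]:
            if (m, str(g)) in edge_set:
                continue
            support = 1
            while support < config.n_predictors and rng.random() < q:
                support += 1
            chosen = rng.choice(config.n_predictors, size=support, replace=False)
            rows.extend((m, str(g), predictors[i]) for i in sorted(chosen))
    return pd.DataFrame(rows, columns=["mirna", "gene", "predictor"])


_BASES = np.array(list("ACGT"))


def simulate_reference(truth: RegulatoryTruth, config: SimulationConfig) -> dict[str, str]:
    """Random mature-miRNA reference sequences (18-23 nt).

    A configurable fraction of miRNAs share a byte-identical sequence with a
    partner, emulating paralog families, which exercises the sequence-group
    collapse in the quantifier.  Distinct sequences are guaranteed not to be
    substrings of one another.
    """
    rng = config.rng(_STREAM_REF)
    seqs: list[str] = []
    for _ in truth.mirna_ids:
        while True:
            length = int(rng.integers(18, 24))
            seq = "".join(rng.choice(_BASES, size=length))
            if all(seq not in s and s not in seq for s in seqs):
                seqs.append(seq)
                break
    n_dup = int(math.floor(config.reference_duplicate_fraction * len(seqs)))
    for i in range(n_dup):
        # overwrite the tail entries with copies of the head entries
        seqs[len(seqs) - 1 - i] = seqs[i]
    return dict(zip(truth.mirna_ids, seqs))


@dataclass
class ReadSim:
    """Simulated FASTQ reads plus the per-miRNA ground-truth draws."""

    reads: dict[str, list[ReadRecord]]
    counts: pd.DataFrame  # miRNA x sample true read draws


def simulate_reads(
    truth: RegulatoryTruth,
    reference: dict[str, str],
    config: SimulationConfig,
) -> ReadSim:
    """Draw reads per miRNA proportional to its (linear-scale) abundance.

    Without an adapter every read is exactly its reference sequence at
    Q40.  With ``read_adapter`` set, the adapter is appended (optionally
    truncated at ``read_length``) and qualities decay linearly toward Q2
    over the adapter bases, emulating deteriorating 3' base calls.
    """
    if not reference:
        raise ValueError("empty mature-miRNA reference")
    for mid, seq in reference.items():
        s = seq.upper().replace("U", "T")
        if not (18 <= len(s) <= 30) or set(s) - set("ACGT"):
            raise ValueError(f"reference {mid!r}: need 18-30 nt over A/C/G/T/U")
    rng = config.rng(_STREAM_READS)
    mirnas = [m for m in truth.mirna_ids if m in reference]
    samples, cmap = _sample_names(config)
    abundance_base = {m: 8.0 for m in mirnas}
    counts = pd.DataFrame(0, index=mirnas, columns=samples, dtype=int)
    reads: dict[str, list[ReadRecord]] = {}
    for sample in samples:
        cond = cmap[sample]
        log2_ab = np.array(
            [
                abundance_base[m] + truth.de_mirnas.get(m, {}).get(cond, 0.0)
                for m in mirnas
            ]
        )
        probs = 2.0**log2_ab
        probs /= probs.sum()
        draw = rng.multinomial(config.n_reads, probs)
        counts[sample] = draw
        sample_reads: list[ReadRecord] = []
        idx = 0
        for m, n in zip(mirnas, draw):
            insert = reference[m].upper().replace("U", "T")
            for _ in range(n):
                seq, qual = _make_read(insert, config)
                sample_reads.append(ReadRecord(f"{sample}:{idx:06d}", seq, qual))
                idx += 1
        reads[sample] = sample_reads
    return ReadSim(reads=reads, counts=counts)


def _make_read(insert: str, config: SimulationConfig) -> tuple[str, np.ndarray]:
    if config.read_adapter:
        seq = insert + config.read_adapter
        if config.read_length is not None:
            seq = seq[: config.read_length]
        qual = np.full(len(seq), 40)
        n_adapter = len(seq) - len(insert)
        if n_adapter > 0:
            qual[len(insert):] = np.linspace(40, 2, n_adapter).round().astype(int)
        return seq, qual
    return insert, np.full(len(insert), 40)


def simulate_cohorts(config: SimulationConfig) -> list[CohortDataset]:
    """Patient cohorts with recurrence labels from a logistic model.

    Marker miRNA expression is standard-normal on the log2 scale with a
    small per-(cohort, miRNA) batch shift; recurrence probability is
    ``expit(logit(prevalence) + sum(beta_i * x_i))`` on the designated
    marker miRNAs, with cohort-specific intercepts hitting the configured
    prevalences.  Both outcome classes are guaranteed present.
    """
    if len(config.cohort_sizes) < 2:
        raise ValueError("need >= 2 cohorts")
    if any(n < 20 for n in config.cohort_sizes):
        raise ValueError("each cohort needs n >= 20")
    from scipy.special import expit, logit

    rng = config.rng(_STREAM_COHORT)
    markers = list(config.marker_mirnas)
    n_extra = max(config.n_cohort_mirnas - len(markers), 0)
    mirna_cols = markers + [f"miR-bg-{i + 1:02d}" for i in range(n_extra)]
    betas = np.asarray(config.marker_betas, dtype=float)
    cohorts: list[CohortDataset] = []
    for c, (n, prev) in enumerate(zip(config.cohort_sizes, config.cohort_prevalence), start=1):
        batch = rng.normal(0, config.cohort_batch_sd, size=len(mirna_cols))
        x_bio = rng.normal(0, 1.0, size=(n, len(mirna_cols)))
        x = x_bio + batch  # technical batch shift: measured, not prognostic
        eta = logit(prev) + x_bio[:, : len(markers)] @ betas
        labels = (rng.random(n) < expit(eta)).astype(int)
        if labels.min() == labels.max():  # force both classes (tiny-n edge case)
            labels[int(rng.integers(0, n))] = 1 - labels[0]
        sample_ids = [f"cohort{c}_s{i + 1:03d}" for i in range(n)]
        cohorts.append(
            CohortDataset(
                cohort_id=f"cohort{c}",
                expression=pd.DataFrame(x, index=sample_ids, columns=mirna_cols),
                labels=pd.Series(labels, index=sample_ids, name="label"),
            )
        )
    return cohorts


def simulate_melt_curves(
    config: SimulationConfig,
    n_assays: int = 20,
    multi_peak_fraction: float = 0.1,
) -> tuple[list[MeltCurve], dict[str, int]]:
    """Melting curves with a known number of melt transitions per assay.

    Fluorescence decreases through one (clean assay) or two (non-specific
    assay) sigmoidal melt transitions; the negative derivative then shows
    the corresponding number of peaks.  Returns the curves and the planted
    peak counts.
    """
    rng = config.rng(_STREAM_MELT)
    temps = np.arange(65.0, 95.5, 0.5)
    curves, truth_counts = [], {}
    n_multi = int(round(multi_peak_fraction * n_assays))
    for i in range(n_assays):
        assay = f"assay{i + 1:03d}"
        n_peaks = 2 if i < n_multi else 1
        tms = [float(rng.uniform(72, 88))]
        if n_peaks == 2:
            tms.append(tms[0] + float(rng.choice([-1, 1])) * float(rng.uniform(6, 10)))
        fluor = np.full_like(temps, 0.05)
        for tm in tms:
            fluor = fluor + (1.0 / len(tms)) / (1.0 + np.exp((temps - tm) / 0.8))
        fluor = fluor + rng.normal(0, 0.002, size=temps.shape)
        curves.append(MeltCurve(assay_id=assay, temperatures=temps, fluorescence=fluor))
        truth_counts[assay] = n_peaks
    return curves, truth_counts


def evaluate_recovery(inferred_pairs: set[tuple[str, str]], truth: RegulatoryTruth) -> dict:
    """Precision / recall of inferred miRNA-target pairs against planted edges."""
    true_edges = truth.edge_set
    tp = len(inferred_pairs & true_edges)
    precision = tp / len(inferred_pairs) if inferred_pairs else float("nan")
    recall = tp / len(true_edges) if true_edges else float("nan")
    return {
        "n_inferred": len(inferred_pairs),
        "n_true_edges": len(true_edges),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }


def generate_all(config: SimulationConfig, outdir) -> dict:
    """Write every simulated input the pipeline consumes into ``outdir``.

    Returns a manifest of written paths.  Identical configs (including the
    seed) produce byte-identical trees.
    """
    from pathlib import Path

    from . import formats_io as io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config)
    sim = simulate_expression(truth, config)
    predictions = simulate_predictions(truth, config)
    reference = simulate_reference(truth, config)
    readsim = simulate_reads(truth, reference, config)
    cohorts = simulate_cohorts(config)
    melts, melt_truth = simulate_melt_curves(config)

    manifest: dict[str, str] = {}

    def _path(name: str):
        manifest[name] = str(outdir / name)
        return outdir / name

    io.write_matrix(sim.cp, _path("cp.tsv"))
    io.write_matrix(sim.expr, _path("expr.tsv"))
    io.write_condition_map(sim.condition_map, _path("conditions.tsv"))
    io.write_predictions(predictions, _path("predictions.tsv"))
    io.write_fasta(reference, _path("reference.fasta"))
    for sample, reads in readsim.reads.items():
        io.write_fastq(reads, _path(f"reads_{sample}.fastq"))
    io.write_matrix(readsim.counts, _path("read_truth_counts.tsv"))
    io.write_cohorts(cohorts, _path("cohorts.tsv"))
    io.write_melt_curves(melts, _path("melt.tsv"))
    io.write_json(
        {"truth": truth.to_dict(), "melt_peaks": melt_truth, "config": asdict(config)},
        _path("truth.json"),
    )
    return manifest
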