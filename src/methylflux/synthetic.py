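"""Ground-truthed synthetic data for the three assay types the pipeline analyses.

Three generators emulate the statistical structure of the study designs:

* time-course RNA-seq counts with planted temporal expression patterns
  (negative-binomial noise; two replicates per condition at days 3/5/7 in the
  emulated design),
* actinomycin-D chase counts across t = 0/4/8 h with known half-lives,
  constant ERCC spike-ins, and optional planted library-scale distortions,
* paired MeRIP IP/input per-nt coverage with planted enriched windows.

Every generator is deterministic given its seed and returns the ground truth
alongside the data so downstream calls can be scored without reaching back
into generator internals. ``write_truth_*`` helpers serialize the truth as
TSV/BED sidecars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, CoveragePair

SPIKE_PREFIX = "ERCC-"


# ---------------------------------------------------------------------------
# truth types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimecoursePattern:
    """A cluster mean trajectory: relative expression per timepoint."""

    pattern_id: str
    template: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.template) == 0 or not any(v != 0 for v in self.template):
            raise ValueError(f"pattern {self.pattern_id}: template needs a nonzero entry")
        if any(v < 0 for v in self.template):
            raise ValueError(f"pattern {self.pattern_id}: template values must be >= 0")


@dataclass(frozen=True)
class DecayTruth:
    """Per-gene decay ground truth: half-life in hours and baseline count at t=0."""

    gene: str
    half_life: float
    baseline: float

    def __post_init__(self) -> None:
        if not self.half_life > 0:  # math.inf allowed
            raise ValueError(f"{self.gene}: half_life must be > 0")
        if not self.baseline > 0:
            raise ValueError(f"{self.gene}: baseline must be > 0")


@dataclass(frozen=True)
class PlantedPeak:
    """A planted enriched interval (0-based half-open) on one transcript."""

    transcript: str
    start: int
    end: int
    enrichment: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.transcript}: require 0 <= start < end")
        if self.enrichment < 1:
            raise ValueError(f"{self.transcript}: enrichment must be >= 1")


def default_patterns(timepoints: Sequence[float], n_patterns: int = 9) -> list[TimecoursePattern]:
    """Canonical temporal templates: monotone up/down, transient, step shapes.

    Templates are positive relative-expression profiles over the given
    timepoints; with nine patterns they play the role of nine distinct
    cluster mean trajectories.
    """
    t = np.asarray(timepoints, dtype=float)
    x = (t - t.min()) / max(t.max() - t.min(), 1e-9)  # scaled to [0, 1]
    # shapes come in mirrored pairs (each pair sums to a constant) so a
    # balanced pattern set keeps the expected library size flat over time
    shapes = [
        ("up_linear", 1 + 4 * x),
        ("down_linear", 5 - 4 * x),
        ("up_late", 1 + 4 * x**3),
        ("down_late", 5 - 4 * x**3),
        ("transient_peak", 1 + 4 * np.exp(-(((x - 0.5) / 0.2) ** 2))),
        ("transient_dip", 5 - 4 * np.exp(-(((x - 0.5) / 0.2) ** 2))),
        ("up_saturating", 1 + 4 * (1 - np.exp(-3 * x))),
        ("down_saturating", 5 - 4 * (1 - np.exp(-3 * x))),
        ("flat", np.full_like(x, 3.0)),
    ]
    if n_patterns > len(shapes):
        raise ValueError(f"at most {len(shapes)} built-in patterns available")
    return [
        TimecoursePattern(pid, tuple(float(v) for v in tmpl))
        for pid, tmpl in shapes[:n_patterns]
    ]


# ---------------------------------------------------------------------------
# time-course counts
# ---------------------------------------------------------------------------

def simulate_timecourse_counts(
    patterns: Sequence[TimecoursePattern],
    genes_per_pattern: int,
    timepoints: Sequence[float],
    conditions: Sequence[str] = ("NC",),
    replicates: int = 2,
    depth: float = 1e6,
    dispersion: float = 0.1,
    condition_effects: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate gene-by-sample counts with planted temporal patterns.

    Each gene follows one pattern's template across timepoints; expected
    counts are the template values under a single per-condition scale chosen
    so the time-averaged expected library size equals ``depth`` (a constant
    scale preserves every gene's temporal shape; with a balanced template set
    the library is flat over time as well). Noise is negative-binomial with
    the given dispersion (variance mu + dispersion * mu^2); dispersion 0
    gives Poisson. ``condition_effects`` optionally maps
    condition -> pattern_id -> multiplier applied before scaling.

    Returns the CountMatrix (with sample metadata) and a truth table mapping
    each gene to its pattern.
    """
    if len(patterns) == 0:
        raise ValueError("need at least one pattern")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if genes_per_pattern < 1 or replicates < 1:
        raise ValueError("genes_per_pattern and replicates must be >= 1")
    T = len(timepoints)
    for p in patterns:
        if len(p.template) != T:
            raise ValueError(
                f"pattern {p.pattern_id}: template length {len(p.template)} "
                f"!= {T} timepoints"
            )

    rng = np.random.default_rng(seed)
    genes, pattern_of = [], []
    templates = []
    for p in patterns:
        for i in range(genes_per_pattern):
            genes.append(f"{p.pattern_id}_g{i:04d}")
            pattern_of.append(p.pattern_id)
            templates.append(p.template)
    base = np.asarray(templates, dtype=float)  # G x T

    columns, meta_rows, blocks = [], [], []
    for cond in conditions:
        w = base.copy()
        if condition_effects and cond in condition_effects:
            eff = condition_effects[cond]
            for g, pid in enumerate(pattern_of):
                w[g] *= eff.get(pid, 1.0)
        # one scale per condition: time-averaged expected library == depth
        mu = depth * w / w.sum(axis=0).mean()  # G x T
        for ti, t in enumerate(timepoints):
            for rep in range(1, replicates + 1):
                columns.append(f"{cond}_t{t:g}_r{rep}")
                meta_rows.append((cond, float(t), rep))
                m = mu[:, ti]
                if dispersion == 0:
                    blocks.append(rng.poisson(m))
                else:
                    n = 1.0 / dispersion
                    blocks.append(rng.negative_binomial(n, n / (n + m)))

    counts = pd.DataFrame(
        np.column_stack(blocks).astype(np.int64), index=genes, columns=columns
    )
    meta = pd.DataFrame(
        meta_rows, index=pd.Index(columns, name="sample"),
        columns=["condition", "timepoint_h", "replicate"],
    )
    truth = pd.DataFrame({"gene": genes, "pattern_id": pattern_of}).set_index("gene")
    spike = pd.Series(False, index=counts.index)
    return CountMatrix(counts=counts, metadata=meta, spike_mask=spike), truth


# ---------------------------------------------------------------------------
# actinomycin-D decay experiment
# ---------------------------------------------------------------------------

def simulate_decay_experiment(
    truths: Sequence[DecayTruth],
    timepoints: Sequence[float] = (0.0, 4.0, 8.0),
    spike_defs: Mapping[str, float] | None = None,
    scale_distortion: Sequence[float] | None = None,
    replicates: int = 1,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate an ActD chase: genes decay exponentially, spike-ins do not.

    Gene expected counts are baseline * 2^(-t / half_life) * sample distortion;
    spike-in expected counts are constant (the per-unit-RNA ERCC addition)
    times the same distortion. Sampling is Poisson. ``scale_distortion`` has
    one multiplier per sample (timepoints x replicates, timepoint-major).
    """
    if 0.0 not in [float(t) for t in timepoints]:
        raise ValueError("timepoints must include 0")
    if spike_defs is None:
        spike_defs = {f"{SPIKE_PREFIX}{i:05d}": 1000.0 for i in range(2, 12)}
    if not spike_defs:
        raise ValueError("spike_defs must be non-empty")
    n_samples = len(timepoints) * replicates
    if scale_distortion is None:
        scale_distortion = [1.0] * n_samples
    if len(scale_distortion) != n_samples:
        raise ValueError(
            f"scale_distortion length {len(scale_distortion)} != {n_samples} samples"
        )
    if any(d <= 0 for d in scale_distortion):
        raise ValueError("distortion factors must be > 0")

    rng = np.random.default_rng(seed)
    gene_ids = [tr.gene for tr in truths]
    spike_ids = list(spike_defs)
    columns, meta_rows, mu_cols = [], [], []
    si = 0
    for t in timepoints:
        for rep in range(1, replicates + 1):
            d = float(scale_distortion[si])
            si += 1
            columns.append(f"t{t:g}_r{rep}")
            meta_rows.append(("ActD", float(t), rep))
            gene_mu = np.array(
                [
                    tr.baseline
                    * (1.0 if math.isinf(tr.half_life) else 2.0 ** (-t / tr.half_life))
                    for tr in truths
                ]
            )
            spike_mu = np.array([spike_defs[s] for s in spike_ids])
            mu_cols.append(np.concatenate([gene_mu, spike_mu]) * d)

    counts = rng.poisson(np.column_stack(mu_cols)).astype(np.int64)
    index = pd.Index(gene_ids + spike_ids)
    df = pd.DataFrame(counts, index=index, columns=columns)
    meta = pd.DataFrame(
        meta_rows, index=pd.Index(columns, name="sample"),
        columns=["condition", "timepoint_h", "replicate"],
    )
    spike = pd.Series(
        [False] * len(gene_ids) + [True] * len(spike_ids), index=index
    )
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "half_life": [tr.half_life for tr in truths],
            "baseline": [tr.baseline for tr in truths],
        }
    ).set_index("gene")
    return CountMatrix(counts=df, metadata=meta, spike_mask=spike), truth


# ---------------------------------------------------------------------------
# MeRIP coverage
# ---------------------------------------------------------------------------

def simulate_merip_coverage(
    transcript_lengths: Mapping[str, int],
    planted: Sequence[PlantedPeak],
    background_depth: float = 30.0,
    seed: int = 0,
) -> tuple[list[CoveragePair], pd.DataFrame]:
    """Simulate paired IP/input per-nt coverage with planted enriched windows.

    Input depth is Poisson(background_depth) at every position; IP depth is
    Poisson(background_depth * enrichment) inside planted intervals and
    Poisson(background_depth) outside. Both tracks carry the same nominal
    library total — the expected background mass over all simulated
    transcripts — mimicking depth-matched IP and input libraries in which the
    simulated transcripts are a negligible fraction of the genome-wide
    library, so the local IP/input RPKM ratio reflects the planted
    enrichment.

    Returns the coverage pairs and the truth table (BED-like columns).
    """
    if background_depth <= 0:
        raise ValueError("background_depth must be > 0")
    by_tx: dict[str, list[PlantedPeak]] = {}
    for pk in planted:
        if pk.transcript not in transcript_lengths:
            raise ValueError(f"planted peak on unknown transcript {pk.transcript!r}")
        if pk.end > transcript_lengths[pk.transcript]:
            raise ValueError(
                f"planted peak [{pk.start},{pk.end}) outside transcript "
                f"{pk.transcript} of length {transcript_lengths[pk.transcript]}"
            )
        by_tx.setdefault(pk.transcript, []).append(pk)

    rng = np.random.default_rng(seed)
    ip_tracks, input_tracks = {}, {}
    for tx, n in transcript_lengths.items():
        lam_ip = np.full(n, background_depth)
        for pk in by_tx.get(tx, ()):
            lam_ip[pk.start : pk.end] = background_depth * pk.enrichment
        ip_tracks[tx] = rng.poisson(lam_ip).astype(float)
        input_tracks[tx] = rng.poisson(np.full(n, background_depth)).astype(float)

    total_nt = sum(transcript_lengths.values())
    ip_total = input_total = background_depth * total_nt
    pairs = [
        CoveragePair(
            transcript=tx,
            ip=ip_tracks[tx],
            input=input_tracks[tx],
            length=transcript_lengths[tx],
            ip_total=ip_total,
            input_total=input_total,
        )
        for tx in transcript_lengths
    ]
    truth = pd.DataFrame(
        {
            "transcript": [pk.transcript for pk in planted],
            "start": [pk.start for pk in planted],
            "end": [pk.end for pk in planted],
            "enrichment": [pk.enrichment for pk in planted],
        }
    )
    return pairs, truth


# ---------------------------------------------------------------------------
# truth sidecars
# ---------------------------------------------------------------------------

def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", lineterminator="\n")


def write_truth_bed(truth: pd.DataFrame, path: str | Path) -> None:
    """Planted peaks as BED6 (score = 100 * enrichment, capped at 1000)."""
    with open(path, "w") as fh:
        for i, row in enumerate(truth.itertuples(index=False), 1):
            score = min(round(100 * row.enrichment), 1000)
            fh.write(
                f"{row.transcript}\t{row.start}\t{row.end}\ttruth_{i}\t{score}\t+\n"
            )
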