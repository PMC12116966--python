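"""Readers and writers for the pipeline's plain-text formats.

Counts travel as TSV (genes as rows, samples as columns; spike-in rows are
identified by id prefix, default ``ERCC-``), with an optional sample-metadata
sidecar TSV (columns: sample, condition, timepoint_h, replicate). Coverage is
bedGraph with the transcript id in the chrom column and 0-based half-open
intervals; peaks are BED6; gene sets are GMT.

All readers validate and reject malformed input rather than coercing it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("methylflux")

SPIKE_PREFIX = "ERCC-"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Non-negative integer gene-by-sample counts plus per-sample metadata.

    ``spike_mask`` flags spike-in rows (by id prefix at read time, or as set
    by a generator). ``metadata`` is indexed by sample name and, when present,
    carries condition, timepoint_h and replicate columns.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None
    spike_mask: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.spike_mask is None:
            self.spike_mask = self.counts.index.to_series().str.startswith(
                SPIKE_PREFIX
            )
        self.spike_mask = self.spike_mask.reindex(self.counts.index, fill_value=False)
        if self.metadata is not None:
            missing = [s for s in self.counts.columns if s not in self.metadata.index]
            if missing:
                raise ValueError(f"metadata missing samples: {missing}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def gene_counts(self) -> pd.DataFrame:
        """Counts restricted to non-spike rows."""
        return self.counts.loc[~self.spike_mask]

    def spike_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.spike_mask]


@dataclass
class CoveragePair:
    """Paired IP/input per-nucleotide depth over one transcript.

    Depths are dense arrays of length ``length`` (read-equivalents per nt).
    Library totals default to the sum of depths but can be overridden when the
    tracks come from a larger library than the one transcript shown.
    """

    transcript: str
    ip: np.ndarray
    input: np.ndarray
    length: int
    ip_total: float = field(default=0.0)
    input_total: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.ip = np.asarray(self.ip, dtype=float)
        self.input = np.asarray(self.input, dtype=float)
        if len(self.ip) != self.length or len(self.input) != self.length:
            raise ValueError(
                f"{self.transcript}: depth array length does not match "
                f"declared transcript length {self.length}"
            )
        if self.ip_total <= 0:
            self.ip_total = float(self.ip.sum())
        if self.input_total <= 0:
            self.input_total = float(self.input.sum())


# ---------------------------------------------------------------------------
# counts TSV
# ---------------------------------------------------------------------------

def read_counts(
    path: str | Path,
    metadata_path: str | Path | None = None,
    spike_prefix: str = SPIKE_PREFIX,
    spike_ids: Iterable[str] = (),
) -> CountMatrix:
    """Read a gene-by-sample counts TSV.

    Cells must be non-negative integers and gene ids unique. If
    ``metadata_path`` is None, a sidecar ``<path>.meta.tsv`` is joined when it
    exists.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups[:5]}")
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna()]
            raise ValueError(
                f"{path}: non-numeric count at gene {bad.index[0]!r}, sample {col!r}"
            )
        arr = vals.to_numpy()
        if np.any(arr != np.floor(arr)):
            gene = vals.index[arr != np.floor(arr)][0]
            raise ValueError(
                f"{path}: non-integer count at gene {gene!r}, sample {col!r}"
            )
        if np.any(arr < 0):
            gene = vals.index[arr < 0][0]
            raise ValueError(
                f"{path}: negative count at gene {gene!r}, sample {col!r}"
            )
    df = df.astype(np.int64)
    df.index = df.index.astype(str)

    meta = None
    if metadata_path is None:
        sidecar = path.with_suffix(path.suffix + ".meta.tsv")
        if sidecar.exists():
            metadata_path = sidecar
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)

    spike = df.index.to_series().str.startswith(spike_prefix) | df.index.isin(
        set(spike_ids)
    )
    return CountMatrix(counts=df, metadata=meta, spike_mask=spike)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write counts in canonical TSV form (gene index named 'gene')."""
    out = cm.counts.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", lineterminator="\n")
    if cm.metadata is not None:
        meta = cm.metadata.copy()
        meta.index.name = "sample"
        meta.to_csv(
            Path(str(path)).with_suffix(Path(str(path)).suffix + ".meta.tsv"),
            sep="\t",
            lineterminator="\n",
        )


# ---------------------------------------------------------------------------
# bedGraph / lengths / BED
# ---------------------------------------------------------------------------

def read_transcript_lengths(path: str | Path) -> dict[str, int]:
    """Two-column TSV: transcript id, length in nt (header optional)."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and not parts[1].lstrip("-").isdigit():
                continue  # header row
            tx, n = parts[0], int(parts[1])
            if n <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {tx}")
            if tx in lengths:
                raise ValueError(f"{path}:{lineno}: duplicate transcript {tx}")
            lengths[tx] = n
    return lengths


def _read_bedgraph_tracks(
    path: str | Path, lengths: Mapping[str, int]
) -> tuple[dict[str, np.ndarray], float | None]:
    tracks = {tx: np.zeros(n, dtype=float) for tx, n in lengths.items()}
    covered = {tx: np.zeros(n, dtype=bool) for tx, n in lengths.items()}
    declared_total: float | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if line.startswith("#library_total="):
                declared_total = float(line.split("=", 1)[1])
                continue
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            tx, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if tx not in lengths:
                raise ValueError(f"{path}:{lineno}: unknown transcript {tx!r}")
            if not (0 <= start < end <= lengths[tx]):
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) outside "
                    f"transcript {tx} of length {lengths[tx]}"
                )
            seg = slice(start, end)
            clash = covered[tx][seg] & (tracks[tx][seg] != value)
            if clash.any():
                raise ValueError(
                    f"{path}:{lineno}: overlapping intervals with conflicting "
                    f"values on {tx}"
                )
            tracks[tx][seg] = value
            covered[tx][seg] = True
    return tracks, declared_total


def read_bedgraph_pair(
    ip_path: str | Path,
    input_path: str | Path,
    lengths_path: str | Path,
    ip_total: float | None = None,
    input_total: float | None = None,
) -> list[CoveragePair]:
    """Read paired IP/input bedGraph tracks into dense per-nt depth arrays.

    Positions absent from a file have depth 0. Library totals come from the
    ``ip_total``/``input_total`` arguments if given, else from a
    ``#library_total=`` header comment in each file (written for tracks
    extracted from a larger library), else from the sum of depths.
    """
    lengths = read_transcript_lengths(lengths_path)
    ip_tracks, ip_declared = _read_bedgraph_tracks(ip_path, lengths)
    input_tracks, input_declared = _read_bedgraph_tracks(input_path, lengths)
    if ip_total is None:
        ip_total = ip_declared
    if input_total is None:
        input_total = input_declared
    ip_sum = sum(float(t.sum()) for t in ip_tracks.values())
    input_sum = sum(float(t.sum()) for t in input_tracks.values())
    pairs = []
    for tx, n in lengths.items():
        pairs.append(
            CoveragePair(
                transcript=tx,
                ip=ip_tracks[tx],
                input=input_tracks[tx],
                length=n,
                ip_total=ip_total if ip_total is not None else ip_sum,
                input_total=input_total if input_total is not None else input_sum,
            )
        )
    return pairs


def write_bedgraph(
    tracks: Mapping[str, np.ndarray],
    path: str | Path,
    library_total: float | None = None,
) -> None:
    """Write dense per-nt tracks as run-length-encoded bedGraph (zeros skipped).

    ``library_total`` is recorded as a ``#library_total=`` header comment when
    the tracks are a slice of a larger library.
    """
    with open(path, "w") as fh:
        if library_total is not None:
            total = int(library_total) if float(library_total).is_integer() else library_total
            fh.write(f"#library_total={total}\n")
        for tx in tracks:
            arr = np.asarray(tracks[tx], dtype=float)
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [arr.size]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v == 0:
                    continue
                sval = int(v) if float(v).is_integer() else v
                fh.write(f"{tx}\t{s}\t{e}\t{sval}\n")


def write_peaks_bed(peaks: Sequence, path: str | Path) -> None:
    """Write peaks as BED6: name peak_N, score = min(round(100*fold), 1000).

    Peaks must be sorted and non-overlapping within each transcript (merging
    is the caller's responsibility).
    """
    by_tx: dict[str, list] = {}
    for p in peaks:
        by_tx.setdefault(p.transcript, []).append(p)
    for tx, plist in by_tx.items():
        for a, b in zip(plist, plist[1:]):
            if b.start < a.end or a.start > b.start:
                raise ValueError(
                    f"peaks on {tx} are unsorted or overlapping: "
                    f"[{a.start},{a.end}) vs [{b.start},{b.end})"
                )
    with open(path, "w") as fh:
        fh.write("# BED6 peaks: transcript, start, end, name, score=min(round(100*fold),1000), strand\n")
        for i, p in enumerate(peaks, 1):
            score = min(round(100 * p.score), 1000)
            fh.write(f"{p.transcript}\t{p.start}\t{p.end}\tpeak_{i}\t{score}\t+\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED (>=3 columns) into a DataFrame with 0-based half-open intervals."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            row = {
                "transcript": parts[0],
                "start": int(parts[1]),
                "end": int(parts[2]),
            }
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4:
                row["score"] = float(parts[4])
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: term <tab> description <tab> genes..."""
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need term, desc, genes")
            term = parts[0]
            if term in collection:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            collection[term] = {g for g in parts[2:] if g}
    return collection


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
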