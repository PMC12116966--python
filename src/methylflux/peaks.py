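"""Sliding-window m6A peak calling from paired MeRIP IP/input coverage.

The caller scans each transcript with a 100-nt window advanced in 50-nt
steps, computes IP and input RPKM per window, and calls a window enriched
when the pseudocount-stabilized IP/input RPKM ratio reaches the fold
threshold (>= 4 by default, inclusive) and the window carries enough raw
coverage. Adjacent (overlapping or book-ended) enriched windows on a
transcript are merged into final peaks.

RPKM for a window is mean per-nt depth * 1e9 / library_total — the per-base
RPKM convention of coverage-track tools, under which a track of uniform
depth 1 from a library of one million reads scores 1000.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import CoveragePair

logger = logging.getLogger("methylflux")


@dataclass(frozen=True)
class WindowRecord:
    """One sliding window with its IP/input RPKM and enrichment fold.

    ``gate_ok`` records whether the window's raw IP+input coverage met the
    minimum read-equivalents gate; ``enriched`` additionally requires the
    fold threshold and is set by :func:`call_peaks` (or by
    :func:`window_enrichment` for its default threshold).
    """

    transcript: str
    start: int
    end: int
    ip_rpkm: float
    input_rpkm: float
    fold: float
    gate_ok: bool
    enriched: bool


@dataclass(frozen=True)
class Peak:
    transcript: str
    start: int
    end: int
    score: float  # max window fold within the peak
    n_windows: int


def window_rpkm(track: np.ndarray, start: int, end: int, library_total: float) -> float:
    """Per-base RPKM of ``track[start:end)`` given the track's library total."""
    if end <= start:
        raise ValueError(f"zero-length window [{start},{end})")
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    if start < 0 or end > len(track):
        raise ValueError(f"window [{start},{end}) outside track of length {len(track)}")
    mean_depth = float(np.mean(track[start:end]))
    return mean_depth * 1e9 / library_total


def window_starts(length: int, window_nt: int, step_nt: int) -> list[tuple[int, int]]:
    """Window intervals over a transcript: full windows at 0, step, 2*step, ...

    A terminal truncated window is kept only if it is at least step_nt long;
    shorter fragments would dominate fold estimates with too few positions.
    """
    out = []
    start = 0
    while start < length:
        end = min(start + window_nt, length)
        if end - start >= step_nt:
            out.append((start, end))
        if end == length:
            break
        start += step_nt
    return out


def window_enrichment(
    pair: CoveragePair,
    window_nt: int = 100,
    step_nt: int = 50,
    pseudo_rpkm: float = 0.5,
    min_window_reads: float = 10,
    min_fold: float = 4.0,
) -> list[WindowRecord]:
    """Compute per-window IP/input enrichment over one transcript.

    fold = (ip_rpkm + pseudo) / (input_rpkm + pseudo). Windows whose summed
    raw IP+input depth is below ``min_window_reads`` fail the coverage gate
    and are never enriched regardless of fold.
    """
    if window_nt < step_nt or step_nt < 1:
        raise ValueError("require window_nt >= step_nt >= 1")
    if pseudo_rpkm <= 0:
        raise ValueError("pseudo_rpkm must be > 0")
    if pair.length < step_nt:
        logger.warning(
            "%s: transcript length %d < step %d; no windows",
            pair.transcript, pair.length, step_nt,
        )
        return []
    records = []
    for start, end in window_starts(pair.length, window_nt, step_nt):
        ip_rpkm = window_rpkm(pair.ip, start, end, pair.ip_total)
        input_rpkm = window_rpkm(pair.input, start, end, pair.input_total)
        fold = (ip_rpkm + pseudo_rpkm) / (input_rpkm + pseudo_rpkm)
        raw = float(pair.ip[start:end].sum() + pair.input[start:end].sum())
        gate_ok = raw >= min_window_reads
        records.append(
            WindowRecord(
                transcript=pair.transcript,
                start=start,
                end=end,
                ip_rpkm=ip_rpkm,
                input_rpkm=input_rpkm,
                fold=fold,
                gate_ok=gate_ok,
                enriched=gate_ok and fold >= min_fold,
            )
        )
    return records


def call_peaks(windows: list[WindowRecord], min_fold: float = 4.0) -> list[Peak]:
    """Merge adjacent enriched windows into final peaks.

    A window is enriched when its coverage gate passed and fold >= min_fold
    (inclusive). Enriched windows on the same transcript that overlap or are
    book-ended merge into one peak spanning their union; the peak score is
    the maximum member fold. Windows must be sorted by start within each
    transcript.
    """
    by_tx: dict[str, list[WindowRecord]] = {}
    order: list[str] = []
    for w in windows:
        if w.transcript not in by_tx:
            order.append(w.transcript)
        by_tx.setdefault(w.transcript, []).append(w)

    peaks: list[Peak] = []
    for tx in order:
        ws = by_tx[tx]
        for a, b in zip(ws, ws[1:]):
            if b.start < a.start:
                raise ValueError(f"windows on {tx} are not sorted by start")
        current: list[WindowRecord] = []
        for w in ws:
            if not (w.gate_ok and w.fold >= min_fold):
                continue
            if current and w.start <= current[-1].end:  # overlap or book-ended
                current.append(w)
            else:
                if current:
                    peaks.append(_finish_peak(tx, current))
                current = [w]
        if current:
            peaks.append(_finish_peak(tx, current))
    return peaks


def _finish_peak(tx: str, members: list[WindowRecord]) -> Peak:
    return Peak(
        transcript=tx,
        start=min(w.start for w in members),
        end=max(w.end for w in members),
        score=max(w.fold for w in members),
        n_windows=len(members),
    )


@dataclass(frozen=True)
class PeakCoverageSummary:
    """Per-transcript summary over the union of its peak intervals."""

    transcript: str
    n_peaks: int
    peak_nt: int
    ip_rpkm: float   # mean IP RPKM within peaks
    mean_fold: float  # pseudocount-stabilized IP/input fold within peaks


def transcript_peak_coverage(
    peaks: list[Peak], pair: CoveragePair, pseudo_rpkm: float = 0.5
) -> PeakCoverageSummary:
    """Summarize peak coverage on one transcript.

    Statistics are computed over the union of the peak intervals, so
    splitting one peak into adjacent pieces covering the same union leaves
    the summary unchanged. A transcript with no peak reports zeros.
    """
    for p in peaks:
        if p.transcript != pair.transcript:
            raise ValueError(
                f"peak on {p.transcript!r} does not belong to {pair.transcript!r}"
            )
    mask = np.zeros(pair.length, dtype=bool)
    for p in peaks:
        mask[p.start : p.end] = True
    peak_nt = int(mask.sum())
    if peak_nt == 0:
        return PeakCoverageSummary(pair.transcript, 0, 0, 0.0, 0.0)
    idx = np.flatnonzero(mask)
    ip_rpkm = float(np.mean(pair.ip[idx])) * 1e9 / pair.ip_total
    input_rpkm = float(np.mean(pair.input[idx])) * 1e9 / pair.input_total
    mean_fold = (ip_rpkm + pseudo_rpkm) / (input_rpkm + pseudo_rpkm)
    return PeakCoverageSummary(pair.transcript, len(peaks), peak_nt, ip_rpkm, mean_fold)


def call_peaks_for_pairs(
    pairs: list[CoveragePair],
    window_nt: int = 100,
    step_nt: int = 50,
    min_fold: float = 4.0,
    pseudo_rpkm: float = 0.5,
    min_window_reads: float = 10,
) -> list[Peak]:
    """Window + call over a collection of transcripts (convenience wrapper)."""
    peaks: list[Peak] = []
    for pair in pairs:
        ws = window_enrichment(
            pair,
            window_nt=window_nt,
            step_nt=step_nt,
            pseudo_rpkm=pseudo_rpkm,
            min_window_reads=min_window_reads,
            min_fold=min_fold,
        )
        peaks.extend(call_peaks(ws, min_fold=min_fold))
    return peaks
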