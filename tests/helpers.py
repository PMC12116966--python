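"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation paths: the peak oracle
enumerates every window and merges by connected runs of the enriched union,
the hypergeometric oracle sums the combinatorial tail, and the DEG/stability
oracles re-apply the classification rules gene by gene.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_peaks(pair, window_nt=100, step_nt=50, pseudo=0.5,
                      min_reads=10, min_fold=4.0):
    """Enumerate all windows, mark enriched, merge via a position-union scan."""
    length = pair.length
    windows = []
    start = 0
    while start < length:
        end = min(start + window_nt, length)
        if end - start >= step_nt:
            ip_rpkm = pair.ip[start:end].mean() * 1e9 / pair.ip_total
            inp_rpkm = pair.input[start:end].mean() * 1e9 / pair.input_total
            fold = (ip_rpkm + pseudo) / (inp_rpkm + pseudo)
            raw = pair.ip[start:end].sum() + pair.input[start:end].sum()
            windows.append((start, end, fold, raw >= min_reads and fold >= min_fold))
        if end == length:
            break
        start += step_nt

    # union of enriched windows; peaks are maximal runs of covered positions
    covered = np.zeros(length, dtype=bool)
    for s, e, _, enr in windows:
        if enr:
            covered[s:e] = True
    peaks = []
    i = 0
    while i < length:
        if covered[i]:
            j = i
            while j < length and covered[j]:
                j += 1
            score = max(f for s, e, f, enr in windows if enr and s >= i and e <= j)
            n = sum(1 for s, e, f, enr in windows if enr and s >= i and e <= j)
            peaks.append((i, j, score, n))
            i = j
        else:
            i += 1
    return peaks


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for Hypergeometric(N, K, n) by direct combinatorial sum."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def bh_adjust(pvals):
    """Benjamini-Hochberg from its closed form: reversed cumulative minimum
    of p * m / rank over the sorted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def classify_brute(log2fc, p, mode, lfc_cut=1.0, fc_cut=1.5, p_cut=0.05):
    """Gene-by-gene re-application of the two DEG threshold rules."""
    out = []
    for lfc, pv in zip(log2fc, p):
        if mode == "log2fc":
            if lfc >= lfc_cut:
                out.append("up")
            elif lfc <= -lfc_cut:
                out.append("down")
            else:
                out.append("ns")
        else:
            fold = 2.0**lfc
            if pv < p_cut and fold > fc_cut:
                out.append("up")
            elif pv < p_cut and fold < 1.0 / fc_cut:
                out.append("down")
            else:
                out.append("ns")
    return out


def stability_brute(rows, ratio_cut=1.5, min_r2=0.5):
    """Row-wise stabilization rule: trustworthy fits, decaying control,
    slower treatment, half-life ratio above the cut."""
    calls = {}
    for gene, kc, r2c, kt, r2t in rows:
        ok_c = r2c >= min_r2 or kc == 0
        ok_t = r2t >= min_r2 or kt == 0
        if kt > 0:
            ratio = kc / kt
        elif kc > 0:
            ratio = math.inf
        else:
            ratio = 1.0
        calls[gene] = bool(ok_c and ok_t and kc > 0 and kt < kc and ratio >= ratio_cut)
    return calls


def fcm_objective(X, centroids, U, m):
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float((U**m * d2).sum())
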