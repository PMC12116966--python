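"""mRNA decay kinetics from actinomycin-D chase time courses.

After transcription shutoff, first-order decay gives
count(t) = count(0) * exp(-k t), so ln(count) is linear in time with slope
-k and half-life t1/2 = ln 2 / k. Because global mRNA abundance falls during
the chase, library-size normalization must be anchored to the ERCC spike-ins
(added per unit RNA, hence constant): spike-in size factors equalize spike
totals across samples, and an optional RUV-style factor removal strips
residual sample-level structure learned from the spike-in rows.

Stabilization between conditions is called from the ratio of half-lives
(treatment / control) with a fit-quality gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger("methylflux")

LOG_PSEUDO = 0.5  # added before log to handle zero counts at late timepoints


# ---------------------------------------------------------------------------
# spike-in normalization
# ---------------------------------------------------------------------------

def spike_in_size_factors(cm: CountMatrix) -> pd.Series:
    """Per-sample size factors from spike-in totals.

    factor_s = spike_total_s / geometric_mean(spike totals); dividing sample s
    by factor_s equalizes spike totals across samples, and the factors have
    geometric mean 1.
    """
    spikes = cm.spike_counts()
    if spikes.empty:
        raise ValueError("no spike-in rows flagged in the count matrix")
    totals = spikes.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero spike-in total: {bad}")
    log_totals = np.log(totals)
    return np.exp(log_totals - log_totals.mean()).rename("size_factor")


def normalize_by_factors(cm: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    """Counts divided column-wise by the per-sample factors (floats)."""
    return cm.counts.astype(float).div(factors, axis=1)


def estimate_unwanted_factors(
    log_counts: pd.DataFrame | np.ndarray,
    spike_mask: np.ndarray | pd.Series,
    k_factors: int = 1,
) -> np.ndarray:
    """Unwanted sample-level factors: top left singular vectors of the
    gene-centered spike-in submatrix (samples x k, orthonormal).

    Directions whose singular value is numerically zero carry no spike
    structure and are dropped, so a matrix whose controls are already clean
    yields no factors.
    """
    X = np.asarray(log_counts, dtype=float)
    mask = np.asarray(spike_mask, dtype=bool)
    n_samples, n_genes = X.shape
    if mask.shape[0] != n_genes:
        raise ValueError("spike_mask length must equal the number of gene columns")
    if k_factors < 1 or k_factors >= n_samples:
        raise ValueError("require 1 <= k_factors < number of samples")
    if mask.sum() < k_factors:
        raise ValueError("need at least k_factors spike-in genes")
    spikes = X[:, mask]
    spikes_c = spikes - spikes.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(spikes_c, full_matrices=False)
    floor = max(np.linalg.norm(X), 1.0) * 1e-12
    keep = s[:k_factors] > floor
    return U[:, :k_factors][:, keep]


def ruv_factor_removal(
    log_counts: pd.DataFrame | np.ndarray,
    spike_mask: np.ndarray | pd.Series,
    k_factors: int = 1,
    factors: np.ndarray | None = None,
) -> pd.DataFrame | np.ndarray:
    """Remove unwanted sample-level variation learned from spike-in rows.

    ``log_counts`` is samples x genes on a log scale. The unwanted factors —
    the top ``k_factors`` left singular vectors of the gene-centered spike-in
    submatrix, or ``factors`` if supplied — have their least-squares
    contribution subtracted from every gene column. For a fixed orthonormal
    factor basis this is a projection (idempotent); when the factors are
    re-estimated, controls that were exactly rank-k leave nothing to remove
    on a second pass, while noisy controls would surrender further noise
    directions. k_factors = 0 returns the input unchanged.
    """
    is_frame = isinstance(log_counts, pd.DataFrame)
    X = np.asarray(log_counts, dtype=float)
    if k_factors == 0 and factors is None:
        return log_counts
    W = factors if factors is not None else estimate_unwanted_factors(
        log_counts, spike_mask, k_factors
    )
    if W.shape[1] == 0:
        return log_counts
    Xc = X - X.mean(axis=0, keepdims=True)
    adjusted = X - W @ (W.T @ Xc)
    if is_frame:
        return pd.DataFrame(adjusted, index=log_counts.index, columns=log_counts.columns)
    return adjusted


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayFit:
    gene: str
    k: float          # decay constant, 1/h (clipped at 0)
    half_life: float  # ln2/k hours; inf when k == 0
    r2: float
    n_points: int


def fit_decay(
    normalized_counts: pd.DataFrame,
    timepoints,
    log_input: bool = False,
) -> pd.DataFrame:
    """Fit first-order decay per gene by OLS of ln(count + 0.5) on time.

    ``normalized_counts`` is genes x samples with ``timepoints`` giving the
    hour of each column; replicate columns at the same timepoint are averaged
    after normalization. Positive slopes (apparent synthesis, impossible
    under ActD) are clipped to k = 0. All-zero genes are reported as NaN rows.
    With ``log_input`` the values are taken as already ln-transformed (used
    after RUV adjustment).

    Returns a DataFrame indexed by gene: k, half_life, r2, n_points.
    """
    t = np.asarray(timepoints, dtype=float)
    if t.shape[0] != normalized_counts.shape[1]:
        raise ValueError("timepoints length must match the number of columns")
    if len(np.unique(t)) < 2 or 0.0 not in t:
        raise ValueError("need >=2 distinct timepoints including 0")

    X = normalized_counts.to_numpy(dtype=float)
    # average replicates per timepoint
    uniq = np.unique(t)
    means = np.column_stack([X[:, t == u].mean(axis=1) for u in uniq])
    logy = means if log_input else np.log(np.maximum(means, 0.0) + LOG_PSEUDO)

    tt = uniq - uniq.mean()
    denom = float((tt**2).sum())
    yc = logy - logy.mean(axis=1, keepdims=True)
    slope = (yc @ tt) / denom
    ss_tot = (yc**2).sum(axis=1)
    ss_res = ss_tot - slope**2 * denom
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    k = np.maximum(0.0, -slope)
    with np.errstate(divide="ignore"):
        half_life = np.where(k > 0, np.log(2) / np.where(k > 0, k, 1.0), np.inf)

    out = pd.DataFrame(
        {
            "k": k,
            "half_life": half_life,
            "r2": r2,
            "n_points": len(uniq),
        },
        index=normalized_counts.index.rename("gene"),
    )
    all_zero = (X <= 0).all(axis=1) if not log_input else np.zeros(len(X), dtype=bool)
    if all_zero.any():
        logger.warning("%d all-zero genes skipped in decay fit", int(all_zero.sum()))
        out.loc[all_zero, ["k", "half_life", "r2"]] = np.nan
    return out


def decay_pipeline(
    cm: CountMatrix,
    timepoints=None,
    ruv_k: int = 1,
) -> pd.DataFrame:
    """Spike-in size factors -> optional RUV factor removal -> decay fits.

    ``timepoints`` defaults to the metadata's timepoint_h column. Only
    non-spike genes are fitted.
    """
    if timepoints is None:
        if cm.metadata is None or "timepoint_h" not in cm.metadata.columns:
            raise ValueError("timepoints not given and metadata lacks timepoint_h")
        timepoints = cm.metadata.loc[cm.counts.columns, "timepoint_h"].to_numpy(float)
    factors = spike_in_size_factors(cm)
    norm = normalize_by_factors(cm, factors)
    if ruv_k > 0:
        logn = np.log(norm + LOG_PSEUDO)
        adjusted = ruv_factor_removal(
            logn.T, cm.spike_mask.to_numpy(), k_factors=ruv_k
        ).T
        fits = fit_decay(adjusted.loc[~cm.spike_mask], timepoints, log_input=True)
    else:
        fits = fit_decay(norm.loc[~cm.spike_mask], timepoints)
    return fits


# ---------------------------------------------------------------------------
# stabilization calls
# ---------------------------------------------------------------------------

def compare_stability(
    fits_ctrl: pd.DataFrame,
    fits_trt: pd.DataFrame,
    ratio_cut: float = 1.5,
    min_r2: float = 0.5,
) -> pd.DataFrame:
    """Classify genes whose degradation is inhibited in treatment vs control.

    A gene is stabilized when both fits are trustworthy (r2 >= min_r2, or
    k = 0 with a flat profile, which carries no decay signal to doubt),
    control actually decays (k_ctrl > 0), treatment decays more slowly
    (k_trt < k_ctrl), and the half-life ratio treatment/control >= ratio_cut.
    Output is sorted by half-life ratio, descending.
    """
    genes = fits_ctrl.index.intersection(fits_trt.index)
    if genes.empty:
        raise ValueError("no genes shared between the two fit tables")
    c = fits_ctrl.loc[genes]
    t = fits_trt.loc[genes]

    def trustworthy(f: pd.DataFrame) -> pd.Series:
        return (f["r2"] >= min_r2) | (f["k"] == 0)

    kc, kt = c["k"].to_numpy(), t["k"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        # hl_trt / hl_ctrl == k_ctrl / k_trt; both-flat genes get ratio 1
        hl_ratio = np.where(
            kt > 0, kc / kt, np.where(kc > 0, np.inf, np.where(kc == 0, 1.0, np.nan))
        )
    stabilized = (
        trustworthy(c).to_numpy()
        & trustworthy(t).to_numpy()
        & (c["k"].to_numpy() > 0)
        & (t["k"].to_numpy() < c["k"].to_numpy())
        & (hl_ratio >= ratio_cut)
    )
    out = pd.DataFrame(
        {
            "k_ctrl": c["k"].to_numpy(),
            "k_trt": t["k"].to_numpy(),
            "hl_ratio": hl_ratio,
            "stabilized": stabilized,
        },
        index=genes.rename("gene"),
    )
    return out.sort_values("hl_ratio", ascending=False, kind="mergesort")
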