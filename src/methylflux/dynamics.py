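"""Time-course expression analysis: filtering, normalization, differential
expression, set overlaps, PCA trajectories, and fuzzy c-means clustering.

Differential expression here is a deliberately simple, fully documented
procedure: median-of-ratios size factors, log2 fold changes on normalized
means with a +1 pseudocount, two-sided Welch tests on log2(norm + 1), and
Benjamini-Hochberg adjustment. With n = 2 replicates per condition the
Welch p-values are low-powered; the output header flags this.

Clustering follows the Mfuzz recipe: per-gene standardized temporal profiles
(mean 0, sd 1 across timepoints) partitioned by fuzzy c-means, giving soft
memberships that sum to 1 per gene.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("methylflux")

DE_HEADER_NOTE = (
    "log2fc on normalized means (+1 pseudocount); p from two-sided Welch test "
    "on log2(norm+1) -- low power at n=2 replicates; padj by Benjamini-Hochberg"
)


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def filter_low_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the genes with total count > 1, preserving order."""
    kept = counts.loc[counts.sum(axis=1) > 1]
    if kept.empty:
        logger.warning("low-expression filter removed every gene")
    return kept


def median_of_ratios_normalize(
    counts: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size-factor normalization.

    For genes with nonzero counts in every sample, each sample's factor is the
    median of count / (per-gene geometric mean). Returns the normalized matrix
    and the factors.
    """
    X = counts.to_numpy(dtype=float)
    ok = (X > 0).all(axis=1)
    if not ok.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logX = np.log(X[ok])
    log_geo = logX.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logX - log_geo, axis=0))
    factors = pd.Series(factors, index=counts.columns, name="size_factor")
    return counts.div(factors, axis=1), factors


# ---------------------------------------------------------------------------
# differential expression and classification
# ---------------------------------------------------------------------------

def differential_expression(
    norm_counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Per-gene log2 fold change (B vs A) with Welch p-values and BH padj.

    log2fc = log2((mean_B + 1) / (mean_A + 1)) on normalized counts. With
    fewer than two samples in either group p-values are reported missing and
    classification falls back to fold change only.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups share samples")
    for s in itertools.chain(group_a, group_b):
        if s not in norm_counts.columns:
            raise ValueError(f"unknown sample {s!r}")
    A = norm_counts[group_a].to_numpy(dtype=float)
    B = norm_counts[group_b].to_numpy(dtype=float)
    log2fc = np.log2((B.mean(axis=1) + 1.0) / (A.mean(axis=1) + 1.0))

    if len(group_a) >= 2 and len(group_b) >= 2:
        res = stats.ttest_ind(
            np.log2(B + 1.0), np.log2(A + 1.0), axis=1, equal_var=False
        )
        p = np.asarray(res.pvalue, dtype=float)
        # zero within-group variance makes Welch undefined; identical means
        # are a clean p = 1
        degenerate = np.isnan(p)
        same = degenerate & np.isclose(
            np.log2(B + 1.0).mean(axis=1), np.log2(A + 1.0).mean(axis=1)
        )
        p[same] = 1.0
    else:
        p = np.full(norm_counts.shape[0], np.nan)

    padj = np.full_like(p, np.nan)
    tested = ~np.isnan(p)
    if tested.any():
        padj[tested] = stats.false_discovery_control(p[tested], method="bh")
    out = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "padj": padj},
        index=norm_counts.index.rename("gene"),
    )
    out.attrs["note"] = DE_HEADER_NOTE
    return out


def classify_deg(
    table: pd.DataFrame,
    mode: str,
    lfc_cut: float = 1.0,
    fc_cut: float = 1.5,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Attach an up/down/ns class under one of the two stated threshold rules.

    mode "log2fc": up iff log2fc >= lfc_cut, down iff log2fc <= -lfc_cut
    (inclusive). mode "fc_p": up iff fold > fc_cut and p < p_cut (both
    strict), down symmetric with fold < 1/fc_cut.
    """
    out = table.copy()
    lfc = out["log2fc"].to_numpy(dtype=float)
    if mode == "log2fc":
        klass = np.where(lfc >= lfc_cut, "up", np.where(lfc <= -lfc_cut, "down", "ns"))
    elif mode == "fc_p":
        if "p" not in out.columns or out["p"].isna().all():
            raise ValueError("mode fc_p requires p-values")
        p = out["p"].to_numpy(dtype=float)
        fold = 2.0**lfc
        sig = p < p_cut
        klass = np.where(
            sig & (fold > fc_cut),
            "up",
            np.where(sig & (fold < 1.0 / fc_cut), "down", "ns"),
        )
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'log2fc' or 'fc_p')")
    out["klass"] = klass
    return out


# ---------------------------------------------------------------------------
# set overlaps (Venn)
# ---------------------------------------------------------------------------

def overlap_sets(
    named_sets: dict[str, set[str]],
) -> tuple[pd.DataFrame, set[str]]:
    """Counts for every region of the Venn partition of 2-4 named sets.

    Each region is the subset of elements belonging to exactly the named
    member sets and no others. Returns the region table and the common
    intersection of all sets.
    """
    names = list(named_sets)
    if not (2 <= len(names) <= 4):
        raise ValueError("overlap_sets supports 2 to 4 sets")
    rows = []
    for members in range(1, 2 ** len(names)):
        inside = [n for i, n in enumerate(names) if members >> i & 1]
        outside = [n for n in names if n not in inside]
        region = set.intersection(*(named_sets[n] for n in inside))
        for n in outside:
            region -= named_sets[n]
        rows.append(
            {
                "region": "&".join(inside),
                "n_sets": len(inside),
                "count": len(region),
            }
        )
    common = set.intersection(*named_sets.values())
    return pd.DataFrame(rows), common


# ---------------------------------------------------------------------------
# PCA trajectory
# ---------------------------------------------------------------------------

def pca_trajectory(
    norm_counts: pd.DataFrame,
    n_top_variable: int = 500,
    n_components: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on the most variable genes of log2(norm + 1).

    Genes are centered; components are oriented so each one's
    largest-magnitude gene loading is positive, fixing the sign convention.
    Returns sample coordinates and the per-component variance fractions.
    """
    if norm_counts.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    if norm_counts.shape[0] < 2:
        raise ValueError("PCA needs at least 2 genes")
    L = np.log2(norm_counts.to_numpy(dtype=float) + 1.0)
    var = L.var(axis=1)
    top = np.argsort(var, kind="stable")[::-1][: min(n_top_variable, len(var))]
    M = L[np.sort(top)]  # genes x samples
    M = M - M.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    n_comp = min(
        n_components or M.shape[1] - 1, len(s), M.shape[1] - 1
    )
    # sign fix: the largest-|loading| entry of each component is positive
    for j in range(n_comp):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    coords = (Vt[:n_comp].T * s[:n_comp])
    total_var = float((s**2).sum())
    var_frac = (s[:n_comp] ** 2) / total_var if total_var > 0 else np.zeros(n_comp)
    coords_df = pd.DataFrame(
        coords,
        index=norm_counts.columns.rename("sample"),
        columns=[f"PC{j + 1}" for j in range(n_comp)],
    )
    return coords_df, var_frac


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------

@dataclass
class ClusterModel:
    """Fuzzy c-means result: centroids (c x T), memberships (G x c)."""

    centroids: np.ndarray
    memberships: pd.DataFrame
    fuzzifier: float
    seed: int
    objective: float
    n_iter: int
    objective_history: list[float] = field(default_factory=list)

    @property
    def hard_labels(self) -> pd.Series:
        """argmax membership per gene; ties resolve to the lowest index."""
        return pd.Series(
            np.argmax(self.memberships.to_numpy(), axis=1),
            index=self.memberships.index,
            name="cluster",
        )


def standardize_profiles(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-score across timepoints; zero-variance genes are dropped."""
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance genes", int((~keep).sum()))
    X = X[keep]
    Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    return pd.DataFrame(Z, index=profiles.index[keep], columns=profiles.columns)


def _fcm_objective(X, centroids, U, m):
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return float((U**m * d2).sum())


def fuzzy_cmeans(
    standardized_profiles: pd.DataFrame,
    c: int,
    fuzzifier: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ClusterModel:
    """Fuzzy c-means clustering of standardized temporal profiles.

    Standard alternating updates: centroid_j = sum_i u_ij^m x_i / sum_i u_ij^m
    and u_ij proportional to d_ij^(-2/(m-1)), iterated until the objective
    sum_ij u_ij^m d_ij^2 changes by less than ``tol`` or ``max_iter`` is hit.
    Memberships are initialized from the seed, so the model is reproducible.
    A gene sitting exactly on one or more centroids gets its membership split
    uniformly over those centroids.
    """
    X = standardized_profiles.to_numpy(dtype=float)
    G, T = X.shape
    if c < 1:
        raise ValueError("c must be >= 1")
    if c > G:
        raise ValueError(f"c = {c} exceeds the number of genes {G}")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    if np.any(X.std(axis=1) == 0):
        raise ValueError("zero-variance profile present; standardize/filter first")

    m = float(fuzzifier)
    rng = np.random.default_rng(seed)
    U = rng.random((G, c))
    U /= U.sum(axis=1, keepdims=True)

    prev = np.inf
    history: list[float] = []
    exponent = 2.0 / (m - 1.0)
    for it in range(1, max_iter + 1):
        Um = U**m
        centroids = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        obj = float((Um * d2).sum())
        history.append(obj)
        zero = d2 <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))  # == d^(-2/(m-1))
            U = np.where(
                zero.any(axis=1, keepdims=True),
                zero / np.maximum(zero.sum(axis=1, keepdims=True), 1),
                inv / inv.sum(axis=1, keepdims=True),
            )
        if abs(prev - obj) < tol:
            break
        prev = obj

    memberships = pd.DataFrame(
        U,
        index=standardized_profiles.index.rename("gene"),
        columns=[f"cluster_{j}" for j in range(c)],
    )
    return ClusterModel(
        centroids=centroids,
        memberships=memberships,
        fuzzifier=m,
        seed=seed,
        objective=history[-1],
        n_iter=len(history),
        objective_history=history,
    )
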