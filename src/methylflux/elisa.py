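"""m6A ELISA quantification.

A linear standard curve OD = slope * ng + intercept is fitted to the kit's
positive-control dilution series (0.02-0.4 ng/well); sample optical densities
are inverted through the curve and expressed as
m6A% = (m6A amount / input mRNA amount) x 100, with 200 ng of immobilized
mRNA as the default input. Amounts inferred below the curve intercept are
floored at zero and flagged below-detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class StandardCurve:
    slope: float      # OD per ng
    intercept: float  # OD
    r2: float


@dataclass(frozen=True)
class ElisaResult:
    amount_ng: float
    percent: float
    below_detection: bool


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """OLS line through (ng, OD) standards.

    Needs at least two distinct ng values; a non-positive slope means the
    assay failed and is rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >=2 (ng, OD) standard points")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 2:
        raise ValueError("standards need >=2 distinct ng values")
    xc, yc = x - x.mean(), y - y.mean()
    slope = float((xc * yc).sum() / (xc**2).sum())
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float((yc**2).sum())
    ss_res = float(((y - slope * x - intercept) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if slope <= 0:
        raise ValueError(f"failed assay: standard-curve slope {slope:.4g} <= 0")
    return StandardCurve(slope=slope, intercept=intercept, r2=r2)


def m6a_percent(
    od_sample: float, curve: StandardCurve, input_ng: float = 200.0
) -> ElisaResult:
    """Convert a sample OD into m6A percentage of the input mRNA.

    amount_ng = (OD - intercept) / slope, floored at 0 (below-detection);
    percent = amount_ng / input_ng x 100.
    """
    if input_ng <= 0:
        raise ValueError("input_ng must be > 0")
    if curve.slope <= 0:
        raise ValueError("invalid standard curve (slope <= 0)")
    amount = (od_sample - curve.intercept) / curve.slope
    below = amount < 0
    amount = max(amount, 0.0)
    return ElisaResult(
        amount_ng=amount,
        percent=amount / input_ng * 100.0,
        below_detection=bool(below),
    )
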