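"""qPCR quantification of DNA excision via log-linear standard curves.

A standard curve Ct = intercept + slope * log10(quantity) is fitted by
ordinary least squares to calibration mixtures of known composition;
sample Ct values are inverted through it.  The excision fraction is
N_Lox / N_Total where the edited-target quantity (N_Lox) and the total
template quantity (N_Total, via a control-locus assay) are each read off
their own curve.  Zero-quantity calibration points never amplify and are
excluded from the fit; a NaN Ct is the no-amplification marker
throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "ExcisionEstimate",
    "fit_standard_curve",
    "quantity_from_ct",
    "excision_fraction",
]


@dataclass(frozen=True)
class StandardCurve:
    """Fitted log-linear calibration: Ct = intercept + slope log10(q)."""

    intercept: float
    slope: float
    r_squared: float
    n_points: int
    n_excluded: int = 0
    warning: Optional[str] = None

    @property
    def amplification_efficiency(self) -> float:
        """10**(-1/slope) - 1; 1.0 means perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def valid(self) -> bool:
        return self.slope < 0


def _as_pairs(calibration) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(calibration, pd.DataFrame):
        q = calibration["known_quantity"].to_numpy(dtype=float)
        ct = calibration["Ct"].to_numpy(dtype=float)
    else:
        arr = np.asarray(list(calibration), dtype=float)
        q, ct = arr[:, 0], arr[:, 1]
    return q, ct


def fit_standard_curve(calibration) -> StandardCurve:
    """OLS fit of Ct on log10(known_quantity).

    ``calibration`` is a DataFrame with columns ``known_quantity``/``Ct``
    or a sequence of (quantity, Ct) pairs.  Points with quantity <= 0 or
    a no-amplification marker (NaN Ct) are excluded and counted; a
    non-negative fitted slope attaches a warning to the curve.
    """
    q, ct = _as_pairs(calibration)
    usable = (q > 0) & np.isfinite(ct)
    n_excluded = int((~usable).sum())
    q, ct = q[usable], ct[usable]
    if q.size < 2:
        raise ValueError(f"only {q.size} usable calibration points; need >= 2")
    res = stats.linregress(np.log10(q), ct)
    warn = None
    if res.slope >= 0:
        warn = f"fitted slope {res.slope:.4g} is not negative; curve is not usable for inversion"
        warnings.warn(warn)
    return StandardCurve(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        n_points=int(q.size),
        n_excluded=n_excluded,
        warning=warn,
    )


def quantity_from_ct(ct: float, curve: StandardCurve) -> float:
    """Invert a Ct through the curve: q = 10**((Ct - intercept)/slope).

    A no-amplification marker (NaN) maps to quantity 0.
    """
    if not curve.valid:
        raise ValueError("standard curve has a non-negative slope; cannot invert")
    if ct is None or (isinstance(ct, float) and math.isnan(ct)):
        return 0.0
    return 10.0 ** ((float(ct) - curve.intercept) / curve.slope)


@dataclass(frozen=True)
class ExcisionEstimate:
    """Edited and total template quantities and their ratio.

    ``fraction`` may exceed 1 because both quantities carry measurement
    error; it is flagged, never clipped.
    """

    n_lox: float
    n_total: float
    fraction: float
    over_one: bool

    def __post_init__(self) -> None:
        if self.n_lox < 0 or self.n_total < 0:
            raise ValueError("template quantities must be >= 0")


def _mean_ct(ct) -> float:
    """Average replicate Cts; all-NaN (no amplification) stays NaN."""
    arr = np.atleast_1d(np.asarray(ct, dtype=float))
    finite = arr[np.isfinite(arr)]
    return float(finite.mean()) if finite.size else float("nan")


def excision_fraction(
    sample_ct_lox,
    curve_lox: StandardCurve,
    sample_ct_total,
    curve_total: StandardCurve,
) -> ExcisionEstimate:
    """N_Lox / N_Total from the two assays' Cts and standard curves.

    Replicate Cts are arithmetic-averaged before inversion.  A
    no-amplification edited-target assay gives fraction 0; a zero total
    quantity is an error.
    """
    n_lox = quantity_from_ct(_mean_ct(sample_ct_lox), curve_lox)
    n_total = quantity_from_ct(_mean_ct(sample_ct_total), curve_total)
    if n_total == 0:
        raise ValueError("total-template assay did not amplify; N_Total = 0")
    frac = n_lox / n_total
    return ExcisionEstimate(n_lox=n_lox, n_total=n_total, fraction=frac, over_one=frac > 1)
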