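"""Standard-curve fitting: amplification efficiency and R² from dilution series.

A qPCR assay's amplification efficiency E is estimated from a serial
dilution of template: Ct regressed on log10 relative input is linear with
slope ``-1/log10(1 + E/100)``, so

    E = (10^(-1/slope) - 1) x 100%

A perfect doubling per cycle (E = 100%) corresponds to a slope of
-1/log10(2) ~ -3.32 cycles per tenfold dilution.  R² is reported as the
squared Pearson correlation of the fitted line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ct_io import DilutionSeries

__all__ = ["StandardCurveFit", "fit_standard_curve", "efficiency_from_slope"]


@dataclass
class StandardCurveFit:
    """OLS fit of Ct on log10 input quantity for one assay.

    ``efficiency_pct`` is NaN and ``valid`` False when the slope is
    non-negative (no amplification signal; the efficiency formula does not
    apply).
    """

    gene: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float
    valid: bool


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency (%) from a standard-curve slope.

    Evaluates ``(10^(-1/slope) - 1) x 100`` exactly; requires slope < 0.
    Efficiency decreases strictly as the slope steepens (|slope| grows).
    """
    if not np.isfinite(slope) or slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def fit_standard_curve(d: DilutionSeries) -> StandardCurveFit:
    """Fit the dilution series by ordinary least squares.

    Requires >= 3 points with distinct log10 quantities (enforced by the
    :class:`~refstab.ct_io.DilutionSeries` container).  A non-negative slope
    is returned as a flagged fit with efficiency marked invalid rather than
    an exception, so batch screening can report the failing assay.
    """
    res = stats.linregress(d.log10_quantity, d.ct)
    slope, intercept = float(res.slope), float(res.intercept)
    r_squared = float(res.rvalue**2)
    if slope < 0:
        eff = efficiency_from_slope(slope)
        return StandardCurveFit(d.gene, slope, intercept, r_squared, eff, True)
    return StandardCurveFit(d.gene, slope, intercept, r_squared, float("nan"), False)
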