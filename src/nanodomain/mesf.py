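"""Bead-calibrated molecular counting (MESF quantitation).

MESF beads (Molecules of Equivalent Soluble Fluorochrome) map flow
cytometry fluorescence intensity to absolute fluorophore numbers.  A
least-squares line is fitted to log10(MFI) versus log10(MESF) across bead
populations; sample intensities are then inverted through the line to
molecules per cell.  This is the orthogonal check on the localization-based
antibody-per-cell estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class StandardCurve:
    """log10(MFI) = slope * log10(MESF) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    mesf_range: tuple
    mfi_range: tuple


class Quantification(NamedTuple):
    molecules: float
    extrapolated: bool


def fit_mesf_curve(bead_mfi, bead_mesf) -> StandardCurve:
    """Least-squares line in log-log space through the bead populations.

    Requires >= 2 beads with positive MFI and MESF values; the fitted slope
    must be positive (more fluorophores may never read dimmer).
    """
    mfi = np.asarray(bead_mfi, dtype=float)
    mesf = np.asarray(bead_mesf, dtype=float)
    if mfi.shape != mesf.shape or mfi.ndim != 1:
        raise ValueError("bead_mfi and bead_mesf must be equal-length 1D")
    if len(mfi) < 2:
        raise ValueError("need at least 2 bead populations")
    if np.any(mfi <= 0) or np.any(mesf <= 0):
        raise ValueError("bead values must be positive")
    res = stats.linregress(np.log10(mesf), np.log10(mfi))
    if res.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return StandardCurve(slope=float(res.slope),
                         intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2),
                         mesf_range=(float(mesf.min()), float(mesf.max())),
                         mfi_range=(float(mfi.min()), float(mfi.max())))


def quantify(curve: StandardCurve, sample_mfi: float,
             blank_mfi: float = 0.0) -> Quantification:
    """Invert the standard curve for one sample.

    molecules = 10 ** ((log10(MFI - blank) - intercept) / slope).
    Values outside the calibrated bead range are returned with the
    ``extrapolated`` flag set.
    """
    net = float(sample_mfi) - float(blank_mfi)
    if net <= 0:
        raise ValueError("sample MFI must exceed the blank")
    molecules = 10.0 ** ((np.log10(net) - curve.intercept) / curve.slope)
    extrapolated = not (curve.mfi_range[0] <= net <= curve.mfi_range[1])
    if extrapolated:
        warnings.warn("sample outside the calibrated bead range; "
                      "extrapolating", UserWarning, stacklevel=2)
    return Quantification(float(molecules), extrapolated)


class MESFCalibration(RegressorMixin, BaseEstimator):
    """Scikit-learn style wrapper around the MESF standard curve.

    ``fit(mfi, mesf)`` fits the log-log line; ``predict(mfi)`` returns
    molecules per event.  Fitted attributes: ``slope_``, ``intercept_``,
    ``r_squared_``, ``curve_``.
    """

    def __init__(self, blank_mfi: float = 0.0):
        self.blank_mfi = blank_mfi

    def fit(self, X, y):
        mfi = np.asarray(X, dtype=float).ravel() - self.blank_mfi
        self.curve_ = fit_mesf_curve(mfi, y)
        self.slope_ = self.curve_.slope
        self.intercept_ = self.curve_.intercept
        self.r_squared_ = self.curve_.r_squared
        return self

    def predict(self, X):
        check_is_fitted(self, "curve_")
        mfi = np.asarray(X, dtype=float).ravel()
        return np.array([quantify(self.curve_, v, self.blank_mfi).molecules
                         for v in mfi])


__all__ = ["StandardCurve", "Quantification", "fit_mesf_curve", "quantify",
           "MESFCalibration"]
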