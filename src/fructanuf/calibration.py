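"""Estimation of flux-model parameters and rejection correlations.

Two calibration steps feed the batch simulator:

1. **Limiting-flux parameters.**  Measuring permeate flux J against bulk
   concentration C (fixed TMP, temperature and crossflow) and regressing
   J on ln(C) gives the film-theory line ``J = a + b ln C``; the
   mass-transfer coefficient is ``k = -b`` and the limit concentration is
   the root of the line, ``C_lim = exp(-a/b)``.

2. **Rejection vs. feed make-up.**  The apparent rejection of each
   fructan fraction depends on the feed FOS:Fc ratio.  Over the observed
   ratio range the FOS rejection falls roughly linearly while the Fc
   rejection is nearly constant, so the default correlation is linear for
   FOS and a constant mean for Fc; both forms are selectable per solute.

A scoring helper compares simulated concentration trajectories with timed
observations through per-series sums of squared errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .core import sum_squared_error
from .dynamics import FluxModelParams, UFTrajectory, concentration_profiles

__all__ = [
    "FluxCurve",
    "LimitingFluxCalibrator",
    "fit_flux_params",
    "RejectionCorrelation",
    "fit_rejection_correlation",
    "validate_profiles",
]

logger = logging.getLogger(__name__)

#: Density used to convert mass flux (kg h^-1 m^-2) to velocity (m s^-1);
#: dilute-solution convention (permeate treated as water).
PERMEATE_DENSITY = 1000.0


@dataclass(frozen=True)
class FluxCurve:
    """Permeate flux versus bulk concentration at fixed operating conditions.

    ``flux_unit`` 'm_s' for velocities or 'kg_h_m2' for mass fluxes (the
    latter converted internally assuming dilute permeate).
    """

    conc: tuple[float, ...]
    flux: tuple[float, ...]
    flux_unit: Literal["m_s", "kg_h_m2"] = "m_s"

    def __post_init__(self) -> None:
        c = np.asarray(self.conc, dtype=float)
        j = np.asarray(self.flux, dtype=float)
        if c.size != j.size:
            raise ValueError("conc and flux must have equal length")
        if c.size < 3:
            raise ValueError("a flux curve needs at least 3 points")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if np.unique(c).size != c.size:
            raise ValueError("concentrations must be distinct")

    def flux_m_s(self) -> np.ndarray:
        j = np.asarray(self.flux, dtype=float)
        if self.flux_unit == "kg_h_m2":
            logger.info("converting flux from kg h^-1 m^-2 assuming permeate density "
                        "%.0f kg m^-3", PERMEATE_DENSITY)
            return j / (3600.0 * PERMEATE_DENSITY)
        return j


class LimitingFluxCalibrator(RegressorMixin, BaseEstimator):
    """Least-squares fit of the film-theory line J = a + b ln(C).

    Attributes
    ----------
    k_ : float
        Mass-transfer coefficient, m s^-1 (= -slope).
    c_lim_ : float
        Limit concentration, kg m^-3 (root of the fitted line).
    r2_ : float
        Coefficient of determination of the log-linear fit.
    residuals_ : ndarray
        Per-point flux residuals, m s^-1.
    """

    def fit(self, C, J):
        c = np.asarray(C, dtype=float).ravel()
        j = np.asarray(J, dtype=float).ravel()
        if c.size != j.size or c.size < 2:
            raise ValueError("need >= 2 paired (C, J) points")
        if c.max() / c.min() < 2 and c.size > 2:
            logger.warning("flux-curve concentration span < 2x; C_lim extrapolation "
                           "will be poorly conditioned")
        X = np.column_stack([np.ones_like(c), np.log(c)])
        (a, b), *_ = np.linalg.lstsq(X, j, rcond=None)
        if b >= 0:
            raise ValueError(
                "non-negative slope of J vs ln(C): flux must fall with concentration "
                "under the limiting-flux model"
            )
        self.intercept_ = float(a)
        self.slope_ = float(b)
        self.k_ = float(-b)
        self.c_lim_ = float(np.exp(-a / b))
        fitted = X @ np.array([a, b])
        self.residuals_ = j - fitted
        tss = float(np.sum((j - j.mean()) ** 2))
        self.r2_ = 1.0 - float(self.residuals_ @ self.residuals_) / tss if tss > 0 else np.nan
        return self

    def predict(self, C):
        check_is_fitted(self, "k_")
        c = np.asarray(C, dtype=float)
        return self.intercept_ + self.slope_ * np.log(c)

    def to_params(self, driving_solute: str = "fc") -> FluxModelParams:
        check_is_fitted(self, "k_")
        return FluxModelParams(k=self.k_, c_lim=self.c_lim_, driving_solute=driving_solute)


def fit_flux_params(curve: FluxCurve) -> FluxModelParams:
    """Fit (k, C_lim) from a flux curve; see :class:`LimitingFluxCalibrator`."""
    cal = LimitingFluxCalibrator().fit(np.asarray(curve.conc), curve.flux_m_s())
    return cal.to_params()


@dataclass(frozen=True)
class RejectionCorrelation:
    """Per-solute apparent rejection as a function of feed FOS:Fc ratio.

    Each solute's rejection is either ``slope * ratio + intercept``
    (linear form) or a constant (``slope = 0``).  Predictions are clipped
    to [0, 1]; clipping is logged because it signals extrapolation beyond
    the calibrated ratio range.
    """

    slope: dict[str, float]
    intercept: dict[str, float]

    def predict(self, ratio: float, solute: str) -> float:
        raw = self.slope[solute] * ratio + self.intercept[solute]
        clipped = float(np.clip(raw, 0.0, 1.0))
        if clipped != raw:
            logger.warning("rejection for %s at ratio %.3f clipped from %.4f to %.4f",
                           solute, ratio, raw, clipped)
        return clipped


def fit_rejection_correlation(
    points: Sequence[tuple[float, float, float]],
    form: dict[str, str] | None = None,
) -> RejectionCorrelation:
    """Fit the rejection-vs-ratio correlation from (ratio, Ro_fos, Ro_fc) points.

    Parameters
    ----------
    points : sequence of (ratio, Ro_FOS, Ro_Fc)
    form : dict mapping 'fos'/'fc' to 'linear' or 'constant'
        Defaults to linear for FOS (its rejection falls markedly with the
        ratio) and constant for Fc (nearly flat over the observed range).
    """
    form = {"fos": "linear", "fc": "constant", **(form or {})}
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("points must be (ratio, Ro_fos, Ro_fc) triples")
    ratio = arr[:, 0]
    slope: dict[str, float] = {}
    intercept: dict[str, float] = {}
    for solute, col in (("fos", arr[:, 1]), ("fc", arr[:, 2])):
        if form[solute] == "constant":
            slope[solute] = 0.0
            intercept[solute] = float(col.mean())
        elif form[solute] == "linear":
            if arr.shape[0] < 2:
                raise ValueError("linear form needs at least 2 points")
            b, a = np.polyfit(ratio, col, 1)
            slope[solute] = float(b)
            intercept[solute] = float(a)
        else:
            raise ValueError(f"unknown correlation form {form[solute]!r}")
    return RejectionCorrelation(slope=slope, intercept=intercept)


def validate_profiles(traj: UFTrajectory, observed: pd.DataFrame) -> pd.DataFrame:
    """Per-series SSE between a simulated trajectory and timed observations.

    ``observed`` is a tidy table with columns ``time_s``, ``stream``
    ('retentate'/'permeate'), ``solute`` ('fc'/'fos') and ``conc_kgm3``.
    The trajectory is interpolated at the observation times; observation
    times outside the simulated span raise.
    """
    required = {"time_s", "stream", "solute", "conc_kgm3"}
    if not required <= set(observed.columns):
        raise ValueError(f"observed table must have columns {sorted(required)}")
    rows = []
    for (stream, solute), grp in observed.groupby(["stream", "solute"]):
        prof = concentration_profiles(traj, grp["time_s"].to_numpy())
        suffix = "ret" if stream == "retentate" else "perm"
        pred = prof[f"c_{solute}_{suffix}"].to_numpy()
        sse = sum_squared_error(pred, grp["conc_kgm3"].to_numpy())
        rows.append((stream, solute, len(grp), sse))
    return pd.DataFrame(rows, columns=["stream", "solute", "n", "sse"])
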