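"""Agonist dose-response fitting and efficacy summaries.

The model is the three-parameter log-concentration sigmoid with Hill
slope fixed at 1:

    Y = bottom + (top - bottom) / (1 + 10^(log10(EC50) - X)),
    X = log10([agonist])

equivalently Y = bottom + (top - bottom) * C / (C + EC50). Peak currents
are normalised to the response at a saturating reference concentration
(10 mM glutamate by convention) before fitting; EC50 is reported in mM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .types import ParameterError


def normalize_responses(currents, reference_current: float) -> np.ndarray:
    """Relative responses: |peak current| / |reference current|.

    Current magnitudes are taken as absolute peak amplitudes, so inward
    (negative) currents normalise identically to their magnitudes.
    """
    if reference_current == 0:
        raise ParameterError("reference current must be non-zero")
    return np.abs(np.asarray(currents, dtype=float)) / abs(reference_current)


def hill1(conc_mM: np.ndarray, ec50_mM: float, top: float, bottom: float) -> np.ndarray:
    """Hill-slope-1 sigmoid, concentration domain."""
    conc_mM = np.asarray(conc_mM, dtype=float)
    return bottom + (top - bottom) * conc_mM / (conc_mM + ec50_mM)


@dataclass
class DoseResponseFit:
    ec50_mM: Optional[float]
    top: Optional[float]
    bottom: Optional[float]
    residual_ss: Optional[float]
    converged: bool


class DoseResponseCurve(BaseEstimator, RegressorMixin):
    """Least-squares three-parameter dose-response regressor.

    Parameters
    ----------
    fix_bottom_zero : bool
        Constrain bottom = 0 (two free parameters); by default bottom is
        free.

    The optimiser is restarted from three deterministic initial EC50
    guesses — the geometric mean, minimum and maximum of the tested
    concentrations — and keeps the best solution, so fits are seedless
    and reproducible.

    Fitted attributes: ``ec50_mM_``, ``top_``, ``bottom_``,
    ``residual_ss_``, ``converged_``.
    """

    def __init__(self, fix_bottom_zero: bool = False):
        self.fix_bottom_zero = fix_bottom_zero

    def fit(self, concentrations_mM, responses) -> "DoseResponseCurve":
        conc = np.asarray(concentrations_mM, dtype=float).ravel()
        y = np.asarray(responses, dtype=float).ravel()
        if conc.size != y.size:
            raise ParameterError("concentration and response lengths differ")
        if np.unique(conc).size < 4:
            raise ParameterError(">= 4 distinct concentrations required")
        if (conc <= 0).any():
            raise ParameterError("concentrations must be positive")

        top0 = float(y.max())
        bot0 = 0.0 if self.fix_bottom_zero else float(y.min())

        def residuals(theta):
            if self.fix_bottom_zero:
                log_ec50, top = theta
                bottom = 0.0
            else:
                log_ec50, top, bottom = theta
            return hill1(conc, 10.0 ** log_ec50, top, bottom) - y

        log_inits = [
            float(np.log10(conc).mean()),  # geometric mean
            float(np.log10(conc.min())),
            float(np.log10(conc.max())),
        ]
        best = None
        for le in log_inits:
            x0 = [le, top0] if self.fix_bottom_zero else [le, top0, bot0]
            try:
                sol = optimize.least_squares(residuals, x0, method="lm",
                                             max_nfev=20_000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success or not np.isfinite(best.cost):
            self.ec50_mM_ = self.top_ = self.bottom_ = self.residual_ss_ = None
            self.converged_ = False
            return self
        if self.fix_bottom_zero:
            log_ec50, top = best.x
            bottom = 0.0
        else:
            log_ec50, top, bottom = best.x
        self.ec50_mM_ = float(10.0 ** log_ec50)
        self.top_ = float(top)
        self.bottom_ = float(bottom)
        self.residual_ss_ = float(2 * best.cost)
        self.converged_ = True
        self.n_features_in_ = 1
        return self

    def predict(self, concentrations_mM) -> np.ndarray:
        if not getattr(self, "converged_", False):
            raise ParameterError("fit did not converge; no predictions")
        return hill1(np.asarray(concentrations_mM, dtype=float),
                     self.ec50_mM_, self.top_, self.bottom_)

    def result(self) -> DoseResponseFit:
        return DoseResponseFit(
            ec50_mM=getattr(self, "ec50_mM_", None),
            top=getattr(self, "top_", None),
            bottom=getattr(self, "bottom_", None),
            residual_ss=getattr(self, "residual_ss_", None),
            converged=getattr(self, "converged_", False),
        )


def fit_dose_response(
    concentrations_mM, relative_responses, fix_bottom_zero: bool = False
) -> DoseResponseFit:
    """Functional wrapper around :class:`DoseResponseCurve`."""
    est = DoseResponseCurve(fix_bottom_zero=fix_bottom_zero)
    return est.fit(concentrations_mM, relative_responses).result()


def ka_glu_ratio(peak_kainate: float, peak_glutamate: float) -> float:
    """Kainate / glutamate peak-response ratio, percent — an index of
    partial-agonist efficacy."""
    pk, pg = abs(peak_kainate), abs(peak_glutamate)
    if pg == 0:
        raise ParameterError("glutamate peak must be non-zero")
    return 100.0 * pk / pg
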