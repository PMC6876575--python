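"""Concentration-response modeling for pointed-end depolymerization rates.

The depolymerization rate of a CAP-decorated pointed end follows first-order
(hyperbolic) saturation in the CAP concentration C:

    v(C) = v0 + (vmax - v0) * C / (Kd + C)

with half-maximal acceleration at the dissociation constant Kd.  This module
fits that model to per-concentration rates, summarizes condition contrasts
as fold changes with delta-method errors, and computes the mean number of
subunits removed per association event (rate x residence time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class SaturationFit:
    """First-order saturation fit of rate vs concentration.

    All rates in subunits/s, Kd in µM.  ``unidentifiable`` is set when the
    data cannot constrain Kd (flat response, or Kd beyond the sampled
    concentration range); in that case Kd and its SE are NaN rather than a
    silently meaningless number.
    """

    v0: float
    vmax: float
    Kd: float
    v0_se: float
    vmax_se: float
    Kd_se: float
    residuals: np.ndarray
    concentrations: np.ndarray
    rates: np.ndarray
    unidentifiable: bool = False
    flag_reason: str = ""

    def predict(self, conc: np.ndarray) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return self.v0 + (self.vmax - self.v0) * c / (self.Kd + c)


def _model(c: np.ndarray, v0: float, vmax: float, log_kd: float) -> np.ndarray:
    kd = np.exp(log_kd)
    return v0 + (vmax - v0) * c / (kd + c)


def fit_first_order_saturation(
    concentrations: np.ndarray,
    rates: np.ndarray,
    rate_sds: np.ndarray | None = None,
) -> SaturationFit:
    """Weighted nonlinear least-squares fit of v(C) = v0 + (vmax-v0)C/(Kd+C).

    Kd is fitted on a log scale to enforce positivity.  Weights are 1/SD^2
    when per-point SDs are given, else unweighted.  Initial guesses are
    deterministic: v0 = min rate, vmax = max rate, Kd = concentration whose
    rate is closest to the half-range.
    """
    c = np.asarray(concentrations, dtype=float)
    v = np.asarray(rates, dtype=float)
    if len(c) != len(v):
        raise ValueError("concentrations and rates must have equal length")
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")

    span = float(np.ptp(v))
    if span <= max(1e-12, 1e-9 * abs(np.mean(v))):
        return SaturationFit(
            v0=float(np.mean(v)),
            vmax=float(np.mean(v)),
            Kd=np.nan,
            v0_se=np.nan,
            vmax_se=np.nan,
            Kd_se=np.nan,
            residuals=v - np.mean(v),
            concentrations=c,
            rates=v,
            unidentifiable=True,
            flag_reason="constant rates: Kd unidentifiable",
        )

    half = v.min() + 0.5 * span
    kd0 = float(c[np.argmin(np.abs(v - half))])
    kd0 = max(kd0, np.min(c[c > 0], initial=1.0) * 0.5, 1e-6)
    p0 = (float(v.min()), float(v.max()), float(np.log(kd0)))
    sigma = np.asarray(rate_sds, dtype=float) if rate_sds is not None else None
    popt, pcov = curve_fit(
        _model, c, v, p0=p0, sigma=sigma, absolute_sigma=sigma is not None, maxfev=20000
    )
    v0, vmax, log_kd = popt
    kd = float(np.exp(log_kd))
    perr = np.sqrt(np.diag(pcov))
    resid = v - _model(c, *popt)

    unident, reason = False, ""
    if kd > float(c.max()):
        unident, reason = True, "Kd estimate beyond sampled concentration range"
    return SaturationFit(
        v0=float(v0),
        vmax=float(vmax),
        Kd=kd,
        v0_se=float(perr[0]),
        vmax_se=float(perr[1]),
        Kd_se=kd * float(perr[2]),  # delta method from log scale
        residuals=resid,
        concentrations=c,
        rates=v,
        unidentifiable=unident,
        flag_reason=reason,
    )


def fold_change(
    rate_numerator: float,
    rate_denominator: float,
    se_numerator: float = 0.0,
    se_denominator: float = 0.0,
) -> tuple[float, float]:
    """Ratio of two rates with a delta-method standard error."""
    if rate_denominator <= 0:
        raise ValueError("denominator rate must be > 0")
    ratio = rate_numerator / rate_denominator
    se = abs(ratio) * np.sqrt(
        (se_numerator / rate_numerator) ** 2 + (se_denominator / rate_denominator) ** 2
        if rate_numerator != 0
        else (se_denominator / rate_denominator) ** 2
    )
    return float(ratio), float(se)


def subunits_per_association(
    rate_subunits_s: float,
    residence_s: float,
    rate_se: float = 0.0,
    residence_se: float = 0.0,
) -> tuple[float, float]:
    """Mean subunits removed per binding event: rate x residence time.

    A depolymerase that stays bound for 1/koff seconds while the end loses
    ``rate`` subunits/s removes rate/koff subunits per association.
    """
    if rate_subunits_s < 0 or residence_s < 0:
        raise ValueError("rate and residence must be >= 0")
    prod = rate_subunits_s * residence_s
    if prod == 0:
        return 0.0, 0.0
    se = prod * np.sqrt(
        (rate_se / rate_subunits_s) ** 2 + (residence_se / residence_s) ** 2
    )
    return float(prod), float(se)
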