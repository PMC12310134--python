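"""Milling residence-time statistics and the Kramers escape-rate fit.

Past the milling-to-schooling transition the school lingers transiently in
the milling state before escaping to schooling.  The escape rate
kappa = 1 / mean(T_milling) is fitted with a Kramers-type law

    kappa(r) = A * r * exp(-r / (3 sigma^2)),

where r is the distance from the bifurcation point (r = zl - zl*), A is a
prefactor and sigma the effective noise at the collective level (generally
different from the individual-level noise).  The fit is linear least squares
in log space: log kappa - log r = log A - r / (3 sigma^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .observables import OrderParameterSeries

__all__ = [
    "ResidenceRecord",
    "KramersFit",
    "milling_residence",
    "escape_rate",
    "kramers_rate",
    "fit_kramers",
]


@dataclass(frozen=True)
class ResidenceRecord:
    """Milling occupancy of one run: residence fraction tau = T_milling / T."""

    tau: float
    t_milling: float
    escaped: bool
    zl: float | None = None


@dataclass(frozen=True)
class KramersFit:
    """Fitted prefactor A and collective noise sigma of the escape-rate law."""

    prefactor: float
    sigma_collective: float
    zl_star: float | None = None
    residuals: np.ndarray | None = None

    def rate(self, r) -> np.ndarray:
        return kramers_rate(r, self.prefactor, self.sigma_collective)


def milling_residence(
    series: OrderParameterSeries,
    m_threshold: float = 0.5,
    window: float = 50.0,
    zl: float | None = None,
) -> ResidenceRecord:
    """Fraction of a run spent in the milling state (M >= ``m_threshold``).

    ``escaped`` is true iff the trailing window of length ``window`` is not
    milling (window-mean M below threshold) while some earlier window of the
    same length was — i.e. the run entered and then left milling.
    """
    if not 0 < m_threshold < 1:
        raise ValueError("m_threshold must be in (0, 1)")
    m = series.milling
    t = series.time
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("series must span a positive duration")
    tau = float((m >= m_threshold).mean())
    t_milling = tau * duration

    last = t > t[-1] - window
    final_milling = bool(m[last].mean() >= m_threshold)
    # window-mean M over earlier, non-overlapping windows
    earlier_milling = False
    edge = t[0] + window
    while edge <= t[-1] - window + 1e-9:
        mask = (t > edge - window) & (t <= edge)
        if np.any(mask) and m[mask].mean() >= m_threshold:
            earlier_milling = True
            break
        edge += window
    escaped = earlier_milling and not final_milling
    return ResidenceRecord(tau=tau, t_milling=t_milling, escaped=escaped, zl=zl)


def escape_rate(records: list[ResidenceRecord]) -> float:
    """kappa = 1 / mean(T_milling) over replicates that entered milling;
    NaN when no replicate did."""
    t_mill = np.array([rec.t_milling for rec in records if rec.t_milling > 0])
    if t_mill.size == 0:
        return float("nan")
    return float(1.0 / t_mill.mean())


def kramers_rate(r, prefactor: float, sigma: float):
    """Escape-rate law kappa = A * r * exp(-r / (3 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    r = np.asarray(r, dtype=float)
    out = prefactor * r * np.exp(-r / (3.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def fit_kramers(
    r_values, kappa_values, zl_star: float | None = None, refine: bool = False
) -> KramersFit:
    """Least-squares fit of the escape-rate law in log space.

    log kappa = log A + log r - r/(3 sigma^2) is linear in log A and
    1/(3 sigma^2).  Requires at least three finite pairs with r > 0 and
    kappa > 0 and a decaying exponential component (negative slope).  With
    ``refine`` a nonlinear least-squares pass on the original scale polishes
    the linear estimate.
    """
    r = np.asarray(r_values, dtype=float)
    kappa = np.asarray(kappa_values, dtype=float)
    ok = np.isfinite(r) & np.isfinite(kappa) & (r > 0) & (kappa > 0)
    r, kappa = r[ok], kappa[ok]
    if r.size < 3:
        raise ValueError("need at least 3 finite (r, kappa) pairs with r, kappa > 0")
    if np.ptp(r) == 0:
        raise ValueError("degenerate design: all r values are equal")
    y = np.log(kappa) - np.log(r)
    design = np.column_stack([np.ones_like(r), r])
    (intercept, slope), *_ = np.linalg.lstsq(design, y, rcond=None)
    if slope >= 0:
        raise ValueError(
            "no decaying exponential component (slope >= 0); the escape-rate "
            "law cannot be fitted to these data"
        )
    prefactor = float(np.exp(intercept))
    sigma = float(np.sqrt(-1.0 / (3.0 * slope)))
    if refine:
        try:
            popt, _ = optimize.curve_fit(
                lambda rr, a, s: kramers_rate(rr, a, s),
                r,
                kappa,
                p0=[prefactor, sigma],
                maxfev=10000,
            )
            if popt[0] > 0 and popt[1] > 0:
                prefactor, sigma = float(popt[0]), float(popt[1])
        except RuntimeError:
            pass  # keep the linear estimate
    residuals = np.log(kappa) - np.log(kramers_rate(r, prefactor, sigma))
    return KramersFit(
        prefactor=prefactor,
        sigma_collective=sigma,
        zl_star=zl_star,
        residuals=residuals,
    )
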