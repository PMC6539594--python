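"""Bioassay arithmetic: competitive-ELISA percent inhibition, replicate
summaries, log-logistic dose–response (IC50) fitting and first-order
stability-decay summarization.

Percent inhibition of a competitive ELISA reads

    inh = 100 − (S − NS)·100 / (Pmax − NS)

where S is the signal with inhibitor, NS the negative-control signal and
Pmax the maximum binding signal without inhibitor.  The dose–response
model is the standard log-logistic

    inh(c) = 100 / (1 + 10^{h·(logIC50 − log10 c)})

rising to 100% at saturating inhibitor, with Hill slope h (fit or fixed
to 1).  Plasma stability series are summarized by a single-exponential
decay f(t) = 100·exp(−k t) with t½ = ln 2 / k; series whose fitted decline
over the observation window is below a resolution threshold are reported
as censored, t½ bounded below by the window end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "percent_inhibition", "summarize_replicates",
    "DoseResponseFit", "fit_dose_response", "ic50_micromolar",
    "DecayFit", "fit_decay",
]


def percent_inhibition(S, NS, Pmax) -> np.ndarray | float:
    """Percent inhibition from signal, negative control and maximum
    binding signal.  S = Pmax gives 0%, S = NS gives 100%; undefined when
    Pmax == NS."""
    S = np.asarray(S, dtype=float)
    if np.any(np.asarray(Pmax, dtype=float) == np.asarray(NS, dtype=float)):
        raise ValueError("Pmax equals NS: percent inhibition is undefined")
    out = 100.0 - (S - NS) * 100.0 / (Pmax - NS)
    return float(out) if out.ndim == 0 else out


def summarize_replicates(values: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and sample SD (n−1 denominator) of replicates;
    fewer than two values leave the SD undefined (NaN)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no replicate values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size >= 2 else float("nan")
    return mean, sd


@dataclass(frozen=True)
class DoseResponseFit:
    log_ic50: float  # log10 of molar IC50
    log_ic50_se: float
    hill: float
    hill_se: Optional[float]  # None when the slope was fixed
    r_squared: float
    n: int

    @property
    def ic50_micromolar(self) -> float:
        return ic50_micromolar(self.log_ic50)

    def curve(self, conc_molar) -> np.ndarray:
        return _log_logistic(np.asarray(conc_molar, dtype=float),
                             self.log_ic50, self.hill)


def _log_logistic(conc: np.ndarray, log_ic50: float, hill: float) -> np.ndarray:
    return 100.0 / (1.0 + 10.0 ** (hill * (log_ic50 - np.log10(conc))))


def fit_dose_response(conc_molar: Sequence[float],
                      inhibition: Sequence[float],
                      fix_hill: Optional[float] = None) -> DoseResponseFit:
    """Nonlinear least squares of the log-logistic dose–response.

    ``conc_molar`` are molar concentrations (> 0); ``inhibition`` the
    percent-inhibition readings.  At least four distinct concentrations
    are required.  ``fix_hill`` freezes the slope (typically 1.0);
    otherwise the slope is fit, initialized at 1.  Standard errors come
    from the Jacobian at the optimum; R² is computed on the inhibition
    scale.
    """
    c = np.asarray(list(conc_molar), dtype=float)
    y = np.asarray(list(inhibition), dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValueError("concentration and inhibition must be 1-D and equal length")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive (molar)")
    if np.unique(c).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    x0_log = float(np.median(np.log10(c)))
    try:
        if fix_hill is None:
            popt, pcov = curve_fit(
                _log_logistic, c, y, p0=[x0_log, 1.0], maxfev=20000)
            log_ic50, hill = popt
            se = np.sqrt(np.diag(pcov))
            log_se, hill_se = float(se[0]), float(se[1])
        else:
            def model(cc, l50):
                return _log_logistic(cc, l50, fix_hill)
            popt, pcov = curve_fit(model, c, y, p0=[x0_log], maxfev=20000)
            log_ic50, hill = float(popt[0]), float(fix_hill)
            log_se, hill_se = float(np.sqrt(pcov[0, 0])), None
    except RuntimeError as exc:
        raise RuntimeError(
            f"dose-response fit did not converge: {exc}") from exc
    resid = y - _log_logistic(c, log_ic50, hill)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / tss if tss > 0 else 1.0
    return DoseResponseFit(log_ic50=float(log_ic50), log_ic50_se=log_se,
                           hill=float(hill), hill_se=hill_se,
                           r_squared=r2, n=len(c))


def ic50_micromolar(log_ic50: float) -> float:
    """Convert a molar log10 IC50 to µM (e.g. −5.076 → 8.39)."""
    if not math.isfinite(log_ic50):
        raise ValueError("logIC50 must be finite")
    return round(10.0 ** (log_ic50 + 6.0), 2)


@dataclass(frozen=True)
class DecayFit:
    k: float  # first-order rate constant, 1/h
    half_life_h: float  # ln2/k; lower bound when censored
    censored: bool
    r_squared: float
    window_h: float


def fit_decay(times_h: Sequence[float], fraction_pct: Sequence[float],
              resolution_pct: float = 10.0) -> DecayFit:
    """Least-squares fit of f(t) = 100·exp(−k t) to a fraction-remaining
    series (percent scale, t=0 expected at 100%).

    When the fitted decline over the observation window is smaller than
    ``resolution_pct`` percentage points, the decay is below assay
    resolution: the result is censored with t½ reported as a lower bound
    at the window end.
    """
    t = np.asarray(list(times_h), dtype=float)
    f = np.asarray(list(fraction_pct), dtype=float)
    if t.shape != f.shape or t.ndim != 1 or t.size < 3:
        raise ValueError("need ≥ 3 (time, fraction) points")
    if np.any(t < 0):
        raise ValueError("negative times")
    if 0.0 not in t:
        raise ValueError("series must include t = 0")
    window = float(t.max())

    def model(tt, k):
        return 100.0 * np.exp(-k * tt)

    if np.allclose(f, f[0]):
        k = 0.0
    else:
        popt, _ = curve_fit(model, t, f, p0=[0.01],
                            bounds=(0.0, np.inf), maxfev=20000)
        k = float(popt[0])
    resid = f - model(t, k)
    tss = float(((f - f.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / tss if tss > 0 else 1.0
    decline = 100.0 * (1.0 - math.exp(-k * window)) if window > 0 else 0.0
    if k <= 0 or decline < resolution_pct:
        return DecayFit(k=k, half_life_h=window, censored=True,
                        r_squared=r2, window_h=window)
    return DecayFit(k=k, half_life_h=math.log(2.0) / k, censored=False,
                    r_squared=r2, window_h=window)
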