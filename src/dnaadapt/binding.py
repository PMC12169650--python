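"""Binding affinity and fluorescence lifetime analysis.

Quenching titrations are corrected for the inner filter effect,
``F_corr = F_obs * exp((A_ex + A_em) / 2)``, normalised to a fractional
saturation theta = (F0 - F) / (F0 - F_inf), and fitted to the Hill
isotherm theta = c^n / (K^n + c^n) against log10 concentration.  The
half-saturation constant converts to a standard-state Gibbs energy via
``dG = -RT ln(1/K_D)`` at 298 K (R = 1.98720e-3 kcal/mol/K, K_D on the
1 M standard state).  Time-resolved decays are fitted as a sum of
exponentials ``I(t) = sum_i alpha_i exp(-t / tau_i)`` numerically
convolved with the instrument response function, by weighted least
squares with Poisson weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TitrationSeries", "BindingFit", "DecayHistogram", "DecayFit",
    "inner_filter_correct", "hill_fit", "delta_g", "fit_decay",
    "mean_lifetime", "GAS_CONSTANT_KCAL",
]

GAS_CONSTANT_KCAL = 1.98720e-3   # kcal / (mol K)
DEFAULT_TEMPERATURE = 298.0      # K


@dataclass
class TitrationSeries:
    """One quenching titration: concentrations (nM, increasing), observed
    fluorescence, and optional absorbances for inner-filter correction."""

    concentration: np.ndarray
    F_obs: np.ndarray
    A_ex: np.ndarray | None = None
    A_em: np.ndarray | None = None

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, float)
        self.F_obs = np.asarray(self.F_obs, float)
        if np.any(self.concentration <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentration) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any(self.F_obs <= 0):
            raise ValueError("fluorescence must be positive")
        for attr in ("A_ex", "A_em"):
            v = getattr(self, attr)
            setattr(self, attr, np.zeros_like(self.concentration)
                    if v is None else np.asarray(v, float))

    @property
    def F_corrected(self) -> np.ndarray:
        return inner_filter_correct(self.F_obs, self.A_ex, self.A_em)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"concentration": self.concentration,
                             "F_obs": self.F_obs, "A_ex": self.A_ex,
                             "A_em": self.A_em})


def inner_filter_correct(F_obs, A_ex, A_em):
    """Inner-filter correction F_corr = F_obs * exp((A_ex + A_em) / 2)."""
    A_ex = np.asarray(A_ex, float)
    A_em = np.asarray(A_em, float)
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValueError("absorbances must be >= 0")
    return np.asarray(F_obs, float) * np.exp((A_ex + A_em) / 2.0)


@dataclass
class BindingFit:
    """Hill fit result: K (nM), Hill coefficient n, standard errors,
    fitted saturation per point, and dG (kcal/mol) at the stated T."""

    K: float
    n: float
    K_se: float
    n_se: float
    F0: float
    F_inf: float
    theta: np.ndarray
    delta_G: float
    temperature: float = DEFAULT_TEMPERATURE

    def K_confidence_interval(self, z: float = 1.959964) -> tuple[float, float]:
        return (self.K - z * self.K_se, self.K + z * self.K_se)


def _hill_theta(logc: np.ndarray, logK: float, n: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (n * (logK - logc)))


def hill_fit(series: TitrationSeries, F0: float | None = None,
             F_inf: float | None = None,
             temperature: float = DEFAULT_TEMPERATURE) -> BindingFit:
    """Fit a quenching titration to the Hill isotherm.

    The saturation theta(c) = (F0 - F(c)) / (F0 - F_inf) uses the
    inner-filter-corrected fluorescence; F0 and F_inf are fitted unless
    supplied.  The fit runs against log10 concentration; standard errors
    come from the fit covariance.  Requires >= 5 points spanning both
    sides of half-saturation.
    """
    c = series.concentration
    F = series.F_corrected
    if len(c) < 5:
        raise ValueError("need at least 5 titration points")
    logc = np.log10(c)

    fit_ends = F0 is None or F_inf is None
    F0_0 = F.max() if F0 is None else F0
    Finf_0 = F.min() if F_inf is None else F_inf
    halfway = 0.5 * (F0_0 + Finf_0)
    logK0 = float(np.interp(halfway, F[::-1], logc[::-1])) \
        if F[0] > F[-1] else float(np.median(logc))

    if fit_ends:
        def model(lc, logK, n, F0p, Finfp):
            return F0p - (F0p - Finfp) * _hill_theta(lc, logK, n)
        p0 = [logK0, 1.0, F0_0, Finf_0]
    else:
        def model(lc, logK, n):
            return F0 - (F0 - F_inf) * _hill_theta(lc, logK, n)
        p0 = [logK0, 1.0]
    try:
        popt, pcov = curve_fit(model, logc, F, p0=p0, maxfev=20000,
                               xtol=1e-14, ftol=1e-14)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Hill fit did not converge (start K=10^{logK0:.2f} nM): "
            f"{exc}") from exc
    logK, n = popt[0], popt[1]
    F0_fit = popt[2] if fit_ends else F0
    Finf_fit = popt[3] if fit_ends else F_inf
    K = 10.0 ** logK
    perr = np.sqrt(np.diag(pcov))
    K_se = K * np.log(10.0) * perr[0]
    n_se = perr[1]
    theta = (F0_fit - F) / (F0_fit - Finf_fit)
    if np.any(theta < -0.05) or np.any(theta > 1.05):
        import warnings
        warnings.warn("normalised saturation outside [-0.05, 1.05]; check "
                      "F0/F_inf", stacklevel=2)
    dG = delta_g(K * 1e-9, temperature)
    return BindingFit(float(K), float(n), float(K_se), float(n_se),
                      float(F0_fit), float(Finf_fit), theta, dG, temperature)


def delta_g(K_D_molar: float, temperature: float = DEFAULT_TEMPERATURE,
            ) -> float:
    """Standard-state binding free energy dG = -RT ln(1/K_D), kcal/mol.

    K_D is interpreted on the 1 M standard state, so dG(K_D = 1 M) = 0 and
    dG is strictly increasing in K_D (more negative = tighter binding).
    """
    if K_D_molar <= 0:
        raise ValueError("K_D must be positive")
    return -GAS_CONSTANT_KCAL * temperature * np.log(1.0 / K_D_molar)


@dataclass
class DecayHistogram:
    """TCSPC decay: uniform time grid (ns), photon counts per channel, and
    the (unit-area) instrument response on the same grid."""

    time: np.ndarray
    counts: np.ndarray
    irf: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.counts = np.asarray(self.counts, float)
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        dt = np.diff(self.time)
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("time channels must be uniform")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.time, "counts": self.counts})


@dataclass
class DecayFit:
    """Multi-exponential reconvolution fit result."""

    amplitudes: np.ndarray
    lifetimes: np.ndarray
    scale: float
    chi2_reduced: float
    residuals: np.ndarray


def _reconvolved_model(t: np.ndarray, irf: np.ndarray,
                       amplitudes: np.ndarray, lifetimes: np.ndarray,
                       ) -> np.ndarray:
    decay = np.sum(amplitudes[:, None] * np.exp(-t[None, :] / lifetimes[:, None]),
                   axis=0)
    return np.convolve(irf, decay)[:len(t)]


def fit_decay(histogram: DecayHistogram, irf: np.ndarray | None = None,
              n_components: int = 1, tau_guess=None) -> DecayFit:
    """Fit an IRF-reconvolved multi-exponential to a TCSPC histogram.

    Weighted least squares with Poisson weights 1/max(counts, 1); at most
    3 components are identifiable.  Amplitudes are reported normalised to
    sum to 1, with the overall scale separate.
    """
    if n_components < 1 or n_components > 3:
        raise ValueError("n_components must be 1..3")
    irf = histogram.irf if irf is None else np.asarray(irf, float)
    if irf is None:
        raise ValueError("an IRF is required (histogram.irf or argument)")
    irf = irf / irf.sum()
    t = histogram.time
    y = histogram.counts
    sigma = np.sqrt(np.maximum(y, 1.0))

    if tau_guess is None:
        # crude moment guess spread over a decade
        total = y.sum()
        tbar = float((t * y).sum() / total) if total > 0 else 1.0
        tau_guess = tbar * np.geomspace(0.3, 3.0, n_components)
    tau_guess = np.asarray(tau_guess, float)

    def model(tt, *params):
        amps = np.abs(np.array(params[:n_components]))
        taus = np.abs(np.array(params[n_components:]))
        return _reconvolved_model(tt, irf, amps, taus)

    scale0 = y.max() if y.max() > 0 else 1.0
    p0 = list(np.full(n_components, scale0 / n_components)) + list(tau_guess)
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, sigma=sigma,
                            absolute_sigma=True, maxfev=40000,
                            xtol=1e-13, ftol=1e-13)
    except RuntimeError as exc:
        raise RuntimeError(
            f"decay fit did not converge (tau guesses {tau_guess}): "
            f"{exc}") from exc
    amps = np.abs(popt[:n_components])
    taus = np.abs(popt[n_components:])
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    yhat = _reconvolved_model(t, irf, amps, taus)
    resid = (y - yhat) / sigma
    dof = max(len(t) - 2 * n_components, 1)
    chi2 = float((resid ** 2).sum() / dof)
    scale = float(amps.sum())
    return DecayFit(amps / scale, taus, scale, chi2, resid)


def mean_lifetime(fit: DecayFit) -> float:
    """Amplitude-weighted mean lifetime sum(a_i tau_i) / sum(a_i), ns."""
    return float(np.sum(fit.amplitudes * fit.lifetimes)
                 / np.sum(fit.amplitudes))
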