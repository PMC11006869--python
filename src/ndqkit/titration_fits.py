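"""Closed-form-model fits for steady-state and electrophysiology readouts.

Covers the small nonlinear/linear fits used around the spectroscopy and
patch-clamp data: multi-pKa Henderson–Hasselbalch titration of a spectral
observable, Hill analysis of the sodium dependence of the O-state amplitude,
monoexponential photocurrent off-kinetics, the linear I–V readout at +60 mV,
absorption-spectrum utilities (peak position, normalization at 280 nm), and
the 95%-power Gaussian beam radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

__all__ = [
    "Spectrum",
    "TitrationCurve",
    "PkaFitResult",
    "HillFitResult",
    "ExpDecayFit",
    "lambda_max",
    "normalize_at_280",
    "fit_multi_pka",
    "fit_hill",
    "fit_monoexp",
    "extract_current_at",
    "beam_r95",
]


@dataclass
class Spectrum:
    """Absorption spectrum A(λ) with condition metadata."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelength/absorbance length mismatch")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass
class TitrationCurve:
    """(pH, observable) table; the observable is λmax or an absorbance."""

    pH: np.ndarray
    observable: np.ndarray
    observable_kind: str = "lambda_max"

    def __post_init__(self):
        self.pH = np.asarray(self.pH, dtype=float)
        self.observable = np.asarray(self.observable, dtype=float)
        if self.pH.shape != self.observable.shape:
            raise ValueError("pH/observable length mismatch")
        if not np.all(np.isfinite(self.pH)):
            raise ValueError("pH must be finite")


@dataclass
class PkaFitResult:
    pka: np.ndarray            # ascending
    amplitudes: np.ndarray     # matched to pka order
    baseline: float
    pka_stderr: np.ndarray
    amplitude_stderr: np.ndarray
    baseline_stderr: float
    residual_rms: float
    converged: bool


@dataclass
class HillFitResult:
    K_half: float
    n_hill: float
    y_max: float
    K_stderr: float
    n_stderr: float
    y_max_stderr: float
    residual_rms: float
    converged: bool


@dataclass
class ExpDecayFit:
    t_off: float
    amplitude: float
    offset: float
    t_off_stderr: float
    residual_rms: float
    decaying: bool


def lambda_max(spectrum: Spectrum, window: tuple[float, float] | None = None) -> float:
    """Sub-grid peak wavelength via parabolic interpolation.

    Fits a parabola through the maximum sample and its two neighbours within
    ``window`` (nm).  A peak sitting on the window edge is flagged with a
    warning and returned at the sample position.
    """
    wl, ab = spectrum.wavelengths, spectrum.absorbance
    if window is not None:
        lo, hi = window
        if lo < wl[0] or hi > wl[-1]:
            raise ValueError("window outside spectrum range")
        sel = (wl >= lo) & (wl <= hi)
        wl, ab = wl[sel], ab[sel]
    i = int(np.argmax(ab))
    if i == 0 or i == len(ab) - 1:
        warnings.warn("spectral peak at window edge; returning sample maximum")
        return float(wl[i])
    x0, x1, x2 = wl[i - 1], wl[i], wl[i + 1]
    y0, y1, y2 = ab[i - 1], ab[i], ab[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom == 0:
        return float(x1)
    # vertex of the parabola through the three samples (uniform grid assumed
    # locally; general form used for safety)
    d = 0.5 * (y0 - y2) / denom
    return float(x1 + d * (x2 - x1))


def normalize_at_280(spectrum: Spectrum) -> tuple[Spectrum, float]:
    """Scale a spectrum so its (interpolated) absorbance at 280 nm is 1."""
    wl = spectrum.wavelengths
    if not (wl[0] <= 280.0 <= wl[-1]):
        raise ValueError("280 nm outside spectrum range")
    a280 = float(np.interp(280.0, wl, spectrum.absorbance))
    if a280 == 0:
        raise ValueError("absorbance at 280 nm is zero")
    factor = 1.0 / a280
    return (
        Spectrum(wl.copy(), spectrum.absorbance * factor, dict(spectrum.metadata)),
        factor,
    )


def _hh_model(ph, baseline, pka, amps):
    y = np.full_like(ph, baseline, dtype=float)
    for p, a in zip(pka, amps):
        y = y + a / (1.0 + 10.0 ** (ph - p))
    return y


def _initial_pkas(curve: TitrationCurve, n: int) -> np.ndarray:
    """Initial pKa guesses from an inflection scan of the smoothed derivative."""
    ph, y = curve.pH, curve.observable
    order = np.argsort(ph)
    ph, y = ph[order], y[order]
    dy = np.abs(np.gradient(y, ph))
    if len(dy) >= 5:  # light smoothing against noise
        kernel = np.ones(3) / 3.0
        dy = np.convolve(dy, kernel, mode="same")
    cand = [
        j
        for j in range(1, len(dy) - 1)
        if dy[j] >= dy[j - 1] and dy[j] > dy[j + 1]
    ]
    cand.sort(key=lambda j: -dy[j])
    guesses = sorted(ph[j] for j in cand[:n])
    while len(guesses) < n:  # fall back to range quantiles
        guesses = list(np.quantile(ph, np.linspace(0.2, 0.8, n)))
    return np.asarray(guesses[:n], dtype=float)


def fit_multi_pka(curve: TitrationCurve, n_transitions: int) -> PkaFitResult:
    """Least-squares fit of baseline + sum_k A_k / (1 + 10^(pH - pKa_k)).

    pKa values are reported ascending with amplitudes matched; parameter
    uncertainties come from the curvature of the least-squares objective.
    """
    ph, y = curve.pH, curve.observable
    if ph.size < 2 * n_transitions + 2:
        raise ValueError("too few points for the requested number of transitions")
    init_pka = _initial_pkas(curve, n_transitions)
    span = (y.max() - y.min()) or 1.0
    sign = 1.0 if y[np.argmin(ph)] >= y[np.argmax(ph)] else -1.0

    params = lmfit.Parameters()
    params.add("baseline", value=float(y[np.argmax(ph)]))
    for k in range(n_transitions):
        params.add(f"pka{k}", value=float(init_pka[k]), min=ph.min() - 2, max=ph.max() + 2)
        params.add(f"amp{k}", value=float(sign * span / n_transitions))

    def resid(p):
        pka = [p[f"pka{k}"].value for k in range(n_transitions)]
        amp = [p[f"amp{k}"].value for k in range(n_transitions)]
        return _hh_model(ph, p["baseline"].value, pka, amp) - y

    out = lmfit.minimize(resid, params)
    pka = np.array([out.params[f"pka{k}"].value for k in range(n_transitions)])
    amp = np.array([out.params[f"amp{k}"].value for k in range(n_transitions)])
    pka_err = np.array(
        [out.params[f"pka{k}"].stderr or np.nan for k in range(n_transitions)]
    )
    amp_err = np.array(
        [out.params[f"amp{k}"].stderr or np.nan for k in range(n_transitions)]
    )
    order = np.argsort(pka)
    rms = float(np.sqrt(np.mean(out.residual**2)))
    if not out.success:
        warnings.warn("pKa fit did not converge cleanly")
    return PkaFitResult(
        pka=pka[order],
        amplitudes=amp[order],
        baseline=float(out.params["baseline"].value),
        pka_stderr=pka_err[order],
        amplitude_stderr=amp_err[order],
        baseline_stderr=float(out.params["baseline"].stderr or np.nan),
        residual_rms=rms,
        converged=bool(out.success),
    )


def fit_hill(conc, amplitude) -> HillFitResult:
    """Fit y = y_max c^n / (K^n + c^n); the Hill coefficient n is free."""
    c = np.asarray(conc, dtype=float)
    y = np.asarray(amplitude, dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 concentrations")
    if np.ptp(y) == 0:
        raise ValueError("all amplitudes equal; Hill fit undefined")
    y_max0 = float(y.max())
    k0 = float(c[np.argmin(np.abs(y - 0.5 * y_max0))]) or float(np.median(c[c > 0]))

    model = lmfit.Model(
        lambda c, K, n, y_max: y_max * np.where(c > 0, c**n / (K**n + c**n), 0.0)
    )
    params = model.make_params(K=k0, n=1.0, y_max=y_max0)
    params["K"].min = 1e-12
    params["n"].min = 1e-3
    out = model.fit(y, params, c=c)
    if not out.success:
        warnings.warn("Hill fit did not converge cleanly")
    return HillFitResult(
        K_half=float(out.params["K"].value),
        n_hill=float(out.params["n"].value),
        y_max=float(out.params["y_max"].value),
        K_stderr=float(out.params["K"].stderr or np.nan),
        n_stderr=float(out.params["n"].stderr or np.nan),
        y_max_stderr=float(out.params["y_max"].stderr or np.nan),
        residual_rms=float(np.sqrt(np.mean(out.residual**2))),
        converged=bool(out.success),
    )


def fit_monoexp(times, current) -> ExpDecayFit:
    """Monoexponential decay fit I(t) = A exp(-t/t_off) + C.

    The caller supplies the decaying segment (starting at light-off).
    Non-decaying input is flagged via ``decaying=False``.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(current, dtype=float)
    c0 = float(y[-1])
    a0 = float(y[0] - c0)
    decaying_guess = abs(a0) > 1e-12 * max(1.0, abs(c0))
    if not decaying_guess:
        warnings.warn("signal does not decay; monoexponential fit flagged")
        return ExpDecayFit(np.nan, 0.0, c0, np.nan, float(np.std(y)), False)
    # crude rate guess from the 1/e crossing
    target = c0 + a0 / np.e
    idx = np.argmin(np.abs(y - target))
    tau0 = float(t[idx] - t[0]) or float((t[-1] - t[0]) / 3)

    model = lmfit.Model(lambda t, A, tau, C: A * np.exp(-(t - t[0]) / tau) + C)
    params = model.make_params(A=a0, tau=max(tau0, 1e-12), C=c0)
    params["tau"].min = 1e-15
    out = model.fit(y, params, t=t)
    tau = float(out.params["tau"].value)
    return ExpDecayFit(
        t_off=tau,
        amplitude=float(out.params["A"].value),
        offset=float(out.params["C"].value),
        t_off_stderr=float(out.params["tau"].stderr or np.nan),
        residual_rms=float(np.sqrt(np.mean(out.residual**2))),
        decaying=bool(out.success) and tau > 0,
    )


def extract_current_at(voltage_points, currents, v_target: float = 60.0) -> float:
    """Photocurrent at ``v_target`` from an OLS line through positive voltages."""
    v = np.asarray(voltage_points, dtype=float)
    i = np.asarray(currents, dtype=float)
    pos = v > 0
    if pos.sum() < 2:
        raise ValueError("need at least 2 positive-voltage points")
    slope, intercept = np.polyfit(v[pos], i[pos], 1)
    return float(slope * v_target + intercept)


def beam_r95(sigma: float) -> float:
    """Radius enclosing 95% of the power of an isotropic 2-D Gaussian beam.

    For intensity ~ exp(-r^2 / 2 sigma^2) the enclosed fraction is
    1 - exp(-r^2 / 2 sigma^2), so r95 = sigma * sqrt(2 ln 20).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(sigma * np.sqrt(2.0 * np.log(20.0)))
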