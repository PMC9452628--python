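"""Parametric fits of gating and binding data, plus summary statistics.

Models
------
* Boltzmann steady-state activation:
  ``I/I_max = I/I_max,satV / (1 + exp(zδ·F·(V − V_1/2)/(R·T)))``
  yielding the half-activation voltage V_1/2 (mV) and the effective
  gating charge zδ.
* Exponential activation time course.  The printed form of the time
  constant refers to a relaxation, and activation currents grow toward
  a steady state, so the fitted model is
  ``I(t) = I_inf − A·exp(−(t − delay)/τ)`` for ``t ≥ delay`` — τ is the
  same relaxation constant either way.
* Hill concentration–binding: ``F/F_max = 1 / (1 + (BC50/x)^Hb)``.

All fits are unweighted nonlinear least squares; standard errors come
from the Jacobian-based parameter covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from hcnflex.constants import PhysicalConstants

__all__ = [
    "ActivationCurve",
    "BoltzmannFit",
    "ActivationTrace",
    "ExponentialFit",
    "BindingCurve",
    "HillFit",
    "FitError",
    "boltzmann_model",
    "hill_model",
    "fit_boltzmann",
    "fit_activation_exponential",
    "fit_hill",
    "extract_bound_fluorescence",
    "grand_mean_sem",
    "unpaired_t",
]


class FitError(RuntimeError):
    """Raised when a fit fails or the data are degenerate; carries the
    last parameter iterate when available."""

    def __init__(self, message: str, last_params=None):
        super().__init__(message)
        self.last_params = last_params


# ---------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------

@dataclass
class ActivationCurve:
    """Relative tail current vs step voltage (mV)."""

    V: np.ndarray
    rel_I: np.ndarray
    n_per_point: np.ndarray | None = None

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=float)
        self.rel_I = np.asarray(self.rel_I, dtype=float)
        if self.V.shape != self.rel_I.shape:
            raise ValueError("V and rel_I must have equal length")
        if self.V.size < 4:
            raise ValueError("need >= 4 points to fit an activation curve")


@dataclass
class BoltzmannFit:
    V_half: float
    z_delta: float
    rel_I_satV: float
    V_half_se: float
    z_delta_se: float
    rel_I_satV_se: float
    residual_norm: float
    T: float


@dataclass
class ActivationTrace:
    """Current time course after a voltage step (t in ms)."""

    t: np.ndarray
    I: np.ndarray
    delay: float | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.t.shape != self.I.shape:
            raise ValueError("t and I must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


@dataclass
class ExponentialFit:
    A: float
    tau: float
    I_inf: float
    delay_used: float
    A_se: float
    tau_se: float
    residual_norm: float


@dataclass
class BindingCurve:
    """Normalized bound fluorescence vs ligand concentration (µM)."""

    x: np.ndarray
    rel_F: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.rel_F = np.asarray(self.rel_F, dtype=float)
        if self.x.shape != self.rel_F.shape:
            raise ValueError("x and rel_F must have equal length")
        if self.x.size < 4:
            raise ValueError("need >= 4 concentrations to fit a Hill curve")
        if np.any(self.x <= 0):
            raise ValueError("concentrations must be positive")


@dataclass
class HillFit:
    BC50: float
    H_b: float
    BC50_se: float
    H_b_se: float
    residual_norm: float


# ---------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------

def boltzmann_model(V_mV, V_half, z_delta, rel_I_satV,
                    constants: PhysicalConstants | None = None):
    c = constants or PhysicalConstants()
    arg = z_delta * (np.asarray(V_mV, dtype=float) - V_half) / c.kT_over_e_mV
    return rel_I_satV / (1.0 + np.exp(arg))


def hill_model(x, BC50, H_b):
    return 1.0 / (1.0 + (BC50 / np.asarray(x, dtype=float)) ** H_b)


# ---------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------

def fit_boltzmann(curve: ActivationCurve,
                  T: float | None = None) -> BoltzmannFit:
    """Fit the Boltzmann activation relation to one recording.

    For data from a hyperpolarization-activated channel the slope
    parameter zδ is positive (current rises toward negative voltages).
    Recordings are meant to be fitted individually and the parameters
    summarized afterwards.
    """
    span = curve.rel_I.max() - curve.rel_I.min()
    if span < 0.3:
        raise FitError("curve does not span its midpoint (range < 0.3); "
                       "cannot constrain V_half")
    constants = PhysicalConstants() if T is None else PhysicalConstants(T=T)

    half = curve.rel_I.min() + span / 2.0
    v0 = float(curve.V[np.argmin(np.abs(curve.rel_I - half))])
    p0 = (v0, 4.0, float(curve.rel_I.max()))

    def model(V, V_half, z_delta, rel_I_satV):
        return boltzmann_model(V, V_half, z_delta, rel_I_satV, constants)

    try:
        popt, pcov = optimize.curve_fit(model, curve.V, curve.rel_I, p0=p0,
                                        maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Boltzmann fit did not converge: {exc}",
                       last_params=p0) from exc
    resid = curve.rel_I - model(curve.V, *popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return BoltzmannFit(V_half=float(popt[0]), z_delta=float(popt[1]),
                        rel_I_satV=float(popt[2]), V_half_se=float(se[0]),
                        z_delta_se=float(se[1]), rel_I_satV_se=float(se[2]),
                        residual_norm=float(np.linalg.norm(resid)),
                        T=constants.T)


def estimate_delay(trace: ActivationTrace, threshold: float = 0.1) -> float:
    """Slope-threshold delay estimate.

    Returns the latest time before the absolute smoothed slope first
    exceeds ``threshold`` times its maximum.
    """
    dI = np.gradient(trace.I, trace.t)
    s = np.abs(dI)
    peak = s.max()
    if peak == 0:
        return float(trace.t[0])
    above = np.nonzero(s >= threshold * peak)[0]
    k = int(above[0])
    return float(trace.t[max(0, k - 1)])


def fit_activation_exponential(trace: ActivationTrace,
                               delay: float | None = None) -> ExponentialFit:
    """Fit a single-exponential relaxation to an activation time course.

    ``I(t) = I_inf − A·exp(−(t − delay)/τ)`` for ``t >= delay``.  The
    delay is user-fixed or estimated from the slope threshold.  A trace
    already at steady state (no resolvable amplitude) is rejected
    because τ is unidentifiable.
    """
    if delay is None:
        delay = trace.delay if trace.delay is not None else estimate_delay(trace)
    mask = trace.t >= delay
    t = trace.t[mask] - delay
    y = trace.I[mask]
    if len(t) < 4:
        raise FitError("fewer than 4 samples after the delay")
    amp0 = y[-1] - y[0]
    scale = np.max(np.abs(y)) or 1.0
    if abs(amp0) < 1e-6 * scale or np.ptp(y) < 1e-6 * scale:
        raise FitError("trace is already at steady state; tau is "
                       "unidentifiable")
    # initial tau from the 1/e crossing of the remaining amplitude
    target = y[-1] - amp0 / np.e
    k = np.nonzero((y - target) * np.sign(amp0) >= 0)[0]
    tau0 = float(t[k[0]]) if len(k) and t[k[0]] > 0 else float(t[-1] / 3)

    def model(tt, I_inf, A, tau):
        return I_inf - A * np.exp(-tt / tau)

    p0 = (float(y[-1]), float(amp0), tau0)
    try:
        popt, pcov = optimize.curve_fit(model, t, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}",
                       last_params=p0) from exc
    if popt[2] <= 0:
        raise FitError("fitted tau is non-positive", last_params=popt)
    resid = y - model(t, *popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return ExponentialFit(A=float(popt[1]), tau=float(popt[2]),
                          I_inf=float(popt[0]), delay_used=float(delay),
                          A_se=float(se[1]), tau_se=float(se[2]),
                          residual_norm=float(np.linalg.norm(resid)))


def fit_hill(curve: BindingCurve) -> HillFit:
    """Fit the Hill equation to (mean) concentration–binding data."""
    if curve.rel_F.max() - curve.rel_F.min() < 1e-12:
        raise FitError("binding data are flat (all saturated or all zero)")
    if curve.rel_F.max() < 0.05:
        raise FitError("binding data are all near zero")
    if curve.rel_F.min() > 0.95:
        raise FitError("binding data are all saturated")
    # BC50 guess: interpolated half-maximum on a log axis
    order = np.argsort(curve.x)
    x, y = curve.x[order], curve.rel_F[order]
    bc0 = float(np.interp(0.5, y, x)) if np.any(y >= 0.5) else float(np.median(x))
    p0 = (max(bc0, 1e-6), 1.5)
    try:
        popt, pcov = optimize.curve_fit(hill_model, curve.x, curve.rel_F,
                                        p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"Hill fit did not converge: {exc}",
                       last_params=p0) from exc
    resid = curve.rel_F - hill_model(curve.x, *popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return HillFit(BC50=float(popt[0]), H_b=float(popt[1]),
                   BC50_se=float(se[0]), H_b_se=float(se[1]),
                   residual_norm=float(np.linalg.norm(resid)))


# ---------------------------------------------------------------------
# Two-channel bound-fluorescence correction
# ---------------------------------------------------------------------

def extract_bound_fluorescence(
    green: np.ndarray,
    red: np.ndarray,
    bath_mask: np.ndarray,
    patch_mask: np.ndarray,
    border_mask: np.ndarray | None = None,
    f_max: float | None = None,
):
    """Bound-dye fluorescence from a dual-dye confocal image pair.

    The red (free-dye reference) channel is scaled to the green channel
    in the bath region; the per-pixel difference green − scale·red is
    the signal of the bound ligand.  ``F`` is its mean inside the patch
    mask.  Offsets, when a signal-free ``border_mask`` is given, are
    subtracted from both channels first.  With ``f_max`` (from a
    saturating reference recording) the normalized ``F/F_max`` is also
    returned.

    Returns a dict with ``scale``, ``bound`` (image), ``F`` and
    optionally ``rel_F``.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    bath_mask = np.asarray(bath_mask, dtype=bool)
    patch_mask = np.asarray(patch_mask, dtype=bool)
    if green.shape != red.shape:
        raise ValueError("channel shapes differ")
    if not bath_mask.any() or not patch_mask.any():
        raise ValueError("bath and patch masks must be non-empty")
    if (bath_mask & patch_mask).any():
        raise ValueError("bath and patch masks must be disjoint")
    if border_mask is not None:
        border_mask = np.asarray(border_mask, dtype=bool)
        green = green - green[border_mask].mean()
        red = red - red[border_mask].mean()
    red_bath = red[bath_mask].mean()
    if abs(red_bath) < 1e-12:
        raise ValueError("zero red-channel signal in the bath; cannot scale")
    scale = green[bath_mask].mean() / red_bath
    bound = green - scale * red
    F = float(bound[patch_mask].mean())
    out = {"scale": float(scale), "bound": bound, "F": F}
    if f_max is not None:
        if f_max == 0:
            raise ValueError("F_max must be non-zero")
        out["rel_F"] = F / f_max
    return out


# ---------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------

def grand_mean_sem(values) -> tuple[float, float | None]:
    """Two-level grand mean ± SEM.

    ``values`` is a mapping or sequence of runs, each run a sequence of
    per-subunit time averages.  Subunit values are averaged within each
    run; the grand mean is the mean of the run means and the SEM is
    computed across run means.  With a single run the SEM is undefined
    and returned as None.
    """
    if hasattr(values, "values"):
        runs = list(values.values())
    else:
        runs = list(values)
    if len(runs) == 0:
        raise ValueError("need at least one run")
    run_means = np.array([np.mean(np.asarray(r, dtype=float)) for r in runs])
    grand = float(run_means.mean())
    if len(run_means) < 2:
        return grand, None
    sem = float(run_means.std(ddof=1) / np.sqrt(len(run_means)))
    return grand, sem


def unpaired_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided unpaired t-test (Welch variant).

    Returns (t, p).  Two groups with zero variance and equal means give
    p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf * np.sign(a.mean() - b.mean())), 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant groups
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
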