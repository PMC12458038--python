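"""FCS correlation models, amplitude fits and the CCP bound-fraction statistic.

The single-component 3D-Gaussian diffusion model

    G(tau) = G0 * (1 + tau/tau_D)^-1 * (1 + tau/(s^2 tau_D))^-1/2

is fitted to measured correlation curves to extrapolate the tau = 0
amplitude G0 and the diffusion time tau_D. The dual-color observable is the
cross-correlation percentage

    CCP = 100 * G_x(0) / G_L(0),

the fitted cross-correlation amplitude over the ligand autocorrelation
amplitude, which equals (percent of nanopores bound) x f_ov under the
analytic amplitude relations implemented in
:func:`amplitudes_from_concentrations`. The optical-overlap efficiency f_ov
caps CCP (around 60% here) and is never divided out of measured values; it
is carried in forward models and absorbed by the plateau parameter of the
kinetic fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .correlate import CorrelationCurve
from .geometry import AVOGADRO, ConfocalGeometry, effective_volume

__all__ = [
    "CorrFitResult",
    "CCPMeasurement",
    "g_diffusion_3d",
    "g_cross_displaced",
    "DiffusionCurveModel",
    "fit_autocorrelation",
    "fit_crosscorrelation",
    "amplitudes_from_concentrations",
    "compute_ccp",
    "calibrate_overlap",
]


def g_diffusion_3d(tau, G0: float, tau_D: float, s: float):
    """Single-component 3D-Gaussian diffusion correlation model.

    Monotone decreasing in tau; G(0) = G0 exactly.
    """
    if tau_D <= 0:
        raise ValueError(f"tau_D must be > 0, got {tau_D}")
    if s < 1:
        raise ValueError(f"structure parameter s must be >= 1, got {s}")
    tau = np.asarray(tau, dtype=float)
    x = tau / tau_D
    return G0 / ((1.0 + x) * np.sqrt(1.0 + x / (s * s)))


def g_cross_displaced(tau, G0: float, tau_D: float, s: float, dr2: float):
    """Cross-correlation model for laterally displaced detection volumes.

    For two equal-waist volumes displaced laterally by d, the
    cross-correlation carries an extra factor exp(-d^2 / (w_xy^2 (1+tau/tau_D)))
    relative to the coincident-volume shape. Here it is normalised so that
    ``G0`` remains the true tau = 0 amplitude:

        G(tau) = G0 * shape(tau) * exp(dr2 * (tau/tau_D) / (1 + tau/tau_D)),

    with dr2 = d^2 / w_xy^2 = -ln(f_ov). dr2 = 0 recovers the standard model.
    """
    tau = np.asarray(tau, dtype=float)
    x = tau / tau_D
    return g_diffusion_3d(tau, G0, tau_D, s) * np.exp(dr2 * x / (1.0 + x))


@dataclass
class CorrFitResult:
    """Fitted correlation-curve parameters.

    ``G0`` is the tau -> 0 extrapolated amplitude; ``cov`` the covariance of
    the free parameters in fit order.
    """

    G0: float
    tau_D: float
    s: float
    G0_err: float
    tau_D_err: float
    cov: np.ndarray
    residual_norm: float
    converged: bool
    free_params: tuple[str, ...]
    flags: tuple[str, ...] = ()
    model: str = "auto3d"

    def summary(self) -> str:
        lines = [
            f"Correlation fit [{self.model}]  converged={self.converged}"
            + (f"  flags={list(self.flags)}" if self.flags else ""),
            f"  G(0)   = {self.G0:.5g} +/- {self.G0_err:.2g}",
            f"  tau_D  = {self.tau_D:.5g} +/- {self.tau_D_err:.2g} s"
            + ("" if "tau_D" in self.free_params else " (fixed)"),
            f"  s      = {self.s:.3g} (fixed)",
            f"  resid. norm = {self.residual_norm:.3g}",
        ]
        return "\n".join(lines)


class DiffusionCurveModel:
    """Weighted least-squares fit of the 3D diffusion model to a curve.

    Weights are 1/G_err^2 where per-lag errors are available (and positive),
    uniform otherwise. The structure parameter is fixed by calibration; the
    diffusion time may be fixed too (used for cross-correlation curves,
    which share tau_D with the slower, pore-sized species). A nonzero
    ``overlap_dr2`` selects the displaced-volume cross model.
    """

    def __init__(
        self,
        curve: CorrelationCurve,
        *,
        s: float = 5.0,
        tau_D_fixed: float | None = None,
        overlap_dr2: float = 0.0,
    ) -> None:
        if len(curve) < 8:
            raise ValueError("need >= 8 lag points to fit")
        if not np.any(curve.G != 0):
            raise ValueError("degenerate curve: all correlation values are zero")
        self.curve = curve
        self.s = float(s)
        self.tau_D_fixed = tau_D_fixed
        self.overlap_dr2 = float(overlap_dr2)

    # -- internals ---------------------------------------------------------
    def _shape(self, tau, tau_D):
        if self.overlap_dr2:
            return g_cross_displaced(tau, 1.0, tau_D, self.s, self.overlap_dr2)
        return g_diffusion_3d(tau, 1.0, tau_D, self.s)

    def _weights(self) -> np.ndarray | None:
        err = self.curve.G_err
        if err is not None and np.all(err > 0):
            return err
        return None

    def _guess_tau(self) -> float:
        g_vals, lags = self.curve.G, self.curve.lags
        g0 = g_vals[0] if g_vals[0] > 0 else np.max(np.abs(g_vals))
        below = np.nonzero(g_vals < 0.5 * g0)[0]
        if below.size:
            return float(lags[below[0]])
        return float(lags[len(lags) // 2])

    def fit(self, init: dict | None = None, bounds: dict | None = None) -> CorrFitResult:
        curve = self.curve
        tau, g_obs = curve.lags, curve.G
        sigma = self._weights()
        init = init or {}

        if self.tau_D_fixed is not None:
            # amplitude-only fit is weighted linear in G0 -> solve in closed form
            tau_d = float(self.tau_D_fixed)
            shape = self._shape(tau, tau_d)
            w = 1.0 / sigma**2 if sigma is not None else np.ones_like(g_obs)
            denom = float(np.sum(w * shape * shape))
            g0 = float(np.sum(w * shape * g_obs)) / denom
            resid = g_obs - g0 * shape
            dof = max(len(curve) - 1, 1)
            scale = float(np.sum(w * resid**2)) / dof if sigma is None else 1.0
            g0_var = scale / denom
            flags = ("negative_amplitude",) if g0 < 0 else ()
            return CorrFitResult(
                g0, tau_d, self.s, math.sqrt(g0_var), 0.0,
                np.array([[g0_var]]), float(np.linalg.norm(resid)), True,
                ("G0",), flags, "cross3d" if self.overlap_dr2 else "auto3d",
            )

        p0 = [init.get("G0", g_obs[0] if g_obs[0] > 0 else 0.1),
              init.get("tau_D", self._guess_tau())]
        lo = [-np.inf, 1e-12]
        hi = [np.inf, np.inf]
        if bounds:
            if "G0" in bounds:
                lo[0], hi[0] = bounds["G0"]
            if "tau_D" in bounds:
                lo[1], hi[1] = bounds["tau_D"]
        p0[1] = min(max(p0[1], lo[1]), hi[1] if np.isfinite(hi[1]) else p0[1])

        def f(tau, g0, tau_d):
            return g0 * self._shape(tau, tau_d)

        try:
            popt, pcov = curve_fit(
                f, tau, g_obs, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
                bounds=(lo, hi), maxfev=20000,
            )
            converged = np.all(np.isfinite(popt)) and np.all(np.isfinite(pcov))
        except RuntimeError:
            popt = np.array([np.nan, np.nan])
            pcov = np.full((2, 2), np.nan)
            converged = False
        resid = g_obs - f(tau, *popt) if converged else np.full_like(g_obs, np.nan)
        flags = []
        if not converged:
            flags.append("did_not_converge")
        elif popt[0] < 0:
            flags.append("negative_amplitude")
        return CorrFitResult(
            float(popt[0]), float(popt[1]), self.s,
            float(np.sqrt(pcov[0, 0])), float(np.sqrt(pcov[1, 1])),
            pcov, float(np.linalg.norm(resid)) if converged else np.inf,
            converged, ("G0", "tau_D"), tuple(flags),
            "cross3d" if self.overlap_dr2 else "auto3d",
        )


def fit_autocorrelation(
    curve: CorrelationCurve,
    init: dict | None = None,
    bounds: dict | None = None,
    *,
    s: float = 5.0,
) -> CorrFitResult:
    """Fit the 3D diffusion model to an autocorrelation curve.

    Returns the tau -> 0 extrapolated amplitude G0 and diffusion time; a
    non-converged fit is returned flagged, never silently.
    """
    return DiffusionCurveModel(curve, s=s).fit(init=init, bounds=bounds)


def fit_crosscorrelation(
    curve: CorrelationCurve,
    *,
    tau_D: float | None = None,
    s: float = 5.0,
    f_ov: float = 1.0,
    init: dict | None = None,
) -> CorrFitResult:
    """Fit a cross-correlation curve, optionally with tau_D fixed.

    By default tau_D should be fixed to the fitted diffusion time of the
    slower (pore-sized) species, since the complex diffuses like the pore.
    ``f_ov`` < 1 selects the displaced-volume model so G0 remains the true
    tau = 0 amplitude under partial overlap.
    """
    dr2 = -math.log(f_ov) if f_ov < 1.0 else 0.0
    return DiffusionCurveModel(curve, s=s, tau_D_fixed=tau_D, overlap_dr2=dr2).fit(init=init)


def amplitudes_from_concentrations(
    c_np: float, c_l: float, c_x: float, geometry: ConfocalGeometry
) -> tuple[float, float, float]:
    """Analytic tau = 0 amplitudes of a three-species FCCS system.

    ``c_np``/``c_l`` are *free* pore and ligand concentrations, ``c_x`` the
    complex concentration (all M). With n_A = N_A * V_eff:

        G_NP(0) = 1 / (n_A (c_np + c_x))
        G_L(0)  = 1 / (n_A (c_l + c_x))
        G_X(0)  = f_ov * c_x / (n_A (c_np + c_x) (c_l + c_x))

    so that G_X(0)/G_L(0) = f_ov * c_x / (c_np + c_x), the bound-pore
    fraction scaled by the optical overlap. This is the forward model (and
    test oracle) for the CCP statistic.
    """
    for name, c in (("c_np", c_np), ("c_l", c_l), ("c_x", c_x)):
        if c < 0:
            raise ValueError(f"{name} must be >= 0, got {c}")
    n_a = AVOGADRO * effective_volume(geometry)
    tot_np = c_np + c_x
    tot_l = c_l + c_x
    if tot_np <= 0 or tot_l <= 0:
        raise ValueError("need a nonzero pore-channel and ligand-channel population")
    g_np = 1.0 / (n_a * tot_np)
    g_l = 1.0 / (n_a * tot_l)
    g_x = geometry.f_ov * c_x / (n_a * tot_np * tot_l)
    return g_np, g_l, g_x


@dataclass
class CCPMeasurement:
    """Cross-correlation percentage at one incubation time and concentration."""

    ccp: float
    t: float = 0.0
    L_conc: float = 0.0
    ccp_err: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("incubation time must be >= 0")
        if self.L_conc < 0:
            raise ValueError("ligand concentration must be >= 0")


def compute_ccp(
    cross_fit: CorrFitResult,
    ligand_fit: CorrFitResult,
    *,
    t: float = 0.0,
    L_conc: float = 0.0,
) -> CCPMeasurement:
    """CCP = 100 * G_x(0) / G_L(0) from two converged amplitude fits.

    Negative cross amplitudes (pure noise around zero binding) are reported
    as-is with a warning flag rather than clipped, so titration fits remain
    unbiased near zero.
    """
    if not (cross_fit.converged and ligand_fit.converged):
        raise ValueError("both fits must have converged to form a CCP")
    if ligand_fit.G0 <= 0:
        raise ValueError(f"ligand amplitude must be > 0, got {ligand_fit.G0}")
    ccp = 100.0 * cross_fit.G0 / ligand_fit.G0
    flags = []
    if cross_fit.G0 < 0:
        flags.append("negative_cross_amplitude")
        warnings.warn("negative fitted cross amplitude; CCP reported as-is", stacklevel=2)
    err = None
    if cross_fit.G0 != 0:
        err = abs(ccp) * math.sqrt(
            (cross_fit.G0_err / cross_fit.G0) ** 2
            + (ligand_fit.G0_err / ligand_fit.G0) ** 2
        )
    return CCPMeasurement(ccp, t=t, L_conc=L_conc, ccp_err=err, flags=tuple(flags))


def calibrate_overlap(control_ccp: float) -> float:
    """Overlap efficiency f_ov from a double-labeled control measurement.

    A species carrying both labels has a true bound fraction of 1, so its
    measured CCP (in percent) directly calibrates f_ov = CCP/100. Measured
    CCP values are *not* rescaled by this factor; it parameterises forward
    models and is absorbed by the plateau of the kinetic fits.
    """
    if not (0.0 < control_ccp <= 100.0):
        raise ValueError(f"control CCP must be in (0, 100], got {control_ccp}")
    return control_ccp / 100.0
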