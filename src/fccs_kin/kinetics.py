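"""Binding-kinetics models and fits for dc-FCCS time courses and titrations.

The measurement chain behind a kinetic experiment is:

* equilibration time courses at fixed ligand concentration follow
  CCP(t) = A (1 - exp(-k_eq t))                       (pseudo-first-order),
* the observed rates obey the rate law k_eq = k_on [L] + k_off, a line
  whose slope is the association rate constant,
* equilibrium titrations follow the Langmuir-Hill isotherm
  CCP = A [L] / ([L] + K_d) with Hill exponent fixed at 1,
* competition displacement decays follow CCP = A' exp(-k_off t) + o,
* and any one of (K_d, k_on, k_off) closes the triple via K_d = k_off/k_on.

Each fit is exposed statsmodels-style: a Model built from data whose
``fit()`` returns a :class:`KineticResults` carrying estimates, standard
errors, covariance, diagnostics and a ``summary()`` table. Functional
wrappers (``fit_equilibration`` etc.) cover quick scripting.

The exact reversible bimolecular ODE and the two-ligand competition ODE are
provided as generating models: they are what the synthetic pipeline
integrates, and what the pseudo-first-order and single-exponential
approximations are validated against.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .fcsmodels import CCPMeasurement

__all__ = [
    "equilibrium_complex",
    "bound_fraction_ode",
    "displacement_ode",
    "pseudo_first_order_timecourse",
    "KineticResults",
    "EquilibrationModel",
    "RateLawModel",
    "IsothermModel",
    "DepletionIsothermModel",
    "DisplacementModel",
    "fit_equilibration",
    "fit_rate_law",
    "fit_isotherm",
    "fit_isotherm_depletion",
    "fit_displacement",
    "AffinityRecord",
    "complete_affinity",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# generating models (mass-action ODEs and closed forms)
# ---------------------------------------------------------------------------

def equilibrium_complex(P0: float, L0: float, Kd: float) -> float:
    """Equilibrium complex concentration of P + L <-> C with totals P0, L0.

    The physically admissible (smaller) root of
    ``Kd C = (P0 - C)(L0 - C)``, written in the cancellation-free form
    2 P0 L0 / (b + sqrt(b^2 - 4 P0 L0)) with b = P0 + L0 + Kd, which stays
    accurate in the tight-binding limit Kd -> 0.
    """
    if P0 < 0 or L0 < 0 or Kd < 0:
        raise ValueError("concentrations and Kd must be >= 0")
    if P0 == 0 or L0 == 0:
        return 0.0
    b = P0 + L0 + Kd
    disc = b * b - 4.0 * P0 * L0
    return 2.0 * P0 * L0 / (b + math.sqrt(max(disc, 0.0)))


def bound_fraction_ode(
    P0: float, L0: float, k_on: float, k_off: float, times: np.ndarray
) -> np.ndarray:
    """Exact reversible bimolecular kinetics, C(t) with C(0) = 0.

    Integrates dC/dt = k_on (P0 - C)(L0 - C) - k_off C adaptively
    (relative tolerance 1e-10). C(t) rises monotonically to the smaller
    root of the mass-action quadratic.
    """
    times = np.asarray(times, dtype=float)
    if P0 < 0 or L0 < 0 or k_on < 0 or k_off < 0:
        raise ValueError("negative inputs are not allowed")
    if times.size and (times[0] < 0 or np.any(np.diff(times) <= 0)):
        raise ValueError("times must be increasing and start at t >= 0")
    if times.size == 0:
        return np.empty(0)

    def rhs(_t, y):
        c = y[0]
        return [k_on * (P0 - c) * (L0 - c) - k_off * c]

    scale = max(P0, L0, 1e-30)
    sol = solve_ivp(
        rhs,
        (0.0, float(times[-1]) if times[-1] > 0 else 1e-9),
        [0.0],
        t_eval=times if times[-1] > 0 else None,
        method="LSODA",
        rtol=1e-10,
        atol=1e-14 * scale,
    )
    if times[-1] <= 0:
        return np.zeros_like(times)
    return sol.y[0]


def displacement_ode(
    P0: float,
    Lstar0: float,
    Lu0: float,
    k_on: float,
    k_off: float,
    times: np.ndarray,
    *,
    preequilibrated: bool = True,
) -> np.ndarray:
    """Labeled-complex trajectory under competition displacement.

    Two ligands with identical kinetics (the same antibody, labeled and
    unlabeled) compete for the pore:

        dC*/dt = k_on (Lstar0 - C*) P_free - k_off C*
        dCu/dt = k_on (Lu0  - Cu) P_free - k_off Cu,   P_free = P0 - C* - Cu.

    With ``preequilibrated`` the labeled complex starts from the equilibrium
    of pore + labeled ligand alone and the competitor is added at t = 0. As
    Lu0 -> infinity the labeled-complex decay approaches a single
    exponential with rate k_off.
    """
    times = np.asarray(times, dtype=float)
    if min(P0, Lstar0, Lu0, k_on, k_off) < 0:
        raise ValueError("negative inputs are not allowed")
    c0 = 0.0
    if preequilibrated and k_on > 0:
        c0 = equilibrium_complex(P0, Lstar0, k_off / k_on) if k_off > 0 else min(P0, Lstar0)

    def rhs(_t, y):
        cs, cu = y
        p_free = P0 - cs - cu
        return [
            k_on * (Lstar0 - cs) * p_free - k_off * cs,
            k_on * (Lu0 - cu) * p_free - k_off * cu,
        ]

    if times[-1] <= 0:
        return np.full_like(times, c0)
    scale = max(P0, Lstar0, Lu0, 1e-30)
    sol = solve_ivp(
        rhs, (0.0, float(times[-1])), [c0, 0.0], t_eval=times,
        method="LSODA", rtol=1e-10, atol=1e-14 * scale,
    )
    return sol.y[0]


def pseudo_first_order_timecourse(A: float, k_eq: float, times) -> np.ndarray:
    """Evaluate CCP(t) = A (1 - exp(-k_eq t)) exactly."""
    if k_eq < 0:
        raise ValueError("k_eq must be >= 0")
    times = np.asarray(times, dtype=float)
    return A * (1.0 - np.exp(-k_eq * times))


# ---------------------------------------------------------------------------
# Model / Results framework
# ---------------------------------------------------------------------------

@dataclass
class KineticResults:
    """Fit results: estimates, uncertainties, diagnostics.

    ``params``/``bse`` are pandas Series indexed by parameter name;
    ``cov_params`` the covariance DataFrame. Non-converged or degenerate
    fits carry ``converged=False`` plus explanatory ``flags``; they are
    returned, never silently dropped.
    """

    model_name: str
    equation: str
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    nobs: int
    ssr: float
    converged: bool
    flags: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)
    _predict: callable = None

    def __getattr__(self, name):
        params = object.__getattribute__(self, "params")
        if name in params.index:
            return float(params[name])
        raise AttributeError(name)

    @property
    def rsquared(self) -> float | None:
        return self.extra.get("rsquared")

    def predict(self, x) -> np.ndarray:
        if self._predict is None:
            raise ValueError("no prediction function attached")
        return self._predict(np.asarray(x, dtype=float), *self.params.values)

    def summary(self) -> str:
        head = [
            f"{self.model_name}: {self.equation}",
            f"  nobs = {self.nobs}   converged = {self.converged}"
            + (f"   flags = {list(self.flags)}" if self.flags else ""),
        ]
        rows = [
            f"  {name:<10s} {self.params[name]: .6g}  +/- {self.bse[name]:.3g}"
            for name in self.params.index
        ]
        tail = [f"  SSR = {self.ssr:.4g}"]
        if self.rsquared is not None:
            tail.append(f"  R^2 = {self.rsquared:.5f}")
        return "\n".join(head + rows + tail)

    def plot(self, ax=None, x=None):
        """Data with the fitted curve overlaid (diagnostic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xd = self.extra.get("x")
        yd = self.extra.get("y")
        if xd is not None:
            ax.plot(xd, yd, "o", label="data")
            grid = np.linspace(min(xd), max(xd), 200) if x is None else x
            ax.plot(grid, self.predict(grid), "-", label="fit")
            ax.legend()
        ax.set_title(self.model_name)
        return ax


def _coerce_xy(data, x_col: str, y_col: str, err_col: str):
    """Accept a DataFrame, a list of CCPMeasurement, or (x, y[, err]) arrays."""
    if isinstance(data, pd.DataFrame):
        x = data[x_col].to_numpy(dtype=float)
        y = data[y_col].to_numpy(dtype=float)
        err = data[err_col].to_numpy(dtype=float) if err_col in data else None
        return x, y, err
    if len(data) and isinstance(data[0], CCPMeasurement):
        x = np.array([getattr(m, "t" if x_col == "t_s" else "L_conc") for m in data])
        y = np.array([m.ccp for m in data])
        errs = [m.ccp_err for m in data]
        err = np.array(errs, dtype=float) if all(e is not None for e in errs) else None
        return x, y, err
    raise TypeError("pass a DataFrame, a list of CCPMeasurement, or use model(x, y)")


class _NonlinearModel:
    """Shared trust-region nonlinear least-squares machinery."""

    name = "model"
    equation = ""
    param_names: tuple[str, ...] = ()
    x_col, y_col = "t_s", "ccp"

    def __init__(self, x, y, yerr=None):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.yerr = None if yerr is None else np.asarray(yerr, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        self._validate()

    @classmethod
    def from_dataframe(cls, data, **kwargs):
        x, y, err = _coerce_xy(data, cls.x_col, cls.y_col, "ccp_err")
        return cls(x, y, err, **kwargs)

    def _validate(self) -> None:
        pass

    # subclasses: _func(x, *params), _guess(), _bounds()
    def _bounds(self):
        k = len(self.param_names)
        return ([-np.inf] * k, [np.inf] * k)

    def _degenerate(self) -> tuple[str, ...] | None:
        return None

    def _multistart(self):
        return [self._guess()]

    def fit(self, p0=None) -> KineticResults:
        flags = self._degenerate()
        k = len(self.param_names)
        if flags is not None:
            res = KineticResults(
                self.name, self.equation,
                pd.Series(np.full(k, np.nan), index=self.param_names),
                pd.Series(np.full(k, np.nan), index=self.param_names),
                pd.DataFrame(np.full((k, k), np.nan), index=self.param_names,
                             columns=self.param_names),
                self.x.size, np.nan, False, flags,
                {"x": self.x, "y": self.y}, self._func,
            )
            logger.warning("%s fit degenerate: %s", self.name, flags)
            return res
        sigma = self.yerr if (self.yerr is not None and np.all(self.yerr > 0)) else None
        starts = [np.asarray(p0, dtype=float)] if p0 is not None else self._multistart()
        lo, hi = (np.asarray(b, dtype=float) for b in self._bounds())
        best = None
        for start in starts:
            # parameters span many decades (e.g. A ~ 60 vs K_d ~ 1e-9);
            # rescale each to O(1) around its start or the bounded optimiser
            # cannot take sensible steps
            scale = np.where(np.abs(start) > 0, np.abs(start), 1.0)

            def f_scaled(x, *q, _scale=scale):
                return self._func(x, *(np.asarray(q) * _scale))

            try:
                q_opt, q_cov = curve_fit(
                    f_scaled, self.x, self.y, p0=start / scale, sigma=sigma,
                    absolute_sigma=sigma is not None,
                    bounds=(lo / scale, hi / scale),
                    maxfev=40000, xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
            except (RuntimeError, ValueError):
                continue
            popt = q_opt * scale
            pcov = q_cov * np.outer(scale, scale)
            ssr = float(np.sum((self.y - self._func(self.x, *popt)) ** 2))
            if best is None or ssr < best[2]:
                best = (popt, pcov, ssr)
        if best is None:
            return KineticResults(
                self.name, self.equation,
                pd.Series(np.full(k, np.nan), index=self.param_names),
                pd.Series(np.full(k, np.nan), index=self.param_names),
                pd.DataFrame(np.full((k, k), np.nan), index=self.param_names,
                             columns=self.param_names),
                self.x.size, np.nan, False, ("did_not_converge",),
                {"x": self.x, "y": self.y}, self._func,
            )
        popt, pcov, ssr = best
        sst = float(np.sum((self.y - self.y.mean()) ** 2))
        res = KineticResults(
            self.name, self.equation,
            pd.Series(popt, index=self.param_names),
            pd.Series(np.sqrt(np.diag(pcov)), index=self.param_names),
            pd.DataFrame(pcov, index=self.param_names, columns=self.param_names),
            self.x.size, ssr, True, (),
            {"x": self.x, "y": self.y,
             "rsquared": 1.0 - ssr / sst if sst > 0 else None},
            self._func,
        )
        logger.info("%s fit converged: %s", self.name,
                    dict(zip(self.param_names, np.round(popt, 6))))
        return res


class EquilibrationModel(_NonlinearModel):
    """CCP(t) = A (1 - exp(-k_eq t)) at fixed ligand concentration."""

    name = "Equilibration"
    equation = "CCP = A*(1 - exp(-k_eq*t))"
    param_names = ("A", "k_eq")

    def _validate(self):
        if self.x.size < 4:
            warnings.warn("fewer than 4 time points; k_eq poorly constrained",
                          stacklevel=3)

    @staticmethod
    def _func(t, A, k_eq):
        return A * (1.0 - np.exp(-k_eq * t))

    def _degenerate(self):
        if np.ptp(self.y) == 0:
            return ("k_eq_unidentifiable", "constant_data")
        return None

    def _guess(self):
        a0 = float(self.y.max())
        half = np.nonzero(self.y >= 0.5 * a0)[0]
        t_half = self.x[half[0]] if half.size and self.x[half[0]] > 0 else (
            self.x[self.x > 0][0] if np.any(self.x > 0) else 1.0
        )
        k0 = math.log(2.0) / t_half
        if self.x.max() * k0 < 1.0:
            warnings.warn("time span may not cover 1/k_eq", stacklevel=4)
        return np.array([a0, k0])

    def _bounds(self):
        return ([-np.inf, 1e-15], [np.inf, np.inf])


class RateLawModel:
    """Weighted linear rate law k_eq = k_on [L] + k_off.

    The slope is the association rate constant; the intercept is a nominal
    k_off that extrapolation makes unreliable, so it is reported flagged and
    is never used to close the kinetic triple.
    """

    name = "RateLaw"
    equation = "k_eq = k_on*[L] + k_off"
    param_names = ("k_on", "k_off_intercept")

    def __init__(self, L, k_eq, k_eq_err=None):
        self.L = np.asarray(L, dtype=float)
        self.k_eq = np.asarray(k_eq, dtype=float)
        self.k_eq_err = None if k_eq_err is None else np.asarray(k_eq_err, dtype=float)
        if np.unique(self.L).size < 3:
            raise ValueError("need >= 3 distinct ligand concentrations")
        if np.ptp(self.L) == 0:
            raise ValueError("zero concentration spread")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame):
        err = df["k_eq_err"].to_numpy() if "k_eq_err" in df else None
        return cls(df["L_conc_M"].to_numpy(), df["k_eq"].to_numpy(), err)

    def fit(self) -> KineticResults:
        exog = sm.add_constant(self.L)
        if self.k_eq_err is not None and np.all(self.k_eq_err > 0):
            wls = sm.WLS(self.k_eq, exog, weights=1.0 / self.k_eq_err**2)
        else:
            wls = sm.OLS(self.k_eq, exog)
        fit = wls.fit()
        slope, intercept = fit.params[1], fit.params[0]
        order = [1, 0]  # (k_on, k_off_intercept)
        cov = np.asarray(fit.cov_params())[np.ix_(order, order)]
        return KineticResults(
            self.name, self.equation,
            pd.Series([slope, intercept], index=self.param_names),
            pd.Series([fit.bse[1], fit.bse[0]], index=self.param_names),
            pd.DataFrame(cov, index=self.param_names, columns=self.param_names),
            self.L.size, float(fit.ssr), True, ("unreliable_intercept",),
            {"x": self.L, "y": self.k_eq, "rsquared": float(fit.rsquared)},
            lambda L, k_on, k_off: k_on * L + k_off,
        )


class IsothermModel(_NonlinearModel):
    """Langmuir-Hill equilibrium isotherm CCP = A [L]/([L] + K_d).

    Hill exponent fixed at 1 (hyperbolic form). Valid when the free-ligand
    pool is not depleted, i.e. K_d well above the pore concentration;
    otherwise use :class:`DepletionIsothermModel`.
    """

    name = "Isotherm"
    equation = "CCP = A*[L]/([L] + K_d)"
    param_names = ("A", "K_d")
    x_col = "L_conc_M"
    model_tag = "hyperbolic"

    def _validate(self):
        if self.x.size < 4:
            warnings.warn("fewer than 4 concentrations; K_d poorly constrained",
                          stacklevel=3)

    @staticmethod
    def _func(L, A, K_d):
        return A * L / (L + K_d)

    def _degenerate(self):
        if np.ptp(self.y) == 0 and self.y[0] == 0:
            return ("degenerate_all_zero",)
        return None

    def _guess(self):
        a0 = float(self.y.max()) * 1.05
        above = np.nonzero(self.y >= 0.5 * a0)[0]
        kd0 = float(self.x[above[0]]) if above.size else float(np.median(self.x))
        if not (self.x.min() <= kd0 <= self.x.max()):
            warnings.warn("titration may not span K_d", stacklevel=4)
        return np.array([a0, max(kd0, 1e-15)])

    def _bounds(self):
        return ([-np.inf, 1e-18], [np.inf, np.inf])

    def _multistart(self):
        base = self._guess()
        return [base] + [
            np.array([base[0], kd]) for kd in np.logspace(-12, -6, 7)
        ]


class DepletionIsothermModel(IsothermModel):
    """Tight-binding (ligand-depletion) isotherm.

    CCP = A * C_eq(P0, [L], K_d) / P0 with C_eq the quadratic mass-action
    root; required when K_d is comparable to or below the pore concentration
    P0, where the hyperbolic form is systematically biased. This is the
    depletion-corrected fit used for the streptavidin-class interactions.
    """

    name = "DepletionIsotherm"
    equation = "CCP = A*C_eq(P0,[L],K_d)/P0"
    model_tag = "depletion-corrected"

    def __init__(self, L, ccp, yerr=None, *, P0: float):
        if P0 <= 0:
            raise ValueError("P0 must be > 0")
        self.P0 = float(P0)
        super().__init__(L, ccp, yerr)
        # bind P0 into the curve function (curve_fit sees only (A, K_d))
        p0_conc = self.P0

        def func(L, A, K_d):
            ceq = np.array([equilibrium_complex(p0_conc, li, K_d) for li in np.atleast_1d(L)])
            return A * ceq / p0_conc

        self._func = func

    def _multistart(self):
        # A enters linearly, so profile it out and scan log10(K_d) for the
        # best start; the tight-binding SSR surface is extremely flat in K_d
        # below P0 and defeats a cold trust-region start.
        w = 1.0 / self.yerr**2 if (self.yerr is not None and np.all(self.yerr > 0)) else np.ones_like(self.y)
        best_kd, best_ssr, best_a = None, np.inf, None
        grid = np.logspace(-16, -7, 181)
        for kd in grid:
            shape = np.array([equilibrium_complex(self.P0, li, kd) for li in self.x]) / self.P0
            denom = float(np.sum(w * shape * shape))
            if denom == 0:
                continue
            a = float(np.sum(w * shape * self.y)) / denom
            ssr = float(np.sum(w * (self.y - a * shape) ** 2))
            if ssr < best_ssr:
                best_kd, best_ssr, best_a = kd, ssr, a
        return [np.array([best_a, best_kd])]


class DisplacementModel(_NonlinearModel):
    """Competition decay CCP(t) = A' exp(-k_off t) + o.

    ``o`` is the offset from zero for incomplete displacement of the labeled
    ligand at finite competitor excess.
    """

    name = "Displacement"
    equation = "CCP = A'*exp(-k_off*t) + o"
    param_names = ("A_prime", "k_off", "o")

    def _validate(self):
        if self.x.size < 5:
            raise ValueError("need >= 5 time points for a displacement fit")
        n = self.y.size
        if np.mean(self.y[: n // 3]) <= np.mean(self.y[-(n // 3) :]):
            warnings.warn("no decreasing trend in displacement data", stacklevel=3)

    @staticmethod
    def _func(t, A_prime, k_off, o):
        return A_prime * np.exp(-k_off * t) + o

    def _degenerate(self):
        if np.ptp(self.y) == 0:
            return ("k_off_unidentifiable", "constant_data")
        return None

    def _guess(self):
        a0 = float(self.y[0] - self.y[-1])
        o0 = float(self.y[-1])
        target = o0 + 0.5 * a0
        below = np.nonzero(self.y <= target)[0]
        t_half = self.x[below[0]] if below.size and self.x[below[0]] > 0 else (
            self.x[-1] / 2 or 1.0
        )
        return np.array([a0, math.log(2.0) / t_half, o0])

    def _bounds(self):
        return ([-np.inf, 1e-15, -np.inf], [np.inf, np.inf, np.inf])


# ---------------------------------------------------------------------------
# functional wrappers over the Model classes
# ---------------------------------------------------------------------------

def _model_fit(cls, data, **kwargs) -> KineticResults:
    if isinstance(data, (pd.DataFrame, list)):
        model = cls.from_dataframe(data, **kwargs) if not isinstance(data, list) else None
        if model is None:  # list of CCPMeasurement
            x, y, err = _coerce_xy(data, cls.x_col, cls.y_col, "ccp_err")
            model = cls(x, y, err, **kwargs)
        return model.fit()
    raise TypeError("pass a DataFrame or a list of CCPMeasurement")


def fit_equilibration(time_course) -> KineticResults:
    """Fit CCP(t) = A (1 - exp(-k_eq t)) to one time course at fixed [L]."""
    return _model_fit(EquilibrationModel, time_course)


def fit_rate_law(points) -> KineticResults:
    """Weighted line through ([L], k_eq) pairs; slope = k_on.

    ``points`` is a DataFrame with columns L_conc_M, k_eq[, k_eq_err] or an
    iterable of (L, k_eq[, err]) tuples.
    """
    if isinstance(points, pd.DataFrame):
        return RateLawModel.from_dataframe(points).fit()
    arr = np.asarray(list(points), dtype=float)
    err = arr[:, 2] if arr.shape[1] > 2 else None
    return RateLawModel(arr[:, 0], arr[:, 1], err).fit()


def fit_isotherm(titration) -> KineticResults:
    """Langmuir-Hill fit of an equilibrium titration (hyperbolic, Hill = 1)."""
    return _model_fit(IsothermModel, titration)


def fit_isotherm_depletion(titration, P0: float) -> KineticResults:
    """Depletion-corrected (tight-binding) isotherm fit; regime K_d <~ P0."""
    return _model_fit(DepletionIsothermModel, titration, P0=P0)


def fit_displacement(decay_course) -> KineticResults:
    """Fit the competition decay CCP = A' exp(-k_off t) + o."""
    return _model_fit(DisplacementModel, decay_course)


# ---------------------------------------------------------------------------
# affinity records and the K_d = k_off / k_on closure
# ---------------------------------------------------------------------------

@dataclass
class AffinityRecord:
    """One affinity-table row: K_d, k_on, k_off with provenance.

    ``provenance`` maps each constant to "fitted", "derived-via-closure" (from
    K_d = k_off/k_on) or "reference" (a printed input).
    """

    ligand: str = ""
    pore: str = ""
    Kd: float | None = None
    Kd_err: float | None = None
    k_on: float | None = None
    k_on_err: float | None = None
    k_off: float | None = None
    k_off_err: float | None = None
    provenance: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def closure_ratio(self) -> float:
        """K_d k_on / k_off; 1 for a consistent triple."""
        if None in (self.Kd, self.k_on, self.k_off):
            raise ValueError("closure requires all three constants")
        return self.Kd * self.k_on / self.k_off

    def summary(self) -> str:
        def cell(v, e, prov):
            if v is None:
                return "-"
            tag = {"derived-via-closure": "*"}.get(prov, "")
            return f"{v:.3g} +/- {e:.2g}{tag}" if e is not None else f"{v:.3g}{tag}"

        return (
            f"{self.ligand:>8s} {self.pore:>10s}  "
            f"Kd={cell(self.Kd, self.Kd_err, self.provenance.get('Kd'))} M  "
            f"k_on={cell(self.k_on, self.k_on_err, self.provenance.get('k_on'))} /M/s  "
            f"k_off={cell(self.k_off, self.k_off_err, self.provenance.get('k_off'))} /s"
        )


def _quad_rel(z: float, x: float, sx: float, y: float, sy: float) -> float:
    return abs(z) * math.sqrt((sx / x) ** 2 + (sy / y) ** 2)


def complete_affinity(
    *,
    Kd: float | None = None,
    Kd_err: float = 0.0,
    k_on: float | None = None,
    k_on_err: float = 0.0,
    k_off: float | None = None,
    k_off_err: float = 0.0,
    ligand: str = "",
    pore: str = "",
    provenance: dict | None = None,
) -> AffinityRecord:
    """Close the kinetic triple via K_d = k_off / k_on.

    Exactly two of (Kd, k_on, k_off) must be supplied; the third is computed
    with its uncertainty from first-order quadrature of relative errors and
    marked "derived-via-closure".
    """
    given = {"Kd": Kd, "k_on": k_on, "k_off": k_off}
    present = [k for k, v in given.items() if v is not None]
    if len(present) != 2:
        raise ValueError(
            f"exactly two of (Kd, k_on, k_off) required, got {len(present)}: {present}"
        )
    prov = dict(provenance or {k: "fitted" for k in present})
    if Kd is None:
        if k_on == 0:
            raise ValueError("cannot derive Kd with k_on = 0")
        Kd = k_off / k_on
        Kd_err = _quad_rel(Kd, k_off, k_off_err, k_on, k_on_err)
        prov["Kd"] = "derived-via-closure"
    elif k_off is None:
        k_off = Kd * k_on
        k_off_err = _quad_rel(k_off, Kd, Kd_err, k_on, k_on_err)
        prov["k_off"] = "derived-via-closure"
    else:
        if Kd == 0:
            raise ValueError("cannot derive k_on with Kd = 0")
        k_on = k_off / Kd
        k_on_err = _quad_rel(k_on, k_off, k_off_err, Kd, Kd_err)
        prov["k_on"] = "derived-via-closure"
    return AffinityRecord(
        ligand, pore, Kd, Kd_err, k_on, k_on_err, k_off, k_off_err, prov
    )
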