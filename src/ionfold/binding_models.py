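"""Two-state (Hill) analysis of ion-titration folding curves.

A DNA four-way junction folds from the extended open form into the stacked-X
form as multivalent cations are added.  Any signal that tracks the folded
population — FRET efficiency of end-labeled junctions, or sensitized
lanthanide luminescence — follows a two-state isotherm in the total ion
concentration ``c``::

    S(c) = S0 + (Si - S0) * Ka * c**n / (1 + Ka * c**n)

where ``S0``/``Si`` are the initial (open) and final (stacked) signal levels,
``Ka`` is the apparent association constant (units M^-n) and ``n`` is the
Hill coefficient.  The apparent dissociation constant is the concentration at
which open and stacked populations are equal::

    Kd = Ka**(-1/n)

The Hill coefficient here reflects the *net* change in bound ions between the
open and stacked states (counterion displacement included), not a literal
binding-site count; for this junction it is empirically non-cooperative
(n ~ 1-1.1).

Free-ion concentration is approximated by total added ion: the titrant is in
large excess over the ~50 nM junction, so depletion is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np

from .exceptions import (
    FitConvergenceError,
    GridMismatchError,
    NoTransitionError,
)

__all__ = [
    "TitrationSeries",
    "TwoStateFit",
    "two_state_model",
    "fit_two_state",
    "kd_from_ka",
]

#: Bounds on the Hill coefficient during fitting.  Non-cooperative ion
#: binding gives n ~ 1; the wide band guards against runaway exponents on
#: poorly sampled transitions without constraining real data.
HILL_N_BOUNDS = (0.3, 4.0)

#: Log-spaced density of the Kd initialisation grid (points per decade).
KD_GRID_PER_DECADE = 8

#: Minimum number of titration points for a four-parameter fit.
MIN_FIT_POINTS = 5


@dataclass
class TitrationSeries:
    """Ordered (ion concentration, signal) pairs from one titration.

    Parameters
    ----------
    concentration_M
        Total added ion concentration in molar, weakly increasing, >= 0.
    signal
        Dimensionless signal (FRET efficiency, normalized intensity, ...).
    signal_sd
        Optional per-point standard deviation, same length as ``signal``.
    ion
        Label for the titrated ion (e.g. ``"Mg2+"``).
    temperature_K
        Sample temperature in kelvin.
    """

    concentration_M: np.ndarray
    signal: np.ndarray
    signal_sd: Optional[np.ndarray] = None
    ion: str = ""
    temperature_K: float = 283.15

    def __post_init__(self):
        self.concentration_M = np.asarray(self.concentration_M, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal_sd is not None:
            self.signal_sd = np.asarray(self.signal_sd, dtype=float)
        c = self.concentration_M
        if c.ndim != 1 or c.size == 0:
            raise ValueError("concentration grid must be a non-empty 1-D array")
        if c.size != self.signal.size:
            raise GridMismatchError(
                f"{c.size} concentrations but {self.signal.size} signal points"
            )
        if self.signal_sd is not None and self.signal_sd.size != c.size:
            raise GridMismatchError("signal_sd length does not match grid")
        if np.any(c < 0):
            raise ValueError("negative ion concentration")
        if np.any(np.diff(c) < 0):
            raise ValueError("concentrations must be weakly increasing")
        # beyond the first point (often c = 0) concentrations must be distinct
        if np.any(np.diff(c[1:]) <= 0) if c.size > 2 else False:
            raise ValueError("concentrations beyond the first point must be distinct")

    def __len__(self):
        return self.concentration_M.size


@dataclass
class TwoStateFit:
    """Result (or truth parameters) of a two-state isotherm fit.

    ``ka`` has units M^-n so that ``kd_apparent = ka**(-1/hill_n)`` is molar.
    ``stderr`` maps free-parameter names to standard errors (None when the
    covariance could not be estimated); ``covariance`` is ordered as
    ``param_names``.
    """

    e0: float
    ei: float
    ka: float
    hill_n: float
    kd_apparent: float = field(default=None)  # type: ignore[assignment]
    stderr: dict = field(default_factory=dict)
    covariance: Optional[np.ndarray] = None
    param_names: tuple = ()
    converged: bool = True
    residuals: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.kd_apparent is None:
            self.kd_apparent = kd_from_ka(self.ka, self.hill_n)

    @property
    def amplitude(self) -> float:
        """Total signal change Ei - E0 across the transition."""
        return self.ei - self.e0


def two_state_model(conc, e0: float, ei: float, ka: float, hill_n: float):
    """Evaluate the two-state folding isotherm at concentration(s) ``conc`` (M).

    Returns ``e0`` at zero concentration and approaches ``ei`` at saturation;
    at ``conc == ka**(-1/hill_n)`` the value is the midpoint ``(e0 + ei)/2``.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("invalid concentration: must be >= 0")
    occ = np.empty_like(c, dtype=float)
    with np.errstate(over="ignore"):
        x = ka * np.power(c, hill_n)
    occ = x / (1.0 + x)
    occ = np.where(np.isinf(x), 1.0, occ)
    out = e0 + (ei - e0) * occ
    return out if out.ndim else float(out)


def kd_from_ka(ka: float, hill_n: float) -> float:
    """Apparent dissociation constant Kd = Ka**(-1/n), in molar."""
    if ka <= 0 or hill_n <= 0:
        raise ValueError("Ka and Hill n must be positive")
    return float(ka ** (-1.0 / hill_n))


def _initial_guess(series: TitrationSeries) -> dict:
    """Endpoint baselines, n = 1, and a log-grid scan for the starting Kd."""
    c, s = series.concentration_M, series.signal
    e0, ei = float(s[0]), float(s[-1])
    cpos = c[c > 0]
    lo, hi = float(cpos.min()), float(cpos.max())
    ndec = max(1.0, np.log10(hi / lo))
    ngrid = max(4, int(np.ceil(ndec * KD_GRID_PER_DECADE)) + 1)
    kd_grid = np.logspace(np.log10(lo), np.log10(hi), ngrid)
    best_kd, best_ssr = kd_grid[0], np.inf
    for kd in kd_grid:
        model = two_state_model(c, e0, ei, 1.0 / kd, 1.0)
        ssr = float(np.sum((model - s) ** 2))
        if ssr < best_ssr:
            best_kd, best_ssr = kd, ssr
    return {"e0": e0, "ei": ei, "kd": float(best_kd), "n": 1.0}


def fit_two_state(series: TitrationSeries, init: Optional[dict] = None) -> TwoStateFit:
    """Fit the two-state isotherm to a titration by weighted least squares.

    All four parameters (E0, Ei, Ka, n) vary.  Ka is fitted as log(Ka) to
    enforce positivity and n is bounded to ``HILL_N_BOUNDS``.  Points are
    weighted by ``1/signal_sd`` when per-point uncertainties are present,
    otherwise unweighted.

    Raises
    ------
    NoTransitionError
        If the signal is flat (no transition to fit).
    FitConvergenceError
        If the optimizer fails; best-so-far parameters are attached.
    """
    if len(series) < MIN_FIT_POINTS:
        raise ValueError(f"need at least {MIN_FIT_POINTS} points to fit")
    s = series.signal
    span = float(np.ptp(s))
    if span == 0.0 or span < 1e-9 * max(1.0, float(np.max(np.abs(s)))):
        raise NoTransitionError("no transition detected: signal is flat")

    guess = _initial_guess(series)
    if init:
        guess.update(init)

    params = lmfit.Parameters()
    params.add("e0", value=guess["e0"])
    params.add("ei", value=guess["ei"])
    params.add("log_ka", value=-guess["n"] * np.log(guess["kd"]))
    params.add("hill_n", value=guess["n"], min=HILL_N_BOUNDS[0], max=HILL_N_BOUNDS[1])

    c = series.concentration_M
    weights = None
    if series.signal_sd is not None and np.all(series.signal_sd > 0):
        weights = 1.0 / series.signal_sd

    def residual(p):
        model = two_state_model(c, p["e0"].value, p["ei"].value,
                                np.exp(p["log_ka"].value), p["hill_n"].value)
        r = model - s
        return r * weights if weights is not None else r

    result = lmfit.minimize(residual, params, method="leastsq",
                            xtol=1e-12, ftol=1e-12)
    p = result.params
    values = {
        "e0": p["e0"].value,
        "ei": p["ei"].value,
        "ka": float(np.exp(p["log_ka"].value)),
        "hill_n": p["hill_n"].value,
    }
    if not result.success:
        raise FitConvergenceError("two-state fit did not converge", best=values)

    names = tuple(result.var_names)
    stderr = {name: p[name].stderr for name in names}
    # delta-method propagation of Kd = exp(-log_ka / n)
    kd = kd_from_ka(values["ka"], values["hill_n"])
    kd_sd = None
    if result.covar is not None and {"log_ka", "hill_n"} <= set(names):
        i, j = names.index("log_ka"), names.index("hill_n")
        lka, n = p["log_ka"].value, p["hill_n"].value
        grad = np.zeros(len(names))
        grad[i] = -kd / n
        grad[j] = kd * lka / n**2
        var = float(grad @ result.covar @ grad)
        kd_sd = float(np.sqrt(var)) if var > 0 else None
    stderr["kd_apparent"] = kd_sd

    return TwoStateFit(
        e0=values["e0"], ei=values["ei"], ka=values["ka"],
        hill_n=values["hill_n"], kd_apparent=kd,
        stderr=stderr, covariance=result.covar, param_names=names,
        converged=bool(result.success),
        residuals=np.asarray(result.residual, dtype=float),
    )
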