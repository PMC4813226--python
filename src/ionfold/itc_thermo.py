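"""Isothermal titration calorimetry with two independent classes of sites.

Mg2+ titrated into the junction shows an initial exothermic phase (two ions
binding site-specifically at the junction center, driving folding) followed
by an endothermic phase (nonspecific displacement of condensed Na+ from the
backbone).  The cumulative heat content of the cell with classes of
independent sites i is::

    Q = V * [M] * sum_i  n_i * dH_i * K_i * [L] / (1 + K_i * [L])

with V the reaction volume, [M] the macromolecule (junction) concentration,
n_i the sites per macromolecule, K_i the per-site association constant and
dH_i the molar binding enthalpy.  The free-ligand concentration [L] is the
unique root of the mass balance::

    L_tot = [L] + [M] * sum_i n_i K_i [L] / (1 + K_i [L])

Because the two-class fit is poorly identified from calorimetry alone, the
class-1 parameters (dH1, K1) are fixed to values measured independently by
van't Hoff analysis of temperature-dependent FRET titrations
(ln Ka = -dH/(R T) + dS/R), and only n1, n2, dH2, K2 vary.

Injection bookkeeping uses the standard overfill-cell perfusion model: each
injection of volume v displaces cell liquid, so concentrations dilute by
(1 - v/V) while the syringe ligand enters at v/V of its syringe
concentration.  Per-injection heats carry the midpoint displaced-volume
correction dQ_i = Q_i - Q_{i-1} + (v_i/V) * (Q_i + Q_{i-1}) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import lmfit
import numpy as np
from scipy import optimize, stats

from .exceptions import FitConvergenceError, UnidentifiableModelError

__all__ = [
    "R_CAL",
    "BindingClass",
    "ItcExperiment",
    "InjectionSeries",
    "ThermoParams",
    "VantHoffFit",
    "TwoClassFitResult",
    "solve_free_ligand",
    "cumulative_heat",
    "simulate_injection_series",
    "fit_two_class",
    "fit_one_class",
    "concatenate",
    "vant_hoff_fit",
    "entropy_from",
    "thermo_params",
]

#: Gas constant in cal/(mol K).
R_CAL = 1.9872

#: Default reaction-cell volume (L) for a VP-class titration calorimeter.
DEFAULT_CELL_VOLUME_L = 1.4e-3


@dataclass(frozen=True)
class BindingClass:
    """One class of independent binding sites.

    ``n_sites`` is sites per macromolecule, ``ka_per_M`` the per-site
    association constant (M^-1), ``dh_kcal`` the binding enthalpy in
    kcal/(mol ion).  ``fixed`` lists field names held constant in fits.
    """

    n_sites: float
    ka_per_M: float
    dh_kcal: float
    fixed: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_sites <= 0:
            raise ValueError("n_sites must be > 0")
        if self.ka_per_M < 0:
            raise ValueError("Ka must be >= 0")


@dataclass
class ItcExperiment:
    """Cell/syringe composition and injection schedule of one ITC run."""

    cell_volume_L: float = DEFAULT_CELL_VOLUME_L
    cell_macromolecule_M: float = 16e-6
    syringe_ligand_M: float = 0.85e-3
    injection_volumes_L: np.ndarray = field(
        default_factory=lambda: np.full(50, 10e-6)
    )
    heats_ucal: Optional[np.ndarray] = None
    temperature_K: float = 283.15

    def __post_init__(self):
        self.injection_volumes_L = np.asarray(self.injection_volumes_L, dtype=float)
        if self.heats_ucal is not None:
            self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.cell_volume_L <= 0 or np.any(self.injection_volumes_L <= 0):
            raise ValueError("volumes must be positive")
        if self.injection_volumes_L.size < 1:
            raise ValueError("at least one injection required")
        if (self.heats_ucal is not None
                and self.heats_ucal.size != self.injection_volumes_L.size):
            raise ValueError("heats length does not match injection schedule")

    @property
    def n_injections(self) -> int:
        return int(self.injection_volumes_L.size)


@dataclass(frozen=True)
class InjectionSeries:
    """Forward-modeled per-injection heats and cell composition trajectory."""

    heats_ucal: np.ndarray               # per-injection heat, µcal
    ndh_kcal_per_mol: np.ndarray         # normalized heat per mole injectant
    macromolecule_M: np.ndarray          # cell [M] after each injection
    ligand_total_M: np.ndarray           # cell total [L] after each injection
    q_cumulative_cal: np.ndarray         # cumulative heat content, cal


def solve_free_ligand(
    l_tot_M: float, m_tot_M: float, classes: Sequence[BindingClass]
) -> float:
    """Free-ligand concentration from the mass balance, in molar.

    The root of ``L + M * sum_i n_i K_i L/(1+K_i L) - L_tot`` on
    ``[0, L_tot]``; the left side is strictly increasing in L so the root is
    unique.  Bracketed Brent root-finding to ~1e-12 relative tolerance.
    """
    if l_tot_M < 0 or m_tot_M < 0:
        raise ValueError("concentrations must be >= 0")
    if l_tot_M == 0.0:
        return 0.0
    if m_tot_M == 0.0 or all(c.ka_per_M == 0.0 for c in classes):
        return float(l_tot_M)

    def f(L):
        bound = sum(
            c.n_sites * c.ka_per_M * L / (1.0 + c.ka_per_M * L) for c in classes
        )
        return L + m_tot_M * bound - l_tot_M

    if f(l_tot_M) <= 0:          # numerically saturated: all ligand free
        return float(l_tot_M)
    root = optimize.brentq(f, 0.0, l_tot_M, xtol=1e-30, rtol=8.9e-16)
    return float(min(max(root, 0.0), l_tot_M))


def _heat_content_cal(
    m_tot_M: float,
    l_tot_M: float,
    volume_L: float,
    classes: Sequence[BindingClass],
) -> float:
    """Cumulative heat content Q (cal) of a cell at the given composition."""
    L = solve_free_ligand(l_tot_M, m_tot_M, classes)
    q = 0.0
    for c in classes:
        occ = c.ka_per_M * L / (1.0 + c.ka_per_M * L)
        q += c.n_sites * c.dh_kcal * 1000.0 * occ     # kcal/mol -> cal/mol
    return volume_L * m_tot_M * q


def cumulative_heat(
    l_tot_M: float, exp: ItcExperiment, classes: Sequence[BindingClass]
) -> float:
    """Cumulative heat (cal) at total ligand ``l_tot_M`` in the given cell."""
    return _heat_content_cal(
        exp.cell_macromolecule_M, l_tot_M, exp.cell_volume_L, classes
    )


def simulate_injection_series(
    exp: ItcExperiment,
    classes: Sequence[BindingClass],
    displaced_volume_correction: bool = True,
) -> InjectionSeries:
    """Forward-model per-injection heats for an injection schedule.

    Cell dilution follows the perfusion model (concentrations scale by
    ``1 - v/V`` per injection); the per-injection heat is the increment of
    cumulative heat content plus, when enabled, the midpoint correction for
    the reaction volume displaced by the injection.
    """
    V = exp.cell_volume_L
    m = exp.cell_macromolecule_M
    lt = 0.0
    q_prev = _heat_content_cal(m, lt, V, classes)
    heats, ndh, ms, lts, qs = [], [], [], [], []
    for v in exp.injection_volumes_L:
        d = v / V
        m = m * (1.0 - d)
        lt = lt * (1.0 - d) + exp.syringe_ligand_M * d
        q = _heat_content_cal(m, lt, V, classes)
        dq = q - q_prev
        if displaced_volume_correction:
            dq += d * (q + q_prev) / 2.0
        heats.append(dq * 1e6)                        # cal -> µcal
        mol_injected = v * exp.syringe_ligand_M
        ndh.append(dq / mol_injected / 1000.0)        # cal/mol -> kcal/mol
        ms.append(m)
        lts.append(lt)
        qs.append(q)
        q_prev = q
    return InjectionSeries(
        heats_ucal=np.array(heats),
        ndh_kcal_per_mol=np.array(ndh),
        macromolecule_M=np.array(ms),
        ligand_total_M=np.array(lts),
        q_cumulative_cal=np.array(qs),
    )


def concatenate(exps: Sequence[ItcExperiment]) -> ItcExperiment:
    """Append titration rounds performed on the same cell contents.

    The syringe is refilled with the same titrant between rounds, so the
    concatenated schedule is simply the joined injection list; cumulative
    dilution carries across rounds because the forward model tracks cell
    state per injection from the initial composition.
    """
    exps = [e for e in exps if e.n_injections > 0]
    if not exps:
        raise ValueError("nothing to concatenate")
    first = exps[0]
    for e in exps[1:]:
        same = (
            np.isclose(e.cell_volume_L, first.cell_volume_L, rtol=1e-12)
            and np.isclose(e.cell_macromolecule_M, first.cell_macromolecule_M, rtol=1e-12)
            and np.isclose(e.syringe_ligand_M, first.syringe_ligand_M, rtol=1e-12)
            and np.isclose(e.temperature_K, first.temperature_K, rtol=1e-12)
        )
        if not same:
            raise ValueError("mismatched cell metadata between titration rounds")
    volumes = np.concatenate([e.injection_volumes_L for e in exps])
    heats = None
    if all(e.heats_ucal is not None for e in exps):
        heats = np.concatenate([e.heats_ucal for e in exps])
    return replace(first, injection_volumes_L=volumes, heats_ucal=heats)


# --- fitting ----------------------------------------------------------------

@dataclass
class TwoClassFitResult:
    """Two-class ITC fit with class-1 (dH, Ka) fixed a priori."""

    class1: BindingClass
    class2: BindingClass
    blank_offset_ucal: float
    chi2_ucal2: float                     # sum of squared residuals, (µcal)^2
    stderr: dict
    covariance: Optional[np.ndarray]
    converged: bool
    residuals_ucal: np.ndarray
    ds1_cal: float = None                 # type: ignore[assignment]
    ds2_cal: float = None                 # type: ignore[assignment]


def fit_two_class(
    exp: ItcExperiment,
    fixed_class1: BindingClass,
    fit_blank_offset: bool = True,
) -> TwoClassFitResult:
    """Fit a two-class site model with class-1 dH and Ka held fixed.

    Free parameters are n1, n2 (log-transformed for positivity), dH2 and
    log K2, plus an optional constant per-injection blank offset for
    dilution heats.  Residuals are in µcal; ``chi2_ucal2`` is their sum of
    squares (comparability with any particular vendor software's chi-square
    is not claimed).  Per-class entropies at the experiment temperature are
    derived from the fitted parameters.
    """
    if exp.heats_ucal is None:
        raise ValueError("experiment carries no measured heats")
    data = exp.heats_ucal

    params = lmfit.Parameters()
    params.add("log_n1", value=np.log(max(fixed_class1.n_sites, 1e-3)))
    total_ligand = float(
        np.sum(exp.injection_volumes_L) * exp.syringe_ligand_M / exp.cell_volume_L
    )
    n2_init = max(1.0, 0.5 * total_ligand / exp.cell_macromolecule_M)
    params.add("log_n2", value=np.log(n2_init))
    params.add("dh2", value=1.0)
    params.add("log_k2", value=np.log(1e4))
    params.add("offset", value=0.0, vary=fit_blank_offset)

    def residual(p):
        c1 = BindingClass(
            n_sites=np.exp(p["log_n1"].value),
            ka_per_M=fixed_class1.ka_per_M,
            dh_kcal=fixed_class1.dh_kcal,
        )
        c2 = BindingClass(
            n_sites=np.exp(p["log_n2"].value),
            ka_per_M=np.exp(p["log_k2"].value),
            dh_kcal=p["dh2"].value,
        )
        model = simulate_injection_series(exp, [c1, c2]).heats_ucal
        return model + p["offset"].value - data

    result = lmfit.minimize(residual, params, method="leastsq",
                            xtol=1e-12, ftol=1e-12)
    p = result.params
    best = {
        "n1": float(np.exp(p["log_n1"].value)),
        "n2": float(np.exp(p["log_n2"].value)),
        "dh2": float(p["dh2"].value),
        "k2": float(np.exp(p["log_k2"].value)),
        "offset": float(p["offset"].value),
    }
    if not result.success:
        raise FitConvergenceError("two-class ITC fit did not converge", best=best)
    if result.covar is None:
        raise UnidentifiableModelError(
            "unidentifiable: singular Jacobian in two-class fit", best=best
        )

    class1 = BindingClass(
        n_sites=best["n1"],
        ka_per_M=fixed_class1.ka_per_M,
        dh_kcal=fixed_class1.dh_kcal,
        fixed=("ka_per_M", "dh_kcal"),
    )
    class2 = BindingClass(n_sites=best["n2"], ka_per_M=best["k2"], dh_kcal=best["dh2"])
    res = np.asarray(result.residual, dtype=float)
    return TwoClassFitResult(
        class1=class1,
        class2=class2,
        blank_offset_ucal=best["offset"],
        chi2_ucal2=float(np.sum(res**2)),
        stderr={name: p[name].stderr for name in result.var_names},
        covariance=result.covar,
        converged=True,
        residuals_ucal=res,
        ds1_cal=entropy_from(class1.dh_kcal, class1.ka_per_M, exp.temperature_K),
        ds2_cal=entropy_from(class2.dh_kcal, class2.ka_per_M, exp.temperature_K),
    )


def fit_one_class(
    exp: ItcExperiment, fit_blank_offset: bool = True
) -> TwoClassFitResult:
    """Single-class reference fit (n, dH, K all free) for model comparison.

    Returned in the same container with ``class2`` absent semantics: class2
    has zero sites' worth of heat (n2 -> 0 is not representable, so a zero-Ka
    placeholder is used).
    """
    if exp.heats_ucal is None:
        raise ValueError("experiment carries no measured heats")
    data = exp.heats_ucal
    params = lmfit.Parameters()
    total_ligand = float(
        np.sum(exp.injection_volumes_L) * exp.syringe_ligand_M / exp.cell_volume_L
    )
    params.add("log_n", value=np.log(max(1.0, 0.5 * total_ligand / exp.cell_macromolecule_M)))
    params.add("dh", value=float(np.sign(np.sum(data)) or 1.0))
    params.add("log_k", value=np.log(1e4))
    params.add("offset", value=0.0, vary=fit_blank_offset)

    def residual(p):
        c = BindingClass(
            n_sites=np.exp(p["log_n"].value),
            ka_per_M=np.exp(p["log_k"].value),
            dh_kcal=p["dh"].value,
        )
        model = simulate_injection_series(exp, [c]).heats_ucal
        return model + p["offset"].value - data

    result = lmfit.minimize(residual, params, method="leastsq",
                            xtol=1e-12, ftol=1e-12)
    p = result.params
    c = BindingClass(
        n_sites=float(np.exp(p["log_n"].value)),
        ka_per_M=float(np.exp(p["log_k"].value)),
        dh_kcal=float(p["dh"].value),
    )
    res = np.asarray(result.residual, dtype=float)
    return TwoClassFitResult(
        class1=c,
        class2=BindingClass(n_sites=1e-12, ka_per_M=0.0, dh_kcal=0.0),
        blank_offset_ucal=float(p["offset"].value),
        chi2_ucal2=float(np.sum(res**2)),
        stderr={name: p[name].stderr for name in result.var_names},
        covariance=result.covar,
        converged=bool(result.success),
        residuals_ucal=res,
        ds1_cal=entropy_from(c.dh_kcal, c.ka_per_M, exp.temperature_K),
        ds2_cal=0.0,
    )


# --- van't Hoff and derived thermodynamics ----------------------------------

@dataclass(frozen=True)
class VantHoffFit:
    """Linear van't Hoff regression ln Ka = -(dH/R)(1/T) + dS/R."""

    temperatures_K: np.ndarray
    ka_values_per_M: np.ndarray
    dh_kcal: float
    ds_cal: float
    r_squared: float


def vant_hoff_fit(
    temps_K: Sequence[float], kas_per_M: Sequence[float]
) -> VantHoffFit:
    """Ordinary least squares of ln Ka on 1/T.

    dH = -slope * R (kcal/mol), dS = intercept * R (cal/(mol K)).
    """
    t = np.asarray(temps_K, dtype=float)
    k = np.asarray(kas_per_M, dtype=float)
    if t.size != k.size:
        raise ValueError("temperature and Ka lists differ in length")
    if t.size < 2:
        raise ValueError("need at least 2 temperatures for a van't Hoff line")
    if np.any(t <= 0) or np.any(k <= 0):
        raise ValueError("temperatures and Ka values must be positive")
    x, y = 1.0 / t, np.log(k)
    if t.size == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
        r2 = 1.0
    else:
        reg = stats.linregress(x, y)
        slope, intercept = reg.slope, reg.intercept
        r2 = reg.rvalue**2
    return VantHoffFit(
        temperatures_K=t,
        ka_values_per_M=k,
        dh_kcal=float(-slope * R_CAL / 1000.0),
        ds_cal=float(intercept * R_CAL),
        r_squared=float(r2),
    )


def entropy_from(dh_kcal: float, ka_per_M: float, temperature_K: float) -> float:
    """Binding entropy, cal/(mol K), from dH, Ka and T.

    dG = -R T ln Ka; dS = (dH - dG)/T.
    """
    if ka_per_M <= 0 or temperature_K <= 0:
        raise ValueError("Ka and T must be positive")
    dg_cal = -R_CAL * temperature_K * np.log(ka_per_M)
    return float((dh_kcal * 1000.0 - dg_cal) / temperature_K)


@dataclass(frozen=True)
class ThermoParams:
    """Consistent {dH, dS, dG, Ka, T} bundle for one binding class."""

    dh_kcal: float
    ds_cal: float
    dg_kcal: float
    ka_per_M: float
    temperature_K: float

    def __post_init__(self):
        dg1 = self.dh_kcal - self.temperature_K * self.ds_cal / 1000.0
        dg2 = -R_CAL * self.temperature_K * np.log(self.ka_per_M) / 1000.0
        if abs(dg1 - self.dg_kcal) > 1e-9 or abs(dg2 - self.dg_kcal) > 1e-9:
            raise ValueError("inconsistent thermodynamic bundle")


def thermo_params(dh_kcal: float, ka_per_M: float, temperature_K: float) -> ThermoParams:
    """Build a consistent :class:`ThermoParams` bundle from (dH, Ka, T)."""
    ds = entropy_from(dh_kcal, ka_per_M, temperature_K)
    dg = dh_kcal - temperature_K * ds / 1000.0
    return ThermoParams(
        dh_kcal=dh_kcal, ds_cal=ds, dg_kcal=dg,
        ka_per_M=ka_per_M, temperature_K=temperature_K,
    )
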