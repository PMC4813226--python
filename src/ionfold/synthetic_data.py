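"""Seeded synthetic inputs for every stage of the pipeline.

No instrument data ships with the package, so each analysis consumes data
from a generator whose forward model is exactly the model the corresponding
fitter assumes: two-state Hill titrations, two-class ITC thermograms with
perfusion dilution, Gaussian emission bands, mono-exponential luminescence
decays, and van't Hoff temperature series.  At ``noise_scale = 0`` every
generator is the exact forward model, so generate→fit round trips recover
the truth to numerical tolerance.

Presets encode the study conditions (concentrations, truth parameters and
noise scales) under which the analyses are exercised:

``mg_fret``
    Mg2+ FRET titration: Kd 22 µM, Hill n 1.05, E0 0.05, Ei 0.35, Gaussian
    noise sd 0.01 on a 20-point log grid over 1-1000 µM.
``itc_table1``
    Two-class ITC truth (n1 2.1, K1 40,180 M^-1, dH1 -14.9 kcal/mol;
    n2 15.9, K2 25,000 M^-1, dH2 +1.9 kcal/mol), 50 x 10 µL of 0.85 mM
    titrant into 16 µM junction in a 1.4 mL cell, heat noise sd 0.1 µcal.
``eu_decay`` / ``lret_series``
    Mono-exponential Eu3+ decays at 124.8 µs (junction-bound donor) and
    74.7 µs (Nd3+-quenched), SNR 100.
``tb_lum``
    Tb3+ sensitized-luminescence titration: composite of a specific site
    (Kd 0.2 µM) and a weaker nonspecific component (Kd 10 µM) whose
    amplitude is calibrated so a single-site fit reports an apparent Kd of
    1.2 µM; noise sd 1% of the dynamic range.

Noise scales are conventions chosen to match the relative error visible in
typical data of each kind, not measured instrument parameters.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .binding_models import TitrationSeries, TwoStateFit, fit_two_state, two_state_model
from .fret_core import DyePhotophysics, Spectrum, SpectrumRole, ratio_a_from_efficiency
from .itc_thermo import (
    BindingClass,
    ItcExperiment,
    R_CAL,
    simulate_injection_series,
)
from .lanthanide import LuminescenceDecay

__all__ = [
    "SimConfig",
    "GaussianBand",
    "gen_fret_titration",
    "gen_itc",
    "gen_decay",
    "gen_spectra_pair",
    "gen_temperature_series",
    "gen_tb_binding",
    "noise_sample",
    "make_two_state_truth",
    "preset",
    "PRESET_NAMES",
    "MG_FRET_TRUTH",
    "ITC_CLASS1_TRUTH",
    "ITC_CLASS2_TRUTH",
    "VANT_HOFF_TEMPS_K",
    "ION_KD_TRUTHS_M",
]


@dataclass(frozen=True)
class SimConfig:
    """Seeded noise and grid specification shared by all generators.

    ``noise_scale`` is in the signal units of the generated quantity
    (efficiency units, µcal, counts...).  ``grid_range``/``n_points``/
    ``spacing`` override a generator's default grid when set.
    """

    seed: int = 0
    noise_model: str = "gaussian_additive"   # or "poisson"
    noise_scale: float = 0.0
    n_points: Optional[int] = None
    grid_range: Optional[Tuple[float, float]] = None
    spacing: str = "log"                     # "log" or "linear"

    def __post_init__(self):
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.noise_model not in ("gaussian_additive", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.spacing not in ("log", "linear"):
            raise ValueError("spacing must be 'log' or 'linear'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def make_grid(self, default_range: Tuple[float, float], default_n: int) -> np.ndarray:
        lo, hi = self.grid_range if self.grid_range is not None else default_range
        n = self.n_points if self.n_points is not None else default_n
        if self.spacing == "log":
            return np.logspace(np.log10(lo), np.log10(hi), n)
        return np.linspace(lo, hi, n)


def _apply_noise(rng: np.random.Generator, model: np.ndarray, cfg: SimConfig,
                 floor_zero: bool = False) -> np.ndarray:
    if cfg.noise_model == "poisson":
        return rng.poisson(np.clip(model, 0, None)).astype(float)
    if cfg.noise_scale == 0.0:
        return model.copy()
    out = model + rng.normal(0.0, cfg.noise_scale, size=model.shape)
    if floor_zero:
        out = np.clip(out, 0.0, None)
    return out


def noise_sample(cfg: SimConfig, n: int) -> np.ndarray:
    """Draw ``n`` realizations of the configured additive noise model."""
    return _apply_noise(cfg.rng(), np.zeros(n), cfg)


# --- study-condition constants ---------------------------------------------

def make_two_state_truth(e0: float, ei: float, kd_M: float, hill_n: float) -> TwoStateFit:
    """Truth parameters for a two-state titration with Kd given in molar."""
    return TwoStateFit(e0=e0, ei=ei, ka=kd_M ** (-hill_n), hill_n=hill_n)


#: Mg2+ FRET truth: Kd 22 µM, non-cooperative (n 1.05), efficiency 0.05->0.35.
MG_FRET_TRUTH = make_two_state_truth(e0=0.05, ei=0.35, kd_M=22e-6, hill_n=1.05)

#: Two-class ITC truth parameters (site-specific and backbone classes).
ITC_CLASS1_TRUTH = BindingClass(n_sites=2.1, ka_per_M=40_180.0, dh_kcal=-14.9)
ITC_CLASS2_TRUTH = BindingClass(n_sites=15.9, ka_per_M=25_000.0, dh_kcal=1.9)

#: Temperatures of the van't Hoff FRET series (4, 10, 20, 25, 30 degC).
VANT_HOFF_TEMPS_K = (277.15, 283.15, 293.15, 298.15, 303.15)

#: Apparent Kd truths (M) per ion for the folding titrations.
ION_KD_TRUTHS_M: Dict[str, float] = {
    "Ca2+": 55e-6,
    "Mg2+": 22e-6,
    "Co(NH3)6_3+": 4e-6,
    "Tb3+": 0.1e-6,
    "Eu3+": 3e-6,
    "Nd3+": 0.7e-6,
}


# --- generators -------------------------------------------------------------

def gen_fret_titration(
    truth: TwoStateFit, cfg: SimConfig, ion: str = "", temperature_K: float = 283.15
) -> TitrationSeries:
    """Two-state titration: model curve plus additive noise.

    Default grid: 20 log-spaced concentrations over [Kd/50, 50 Kd].
    """
    kd = truth.kd_apparent
    conc = cfg.make_grid((kd / 50.0, 50.0 * kd), 20)
    model = two_state_model(conc, truth.e0, truth.ei, truth.ka, truth.hill_n)
    signal = _apply_noise(cfg.rng(), model, cfg)
    sd = None
    if cfg.noise_model == "gaussian_additive" and cfg.noise_scale > 0:
        sd = np.full_like(signal, cfg.noise_scale)
    return TitrationSeries(
        concentration_M=conc, signal=signal, signal_sd=sd,
        ion=ion, temperature_K=temperature_K,
    )


def gen_itc(
    classes: Sequence[BindingClass], exp: ItcExperiment, cfg: SimConfig
) -> ItcExperiment:
    """Simulated thermogram: forward-model heats plus Gaussian noise (µcal)."""
    heats = simulate_injection_series(exp, classes).heats_ucal
    noisy = _apply_noise(cfg.rng(), heats, cfg)
    return ItcExperiment(
        cell_volume_L=exp.cell_volume_L,
        cell_macromolecule_M=exp.cell_macromolecule_M,
        syringe_ligand_M=exp.syringe_ligand_M,
        injection_volumes_L=exp.injection_volumes_L.copy(),
        heats_ucal=noisy,
        temperature_K=exp.temperature_K,
    )


def gen_decay(
    tau_us: float,
    amplitude: float,
    baseline: float,
    cfg: SimConfig,
    excitation_wavelength_nm: Optional[float] = None,
    label: str = "",
) -> LuminescenceDecay:
    """Mono-exponential decay I(t) = A exp(-t/tau) + b on a 0-1000 µs, 1 µs grid."""
    if tau_us <= 0:
        raise ValueError("tau must be positive")
    t = (np.arange(0.0, 1000.0 + 1.0, 1.0) if cfg.grid_range is None
         else cfg.make_grid((0.0, 1000.0), 1001))
    model = amplitude * np.exp(-t / tau_us) + baseline
    intensity = _apply_noise(cfg.rng(), model, cfg, floor_zero=True)
    return LuminescenceDecay(
        time_us=t, intensity=intensity,
        excitation_wavelength_nm=excitation_wavelength_nm, label=label,
    )


@dataclass(frozen=True)
class GaussianBand:
    """Gaussian spectral band: center/width in nm, amplitude in signal units."""

    center_nm: float
    sigma_nm: float
    amplitude: float

    def evaluate(self, wl: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-0.5 * ((wl - self.center_nm) / self.sigma_nm) ** 2)


#: Scan windows (nm) and resolution matching the fluorimeter protocol.
DONOR_SCAN_NM = (508.0, 652.0)
ACCEPTOR_SCAN_NM = (570.0, 700.0)
SCAN_STEP_NM = 2.0


def gen_spectra_pair(
    donor: GaussianBand = GaussianBand(520.0, 15.0, 100.0),
    acceptor: GaussianBand = GaussianBand(580.0, 15.0, 100.0),
    crosstalk: float = 0.0,
    cfg: SimConfig = SimConfig(),
    target_efficiency: Optional[float] = None,
    dyes: DyePhotophysics = DyePhotophysics(),
) -> Dict[str, Spectrum]:
    """Gaussian emission bands for the (ratio)_A channels.

    Returns the donor-emission spectrum plus the acceptor-emission band of
    the doubly-labeled sample under donor excitation (``acceptor_AD``) and
    direct acceptor excitation (``acceptor_A``), on 2 nm/pt grids over the
    instrument scan windows.  When ``target_efficiency`` is given, the
    F_AD/F_A amplitude ratio is set by the exact algebraic inverse of the
    (ratio)_A efficiency equation so that the analysis recovers that
    efficiency.  ``crosstalk`` adds that fraction of the donor band into the
    donor-excited acceptor channel (red-tail leakage).
    """
    wl_d = np.arange(DONOR_SCAN_NM[0], DONOR_SCAN_NM[1] + SCAN_STEP_NM, SCAN_STEP_NM)
    wl_a = np.arange(ACCEPTOR_SCAN_NM[0], ACCEPTOR_SCAN_NM[1] + SCAN_STEP_NM, SCAN_STEP_NM)

    rng = cfg.rng()
    donor_em = _apply_noise(rng, donor.evaluate(wl_d), cfg, floor_zero=True)

    if target_efficiency is not None:
        r = ratio_a_from_efficiency(target_efficiency, dyes)
    else:
        r = 1.0
    f_a = acceptor.evaluate(wl_a)
    f_ad = r * f_a + crosstalk * donor.evaluate(wl_a)
    return {
        "donor_emission": Spectrum(wl_d, donor_em, SpectrumRole.DONOR_EMISSION),
        "acceptor_AD": Spectrum(
            wl_a, _apply_noise(rng, f_ad, cfg, floor_zero=True),
            SpectrumRole.ACCEPTOR_EMISSION,
        ),
        "acceptor_A": Spectrum(
            wl_a, _apply_noise(rng, f_a, cfg, floor_zero=True),
            SpectrumRole.ACCEPTOR_EMISSION,
        ),
    }


def gen_temperature_series(
    dh_kcal: float,
    ds_cal: float,
    temps_K: Sequence[float] = VANT_HOFF_TEMPS_K,
    cfg: SimConfig = SimConfig(),
) -> Tuple[np.ndarray, np.ndarray]:
    """Association constants obeying ln Ka = -dH/(R T) + dS/R.

    ``noise_scale`` is interpreted as the sigma of lognormal noise on Ka
    (i.e. Gaussian on ln Ka).
    """
    t = np.asarray(temps_K, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive")
    ln_ka = -dh_kcal * 1000.0 / (R_CAL * t) + ds_cal / R_CAL
    if cfg.noise_scale > 0:
        ln_ka = ln_ka + cfg.rng().normal(0.0, cfg.noise_scale, size=t.shape)
    return t, np.exp(ln_ka)


def gen_tb_binding(
    kd_specific_M: float,
    nonspecific_amp: float,
    kd_nonspecific_M: float,
    cfg: SimConfig,
    specific_amp: float = 1.0,
    temperature_K: float = 283.15,
) -> TitrationSeries:
    """Sensitized-luminescence titration with specific + nonspecific components.

    Signal is the sum of two saturable (Langmuir) components; the specific
    site must be tighter than the nonspecific one.  Default grid: 20
    log-spaced points from kd_specific/20 to 5 x kd_nonspecific.
    """
    if not (0 < kd_specific_M < kd_nonspecific_M):
        raise ValueError("require 0 < kd_specific < kd_nonspecific")
    conc = cfg.make_grid((kd_specific_M / 20.0, 5.0 * kd_nonspecific_M), 20)
    model = (specific_amp * conc / (kd_specific_M + conc)
             + nonspecific_amp * conc / (kd_nonspecific_M + conc))
    signal = _apply_noise(cfg.rng(), model, cfg)
    return TitrationSeries(
        concentration_M=conc, signal=signal,
        signal_sd=(np.full_like(signal, cfg.noise_scale)
                   if cfg.noise_scale > 0 else None),
        ion="Tb3+", temperature_K=temperature_K,
    )


# --- presets ----------------------------------------------------------------

#: Tb3+ composite parameters: specific site from the FRET titration, weak
#: nonspecific backbone component.
TB_KD_SPECIFIC_M = 0.2e-6
TB_KD_NONSPECIFIC_M = 10e-6
TB_TARGET_APPARENT_KD_M = 1.2e-6


@functools.lru_cache(maxsize=8)
def calibrate_tb_nonspecific_amplitude(
    kd_specific_M: float = TB_KD_SPECIFIC_M,
    kd_nonspecific_M: float = TB_KD_NONSPECIFIC_M,
    target_kd_M: float = TB_TARGET_APPARENT_KD_M,
) -> float:
    """Nonspecific amplitude at which a single-site fit of the noiseless
    composite isotherm reports ``target_kd_M``.

    The apparent Kd of the composite grows monotonically with the
    nonspecific amplitude, so a bracketed root-find on the noiseless
    generate→fit map is well posed and deterministic.
    """

    def apparent_kd(amp: float) -> float:
        series = gen_tb_binding(
            kd_specific_M, amp, kd_nonspecific_M, SimConfig(seed=0, noise_scale=0.0)
        )
        return fit_two_state(series).kd_apparent

    return float(
        optimize.brentq(
            lambda a: apparent_kd(a) - target_kd_M, 0.02, 10.0, rtol=1e-10
        )
    )


def default_itc_experiment(temperature_K: float = 283.15) -> ItcExperiment:
    """The ITC protocol: 50 x 10 µL of 0.85 mM titrant into 16 µM junction."""
    return ItcExperiment(
        cell_volume_L=1.4e-3,
        cell_macromolecule_M=16e-6,
        syringe_ligand_M=0.85e-3,
        injection_volumes_L=np.full(50, 10e-6),
        temperature_K=temperature_K,
    )


#: Default noise scales per preset (signal units).
FRET_NOISE_SD = 0.01          # efficiency units
ITC_NOISE_SD_UCAL = 0.1       # µcal per injection
DECAY_SNR = 100.0             # amplitude / gaussian sigma

PRESET_NAMES = ("mg_fret", "itc_table1", "eu_decay", "lret_series", "tb_lum")


def preset(name: str, seed: int = 0):
    """Generate one of the named study-condition datasets.

    Returns a :class:`TitrationSeries`, :class:`ItcExperiment` or
    :class:`LuminescenceDecay` depending on the preset.
    """
    if name == "mg_fret":
        cfg = SimConfig(seed=seed, noise_scale=FRET_NOISE_SD,
                        grid_range=(1e-6, 1e-3), n_points=20)
        return gen_fret_titration(MG_FRET_TRUTH, cfg, ion="Mg2+")
    if name == "itc_table1":
        cfg = SimConfig(seed=seed, noise_scale=ITC_NOISE_SD_UCAL)
        return gen_itc([ITC_CLASS1_TRUTH, ITC_CLASS2_TRUTH],
                       default_itc_experiment(), cfg)
    if name == "eu_decay":
        amp, base = 1000.0, 10.0
        cfg = SimConfig(seed=seed, noise_scale=amp / DECAY_SNR)
        return gen_decay(124.8, amp, base, cfg, label="Eu3+-4WJ donor")
    if name == "lret_series":
        amp, base = 1000.0, 10.0
        cfg = SimConfig(seed=seed, noise_scale=amp / DECAY_SNR)
        return gen_decay(74.7, amp, base, cfg, label="Eu3+-4WJ + Nd3+ (0.25:1)")
    if name == "tb_lum":
        amp = calibrate_tb_nonspecific_amplitude()
        dynamic_range = 1.0 + amp
        cfg = SimConfig(seed=seed, noise_scale=0.01 * dynamic_range)
        return gen_tb_binding(TB_KD_SPECIFIC_M, amp, TB_KD_NONSPECIFIC_M, cfg)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
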