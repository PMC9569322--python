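"""Synthetic data generators: exact forward models of every fitter.

Each generator emits one of the six input data kinds (titration, quenching
series, depth profile, TCSPC decay, binding time course, emission spectrum)
from the same model its consuming fitter assumes, so that every pipeline
stage is testable without experimental data.  The scenario library carries
one parameter set per toxin variant / membrane composition studied
(sticholysins StnI and StnII, their inactive double-Cys mutants and
single-Trp mutants, on DOPC:PSM:Chol 70:15:15 and DOPC:PSM 80:20 vesicles).

Noise defaults: multiplicative Gaussian with CV 2% for steady-state
intensities, additive Gaussian sigma 0.05 on quenching-profile values,
Poisson counting noise for TCSPC histograms.  Pass a zero noise scale for
exact forward-model output.  All stochastic output is reproducible from the
``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .binding import TitrationCurve, bound_fraction
from .depth import DEFAULT_QUENCHER_DEPTHS, DepthProfile, depth_model
from .exceptions import InvalidArgumentError
from .exposure import QuenchingSeries, exposure_model
from .photophysics import DecayTrace, EmissionSpectrum, KineticTrace

__all__ = [
    "ScenarioConfig",
    "SCENARIOS",
    "get_scenario",
    "make_titration",
    "make_quenching_series",
    "make_depth_profile",
    "make_decay",
    "make_kinetic_trace",
    "make_spectrum",
    "make_irf",
]


@dataclass
class ScenarioConfig:
    """Generating parameters for one toxin variant / membrane composition.

    ``binding`` = (n, K_a [1/M], F_b/F_sol); ``exposure`` = (L_n, F_min);
    ``depth`` = (h_m, sigma, S) in Angstrom; ``lifetimes`` = (amplitude
    fractions, tau in ns); ``kinetics`` = (alpha_1, tau_1 [s], tau_2 [s]).
    Entries missing in the source study are None.
    """

    name: str
    binding: tuple | None = None
    exposure: tuple | None = None
    depth: tuple | None = None
    lifetimes: tuple = ((0.2, 0.3, 0.5), (8.0, 3.0, 1.5))
    kinetics: tuple = (0.85, 3.0, 60.0)
    noise_cv: float = 0.02  # steady-state multiplicative CV
    qp_noise_sd: float = 0.05  # additive sigma on QP values
    protein_total: float = 1e-7  # M
    lp_grid: tuple = (0.0, 300.0, 25)  # L/P min, max, points
    q_grid: tuple = (0.0, 0.7, 8)  # quencher fraction min, max, points

    def __post_init__(self):
        if self.binding is not None:
            n, ka, fb = self.binding
            if min(n, ka, fb) <= 0:
                raise InvalidArgumentError("binding parameters must be positive")
        if self.exposure is not None:
            l_n, f_min = self.exposure
            if l_n <= 0 or not 0 <= f_min < 1:
                raise InvalidArgumentError("invalid exposure parameters")
        if self.depth is not None:
            h_m, sigma, s = self.depth
            if h_m < 0 or sigma <= 0 or s <= 0:
                raise InvalidArgumentError("invalid depth parameters")
        a, tau = self.lifetimes
        if abs(sum(a) - 1) > 1e-9 or min(tau) <= 0:
            raise InvalidArgumentError("invalid lifetime parameters")


def _scn(name, comp, binding, exposure, depth):
    return ScenarioConfig(name=name, binding=binding, exposure=exposure,
                          depth=depth)


# One scenario per studied toxin variant and membrane composition.
# binding = (n, K_a 1/M, F_b/F_sol); exposure = (L_n, F_min);
# depth = (h_m A, sigma A, S A).  None where no result exists.
SCENARIOS: dict[str, ScenarioConfig] = {
    s.name: s for s in [
        _scn("StnI_chol", "DOPC:PSM:Chol 70:15:15",
             (55.3, 4.1e8, 1.75), (2.49, 0.72), (15.0, 7.1, 5.2)),
        _scn("StnI_nochol", "DOPC:PSM 80:20",
             (63.2, 1.1e8, 1.45), (2.38, 0.79), (12.9, 6.6, 3.1)),
        _scn("StnI-CC_chol", "DOPC:PSM:Chol 70:15:15",
             (67.7, 4.2e8, 1.94), (2.16, 0.64), (16.0, 8.9, 10.1)),
        _scn("StnI-CC_nochol", "DOPC:PSM 80:20",
             (54.2, 7.5e8, 1.56), (3.26, 0.67), None),
        _scn("StnII_chol", "DOPC:PSM:Chol 70:15:15",
             (58.1, 6.7e8, 1.72), (1.15, 0.76), (15.6, 9.6, 5.3)),
        _scn("StnII_nochol", "DOPC:PSM 80:20",
             (60.8, 0.4e8, 1.25), (7.15, 0.79), (13.1, 8.2, 5.3)),
        _scn("StnII-CC_chol", "DOPC:PSM:Chol 70:15:15",
             (61.5, 9.1e8, 1.84), (1.22, 0.53), (19.0, 11.6, 11.4)),
        _scn("StnII-CC_nochol", "DOPC:PSM 80:20",
             (42.1, 2.1e8, 1.50), (3.06, 0.75), (19.2, 13.0, 9.7)),
        _scn("StnII-W43-110F_chol", "DOPC:PSM:Chol 70:15:15",
             (67.9, 1.2e8, 1.73), (2.40, 0.89), (15.5, 3.8, 2.3)),
        _scn("StnII-W43-110F_nochol", "DOPC:PSM 80:20",
             (60.0, 0.5e8, 1.28), (9.34, 0.89), (13.5, 4.0, 3.1)),
        _scn("StnII-W43-114F_chol", "DOPC:PSM:Chol 70:15:15",
             (79.1, 6.1e8, 1.74), (3.20, 0.64), (12.2, 8.2, 6.9)),
    ]
}


def get_scenario(name: str, **overrides) -> ScenarioConfig:
    try:
        cfg = SCENARIOS[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
    return replace(cfg, **overrides) if overrides else cfg


def _rng(seed):
    if seed is None:
        raise InvalidArgumentError("stochastic generation requires a seed")
    return np.random.default_rng(seed)


def make_titration(config: ScenarioConfig, seed: int | None = None,
                   noise_cv: float | None = None, f_sol: float = 1.0
                   ) -> TitrationCurve:
    """Titration curve over an L/P grid from the binding forward model."""
    if config.binding is None:
        raise InvalidArgumentError(f"scenario {config.name} has no binding row")
    n, ka, fb = config.binding
    lp = np.linspace(*config.lp_grid[:2], int(config.lp_grid[2]))
    P = np.full(lp.size, config.protein_total)
    L = lp * P
    theta = bound_fraction(L, P, n, ka)
    F = f_sol * (1.0 + (fb - 1.0) * theta)
    cv = config.noise_cv if noise_cv is None else noise_cv
    if cv > 0:
        F = F * (1.0 + cv * _rng(seed).standard_normal(F.size))
    return TitrationCurve(protein_total=P, lipid_total=L, intensity=F,
                          meta={"scenario": config.name})


def make_quenching_series(config: ScenarioConfig, seed: int | None = None,
                          noise_cv: float | None = None) -> QuenchingSeries:
    """Normalized quenching series from the boundary-lipid contact model."""
    if config.exposure is None:
        raise InvalidArgumentError(f"scenario {config.name} has no exposure row")
    l_n, f_min = config.exposure
    q = np.linspace(*config.q_grid[:2], int(config.q_grid[2]))
    resp = exposure_model(q, 1.0, f_min, l_n)
    cv = config.noise_cv if noise_cv is None else noise_cv
    if cv > 0:
        resp = resp * (1.0 + cv * _rng(seed).standard_normal(resp.size))
        resp = np.minimum(resp / resp[0], 1.05)  # renormalize to F/F0 = 1 at Q=0
        resp[0] = 1.0
    return QuenchingSeries(quencher_fraction=q, response=resp,
                           response_kind="intensity",
                           meta={"scenario": config.name})


def make_depth_profile(config: ScenarioConfig, seed: int | None = None,
                       noise_sd: float | None = None,
                       depths: dict | None = None,
                       n_replicates: int = 1) -> DepthProfile:
    """Quenching profile at the calibrated label depths from the mirrored-Gaussian model.

    ``n_replicates`` > 1 averages that many independently noised replicates
    per point before the profile is assembled, emulating the replicate
    averaging (n = 2-3) applied to measured quenching values.
    """
    if config.depth is None:
        raise InvalidArgumentError(f"scenario {config.name} has no depth row")
    h_m, sigma, s = config.depth
    catalog = depths or DEFAULT_QUENCHER_DEPTHS
    h = np.array(sorted(catalog.values(), reverse=True))
    qp = depth_model(h, h_m, sigma, s)
    sd = config.qp_noise_sd if noise_sd is None else noise_sd
    if sd > 0:
        rng = _rng(seed)
        reps = qp + sd * rng.standard_normal((n_replicates, qp.size))
        qp = np.maximum(reps.mean(axis=0), 0.0)
    return DepthProfile(quencher_depth=h, qp=qp, meta={"scenario": config.name})


def make_irf(channel_time: np.ndarray, center: float = 2.0,
             fwhm: float = 0.5, peak: float = 10_000.0,
             seed: int | None = None) -> np.ndarray:
    """Synthetic Gaussian instrument response (counts), optionally Poisson-noised."""
    sd = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    shape = np.exp(-((channel_time - center) ** 2) / (2 * sd**2))
    counts = peak * shape
    if seed is not None:
        counts = _rng(seed).poisson(counts).astype(float)
    return counts


def make_decay(config: ScenarioConfig, seed: int | None = None,
               dt: float = 0.004, n_channels: int = 16384,
               peak: float = 12_000.0, irf_center: float = 2.0,
               irf_fwhm: float = 0.5, poisson: bool = True) -> DecayTrace:
    """TCSPC histogram: multi-exponential decay reconvolved with a Gaussian IRF.

    Defaults give a ~65 ns window at the 4 ps native channel width of the
    photon-counting module class, an IRF of 0.5 ns FWHM and ~12,000 counts
    in the peak channel, Poisson-sampled.
    """
    from scipy.signal import fftconvolve

    t = np.arange(n_channels) * dt
    alphas, taus = config.lifetimes
    ideal = np.zeros_like(t)
    for a, tau in zip(alphas, taus):
        ideal += a * np.exp(-t / tau)
    irf_ideal = make_irf(t, center=irf_center, fwhm=irf_fwhm, peak=1.0)
    irf_norm = irf_ideal / irf_ideal.sum()
    model = np.maximum(fftconvolve(irf_norm, ideal)[:n_channels], 0.0)
    model *= peak / model.max()
    rng = _rng(seed) if (poisson or seed is not None) else None
    counts = rng.poisson(model).astype(int) if poisson else np.round(model).astype(int)
    irf_counts = make_irf(t, center=irf_center, fwhm=irf_fwhm, peak=10_000.0,
                          seed=None)
    irf_counts = np.round(irf_counts).astype(int)
    return DecayTrace(channel_time=t, counts=counts, irf_counts=irf_counts,
                      peak_target=peak)


def make_kinetic_trace(config: ScenarioConfig, seed: int | None = None,
                       noise_cv: float | None = None, t_max: float = 300.0,
                       n_points: int = 601, f_inf: float = 1.75,
                       f_0_level: float = 1.0) -> KineticTrace:
    """Rise-to-plateau emission time course after vesicle addition."""
    alpha1, tau1, tau2 = config.kinetics
    t = np.linspace(0.0, t_max, n_points)
    rise = f_inf - f_0_level
    a1, a2 = alpha1 * rise, (1 - alpha1) * rise
    F = f_inf - a1 * np.exp(-t / tau1) - a2 * np.exp(-t / tau2)
    cv = config.noise_cv if noise_cv is None else noise_cv
    if cv > 0:
        F = F * (1.0 + cv * _rng(seed).standard_normal(F.size))
    return KineticTrace(time=t, intensity=F)


def make_spectrum(config: ScenarioConfig, seed: int | None = None,
                  noise_cv: float | None = None, center: float = 335.0,
                  fwhm: float = 55.0, amplitude: float = 1.0,
                  blank_amplitude: float = 0.15,
                  wavelength: tuple = (305.0, 450.0, 1.0)) -> EmissionSpectrum:
    """Gaussian tryptophan emission band plus a Rayleigh-tail scattering blank."""
    w = np.arange(wavelength[0], wavelength[1] + wavelength[2] / 2, wavelength[2])
    sd = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    band = amplitude * np.exp(-((w - center) ** 2) / (2 * sd**2))
    blank = blank_amplitude * np.exp(-(w - w[0]) / 20.0)
    intensity = band + blank
    cv = config.noise_cv if noise_cv is None else noise_cv
    if cv > 0:
        intensity = intensity * (1.0 + cv * _rng(seed).standard_normal(w.size))
    return EmissionSpectrum(wavelength=w, intensity=intensity, blank=blank)
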