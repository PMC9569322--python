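"""Protein-vesicle binding isotherm analysis.

A water-soluble protein P partitions onto large unilamellar vesicles, one
monomer occupying a patch of ``n`` lipids with association constant ``K_a``
(per molar free lipid-site concentration, L_T/n).  Mass action gives the
bound fraction theta as the root of a quadratic in the bound-protein
concentration; the closed form used throughout is

    theta(L_T, P_T) = 1 - 1/2 [ 1 - L_T/(n P_T) - 1/(K_a P_T)
                                + sqrt( (L_T/(n P_T) + 1/(K_a P_T) - 1)^2
                                        + 4/(K_a P_T) ) ].

Tryptophan emission reports binding because the membrane-bound protein is
brighter than the free one; the measured signal is modelled as

    F = F_sol * (1 + (F_b/F_sol - 1) * theta),

so a titration with quencher-free vesicles yields (n, K_a, F_b/F_sol) by
nonlinear least squares.  The module also provides dilution correction for
vesicle-stock additions and membrane surface-geometry utilities (mean
inter-particle distance from surface density).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.optimize import brentq
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import FitFailureError, InvalidArgumentError, OutOfRangeError
from .gof import GoodnessOfFit

__all__ = [
    "TitrationCurve",
    "BindingFit",
    "MembraneGeometry",
    "InterparticleDistance",
    "BindingIsotherm",
    "bound_fraction",
    "correct_dilution",
    "fit_binding",
    "saturation_lp_ratio",
    "mean_interparticle_distance",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class TitrationCurve:
    """Fluorescence vs dilution-corrected total lipid/protein concentrations."""

    protein_total: np.ndarray  # M per point
    lipid_total: np.ndarray  # M per point
    intensity: np.ndarray  # a.u.
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.protein_total = np.asarray(self.protein_total, dtype=float)
        self.lipid_total = np.asarray(self.lipid_total, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = self.protein_total.size
        if not (self.lipid_total.size == n == self.intensity.size):
            raise InvalidArgumentError("titration arrays must have equal length")
        if n < 5:
            raise InvalidArgumentError("titration needs at least 5 points")
        if not np.all(np.isfinite(self.protein_total)) or np.any(
            self.protein_total <= 0
        ):
            raise InvalidArgumentError("protein_total must be positive and finite")
        if np.any(self.lipid_total < 0) or not np.all(np.isfinite(self.lipid_total)):
            raise InvalidArgumentError("lipid_total must be non-negative and finite")
        if np.any(np.diff(self.lipid_total) < 0):
            raise InvalidArgumentError("lipid_total must be non-decreasing")


@dataclass
class BindingFit:
    """Estimated binding parameters with standard errors and fit quality."""

    n: float  # lipids per bound monomer
    K_a: float  # association constant, M^-1
    F_sol: float  # emission of fully free protein, a.u.
    F_b_ratio: float  # bound/solution emission ratio
    se: dict  # parameter name -> standard error
    gof: GoodnessOfFit
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.n <= 0 or self.K_a <= 0 or self.F_b_ratio <= 0:
            raise InvalidArgumentError("n, K_a and F_b_ratio must be positive")
        if any(v < 0 for v in self.se.values() if np.isfinite(v)):
            raise InvalidArgumentError("standard errors must be non-negative")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "K_a": self.K_a,
            "F_sol": self.F_sol,
            "F_b_ratio": self.F_b_ratio,
            "se": dict(self.se),
            "gof": self.gof.to_dict(),
            "flags": list(self.flags),
        }


@dataclass
class MembraneGeometry:
    """Surface-density inputs for inter-particle distance estimates."""

    lipid_per_protein: float  # L/P molar ratio
    lipid_area: float  # cross-sectional area per lipid, A^2
    oligomer_size: int = 1  # protomers per membrane particle
    protein_radius: float = 11.0  # A

    def __post_init__(self):
        if min(self.lipid_per_protein, self.lipid_area, self.oligomer_size,
               self.protein_radius) <= 0:
            raise InvalidArgumentError("all geometry fields must be positive")
        if not 30.0 <= self.lipid_area <= 80.0:
            raise InvalidArgumentError(
                f"lipid_area {self.lipid_area} outside the sane 30-80 A^2 range"
            )


@dataclass
class InterparticleDistance:
    center_to_center: float  # A
    edge_to_edge: float  # A


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------


def bound_fraction(lipid_total, protein_total, n, K_a):
    """Fraction of membrane-bound protein at total lipid/protein concentrations.

    Parameters
    ----------
    lipid_total : float or array, M (>= 0)
    protein_total : float or array, M (> 0)
    n : lipids per bound monomer (> 0)
    K_a : association constant, M^-1 (> 0)

    Returns
    -------
    theta in [0, 1]; the clamp only absorbs floating-point round-off.
    """
    L = np.asarray(lipid_total, dtype=float)
    P = np.asarray(protein_total, dtype=float)
    if not (np.all(np.isfinite(L)) and np.all(np.isfinite(P))):
        raise InvalidArgumentError("concentrations must be finite")
    if np.any(L < 0):
        raise InvalidArgumentError("lipid_total must be >= 0")
    if np.any(P <= 0):
        raise InvalidArgumentError("protein_total must be > 0")
    if not (np.isfinite(n) and np.isfinite(K_a)) or n <= 0 or K_a <= 0:
        raise InvalidArgumentError("n and K_a must be positive and finite")

    u = L / (n * P)
    c = 1.0 / (K_a * P)
    theta = 1.0 - 0.5 * (1.0 - u - c + np.sqrt((u + c - 1.0) ** 2 + 4.0 * c))
    # round-off guard only: the closed form is exact in [0, 1]
    if np.any(theta < -1e-9) or np.any(theta > 1.0 + 1e-9):
        raise FitFailureError("bound-fraction model produced theta outside [0,1]")
    return np.clip(theta, 0.0, 1.0) if theta.ndim else float(np.clip(theta, 0.0, 1.0))


def bound_fraction_mass_action(lipid_total, protein_total, n, K_a):
    """Independent numeric oracle: solve the mass-action equilibrium directly.

    P_free + site <-> complex with sites = L_T/n and
    K_a = [complex]/([P_free][site_free]); the bound concentration B is the
    root of K_a (P_T - B)(L_T/n - B) = B found by bracketed root search.
    Used for cross-checking :func:`bound_fraction`, never in the fit path.
    """
    L = np.atleast_1d(np.asarray(lipid_total, dtype=float))
    P = np.atleast_1d(np.asarray(protein_total, dtype=float))
    P = np.broadcast_to(P, L.shape)
    out = np.empty(L.shape, dtype=float)
    for i, (li, pi) in enumerate(zip(L.ravel(), P.ravel())):
        s = li / n
        if s == 0:
            out.ravel()[i] = 0.0
            continue
        f = lambda b: K_a * (pi - b) * (s - b) - b
        hi = min(pi, s)
        out.ravel()[i] = brentq(f, 0.0, hi, xtol=1e-18, rtol=1e-15) / pi
    return out if np.asarray(lipid_total).ndim else float(out[0])


def correct_dilution(initial_protein, initial_volume, additions):
    """Dilution-corrected concentrations for sequential vesicle-stock additions.

    Parameters
    ----------
    initial_protein : M, protein concentration before any addition
    initial_volume : sample volume before any addition (any consistent unit)
    additions : sequence of (added_volume, lipid_stock_M) tuples

    Returns
    -------
    (protein_total, lipid_total) arrays of length len(additions) + 1, the
    first point being the untouched sample.  Protein mass is conserved:
    protein_total * cumulative_volume is constant.
    """
    if initial_protein <= 0 or initial_volume <= 0:
        raise InvalidArgumentError("initial protein and volume must be positive")
    vols = [initial_volume]
    lipid_moles = [0.0]
    for i, (dv, stock) in enumerate(additions):
        if dv <= 0 or stock <= 0:
            raise InvalidArgumentError(
                f"addition {i}: volume and stock concentration must be positive"
            )
        vols.append(vols[-1] + dv)
        lipid_moles.append(lipid_moles[-1] + dv * stock)
    v = np.asarray(vols, dtype=float)
    protein_total = initial_protein * initial_volume / v
    lipid_total = np.asarray(lipid_moles, dtype=float) / v
    return protein_total, lipid_total


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------


class BindingIsotherm(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the vesicle-titration binding model.

    The design matrix ``X`` has two columns, total lipid and total protein
    concentration (M) per titration point; ``y`` is the fluorescence signal.
    Fitted attributes: ``n_``, ``k_a_``, ``f_sol_``, ``f_b_ratio_``, ``se_``
    (dict of standard errors), ``gof_`` and ``flags_``.

    Parameters
    ----------
    ka_init : starting value for K_a (M^-1).
    n_bounds, ka_bounds : box constraints for the fit.
    saturation_threshold : minimum max(theta-hat) below which the curve is
        flagged as not reaching saturation.
    """

    def __init__(
        self,
        ka_init: float = 1e8,
        n_bounds: tuple = (1.0, 1e4),
        ka_bounds: tuple = (1e4, 1e14),
        saturation_threshold: float = 0.8,
    ):
        self.ka_init = ka_init
        self.n_bounds = n_bounds
        self.ka_bounds = ka_bounds
        self.saturation_threshold = saturation_threshold

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _signal(L, P, n, ka, f_sol, fb):
        return f_sol * (1.0 + (fb - 1.0) * bound_fraction(L, P, n, ka))

    def _initial_n(self, L, P, y):
        """L/P at half-maximal signal rise; falls back to 50."""
        rise = y - y[0]
        if rise.max() <= 0:
            return 50.0
        half = 0.5 * rise.max()
        idx = int(np.argmax(rise >= half))
        lp = L[idx] / P[idx]
        return float(np.clip(lp if lp > 0 else 50.0, *self.n_bounds))

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InvalidArgumentError(
                "X must be (n_points, 2): [lipid_total, protein_total]"
            )
        if X.shape[0] != y.size or y.size < 5:
            raise InvalidArgumentError("need >= 5 points with matching y")
        L, P = X[:, 0], X[:, 1]

        flags: list[str] = []
        f_sol0 = float(y[np.argmin(L)])
        if f_sol0 <= 0:
            f_sol0 = float(np.abs(y).mean()) or 1.0
        span = float(np.ptp(y)) / max(abs(y).max(), 1e-300)
        degenerate = span < 1e-3
        if degenerate:
            flags.append("no_response")
            warnings.warn(
                "intensity does not respond to lipid; binding parameters are "
                "unidentifiable", stacklevel=2,
            )

        params = lmfit.Parameters()
        params.add("n", value=self._initial_n(L, P, y), min=self.n_bounds[0],
                   max=self.n_bounds[1])
        params.add("ka", value=self.ka_init, min=self.ka_bounds[0],
                   max=self.ka_bounds[1])
        params.add("f_sol", value=f_sol0, min=1e-12)
        fb0 = max(float(y.max()) / f_sol0, 1.01)
        params.add("fb", value=fb0, min=1e-6)

        def resid(p):
            return self._signal(L, P, p["n"].value, p["ka"].value,
                                p["f_sol"].value, p["fb"].value) - y

        res = lmfit.minimize(resid, params, method="leastsq", nan_policy="raise")
        gof = GoodnessOfFit.from_residuals(res.residual, n_params=4)
        if not res.success and not degenerate:
            raise FitFailureError(
                "binding fit did not converge",
                last_params={k: v.value for k, v in res.params.items()},
                gof=gof,
            )

        p = res.params
        self.n_ = float(p["n"].value)
        self.k_a_ = float(p["ka"].value)
        self.f_sol_ = float(p["f_sol"].value)
        self.f_b_ratio_ = float(p["fb"].value)
        self.se_ = {
            name: float(p[k].stderr) if p[k].stderr is not None else float("nan")
            for name, k in [("n", "n"), ("K_a", "ka"), ("F_sol", "f_sol"),
                            ("F_b_ratio", "fb")]
        }
        theta_hat = bound_fraction(L, P, self.n_, self.k_a_)
        if np.max(theta_hat) < self.saturation_threshold:
            flags.append("no_saturation")
            warnings.warn(
                "titration does not reach saturation (max theta-hat "
                f"{np.max(theta_hat):.2f} < {self.saturation_threshold})",
                stacklevel=2,
            )
        self.gof_ = gof
        self.flags_ = flags
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self._signal(X[:, 0], X[:, 1], self.n_, self.k_a_,
                            self.f_sol_, self.f_b_ratio_)

    def theta(self, X):
        """Bound fraction at the fitted parameters."""
        X = np.asarray(X, dtype=float)
        return bound_fraction(X[:, 0], X[:, 1], self.n_, self.k_a_)

    def to_result(self) -> BindingFit:
        return BindingFit(
            n=self.n_, K_a=self.k_a_, F_sol=self.f_sol_,
            F_b_ratio=self.f_b_ratio_, se=self.se_, gof=self.gof_,
            flags=list(self.flags_),
        )


def fit_binding(curve: TitrationCurve, **estimator_kwargs) -> BindingFit:
    """Fit the binding isotherm to a titration curve; see :class:`BindingIsotherm`."""
    X = np.column_stack([curve.lipid_total, curve.protein_total])
    est = BindingIsotherm(**estimator_kwargs).fit(X, curve.intensity)
    return est.to_result()


# --------------------------------------------------------------------------
# derived quantities
# --------------------------------------------------------------------------


def saturation_lp_ratio(fit: BindingFit, threshold: float, protein_total: float):
    """Smallest L/P molar ratio at which theta reaches ``threshold``.

    Solved numerically as the root of theta(L) = threshold at fixed protein.
    """
    if not 0.0 < threshold < 1.0:
        raise InvalidArgumentError("threshold must be in (0, 1)")
    if protein_total <= 0:
        raise InvalidArgumentError("protein_total must be positive")

    f = lambda L: bound_fraction(L, protein_total, fit.n, fit.K_a) - threshold
    L_hi = fit.n * protein_total
    for _ in range(80):
        if f(L_hi) >= 0:
            break
        L_hi *= 2.0
    else:
        raise OutOfRangeError(f"theta = {threshold} unreachable")
    L_root = brentq(f, 0.0, L_hi, xtol=1e-30, rtol=1e-14)
    return L_root / protein_total


def mean_interparticle_distance(
    geom: MembraneGeometry, leaflet: str = "both"
) -> InterparticleDistance:
    """Mean distance between membrane-bound particles from their surface density.

    Area per particle A = oligomer_size * (L/P) * lipid_area (all lipids, both
    leaflets, count by default); surface density sigma = 1/A; the mean
    center-to-center spacing is r_av = sqrt(1/sigma)/2 = sqrt(A)/2 and the
    edge-to-edge distance subtracts one protein diameter.

    ``leaflet="outer"`` halves the lipid count (only the binding leaflet's
    lipids contribute area).
    """
    if leaflet not in ("both", "outer"):
        raise InvalidArgumentError("leaflet must be 'both' or 'outer'")
    lp = geom.lipid_per_protein * (0.5 if leaflet == "outer" else 1.0)
    area = geom.oligomer_size * lp * geom.lipid_area
    r_av = np.sqrt(area) / 2.0
    return InterparticleDistance(
        center_to_center=float(r_av),
        edge_to_edge=float(r_av - 2.0 * geom.protein_radius),
    )
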