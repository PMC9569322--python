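"""Boundary-lipid counting from quencher-titration series.

Replacing a fraction [Q] of the membrane PC with a spin-labeled (doxyl) PC
quenches tryptophan emission on contact.  If a fluorophore touches L_n
lipids, the probability that none of them carries the label is
(1 - [Q])^L_n, so the normalized emission follows

    F([Q]) = (F0 - F_min) (1 - [Q])^L_n + F_min,

where F_min is the non-quenchable emission (shielded tryptophans plus
protein in pure quencher lipid).  Fitting (L_n, F_min) to a steady-state
quenching series yields the number of boundary PC lipids in contact with
the accessible tryptophans.  Stern-Volmer representations (F0/F from
intensity, tau0/tau from lifetimes) diagnose static vs dynamic quenching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.stats import gmean
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import FitFailureError, InvalidArgumentError
from .gof import GoodnessOfFit

__all__ = [
    "QuenchingSeries",
    "ExposureFit",
    "SternVolmerSeries",
    "StaticQuenchingSummary",
    "ExposureCurve",
    "exposure_model",
    "fit_exposure",
    "stern_volmer",
    "classify_quenching",
]


@dataclass
class QuenchingSeries:
    """Normalized emission (or lifetime ratio) vs quencher mole fraction."""

    quencher_fraction: np.ndarray  # mole fraction in [0, 1]
    response: np.ndarray  # F/F0 or tau/tau0
    response_kind: str = "intensity"  # intensity | lifetime
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.quencher_fraction = np.asarray(self.quencher_fraction, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.response_kind not in ("intensity", "lifetime"):
            raise InvalidArgumentError("response_kind must be intensity|lifetime")
        if self.quencher_fraction.size != self.response.size:
            raise InvalidArgumentError("array length mismatch")
        if np.any(np.diff(self.quencher_fraction) <= 0):
            raise InvalidArgumentError("quencher_fraction must be strictly increasing")
        if abs(self.quencher_fraction[0]) > 1e-12 or abs(self.response[0] - 1) > 1e-6:
            raise InvalidArgumentError(
                "series must start at quencher_fraction 0 with response 1"
            )
        if np.any(self.quencher_fraction > 1.0):
            raise InvalidArgumentError("quencher_fraction must be <= 1")
        if np.any(self.response <= 0) or np.any(self.response > 1.0 + 0.05):
            raise InvalidArgumentError("responses must lie in (0, 1+eps]")


@dataclass
class ExposureFit:
    """Boundary-lipid count and non-quenchable fraction with uncertainties."""

    L_n: float
    F_min: float
    se: dict
    gof: GoodnessOfFit
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if self.L_n <= 0:
            raise InvalidArgumentError("L_n must be positive")
        if not 0.0 <= self.F_min < 1.0:
            raise InvalidArgumentError("F_min must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "L_n": self.L_n,
            "F_min": self.F_min,
            "se": dict(self.se),
            "gof": self.gof.to_dict(),
            "flags": list(self.flags),
        }


@dataclass
class SternVolmerSeries:
    quencher_fraction: np.ndarray
    ratio: np.ndarray  # F0/F or tau0/tau
    kind: str = "intensity"

    def __post_init__(self):
        self.quencher_fraction = np.asarray(self.quencher_fraction, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.quencher_fraction.size != self.ratio.size:
            raise InvalidArgumentError("array length mismatch")
        if self.quencher_fraction[0] == 0 and self.ratio[0] < 1 - 1e-6:
            raise InvalidArgumentError("ratio at zero quencher must be ~1")


@dataclass
class StaticQuenchingSummary:
    """Per-point apparent-static component (F0/F)/(tau0/tau) and its summary."""

    quencher_fraction: np.ndarray
    static_component: np.ndarray
    geometric_mean: float  # over points with [Q] > 0; >1 => static quenching


def exposure_model(quencher_fraction, F0, F_min, L_n):
    """Emission predicted by the boundary-lipid contact model."""
    q = np.asarray(quencher_fraction, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise InvalidArgumentError("quencher_fraction must lie in [0, 1]")
    if not F0 > F_min >= 0:
        raise InvalidArgumentError("need F0 > F_min >= 0")
    if L_n <= 0:
        raise InvalidArgumentError("L_n must be positive")
    out = (F0 - F_min) * (1.0 - q) ** L_n + F_min
    return out if q.ndim else float(out)


class ExposureCurve(RegressorMixin, BaseEstimator):
    """Least-squares fit of the boundary-lipid contact model.

    ``X`` is the quencher mole fraction (1-D or a single column), ``y`` the
    normalized emission F/F0.  F0 is fixed at 1 for normalized input, leaving
    (L_n, F_min) free.  Fitted attributes: ``l_n_``, ``f_min_``, ``se_``,
    ``gof_``, ``flags_``.
    """

    def __init__(
        self,
        f0: float = 1.0,
        l_n_init: float = 2.0,
        l_n_bounds: tuple = (0.01, 50.0),
        monotone_tol: float = 0.02,
    ):
        self.f0 = f0
        self.l_n_init = l_n_init
        self.l_n_bounds = l_n_bounds
        self.monotone_tol = monotone_tol

    def fit(self, X, y):
        q = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float)
        if q.size != y.size or q.size < 4:
            raise InvalidArgumentError("need >= 4 matched points")
        if q[0] != 0:
            raise InvalidArgumentError("series must include the zero-quencher point")

        flags: list[str] = []
        if np.ptp(y) < 1e-3:
            flags.append("degenerate_no_quenching")
            flags.append("L_n_unidentifiable")
        if np.any(np.diff(y) > self.monotone_tol):
            flags.append("non_monotone_response")
            warnings.warn("quenching response rises beyond noise tolerance",
                          stacklevel=2)

        params = lmfit.Parameters()
        params.add("l_n", value=self.l_n_init, min=self.l_n_bounds[0],
                   max=self.l_n_bounds[1])
        params.add("f_min", value=float(np.clip(y.min(), 0.0, self.f0 * 0.999)),
                   min=0.0, max=self.f0 * (1 - 1e-9))

        def resid(p):
            return exposure_model(q, self.f0, p["f_min"].value, p["l_n"].value) - y

        res = lmfit.minimize(resid, params, method="leastsq", nan_policy="raise")
        gof = GoodnessOfFit.from_residuals(res.residual, n_params=2)
        if not res.success and "degenerate_no_quenching" not in flags:
            raise FitFailureError(
                "exposure fit did not converge",
                last_params={k: v.value for k, v in res.params.items()},
                gof=gof,
            )
        self.l_n_ = float(res.params["l_n"].value)
        self.f_min_ = float(res.params["f_min"].value)
        self.se_ = {
            "L_n": float(res.params["l_n"].stderr)
            if res.params["l_n"].stderr is not None else float("nan"),
            "F_min": float(res.params["f_min"].stderr)
            if res.params["f_min"].stderr is not None else float("nan"),
        }
        self.gof_ = gof
        self.flags_ = flags
        return self

    def predict(self, X):
        q = np.asarray(X, dtype=float).reshape(-1)
        return exposure_model(q, self.f0, self.f_min_, self.l_n_)

    def to_result(self) -> ExposureFit:
        return ExposureFit(L_n=self.l_n_, F_min=min(self.f_min_, 1 - 1e-12),
                           se=self.se_, gof=self.gof_, flags=list(self.flags_))


def fit_exposure(series: QuenchingSeries, **estimator_kwargs) -> ExposureFit:
    """Fit the contact model to a normalized steady-state quenching series."""
    if series.response_kind != "intensity":
        raise InvalidArgumentError(
            "the contact model applies to steady-state intensity series only"
        )
    est = ExposureCurve(**estimator_kwargs).fit(series.quencher_fraction,
                                                series.response)
    return est.to_result()


def stern_volmer(series):
    """Pointwise reciprocal: F/F0 -> F0/F (or back).  An involution.

    Accepts a :class:`QuenchingSeries` (returns a :class:`SternVolmerSeries`)
    or a :class:`SternVolmerSeries` (returns a :class:`QuenchingSeries`).
    """
    if isinstance(series, QuenchingSeries):
        if np.any(series.response <= 0):
            raise InvalidArgumentError("responses must be positive")
        return SternVolmerSeries(
            quencher_fraction=series.quencher_fraction.copy(),
            ratio=1.0 / series.response,
            kind=series.response_kind,
        )
    if isinstance(series, SternVolmerSeries):
        if np.any(series.ratio <= 0):
            raise InvalidArgumentError("ratios must be positive")
        return QuenchingSeries(
            quencher_fraction=series.quencher_fraction.copy(),
            response=1.0 / series.ratio,
            response_kind=series.kind,
        )
    raise InvalidArgumentError("expected QuenchingSeries or SternVolmerSeries")


def classify_quenching(
    intensity: SternVolmerSeries, lifetime: SternVolmerSeries
) -> StaticQuenchingSummary:
    """Split observed quenching into static and dynamic contributions.

    With F0/F = (static factor) x (tau0/tau), the per-point static component
    is (F0/F)/(tau0/tau); values > 1 mean quenching beyond what the lifetime
    shortening explains, i.e. apparent static quenching.  The summary is the
    geometric mean over points with [Q] > 0.
    """
    if intensity.quencher_fraction.size != lifetime.quencher_fraction.size or np.any(
        np.abs(intensity.quencher_fraction - lifetime.quencher_fraction) > 1e-9
    ):
        raise InvalidArgumentError("quencher grids must match")
    static = intensity.ratio / lifetime.ratio
    mask = intensity.quencher_fraction > 0
    gm = float(gmean(static[mask])) if np.any(mask) else float("nan")
    return StaticQuenchingSummary(
        quencher_fraction=intensity.quencher_fraction.copy(),
        static_component=static,
        geometric_mean=gm,
    )
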