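"""Goodness-of-fit summaries shared by every fitter.

Fit quality is reported through the residuals trace, the root mean squared
deviation (RMSD) and the reduced chi-square.  For unweighted fits chi2_red
uses unit variances; Poisson-weighted fits pass the per-point variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GoodnessOfFit:
    residuals: np.ndarray
    rmsd: float
    chi2_red: float

    def __post_init__(self):
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.rmsd < 0 or self.chi2_red < 0:
            raise ValueError("rmsd and chi2_red must be non-negative")

    @classmethod
    def from_residuals(
        cls,
        residuals: np.ndarray,
        n_params: int,
        variances: np.ndarray | float = 1.0,
    ) -> "GoodnessOfFit":
        r = np.asarray(residuals, dtype=float)
        dof = max(r.size - n_params, 1)
        rmsd = float(np.sqrt(np.mean(r**2)))
        chi2_red = float(np.sum(r**2 / np.asarray(variances, dtype=float)) / dof)
        return cls(residuals=r, rmsd=rmsd, chi2_red=chi2_red)

    def to_dict(self) -> dict:
        return {
            "residuals": self.residuals.tolist(),
            "rmsd": self.rmsd,
            "chi2_red": self.chi2_red,
        }


def durbin_watson(residuals: np.ndarray) -> float:
    """Durbin-Watson statistic; ~2 for serially uncorrelated residuals."""
    r = np.asarray(residuals, dtype=float)
    return float(np.sum(np.diff(r) ** 2) / np.sum(r**2))
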