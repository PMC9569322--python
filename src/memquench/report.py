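"""Pipeline orchestration and the analysis report.

``run_pipeline`` executes whichever stages have inputs configured (binding ->
exposure -> depth -> decay -> kinetics -> spectrum), records every fit result
keyed by stage, and attaches provenance (input SHA-256 hashes, seed, package
version).  Stage failures are recorded and do not abort later stages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from . import io as mio
from .binding import fit_binding
from .depth import QuencherCatalog, fit_depth
from .exceptions import FitFailureError, MemquenchError
from .exposure import fit_exposure
from .photophysics import (
    correct_scattering,
    fit_binding_kinetics,
    fit_decay,
    spectral_shape,
)


def _shape_stage(c: dict) -> dict:
    spec = mio.read_spectrum(c["path"])
    if spec.blank is not None:
        spec = correct_scattering(spec)
    shape = spectral_shape(spec)
    return {"lambda_max": shape.lambda_max, "fwhm": shape.fwhm,
            "flags": list(shape.flags)}

__all__ = ["AnalysisReport", "run_pipeline"]


@dataclass
class AnalysisReport:
    """Serializable record of every stage result plus provenance."""

    results: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    created: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {"results": self.results, "provenance": self.provenance,
             "warnings": self.warnings, "created": self.created},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        d = json.loads(text)
        return cls(results=d["results"], provenance=d["provenance"],
                   warnings=d["warnings"], created=d["created"])


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: dict, seed: int | None = None) -> AnalysisReport:
    """Run all configured analysis stages.

    ``config`` maps stage name to its options, e.g.::

        {"binding":  {"path": "...", "protein_M": 1e-7, "volume_ul": 2000},
         "exposure": {"path": "...", "fraction": false},
         "depth":    {"path": "...", "catalog": {"7-SLPC": 11.5, ...}},
         "decay":    {"path": "...", "irf_path": "...", "n_components": 3},
         "kinetics": {"path": "..."},
         "spectrum": {"path": "..."}}

    Absent stages are skipped with a notice; a stage whose fit fails is
    recorded as an error and the pipeline continues.
    """
    report = AnalysisReport(
        provenance={"seed": seed, "version": __version__, "inputs": {}},
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def record_input(stage, path):
        report.provenance["inputs"][stage] = {
            "path": str(path), "sha256": _sha256(path)
        }

    stages = {
        "binding": lambda c: fit_binding(
            mio.read_titration(c["path"], c["protein_M"], c["volume_ul"])
        ).to_dict(),
        "exposure": lambda c: fit_exposure(
            mio.read_quenching(c["path"], fraction=c.get("fraction", False))
        ).to_dict(),
        "depth": lambda c: fit_depth(
            mio.read_depth(
                c["path"],
                QuencherCatalog(c["catalog"]) if c.get("catalog") else None,
            )
        ).to_dict(),
        "decay": lambda c: fit_decay(
            mio.read_decay(c["path"], c["irf_path"]),
            n_components=c.get("n_components", 3),
        ).to_dict(),
        "kinetics": lambda c: fit_binding_kinetics(
            mio.read_kinetics(c["path"])
        ).to_dict(),
        "spectrum": _shape_stage,
    }

    for stage, runner in stages.items():
        c = config.get(stage)
        if not c:
            report.warnings.append(f"stage {stage}: no input configured, skipped")
            continue
        try:
            record_input(stage, c["path"])
            report.results[stage] = runner(c)
        except FitFailureError as exc:
            report.results[stage] = {"error": str(exc)}
            report.warnings.append(f"stage {stage}: fit failure: {exc}")
        except (MemquenchError, FileNotFoundError, KeyError) as exc:
            report.results[stage] = {"error": f"{type(exc).__name__}: {exc}"}
            report.warnings.append(f"stage {stage}: {type(exc).__name__}: {exc}")
    return report
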