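"""CSV readers and JSON writers for every data schema.

One flat CSV schema per data kind:

- titration:  ``added_volume_ul, lipid_stock_mM, intensity`` (initial protein
  concentration and sample volume supplied separately; concentrations are
  dilution-corrected on load)
- quenching:  ``quencher_molpct, response, response_kind`` (mol% converted to
  mole fraction unless ``fraction=True`` says the column already is one)
- depth:      ``quencher_label, F0_over_F`` (or ``qp``), optional ``include``
- decay/irf:  ``time_ns, counts``
- kinetics:   ``time_s, intensity``
- spectrum:   ``wavelength_nm, intensity[, blank]``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import TitrationCurve, correct_dilution
from .depth import DepthProfile, QuencherCatalog
from .exceptions import InvalidArgumentError, SchemaError, ValidationError
from .exposure import QuenchingSeries
from .photophysics import DecayTrace, EmissionSpectrum, KineticTrace

__all__ = ["read_table", "write_report", "write_curve_csv"]


def _load(path, required, optional=()):
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in (*required, *optional)]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")
    return df


def read_titration(path, protein_M: float, volume_ul: float) -> TitrationCurve:
    df = _load(path, ["added_volume_ul", "lipid_stock_mM", "intensity"])
    additions = [
        (row.added_volume_ul, row.lipid_stock_mM * 1e-3)
        for row in df.itertuples()
        if row.added_volume_ul > 0
    ]
    first_is_zero = df.added_volume_ul.iloc[0] == 0
    if not first_is_zero:
        raise ValidationError("first row must be the zero-addition point", row=0)
    protein, lipid = correct_dilution(protein_M, volume_ul, additions)
    return TitrationCurve(protein_total=protein, lipid_total=lipid,
                          intensity=df.intensity.to_numpy())


def read_quenching(path, fraction: bool = False) -> QuenchingSeries:
    col = "quencher_fraction" if fraction else "quencher_molpct"
    df = _load(path, [col, "response"], optional=["response_kind"])
    q = df[col].to_numpy(dtype=float)
    if not fraction:
        q = q / 100.0
    bad = np.nonzero(np.diff(q) <= 0)[0]
    if bad.size:
        raise ValidationError("quencher column not strictly increasing",
                              row=int(bad[0]) + 1)
    kind = (df.response_kind.iloc[0] if "response_kind" in df.columns
            else "intensity")
    return QuenchingSeries(quencher_fraction=q,
                           response=df.response.to_numpy(dtype=float),
                           response_kind=str(kind))


def read_depth(path, catalog: QuencherCatalog | None = None) -> DepthProfile:
    catalog = catalog or QuencherCatalog()
    df = pd.read_csv(path)
    if "quencher_label" not in df.columns:
        raise SchemaError(f"{path}: missing column(s) ['quencher_label']")
    if "qp" in df.columns:
        qp = df.qp.to_numpy(dtype=float)
    elif "F0_over_F" in df.columns:
        qp = df.F0_over_F.to_numpy(dtype=float) - 1.0
    else:
        raise SchemaError(f"{path}: need a 'qp' or 'F0_over_F' column")
    depths = np.array([catalog.depth_of(lbl) for lbl in df.quencher_label])
    mask = (df["include"].to_numpy(dtype=bool) if "include" in df.columns
            else None)
    for i, v in enumerate(qp):
        if v < 0:
            raise ValidationError("negative quenching-profile value", row=i)
    return DepthProfile(quencher_depth=depths, qp=qp, include_mask=mask)


def read_decay(path, irf_path) -> DecayTrace:
    df = _load(path, ["time_ns", "counts"])
    irf = _load(irf_path, ["time_ns", "counts"])
    if df.shape[0] != irf.shape[0] or not np.allclose(df.time_ns, irf.time_ns):
        raise ValidationError("decay and IRF must share the channel grid")
    return DecayTrace(channel_time=df.time_ns.to_numpy(dtype=float),
                      counts=df.counts.to_numpy(),
                      irf_counts=irf.counts.to_numpy())


def read_kinetics(path) -> KineticTrace:
    df = _load(path, ["time_s", "intensity"])
    return KineticTrace(time=df.time_s.to_numpy(dtype=float),
                        intensity=df.intensity.to_numpy(dtype=float))


def read_spectrum(path) -> EmissionSpectrum:
    df = _load(path, ["wavelength_nm", "intensity"], optional=["blank"])
    blank = df.blank.to_numpy(dtype=float) if "blank" in df.columns else None
    return EmissionSpectrum(wavelength=df.wavelength_nm.to_numpy(dtype=float),
                            intensity=df.intensity.to_numpy(dtype=float),
                            blank=blank)


_READERS = {
    "titration": read_titration,
    "quenching": read_quenching,
    "depth": read_depth,
    "decay": read_decay,
    "kinetics": read_kinetics,
    "spectrum": read_spectrum,
}


def read_table(path, schema_kind: str, **kwargs):
    """Load and validate a CSV of the given schema kind into its domain type."""
    try:
        reader = _READERS[schema_kind]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown schema kind {schema_kind!r}; one of {sorted(_READERS)}"
        ) from None
    return reader(path, **kwargs)


def write_report(result, path) -> None:
    """Serialize any fit result (via its to_dict) to a JSON report."""
    payload = result.to_dict() if hasattr(result, "to_dict") else result
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_curve_csv(path, **columns) -> None:
    """Tidy CSV of observed/fitted/residual (or any named) columns."""
    pd.DataFrame(columns).to_csv(path, index=False)
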