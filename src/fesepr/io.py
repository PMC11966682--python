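"""File formats and result serialization.

Field axes are millitesla, ascending, end to end; the only unit conversion
in the package happens here at ingest (Bruker Gauss values multiplied by
exactly 0.1, recorded in provenance).  Spectra travel as two-column ASCII
(field, intensity) with ``#`` header comments carrying instrument metadata,
or as read-only Bruker BES3T descriptor/data (DSC/DTA) pairs.  Condition
series are CSV; ground-truth manifests, model parameters and fit results
are JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__ as _pkg_version
from .conditions import ConditionSeries
from .decompose import FitResult, GlobalFitResult
from .isomers import SpinPopulationRecord
from .spin_sim import InstrumentConfig, Spectrum
from .synthdata import GroundTruth

__all__ = [
    "read_spectrum_ascii",
    "write_spectrum_ascii",
    "read_bes3t",
    "write_dataset",
    "read_dataset",
    "read_condition_series",
    "write_condition_series",
    "read_spin_populations",
    "fit_result_to_dict",
    "RunConfig",
    "result_bundle",
]


class SpectrumParseError(ValueError):
    """Malformed spectrum file; message names the offending line."""


# ---------------------------------------------------------------------------
# two-column ASCII


_HEADER_KEYS = {
    "mw_frequency_GHz": ("mw_frequency", float),
    "modulation_amplitude_mT": ("modulation_amplitude", float),
    "detection_mode": ("detection_mode", str),
    "temperature_K": ("temperature", float),
}


def write_spectrum_ascii(spec: Spectrum, path: str | Path) -> None:
    """Two-column (field mT, intensity) ASCII with metadata header comments."""
    inst = spec.instrument
    lines = [
        "# fesepr spectrum",
        f"# mw_frequency_GHz: {inst.mw_frequency:.6f}",
        f"# modulation_amplitude_mT: {inst.modulation_amplitude}",
        f"# detection_mode: {inst.detection_mode}",
        f"# temperature_K: {inst.temperature}",
        f"# condition: {json.dumps(dict(inst.condition))}",
        "# columns: field_mT intensity",
    ]
    body = "\n".join(f"{b:.12e} {y:.12e}" for b, y in zip(spec.field_axis, spec.intensity))
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_spectrum_ascii(
    path: str | Path,
    mw_frequency: float | None = None,
    field_unit: str = "mT",
) -> Spectrum:
    """Parse a two-column spectrum file.

    Header comments of the form ``# key: value`` populate the
    InstrumentConfig; the microwave frequency must come from either the
    header or the ``mw_frequency`` argument.  ``field_unit="G"`` converts
    Gauss to mT by exactly 0.1 at read time (recorded in provenance).
    """
    if field_unit not in ("mT", "G"):
        raise ValueError("field_unit must be 'mT' or 'G'")
    meta: dict = {}
    condition: dict = {}
    fields, intens = [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            content = line.lstrip("#").strip()
            if ":" in content:
                key, _, val = content.partition(":")
                key, val = key.strip(), val.strip()
                if key in _HEADER_KEYS:
                    attr, conv = _HEADER_KEYS[key]
                    try:
                        meta[attr] = conv(val)
                    except ValueError as e:
                        raise SpectrumParseError(
                            f"{path}:{lineno}: bad header value {val!r} for {key}") from e
                elif key == "condition":
                    try:
                        condition = json.loads(val)
                    except json.JSONDecodeError:
                        condition = {"raw": val}
            continue
        parts = line.split()
        if len(parts) != 2:
            raise SpectrumParseError(
                f"{path}:{lineno}: expected 2 numeric columns, got {len(parts)}")
        try:
            fields.append(float(parts[0]))
            intens.append(float(parts[1]))
        except ValueError:
            raise SpectrumParseError(f"{path}:{lineno}: non-numeric row {line!r}") from None
    if len(fields) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    b = np.asarray(fields)
    if np.any(np.diff(b) <= 0):
        bad = int(np.argmax(np.diff(b) <= 0)) + 2
        raise SpectrumParseError(f"{path}: field axis not strictly increasing at data row {bad}")
    if field_unit == "G":
        b = b * 0.1
    nu = meta.pop("mw_frequency", mw_frequency)
    if nu is None:
        raise SpectrumParseError(
            f"{path}: no microwave frequency in header and none supplied")
    inst = InstrumentConfig(
        mw_frequency=float(nu), field_start=float(b[0]), field_stop=float(b[-1]),
        n_points=b.size, condition=condition, **meta)
    return Spectrum(b, np.asarray(intens), inst,
                    {"origin": "measured", "path": str(path),
                     "field_unit_in": field_unit})


# ---------------------------------------------------------------------------
# Bruker BES3T (read-only)


def _parse_dsc(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("*", "#", ".")):
            continue
        parts = line.split(None, 1)
        if len(parts) == 2:
            out[parts[0]] = parts[1].strip().strip("'")
    return out


_IRFMT = {"D": ">f8", "F": ">f4", "I": ">i4", "S": ">i2"}


def read_bes3t(dsc_path: str | Path, dta_path: str | Path | None = None) -> Spectrum:
    """Read a Bruker BES3T descriptor/data pair as a field-swept spectrum.

    The field axis is reconstructed from XMIN/XWID/XPTS (endpoint
    inclusive); the data format honours IRFMT (default big-endian float64)
    and BSEQ; the microwave frequency comes from MWFQ (Hz).  Gauss axes
    (XUNI) are converted to mT.
    """
    dsc_path = Path(dsc_path)
    if dta_path is None:
        dta_path = dsc_path.with_suffix(".DTA")
    keys = _parse_dsc(dsc_path.read_text())
    missing = [k for k in ("XPTS", "XMIN", "XWID", "MWFQ") if k not in keys]
    if missing:
        raise ValueError(f"{dsc_path}: missing BES3T descriptor keys: {', '.join(missing)}")
    xpts = int(float(keys["XPTS"]))
    xmin, xwid = float(keys["XMIN"]), float(keys["XWID"])
    dtype = _IRFMT.get(keys.get("IRFMT", "D").upper(), ">f8")
    if keys.get("BSEQ", "BIG").upper().startswith("LIT"):
        dtype = "<" + dtype[1:]
    raw = np.fromfile(str(dta_path), dtype=np.dtype(dtype))
    if raw.size != xpts:
        raise ValueError(
            f"{dta_path}: payload has {raw.size} points but XPTS={xpts}")
    axis = xmin + xwid * np.arange(xpts) / (xpts - 1)
    unit = keys.get("XUNI", "G").strip("'\" ")
    prov_unit = unit
    if unit.upper() in ("G", "GAUSS"):
        axis = axis * 0.1
    nu_ghz = float(keys["MWFQ"]) / 1e9
    inst = InstrumentConfig(
        mw_frequency=nu_ghz, field_start=float(axis[0]), field_stop=float(axis[-1]),
        n_points=xpts, detection_mode="absorption")
    return Spectrum(axis, raw.astype(float), inst,
                    {"origin": "measured", "path": str(dta_path),
                     "format": "BES3T", "field_unit_in": prov_unit})


# ---------------------------------------------------------------------------
# dataset directories (synthetic suites)


def write_dataset(
    spectra: Sequence[Sequence[Spectrum]] | Sequence[Spectrum],
    truth: GroundTruth,
    directory: str | Path,
) -> Path:
    """Write a dataset as two-column ASCII spectra plus a truth manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = spectra if spectra and isinstance(spectra[0], (list, tuple)) else [[s] for s in spectra]
    index = []
    for i, row in enumerate(rows):
        for j, spec in enumerate(row):
            name = f"spectrum_c{i:03d}_f{j}.txt"
            write_spectrum_ascii(spec, directory / name)
            index.append({"file": name, "condition_index": i, "instrument_index": j})
    manifest = {"ground_truth": truth.to_dict(), "spectra": index}
    (directory / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
    return directory


def read_dataset(directory: str | Path) -> tuple[list[list[Spectrum]], dict]:
    """Read back a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = json.loads((directory / "ground_truth.json").read_text())
    n_cond = 1 + max(e["condition_index"] for e in manifest["spectra"])
    rows: list[list[Spectrum]] = [[] for _ in range(n_cond)]
    for entry in sorted(manifest["spectra"], key=lambda e: (e["condition_index"],
                                                            e["instrument_index"])):
        rows[entry["condition_index"]].append(
            read_spectrum_ascii(directory / entry["file"]))
    return rows, manifest["ground_truth"]


# ---------------------------------------------------------------------------
# condition series / spin populations (CSV)


def read_condition_series(path: str | Path, species: str = "") -> ConditionSeries:
    """CSV with columns condition, weight[, sigma]."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    for req in ("condition", "weight"):
        if req not in cols:
            raise ValueError(f"{path}: missing required column {req!r}")
    sigma = df[cols["sigma"]].to_numpy() if "sigma" in cols else None
    return ConditionSeries(df[cols["condition"]].to_numpy(),
                           df[cols["weight"]].to_numpy(), sigma, species=species)


def write_condition_series(series: ConditionSeries, path: str | Path) -> None:
    data = {"condition": series.condition, "weight": series.weight}
    if series.sigma is not None:
        data["sigma"] = series.sigma
    pd.DataFrame(data).to_csv(path, index=False)


def read_spin_populations(path: str | Path) -> list[SpinPopulationRecord]:
    """CSV with columns site, population[, conformer]; one record per conformer."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    for req in ("site", "population"):
        if req not in cols:
            raise ValueError(f"{path}: missing required column {req!r}")
    if "conformer" in cols:
        groups = list(df.groupby(df[cols["conformer"]], sort=True))
    else:
        groups = [("", df)]
    records = []
    for label, sub in groups:
        if len(sub) != 4:
            raise ValueError(f"{path}: conformer {label!r} has {len(sub)} sites, need 4")
        records.append(SpinPopulationRecord(
            populations=tuple(sub[cols["population"]].astype(float)),
            sites=tuple(sub[cols["site"]].astype(str)),
            source=str(label)))
    return records


# ---------------------------------------------------------------------------
# results & configuration


def fit_result_to_dict(fr: FitResult | GlobalFitResult) -> dict:
    """JSON-ready view of a fit result."""
    if isinstance(fr, GlobalFitResult):
        return {
            "species": [{"name": sp.name, "g": list(sp.g.values),
                         "g_strain": list(sp.g_strain),
                         "residual_linewidth": sp.residual_linewidth}
                        for sp in fr.species],
            "mixtures": [{"species": list(m.species_refs),
                          "weights_raw": m.weights.tolist(),
                          "weights_normalized": m.normalized_weights.tolist(),
                          "condition": dict(m.condition)} for m in fr.mixtures],
            "residual_norms": fr.residual_norms,
            "pooled_residual_norm": fr.pooled_residual_norm,
            "uncertainties": fr.uncertainties,
            "converged": fr.converged, "at_boundary": fr.at_boundary,
        }
    out = {
        "mixture": {"species": list(fr.mixture.species_refs),
                    "weights_raw": fr.mixture.weights.tolist(),
                    "weights_normalized": fr.mixture.normalized_weights.tolist(),
                    "condition": dict(fr.mixture.condition)},
        "residual_norm": fr.residual_norm,
        "baseline_coeffs": np.asarray(fr.baseline_coeffs).tolist(),
        "uncertainties": fr.uncertainties,
        "mask": [list(m) for m in fr.mask],
        "collinear": fr.collinear, "converged": fr.converged,
        "at_boundary": fr.at_boundary,
    }
    if fr.refined_species is not None:
        out["refined_species"] = [
            {"name": sp.name, "g": list(sp.g.values), "g_strain": list(sp.g_strain),
             "residual_linewidth": sp.residual_linewidth} for sp in fr.refined_species]
    return out


class RunConfig(BaseModel):
    """Validated run configuration for the command-line interface.

    Unknown keys are rejected rather than ignored, so a typo in a YAML file
    fails loudly before any computation starts.
    """

    model_config = ConfigDict(extra="forbid")

    inputs: list[str] = Field(default_factory=list)
    species: list[str] = Field(default_factory=list)  # preset names
    baseline_order: int | None = None
    mask: list[tuple[float, float]] = Field(default_factory=list)
    g_bounds: float = 0.03
    multistart: int = 5
    seed: int = 0
    condition_model: str | None = None  # "nernst" | "ph"
    output_dir: str = "."
    verbosity: int = 1


def result_bundle(payload: dict, config: dict | None = None, seed: int | None = None) -> dict:
    """Wrap results with a provenance block (config hash, versions, seed)."""
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    import scipy
    return {
        "results": payload,
        "provenance": {
            "config": config or {},
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": seed,
            "versions": {"fesepr": _pkg_version, "numpy": np.__version__,
                         "scipy": scipy.__version__},
        },
    }
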