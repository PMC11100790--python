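"""File formats and result schemas shared by all pipeline stages.

Images travel as single-channel multi-page TIFF, tables as CSV with a
header, configuration as YAML, and results as JSON "envelopes" that echo
the configuration and seed so deterministic stages reproduce byte-identical
numeric payloads.

Units are fixed internally: seconds, molar, nanometres, nanoseconds.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .arrayquant import ArrayLayout
from .photophysics import DyeStateParams, Spectrum, TwoStateDyeModel

__all__ = [
    "UnsupportedFormatError",
    "SchemaError",
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_dye_model",
    "write_dye_model",
    "read_layout",
    "write_layout",
    "RunConfig",
    "ResultEnvelope",
]


class UnsupportedFormatError(ValueError):
    """Raised for image files that are not single-channel grayscale stacks."""


class SchemaError(ValueError):
    """Raised when a table or config is missing a required field."""


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


def read_stack(path) -> tuple[np.ndarray, Dict[str, Any]]:
    """Read a grayscale multi-page TIFF as an array ordered (plane, row, col).

    The dtype is preserved; OME metadata, when present, is surfaced in the
    returned metadata dict.  Multi-channel / RGB files are rejected.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes.upper()
        if "S" in axes or "C" in axes:
            raise UnsupportedFormatError(
                f"{path.name}: multi-channel/RGB TIFF is not supported"
            )
        data = series.asarray()
        meta: Dict[str, Any] = {"axes": axes}
        if tif.ome_metadata:
            meta["ome"] = tif.ome_metadata
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise UnsupportedFormatError(f"{path.name}: expected a 2-D or 3-D grayscale stack")
    return data, meta


def write_stack(path, data: np.ndarray) -> None:
    """Write a (plane, row, col) array as a multi-page TIFF."""
    arr = np.asarray(data)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError("stack must be 2-D or 3-D")
    tifffile.imwrite(Path(path), arr)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def read_table(path, required_columns: Sequence[str] = ()) -> pd.DataFrame:
    """Read a CSV with a header, checking that required columns exist."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    if df.shape[0] == 0 and df.shape[1] == 0:
        raise SchemaError(f"{Path(path).name}: empty data section")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing required column(s) {missing}")
    return df


def write_table(path, df: pd.DataFrame) -> None:
    """Write a CSV, serializing floats with 17 significant digits.

    17 digits round-trip IEEE doubles exactly; the decimal point is always
    '.' regardless of locale.
    """
    df.to_csv(Path(path), index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# spectra and dye models
# ---------------------------------------------------------------------------


def read_spectrum_csv(path, kind: str) -> Spectrum:
    """Read a 2-column (wavelength_nm, value) CSV as a Spectrum."""
    df = read_table(path, required_columns=("wavelength_nm", "value"))
    return Spectrum(df["wavelength_nm"].to_numpy(float), df["value"].to_numpy(float), kind)


def write_spectrum_csv(path, spectrum: Spectrum) -> None:
    write_table(
        path,
        pd.DataFrame(
            {"wavelength_nm": spectrum.wavelengths_nm, "value": spectrum.values}
        ),
    )


def write_dye_model(config_path, model: TwoStateDyeModel) -> None:
    """Write a dye model as a YAML config plus four sidecar spectrum CSVs."""
    config_path = Path(config_path)
    stem = config_path.stem
    cfg: Dict[str, Any] = {}
    for state_name in ("unbound", "bound"):
        state: DyeStateParams = getattr(model, state_name)
        abs_csv = config_path.with_name(f"{stem}_{state_name}_absorbance.csv")
        em_csv = config_path.with_name(f"{stem}_{state_name}_emission.csv")
        write_spectrum_csv(abs_csv, state.absorbance)
        write_spectrum_csv(em_csv, state.emission)
        cfg[state_name] = {
            "epsilon_peak": float(state.epsilon_peak),
            "phi": float(state.phi),
            "absorbance_csv": abs_csv.name,
            "emission_csv": em_csv.name,
        }
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=True))


def read_dye_model(config_path) -> TwoStateDyeModel:
    """Read a dye model from the YAML config written by ``write_dye_model``."""
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    states = {}
    for state_name in ("unbound", "bound"):
        if state_name not in cfg:
            raise SchemaError(f"{config_path.name}: missing state {state_name!r}")
        block = cfg[state_name]
        states[state_name] = DyeStateParams(
            epsilon_peak=float(block["epsilon_peak"]),
            phi=float(block["phi"]),
            absorbance=read_spectrum_csv(
                config_path.with_name(block["absorbance_csv"]), "absorbance"
            ),
            emission=read_spectrum_csv(
                config_path.with_name(block["emission_csv"]), "emission"
            ),
        )
    return TwoStateDyeModel(unbound=states["unbound"], bound=states["bound"])


# ---------------------------------------------------------------------------
# array layouts
# ---------------------------------------------------------------------------


def write_layout(path, layout: ArrayLayout) -> None:
    cfg = {
        "glycans": list(layout.glycans),
        "glycan_positions": layout.glycan_positions.tolist(),
        "control_positions": layout.control_positions.tolist(),
        "spot_radius": float(layout.spot_radius),
        "annulus_radii": [float(r) for r in layout.annulus_radii],
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def read_layout(path) -> ArrayLayout:
    cfg = yaml.safe_load(Path(path).read_text())
    for key in ("glycans", "glycan_positions", "control_positions", "spot_radius", "annulus_radii"):
        if key not in cfg:
            raise SchemaError(f"{Path(path).name}: missing layout key {key!r}")
    return ArrayLayout(
        glycans=tuple(cfg["glycans"]),
        glycan_positions=np.asarray(cfg["glycan_positions"], dtype=float),
        control_positions=np.asarray(cfg["control_positions"], dtype=float),
        spot_radius=float(cfg["spot_radius"]),
        annulus_radii=(float(cfg["annulus_radii"][0]), float(cfg["annulus_radii"][1])),
    )


# ---------------------------------------------------------------------------
# run configuration and result envelopes
# ---------------------------------------------------------------------------

_RUNCONFIG_KEYS = {"inputs", "params", "seed", "out_dir", "log_level"}


@dataclass(frozen=True)
class RunConfig:
    """Validated stage configuration; unknown keys are rejected."""

    inputs: tuple = ()
    params: Dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, mapping: Dict[str, Any]) -> "RunConfig":
        unknown = set(mapping) - _RUNCONFIG_KEYS
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        out = dict(mapping)
        if "inputs" in out:
            out["inputs"] = tuple(out["inputs"])
        if "seed" in out and int(out["seed"]) != out["seed"]:
            raise SchemaError("seed must be an integer")
        return cls(**out)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise SchemaError(f"{Path(path).name}: config must be a mapping")
        return cls.from_mapping(data)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


@dataclass
class ResultEnvelope:
    """Serializable record of one stage run.

    The ``outputs`` payload is reproducible given the same config and seed
    for deterministic stages; the timestamp is documented as excluded from
    reproducibility comparisons.
    """

    stage: str
    config: Dict[str, Any]
    seed: Optional[int]
    outputs: Dict[str, Any]
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(_jsonable(dataclasses.asdict(self)), indent=2, sort_keys=True)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")
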