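"""Readers, writers and validated configuration for the command line.

File dialects:

* material CSV — columns ``frequency_hz, eps_rel_real, sigma_s_per_m``
* parametric material JSON — ``{"materials": {name: {eps_inf, sigma_static,
  valid_range, terms: [{delta_eps, tau_s, alpha}]}}}``
* coefficients JSON — ``{kind, values, units_note, provenance}``
* body YAML — layers (material + thickness), geometry, gel, g2, calibration

Tabular outputs are CSV with a commented metadata header (version, seed,
config hash); coefficient fits are JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .dielectric import (
    ColeColeTerm,
    DispersiveMaterial,
    ElectrodeGeometry,
    ParametricMaterial,
    TabulatedMaterial,
)
from .fixtures import builtin_materials
from .network import LayeredBody, TissueLayer
from .partial_capacitance import IFCoefficients

MATERIAL_CSV_COLUMNS = ("frequency_hz", "eps_rel_real", "sigma_s_per_m")


# ---------------------------------------------------------------------------
# materials
# ---------------------------------------------------------------------------


def load_material_csv(path, name: str | None = None) -> TabulatedMaterial:
    df = pd.read_csv(path, comment="#")
    missing = set(MATERIAL_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing material CSV columns {sorted(missing)}")
    return TabulatedMaterial(
        name=name or Path(path).stem,
        frequencies=df["frequency_hz"].to_numpy(),
        eps_rel=df["eps_rel_real"].to_numpy(),
        sigma=df["sigma_s_per_m"].to_numpy(),
    )


def save_material_csv(material: TabulatedMaterial, path) -> None:
    pd.DataFrame({
        "frequency_hz": material.frequencies,
        "eps_rel_real": material.eps_rel,
        "sigma_s_per_m": material.sigma,
    }).to_csv(path, index=False)


class _TermSchema(BaseModel):
    delta_eps: float
    tau_s: float = Field(gt=0)
    alpha: float = Field(ge=0, lt=1, default=0.0)


class _ParametricSchema(BaseModel):
    eps_inf: float = Field(ge=1)
    sigma_static: float = Field(ge=0, default=0.0)
    valid_range: tuple[float, float] = (1e-6, 1e9)
    terms: list[_TermSchema] = []


def load_parametric_materials(path) -> dict[str, ParametricMaterial]:
    raw = json.loads(Path(path).read_text())
    out = {}
    for name, entry in raw["materials"].items():
        m = _ParametricSchema.model_validate(entry)
        out[name] = ParametricMaterial(
            name=name,
            eps_inf=m.eps_inf,
            terms=tuple(ColeColeTerm(t.delta_eps, t.tau_s, t.alpha) for t in m.terms),
            sigma_static=m.sigma_static,
            valid_range=m.valid_range,
        )
    return out


def load_materials(source) -> dict[str, DispersiveMaterial]:
    """Material registry from 'builtin', a JSON file, or a list of CSVs."""
    if source in (None, "builtin"):
        return dict(builtin_materials())
    if isinstance(source, (str, Path)):
        source = [source]
    registry: dict[str, DispersiveMaterial] = {}
    for item in source:
        p = Path(item)
        if p.suffix == ".json":
            registry.update(load_parametric_materials(p))
        else:
            mat = load_material_csv(p)
            registry[mat.name] = mat
    return registry


# ---------------------------------------------------------------------------
# coefficients
# ---------------------------------------------------------------------------


def load_coefficients(path) -> IFCoefficients:
    return IFCoefficients.from_dict(json.loads(Path(path).read_text()))


def save_coefficients(coeffs: IFCoefficients, path, extra: dict | None = None) -> None:
    payload = coeffs.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# body configuration
# ---------------------------------------------------------------------------


class GeometryConfig(BaseModel):
    width_m: float = Field(gt=0)
    length_m: float = Field(gt=0)
    separation_m: float = Field(gt=0)


class LayerConfig(BaseModel):
    material: str
    thickness_mm: Optional[float] = None
    infinite: bool = False

    @field_validator("thickness_mm")
    @classmethod
    def _positive(cls, v):
        if v is not None and v <= 0:
            raise ValueError("thickness_mm must be > 0")
        return v


class BodyConfig(BaseModel):
    """Validated layered-body description (YAML/JSON)."""

    layers: list[LayerConfig]
    geometry: GeometryConfig
    gel_ohms: float = Field(ge=0, default=0.0)
    g2_m: Optional[float] = None
    calibration_scale: float = Field(gt=0, default=1.0)
    materials: object = "builtin"


def load_body(path) -> LayeredBody:
    cfg = BodyConfig.model_validate(yaml.safe_load(Path(path).read_text()))
    registry = load_materials(cfg.materials)
    layers = []
    for lay in cfg.layers:
        if lay.material not in registry:
            raise KeyError(
                f"{path}: material '{lay.material}' not in registry "
                f"{sorted(registry)}"
            )
        layers.append(TissueLayer(material=registry[lay.material],
                                  thickness_mm=lay.thickness_mm,
                                  infinite=lay.infinite))
    return LayeredBody(
        layers=tuple(layers),
        geometry=ElectrodeGeometry(**cfg.geometry.model_dump()),
        gel_resistance=cfg.gel_ohms,
        g2=cfg.g2_m,
        calibration_scale=cfg.calibration_scale,
    )


def config_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------


def _metadata_header(seed=None, config_hash_=None, **extra) -> str:
    meta = {"tpbecm_version": __version__, "seed": seed, "config_hash": config_hash_}
    meta.update(extra)
    return "".join(f"# {k}: {v}\n" for k, v in meta.items() if v is not None)


def write_spectrum_csv(spectrum, path, seed=None, config_hash_=None) -> None:
    """Long-format impedance CSV: ``frequency_hz, layer, z_real, z_imag``."""
    frames = []
    for i, name in enumerate(spectrum.layer_names):
        frames.append(pd.DataFrame({
            "frequency_hz": spectrum.frequencies,
            "layer": name,
            "z_real": spectrum.layer_z[i].real,
            "z_imag": spectrum.layer_z[i].imag,
        }))
    frames.append(pd.DataFrame({
        "frequency_hz": spectrum.frequencies,
        "layer": "total",
        "z_real": spectrum.total.real,
        "z_imag": spectrum.total.imag,
    }))
    _write_with_header(pd.concat(frames, ignore_index=True), path,
                       seed=seed, config_hash_=config_hash_)


def _write_with_header(df: pd.DataFrame, path, index=False, **meta) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_header(**meta))
        df.to_csv(fh, index=index)
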