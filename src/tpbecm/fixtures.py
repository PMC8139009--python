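"""Synthetic stand-ins for physically measured or simulated inputs.

Everything here is generated, not measured: a salted/pure agar material
pair (NaCl-doped agar has the higher conductivity, hence the larger
complex-permittivity magnitude at low frequency), double-layer phantom
capacitance prediction, a model-vs-noisy-measurement agreement study for
the phantom pipeline, and the loader for the external-literature tissue
dielectric starter pack.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .dielectric import (
    ColeColeTerm,
    DispersiveMaterial,
    ElectrodeGeometry,
    ParametricMaterial,
    TabulatedMaterial,
    default_frequency_grid,
)
from .network import LayeredBody, TissueLayer
from .partial_capacitance import (
    IFCoefficients,
    classify_values,
    reduce_stack,
)

#: Default phantom electrode pair: 1 cm x 1 cm electrodes, 1 cm apart.
PHANTOM_GEOMETRY = ElectrodeGeometry(width_m=0.01, length_m=0.01, separation_m=0.01)

#: Fixture conductivities [S/m]: DI-water agar vs 10 g/L NaCl agar.
#: Plausible laboratory values chosen for this synthetic pair.
SIGMA_PURE_DEFAULT = 0.05
SIGMA_SALTED_DEFAULT = 1.6


@dataclass(frozen=True)
class AgarPair:
    """Synthetic salted/pure agar materials with guaranteed ordering."""

    pure: TabulatedMaterial
    salted: TabulatedMaterial
    salt_concentration_g_per_l: float = 10.0

    def __post_init__(self) -> None:
        f = self.pure.frequencies
        if np.any(np.abs(self.salted.eval(f)) <= np.abs(self.pure.eval(f))):
            raise ValueError(
                "|eps*_salted| must exceed |eps*_pure| at every grid frequency"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Double-layer cylinder phantom: a thin top layer on a thick base."""

    top: DispersiveMaterial
    bottom: DispersiveMaterial
    top_thickness_mm: float = 2.0
    bottom_thickness_mm: float = 50.0
    geometry: ElectrodeGeometry = PHANTOM_GEOMETRY

    def __post_init__(self) -> None:
        if self.top_thickness_mm <= 0:
            raise ValueError("top_thickness_mm must be > 0")
        if self.bottom_thickness_mm < 10.0 * self.top_thickness_mm:
            raise ValueError(
                "bottom layer must be >= 10x the top thickness for the "
                "infinite-layer assumption"
            )


def gen_agar_pair(
    seed: int | None = None,
    sigma_pure: float = SIGMA_PURE_DEFAULT,
    sigma_salted: float = SIGMA_SALTED_DEFAULT,
    eps_rel: float = 80.0,
    noise_sd: float = 0.0,
    frequencies: np.ndarray | None = None,
) -> AgarPair:
    """Two tabulated agar materials on the 201-point 0.1 Hz-10 kHz grid.

    Both carry a water-like baseline permittivity plus the strong
    low-frequency alpha-type dispersion that two-electrode impedance
    measurements of ionic hydrogels exhibit (apparent relative
    permittivities of order 1e5 below 1 Hz, decaying by several decades
    towards 10 kHz); the ion-rich salted material has the higher
    conductivity and the stronger dispersion.  ``noise_sd`` adds seeded
    multiplicative roughness to both tables, emulating measurement scatter.
    """
    if not 0 < sigma_pure < sigma_salted:
        raise ValueError("need 0 < sigma_pure < sigma_salted")
    f = default_frequency_grid() if frequencies is None else np.asarray(frequencies)
    rng = np.random.default_rng(seed)

    def table(name: str, sigma: float) -> TabulatedMaterial:
        # alpha-dispersion amplitude grows with the ionic strength
        amp = 1e5 * (sigma / sigma_pure) ** 0.5
        eps = eps_rel + amp / (1.0 + (f / 10.0) ** 0.8)
        sig = np.full_like(f, sigma)
        if noise_sd > 0:
            eps = eps * (1.0 + noise_sd * rng.standard_normal(f.shape))
            sig = sig * (1.0 + noise_sd * rng.standard_normal(f.shape))
        return TabulatedMaterial(name=name, frequencies=f,
                                 eps_rel=np.maximum(eps, 1.0),
                                 sigma=np.maximum(sig, 0.0))

    return AgarPair(pure=table("agar_pure", sigma_pure),
                    salted=table("agar_salted", sigma_salted))


def phantom_body(spec: PhantomSpec, **kwargs) -> LayeredBody:
    """Layered-body view of a phantom (no gel by default)."""
    return LayeredBody(
        layers=(
            TissueLayer(material=spec.top, thickness_mm=spec.top_thickness_mm),
            TissueLayer(material=spec.bottom, infinite=True),
        ),
        geometry=spec.geometry,
        **kwargs,
    )


def predict_phantom_capacitance(
    spec: PhantomSpec,
    frequencies: np.ndarray | None = None,
    ppc_coeffs: IFCoefficients | None = None,
    spc_coeffs: IFCoefficients | None = None,
    g2: float | None = None,
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(frequencies, complex total capacitance) of the two-layer phantom.

    Classification is per frequency: a salted-on-pure phantom takes the PPC
    branch, pure-on-salted the SPC branch.
    """
    f = default_frequency_grid() if frequencies is None else np.asarray(frequencies)
    g2 = spec.geometry.half_space_geometric_factor() if g2 is None else g2
    reduction = reduce_stack(
        [spec.top.eval(f), spec.bottom.eval(f)],
        [spec.top_thickness_mm, spec.bottom_thickness_mm],
        g2,
        ppc_coeffs,
        spc_coeffs,
        scale=scale,
        frequencies=f,
    )
    return f, reduction.total


def phantom_pair_class(spec: PhantomSpec, frequencies: np.ndarray | None = None) -> np.ndarray:
    """Per-frequency class codes (+1 PPC / -1 SPC / 0) of the phantom pair."""
    f = default_frequency_grid() if frequencies is None else np.asarray(frequencies)
    from .dielectric import EPS0

    return classify_values(spec.top.eval(f) / EPS0, spec.bottom.eval(f) / EPS0)


def capacitance_agreement_study(
    spec: PhantomSpec,
    n_replicates: int = 200,
    noise_sd: float = 0.05,
    seed: int = 0,
    frequencies: np.ndarray | None = None,
) -> np.ndarray:
    """Model-vs-synthetic-measurement correlation study for one phantom.

    For each replicate, a synthetic "measured" capacitance spectrum is drawn
    as the model prediction with independent multiplicative Gaussian noise
    on the real and imaginary parts, and the Pearson correlation between
    model and measurement is computed for each part across the frequency
    grid.  Returns an ``(n_replicates, 2)`` array of (real, imag)
    correlations.  This is a pipeline self-consistency harness, not a
    reproduction of a physical measurement.
    """
    f, c_model = predict_phantom_capacitance(spec, frequencies)
    rng = np.random.default_rng(seed)
    out = np.empty((n_replicates, 2))
    for i in range(n_replicates):
        re = c_model.real * (1.0 + noise_sd * rng.standard_normal(f.shape))
        im = c_model.imag * (1.0 + noise_sd * rng.standard_normal(f.shape))
        out[i, 0] = np.corrcoef(c_model.real, re)[0, 1]
        out[i, 1] = np.corrcoef(c_model.imag, im)[0, 1]
    return out


# ---------------------------------------------------------------------------
# tissue dielectric starter pack
# ---------------------------------------------------------------------------


def builtin_materials() -> dict[str, ParametricMaterial]:
    """Load the shipped external-literature tissue dielectric models."""
    path = resources.files("tpbecm.data") / "tissue_dielectrics.json"
    raw = json.loads(path.read_text())
    out = {}
    for name, m in raw["materials"].items():
        out[name] = ParametricMaterial(
            name=name,
            eps_inf=m["eps_inf"],
            terms=tuple(ColeColeTerm(**t) for t in m["terms"]),
            sigma_static=m["sigma_static"],
            valid_range=tuple(m["valid_range"]),
        )
    return out


def forearm_body(
    skin_thickness_mm: float = 1.5,
    fat_thickness_mm: float = 2.5,
    gel_resistance: float = 160.0,
    calibration_scale: float = 1.0,
    **kwargs,
) -> LayeredBody:
    """Baseline three-layer forearm: skin / fat / infinite muscle.

    Defaults: 1.5 mm skin over 2.5 mm fat over muscle, 160 ohm series gel,
    1 cm x 1 cm electrodes separated by 1 cm.
    """
    mats = builtin_materials()
    return LayeredBody(
        layers=(
            TissueLayer(material=mats["skin_dry"], thickness_mm=skin_thickness_mm),
            TissueLayer(material=mats["fat"], thickness_mm=fat_thickness_mm),
            TissueLayer(material=mats["muscle"], infinite=True),
        ),
        geometry=PHANTOM_GEOMETRY,
        gel_resistance=gel_resistance,
        calibration_scale=calibration_scale,
        **kwargs,
    )
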