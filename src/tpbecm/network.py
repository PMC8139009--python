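"""Layered-body impedance network.

Builds the equivalent circuit of an ordered tissue stack (e.g.
skin / fat / muscle) under a coplanar electrode pair: each layer becomes a
complex capacitor via the partial-capacitance reduction, capacitors are
chained serially (SPC interfaces) or in parallel (PPC interfaces) from the
bottom up, and an optional series gel resistance models the electrode
coupling.  Exposes per-layer and total impedance spectra plus thickness and
permittivity sweeps for variability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dielectric import DispersiveMaterial, ElectrodeGeometry
from .partial_capacitance import IFCoefficients, StackReduction, reduce_stack

_CLASS_NAME = {1: "parallel", 0: "merged", -1: "series"}


@dataclass(frozen=True)
class TissueLayer:
    """One layer of the stack: a material plus its thickness.

    The bottom layer of a body is marked ``infinite`` and needs no
    thickness (any value given is ignored in the composition).
    """

    material: DispersiveMaterial
    thickness_mm: float | None = None
    infinite: bool = False

    def __post_init__(self) -> None:
        if not self.infinite and (self.thickness_mm is None or self.thickness_mm <= 0):
            raise ValueError("finite layers need thickness_mm > 0")

    @property
    def name(self) -> str:
        return self.material.name


@dataclass(frozen=True)
class LayeredBody:
    """Ordered top-to-bottom tissue stack with electrode geometry.

    ``g2`` is the geometric factor of the effectively infinite bottom
    layer [m]; when ``None`` it is estimated from the electrode geometry by
    conformal mapping.  ``calibration_scale`` multiplies every evaluated
    interdimensional factor (unit-interpretation calibration, default 1).
    """

    layers: tuple[TissueLayer, ...]
    geometry: ElectrodeGeometry
    gel_resistance: float = 0.0
    g2: float | None = None
    calibration_scale: float = 1.0
    ppc_coeffs: IFCoefficients = field(default_factory=lambda: IFCoefficients.default("PPC"))
    spc_coeffs: IFCoefficients = field(default_factory=lambda: IFCoefficients.default("SPC"))

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ValueError("body needs at least one layer")
        flags = [lay.infinite for lay in self.layers]
        if sum(flags) != 1 or not flags[-1]:
            raise ValueError("exactly one infinite layer is required, at the bottom")
        if self.gel_resistance < 0:
            raise ValueError("gel_resistance must be >= 0")
        if self.calibration_scale <= 0:
            raise ValueError("calibration_scale must be > 0")

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(lay.name for lay in self.layers)

    def bottom_geometric_factor(self) -> float:
        if self.g2 is not None:
            if self.g2 <= 0:
                raise ValueError("g2 must be > 0")
            return self.g2
        return self.geometry.half_space_geometric_factor()

    def thicknesses_mm(self) -> list[float]:
        return [np.inf if lay.infinite else float(lay.thickness_mm) for lay in self.layers]

    def layer_index(self, layer_name: str) -> int:
        names = self.layer_names
        if layer_name not in names:
            raise KeyError(f"unknown layer '{layer_name}'; have {list(names)}")
        return names.index(layer_name)

    def with_layer(self, index: int, layer: TissueLayer) -> "LayeredBody":
        layers = list(self.layers)
        layers[index] = layer
        return replace(self, layers=tuple(layers))


@dataclass
class ImpedanceSpectrum:
    """Per-layer and total complex impedance over a frequency grid.

    ``layer_z[i]`` is the impedance of layer ``i``'s partial capacitor;
    ``subtree_z[i]`` the impedance of the sub-network from layer ``i`` down
    (used by the pulse engine to distribute voltages); ``total`` includes the
    series gel resistance.  ``interface_codes[i]`` holds +1 (parallel/PPC),
    -1 (series/SPC) or 0 (merged/homogeneous) per frequency.
    """

    frequencies: np.ndarray
    layer_names: tuple[str, ...]
    layer_z: np.ndarray  # (n_layers, n_freq)
    subtree_z: np.ndarray  # (n_layers, n_freq)
    total: np.ndarray  # (n_freq,)
    gel_resistance: float
    interface_codes: np.ndarray  # (n_layers - 1, n_freq)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def topology(self) -> tuple[str, ...]:
        """'series'/'parallel'/'merged' per interface ('mixed' if it flips)."""
        out = []
        for codes in np.atleast_2d(self.interface_codes):
            u = np.unique(codes)
            out.append(_CLASS_NAME[int(u[0])] if len(u) == 1 else "mixed")
        return tuple(out)

    def layer(self, name: str) -> np.ndarray:
        return self.layer_z[self.layer_names.index(name)]


def _combine_down(layer_z: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Subtree impedances: combine partial capacitors from the bottom up."""
    n = layer_z.shape[0]
    subtree = np.empty_like(layer_z)
    subtree[-1] = layer_z[-1]
    for i in range(n - 2, -1, -1):
        series = subtree[i + 1] + layer_z[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            par = 1.0 / (1.0 / subtree[i + 1] + 1.0 / layer_z[i])
        # merged (homogeneous) interfaces contribute no extra element
        subtree[i] = np.where(codes[i] == 1, par,
                              np.where(codes[i] == 0, subtree[i + 1], series))
    return subtree


def _network_arrays(body: LayeredBody, frequencies: np.ndarray,
                    reduction: StackReduction) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(layer_z, subtree_z, codes) from a stack reduction at ``frequencies``."""
    w = 2.0 * np.pi * frequencies
    partials = np.vstack([np.asarray(p) for p in reduction.partials])
    with np.errstate(divide="ignore", invalid="ignore"):
        layer_z = 1.0 / (1j * w[None, :] * partials)
    # an infinite partial capacitor (homogeneous interface) is a short
    layer_z = np.where(np.isfinite(partials), layer_z, 0.0)
    codes = (np.vstack(reduction.classes) if reduction.classes
             else np.empty((0, len(frequencies)), dtype=int))
    subtree = _combine_down(layer_z, codes)
    return layer_z, subtree, codes


def evaluate_stack(body: LayeredBody, frequencies: np.ndarray) -> StackReduction:
    """Permittivity evaluation + partial-capacitance reduction of a body."""
    eps = [lay.material.eval(frequencies) for lay in body.layers]
    return reduce_stack(
        eps,
        body.thicknesses_mm(),
        body.bottom_geometric_factor(),
        body.ppc_coeffs,
        body.spc_coeffs,
        scale=body.calibration_scale,
        frequencies=frequencies,
    )


def build_network(body: LayeredBody, frequencies) -> ImpedanceSpectrum:
    """Impedance spectrum of the layered body over ``frequencies`` [Hz]."""
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    reduction = evaluate_stack(body, f)
    layer_z, subtree, codes = _network_arrays(body, f, reduction)
    total = subtree[0] + body.gel_resistance
    return ImpedanceSpectrum(
        frequencies=f,
        layer_names=body.layer_names,
        layer_z=layer_z,
        subtree_z=subtree,
        total=total,
        gel_resistance=body.gel_resistance,
        interface_codes=codes,
    )


def dc_conductances(body: LayeredBody, if_frequency: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DC limit of the network: per-layer and subtree conductances [S].

    As ``w -> 0`` the complex-capacitor network maps onto a conductance
    network with ``sigma`` playing the role of the permittivity and the
    geometric/interdimensional factors unchanged (``Y = j*w*C* -> sigma*g``).
    The IF log arguments keep their finite-frequency permittivities,
    evaluated at ``if_frequency`` (the pulse fundamental), since the
    relative-permittivity contrast has no DC limit for PPC pairs.
    Returns ``(layer_g, subtree_g, codes)``.
    """
    sig = [np.asarray([lay.material.dc_conductivity()], dtype=complex)
           for lay in body.layers]
    from .dielectric import EPS0

    log_eps = [lay.material.eval(np.asarray([if_frequency])) / EPS0 for lay in body.layers]
    reduction = reduce_stack(
        sig,
        body.thicknesses_mm(),
        body.bottom_geometric_factor(),
        body.ppc_coeffs,
        body.spc_coeffs,
        scale=body.calibration_scale,
        log_eps=log_eps,
    )
    layer_g = np.vstack([np.asarray(p) for p in reduction.partials]).real
    with np.errstate(divide="ignore"):
        layer_z = np.where(np.isfinite(layer_g), 1.0 / layer_g, 0.0)
    codes = (np.vstack(reduction.classes) if reduction.classes
             else np.empty((0, 1), dtype=int))
    subtree_z = _combine_down(layer_z.astype(complex), codes)
    with np.errstate(divide="ignore"):
        subtree_g = np.where(subtree_z.real != 0, 1.0 / subtree_z.real, np.inf)
    return layer_g[:, 0], subtree_g[:, 0], codes[:, 0] if codes.size else codes


def thickness_sweep(body: LayeredBody, layer_name: str, values_mm,
                    frequencies=None) -> list[ImpedanceSpectrum]:
    """One spectrum per thickness value of the named (finite) layer."""
    from .dielectric import default_frequency_grid

    if frequencies is None:
        frequencies = default_frequency_grid()
    idx = body.layer_index(layer_name)
    if body.layers[idx].infinite:
        raise ValueError(f"cannot sweep the infinite layer '{layer_name}'")
    out = []
    for h in values_mm:
        layer = replace(body.layers[idx], thickness_mm=float(h))
        out.append(build_network(body.with_layer(idx, layer), frequencies))
    return out


def permittivity_sweep(body: LayeredBody, layer_name: str,
                       scale_factors=(0.8, 0.9, 1.0, 1.1, 1.2),
                       frequencies=None) -> list[ImpedanceSpectrum]:
    """One spectrum per uniform eps*(f) scale factor of the named layer."""
    from .dielectric import default_frequency_grid

    if frequencies is None:
        frequencies = default_frequency_grid()
    idx = body.layer_index(layer_name)
    if any(s <= 0 for s in scale_factors):
        raise ValueError("scale factors must be > 0")
    out = []
    for s in scale_factors:
        layer = replace(body.layers[idx], material=body.layers[idx].material.scaled(s))
        out.append(build_network(body.with_layer(idx, layer), frequencies))
    return out


def calibrate_scale(body: LayeredBody, layer_name: str, target_ohm: float,
                    frequency: float) -> float:
    """One-time calibration of the IF unit-interpretation factor.

    Returns the ``calibration_scale`` that makes the named layer's
    partial-capacitor impedance magnitude equal ``target_ohm`` at
    ``frequency``.  Valid because every IF-derived layer impedance is
    exactly inversely proportional to the scale.
    """
    idx = body.layer_index(layer_name)
    if body.layers[idx].infinite:
        raise ValueError("the bottom layer has no IF; calibrate on a finite layer")
    base = replace(body, calibration_scale=1.0)
    spec = build_network(base, np.asarray([frequency]))
    return float(np.abs(spec.layer_z[idx, 0]) / target_ohm)
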