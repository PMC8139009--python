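"""Partial-capacitance composition of layered dielectric stacks.

The total capacitance seen by a coplanar electrode pair on a layered
structure decomposes into one partial capacitor per layer.  The connection
of the top layer's capacitor is decided by the permittivity contrast with
the layer below it:

* PPC (parallel partial capacitance), ``|eps1*| > |eps2*|`` — field lines
  shunt along the high-permittivity upper layer; capacitors in parallel::

      C_tot = (eps1 - eps2) * I_PPC + eps2 * g2
      I_PPC = a0 + a1*ln|d_eps_rel| + a2*ln(h1_mm)

* SPC (serial partial capacitance), ``|eps1*| < |eps2*|`` — the field
  penetrates the low-permittivity upper layer; capacitors in series::

      1/C_tot = (1/eps1 - 1/eps2) / I_SPC + 1/(eps2 * g2)
      I_SPC = (b0 + b1*ln|eps2_rel/eps1_rel|) / h1_mm + c0

``I`` is the *interdimensional factor* (IF): a regression-corrected
geometric factor that absorbs the error of extending the planar (2-D)
partial-capacitance formulas to a finite 3-D electrode geometry.  The IF
log arguments use dimensionless relative permittivities (magnitudes, so the
IF stays real for lossy media) and the top-layer thickness ``h1`` in
millimetres; the permittivities in the linear terms are the full complex
absolute values, which is what makes the composition valid for conductive
layers.  The absolute unit of the IF is tied to the dataset it was fitted
on; a multiplicative ``scale`` calibration factor (default 1.0) is exposed
wherever an IF is evaluated.

An N-layer stack is reduced recurrently from top to bottom: each pairwise
composition yields an integrated upper layer (effective permittivity
``C/g2``, summed thickness) that is then paired with the next layer down.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np

from .dielectric import EPS0, ComplexCapacitance, ComplexPermittivity

#: Relative tolerance on |eps*| below which a pair counts as homogeneous.
HOMOGENEOUS_RTOL = 1e-9

#: Default PPC IF coefficients (a0, a1, a2).
PPC_DEFAULT_COEFFS = (4.69e-3, 1.12e-3, 4.40e-3)
#: Default SPC IF coefficients (b0, b1, c0).
SPC_DEFAULT_COEFFS = (2.83e3, 1.00e3, 1.30e3)

# integer class codes used on per-frequency arrays
_PPC, _HOM, _SPC = 1, 0, -1


class PairClass(Enum):
    """Connection class of a layer pair."""

    PPC = "PPC"
    SPC = "SPC"
    HOMOGENEOUS = "HOMOGENEOUS"


class HomogeneousPairError(ValueError):
    """IF evaluation requested for a (near-)homogeneous pair.

    Use the homogeneous path ``C = eps2*g2`` instead.
    """


class ClassCrossoverWarning(UserWarning):
    """A pair's PPC/SPC class flips across the frequency grid."""


@dataclass(frozen=True)
class IFCoefficients:
    """Interdimensional-factor regression coefficients.

    ``values`` is ``(a0, a1, a2)`` for PPC or ``(b0, b1, c0)`` for SPC.
    ``units_note`` records the fixed unit interpretation: thickness in mm
    inside the log / inverse terms, permittivity arguments relative
    (dimensionless), IF output in geometric-factor units.
    """

    kind: str
    values: tuple[float, float, float]
    units_note: str = (
        "h1 in mm; permittivity log arguments relative (dimensionless); "
        "IF in geometric-factor units"
    )
    provenance: str = "user"

    def __post_init__(self) -> None:
        if self.kind not in ("PPC", "SPC"):
            raise ValueError("kind must be 'PPC' or 'SPC'")
        if len(self.values) != 3:
            raise ValueError("exactly three coefficients are required")
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @classmethod
    def default(cls, kind: str) -> "IFCoefficients":
        """The shipped published coefficient triple for ``kind``."""
        vals = {"PPC": PPC_DEFAULT_COEFFS, "SPC": SPC_DEFAULT_COEFFS}[kind]
        return cls(kind=kind, values=vals, provenance="published-default")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "values": list(self.values),
            "units_note": self.units_note,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IFCoefficients":
        return cls(
            kind=d["kind"],
            values=tuple(d["values"]),
            units_note=d.get("units_note", cls.default(d["kind"]).units_note),
            provenance=d.get("provenance", "file"),
        )


def default_coefficients() -> dict[str, IFCoefficients]:
    """Load both shipped coefficient triples from the packaged JSON file."""
    path = resources.files("tpbecm.data") / "default_if_coefficients.json"
    raw = json.loads(path.read_text())
    return {k: IFCoefficients.from_dict(v) for k, v in raw.items()}


@dataclass(frozen=True)
class LayerPair:
    """Upper layer over an effectively infinite lower layer at one frequency."""

    eps1: ComplexPermittivity
    eps2: ComplexPermittivity
    h1_mm: float
    g2: float

    def __post_init__(self) -> None:
        if self.h1_mm <= 0:
            raise ValueError("h1_mm must be > 0")
        if self.g2 <= 0:
            raise ValueError("g2 must be > 0")


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_values(eps1, eps2, rtol: float = HOMOGENEOUS_RTOL):
    """Vectorised class codes (+1 PPC, 0 homogeneous, -1 SPC) from |eps*|."""
    m1 = np.abs(np.asarray(eps1))
    m2 = np.abs(np.asarray(eps2))
    scale = np.maximum(m1, m2)
    tie = np.abs(m1 - m2) <= rtol * np.where(scale > 0, scale, 1.0)
    code = np.where(m1 > m2, _PPC, _SPC)
    return np.where(tie, _HOM, code)


def classify_pair(eps1: ComplexPermittivity, eps2: ComplexPermittivity,
                  rtol: float = HOMOGENEOUS_RTOL) -> PairClass:
    """PPC/SPC/homogeneous decision for one layer pair at one frequency."""
    code = int(classify_values(eps1.value, eps2.value, rtol=rtol))
    return {_PPC: PairClass.PPC, _HOM: PairClass.HOMOGENEOUS, _SPC: PairClass.SPC}[code]


# ---------------------------------------------------------------------------
# IF evaluation (raw functional forms, vectorised)
# ---------------------------------------------------------------------------


def ppc_if_value(delta_eps_rel, h1_mm, coeffs: IFCoefficients):
    """``I = a0 + a1*ln(delta) + a2*ln(h1)`` with relative ``delta > 0``, h1 in mm."""
    if coeffs.kind != "PPC":
        raise ValueError("PPC coefficients required")
    delta = np.asarray(delta_eps_rel, dtype=float)
    if np.any(delta <= 0):
        raise HomogeneousPairError(
            "zero/negative permittivity difference: use the homogeneous path"
        )
    a0, a1, a2 = coeffs.values
    out = a0 + a1 * np.log(delta) + a2 * np.log(h1_mm)
    return out if out.shape else float(out)


def spc_if_value(eps_ratio, h1_mm, coeffs: IFCoefficients):
    """``I = (b0 + b1*ln(ratio))/h1 + c0`` with relative ``ratio > 0``, h1 in mm."""
    if coeffs.kind != "SPC":
        raise ValueError("SPC coefficients required")
    ratio = np.asarray(eps_ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValueError("permittivity ratio must be > 0")
    h1 = np.asarray(h1_mm, dtype=float)
    if np.any(h1 <= 0):
        raise ValueError("h1_mm must be > 0")
    b0, b1, c0 = coeffs.values
    out = (b0 + b1 * np.log(ratio)) / h1 + c0
    return out if out.shape else float(out)


def eval_ppc_if(pair: LayerPair, coeffs: IFCoefficients) -> float:
    """PPC IF of a pair: the log argument is ``| (eps1*-eps2*)/eps0 |``."""
    delta = abs(pair.eps1.value - pair.eps2.value) / EPS0
    return ppc_if_value(delta, pair.h1_mm, coeffs)


def eval_spc_if(pair: LayerPair, coeffs: IFCoefficients) -> float:
    """SPC IF of a pair: the log argument is ``|eps2*/eps1*|``."""
    ratio = abs(pair.eps2.value) / abs(pair.eps1.value)
    return spc_if_value(ratio, pair.h1_mm, coeffs)


# ---------------------------------------------------------------------------
# pairwise composition
# ---------------------------------------------------------------------------


def compose_ppc(pair: LayerPair, coeffs: IFCoefficients, *,
                if_value: float | None = None, scale: float = 1.0) -> ComplexCapacitance:
    """Total capacitance of a PPC pair: ``C = (eps1-eps2)*I + eps2*g2``.

    ``if_value`` overrides the regression IF (test harnesses, fitted values);
    otherwise ``I = scale * eval_ppc_if(pair, coeffs)``.  As ``eps1 -> eps2``
    the ``(eps1-eps2)*I`` term vanishes (x*ln x -> 0) and the homogeneous
    limit ``eps2*g2`` is returned.
    """
    e1, e2 = pair.eps1.value, pair.eps2.value
    if classify_pair(pair.eps1, pair.eps2) is PairClass.HOMOGENEOUS:
        return ComplexCapacitance(value=e2 * pair.g2, frequency=pair.eps1.frequency)
    i_val = scale * eval_ppc_if(pair, coeffs) if if_value is None else if_value
    return ComplexCapacitance(value=(e1 - e2) * i_val + e2 * pair.g2,
                              frequency=pair.eps1.frequency)


def compose_spc(pair: LayerPair, coeffs: IFCoefficients, *,
                if_value: float | None = None, scale: float = 1.0) -> ComplexCapacitance:
    """Total capacitance of an SPC pair: ``1/C = (1/eps1-1/eps2)/I + 1/(eps2*g2)``."""
    e1, e2 = pair.eps1.value, pair.eps2.value
    if e2 == 0:
        raise SingularTermError("eps2 is zero: bottom-layer term 1/(eps2*g2) singular")
    if classify_pair(pair.eps1, pair.eps2) is PairClass.HOMOGENEOUS:
        return ComplexCapacitance(value=e2 * pair.g2, frequency=pair.eps1.frequency)
    if e1 == 0:
        raise SingularTermError("eps1 is zero: series term 1/eps1 singular")
    i_val = scale * eval_spc_if(pair, coeffs) if if_value is None else if_value
    if i_val == 0:
        raise SingularTermError("IF is zero: series term 1/I singular")
    inv = (1.0 / e1 - 1.0 / e2) / i_val + 1.0 / (e2 * pair.g2)
    if inv == 0:
        raise SingularTermError("total reciprocal capacitance is zero")
    return ComplexCapacitance(value=1.0 / inv, frequency=pair.eps1.frequency)


class SingularTermError(ZeroDivisionError):
    """A reciprocal term in the SPC composition is singular."""


# ---------------------------------------------------------------------------
# vectorised stack reduction
# ---------------------------------------------------------------------------


@dataclass
class StackReduction:
    """Result of reducing an N-layer stack at a set of frequencies.

    ``partials[i]`` is the per-layer partial capacitor built from the
    ``(i, i+1)`` interface (the bottom layer's is ``eps_N * g2``);
    ``classes[i]`` the per-frequency class codes of interface ``i``;
    ``total`` the recurrently integrated top-to-bottom capacitance.
    All arrays are shaped like the frequency grid.
    """

    total: np.ndarray
    partials: list[np.ndarray]
    classes: list[np.ndarray]

    def interface_class(self, i: int) -> PairClass:
        """Single class of interface ``i`` if it is uniform over frequency."""
        codes = np.unique(self.classes[i])
        if len(codes) != 1:
            raise ValueError(f"interface {i} class varies across the grid")
        return {_PPC: PairClass.PPC, _HOM: PairClass.HOMOGENEOUS,
                _SPC: PairClass.SPC}[int(codes[0])]


def _compose_arrays(e1, e2, log_e1, log_e2, h1_mm, g2, ppc, spc, scale):
    """Elementwise pair composition; returns (C_total, class codes, C_partial1)."""
    e1 = np.asarray(e1, dtype=complex)
    e2 = np.asarray(e2, dtype=complex)
    codes = classify_values(log_e1, log_e2)

    hom = e2 * g2
    total = np.array(np.broadcast_to(hom, codes.shape), dtype=complex)
    partial = np.full(codes.shape, np.inf + 0j)

    is_ppc = codes == _PPC
    if np.any(is_ppc):
        delta = np.abs(np.asarray(log_e1) - np.asarray(log_e2))
        i_ppc = scale * ppc_if_value(np.where(is_ppc, delta, 1.0), h1_mm, ppc)
        c1 = (e1 - e2) * i_ppc
        total = np.where(is_ppc, c1 + e2 * g2, total)
        partial = np.where(is_ppc, c1, partial)

    is_spc = codes == _SPC
    if np.any(is_spc):
        ratio = np.abs(np.asarray(log_e2)) / np.abs(np.asarray(log_e1))
        i_spc = scale * spc_if_value(np.where(is_spc, ratio, 1.0), h1_mm, spc)
        c1 = i_spc / (1.0 / e1 - 1.0 / np.where(e2 == 0, np.nan, e2))
        inv = 1.0 / c1 + 1.0 / (e2 * g2)
        total = np.where(is_spc, 1.0 / inv, total)
        partial = np.where(is_spc, c1, partial)

    return total, codes, partial


def reduce_stack(
    eps_values,
    thicknesses_mm,
    g2: float,
    ppc_coeffs: IFCoefficients | None = None,
    spc_coeffs: IFCoefficients | None = None,
    *,
    scale: float = 1.0,
    log_eps=None,
    frequencies=None,
    infinite_ratio_warn: float = 10.0,
) -> StackReduction:
    """Recurrent top-to-bottom reduction of an ordered layer stack.

    Parameters
    ----------
    eps_values
        Sequence of complex permittivities [F/m], one entry per layer, each a
        scalar or an array over the frequency grid.  Top layer first; the
        last layer is the effectively infinite bottom layer.
    thicknesses_mm
        Thickness of each layer in mm.  The bottom entry is only used for
        the infinite-layer sanity warning and may be ``numpy.inf``.
    g2
        Geometric factor [m] of the effectively infinite bottom layer.
    log_eps
        Optional permittivity-like values used for the IF log arguments and
        pair classification (defaults to ``eps_values / eps0``).  The DC
        path of the pulse engine passes conductivities as ``eps_values``
        while keeping finite-frequency permittivities here.
    frequencies
        Optional grid, used only to name crossover frequencies in warnings.

    Returns a :class:`StackReduction` holding the recurrent total and the
    per-interface partial capacitors used to build the series/parallel
    network (``C_i = (eps_i - eps_{i+1})*I`` for PPC, ``C_i = I /
    (1/eps_i - 1/eps_{i+1})`` for SPC, ``eps_N*g2`` for the bottom layer).
    """
    eps_values = [np.asarray(e, dtype=complex) for e in eps_values]
    n = len(eps_values)
    if n == 0:
        raise ValueError("empty stack")
    thicknesses_mm = [float(h) for h in thicknesses_mm]
    if len(thicknesses_mm) != n:
        raise ValueError("one thickness per layer required")
    ppc_coeffs = ppc_coeffs or IFCoefficients.default("PPC")
    spc_coeffs = spc_coeffs or IFCoefficients.default("SPC")
    if log_eps is None:
        log_eps = [e / EPS0 for e in eps_values]
    else:
        log_eps = [np.asarray(e, dtype=complex) for e in log_eps]

    if n >= 2 and np.isfinite(thicknesses_mm[-1]):
        above = thicknesses_mm[-2]
        if thicknesses_mm[-1] < infinite_ratio_warn * above:
            warnings.warn(
                f"bottom layer ({thicknesses_mm[-1]:g} mm) is thinner than "
                f"{infinite_ratio_warn:g}x the layer above ({above:g} mm); the "
                "infinite-layer assumption may be poor",
                stacklevel=2,
            )

    shape = np.broadcast_shapes(*(e.shape for e in eps_values)) or (1,)
    if n == 1:
        total = np.broadcast_to(eps_values[0], shape).astype(complex) * g2
        return StackReduction(total=total, partials=[total.copy()], classes=[])

    # per-interface partial capacitors for the network view
    partials: list[np.ndarray] = []
    classes: list[np.ndarray] = []
    for i in range(n - 1):
        _, codes, partial = _compose_arrays(
            eps_values[i], eps_values[i + 1], log_eps[i], log_eps[i + 1],
            thicknesses_mm[i], g2, ppc_coeffs, spc_coeffs, scale,
        )
        codes = np.broadcast_to(codes, shape)
        partials.append(np.broadcast_to(partial, shape).astype(complex))
        classes.append(np.asarray(codes))
        flips = np.unique(codes)
        if len(flips) > 1:
            msg = f"interface {i} changes PPC/SPC class across the grid"
            if frequencies is not None:
                f = np.asarray(frequencies)
                idx = np.nonzero(np.diff(codes))[0]
                msg += f" near f = {np.round(f[idx], 4).tolist()} Hz"
            warnings.warn(ClassCrossoverWarning(msg), stacklevel=2)
    partials.append(np.broadcast_to(eps_values[-1], shape).astype(complex) * g2)

    # recurrent top-to-bottom integration for the total capacitance
    e_top = np.broadcast_to(eps_values[0], shape).astype(complex)
    log_top = np.broadcast_to(log_eps[0], shape).astype(complex)
    h_top = thicknesses_mm[0]
    total = e_top * g2
    for i in range(1, n):
        total, _, _ = _compose_arrays(
            e_top, eps_values[i], log_top, log_eps[i],
            h_top, g2, ppc_coeffs, spc_coeffs, scale,
        )
        e_top = total / g2
        log_top = e_top / EPS0
        if np.isfinite(thicknesses_mm[i]):
            h_top = h_top + thicknesses_mm[i]
    return StackReduction(total=np.asarray(total, dtype=complex),
                          partials=partials, classes=classes)
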