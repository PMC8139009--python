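"""Complex-permittivity algebra and the complex-capacitor correspondence.

A conductive dielectric layer driven at angular frequency ``w = 2*pi*f`` is
fully described by its complex permittivity

    eps* = eps - j*sigma/w        [F/m]

(engineering ``e^{+jwt}`` sign convention, used consistently throughout the
package).  A parallel RC one-port built from that material and a purely
geometric factor ``g = C/eps`` [m] collapses to a single *complex capacitor*
``C* = eps* * g`` whose impedance is ``Z = 1/(j*w*C*)``.  This module
provides that algebra, dispersive material models (tabulated spectra and
Cole-Cole parametric terms), electrode geometry, and the inversion that
recovers a permittivity table from a measured impedance spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ellipk

#: Vacuum permittivity [F/m].
EPS0 = 8.8541878128e-12


class FrequencyRangeError(ValueError):
    """Raised when a material is evaluated outside its declared validity."""


class SingularImpedanceError(ZeroDivisionError):
    """Raised when a complex capacitor has zero admittance (DC, sigma = 0)."""


# ---------------------------------------------------------------------------
# scalar value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComplexPermittivity:
    """Absolute complex permittivity [F/m] evaluated at one frequency.

    For passive media at ``f > 0`` the imaginary part is non-positive,
    since ``eps* = eps - j*sigma/w`` with ``sigma >= 0``.
    """

    value: complex
    frequency: float

    @classmethod
    def from_relative(cls, eps_rel: float, sigma: float, frequency: float) -> "ComplexPermittivity":
        """Build ``eps* = eps_rel*eps0 - j*sigma/w`` at ``frequency`` [Hz]."""
        if frequency <= 0:
            raise ValueError("frequency must be > 0 to form eps - j*sigma/w")
        w = 2.0 * np.pi * frequency
        return cls(value=complex(eps_rel * EPS0, -sigma / w), frequency=float(frequency))

    @property
    def relative(self) -> complex:
        """Dimensionless relative form ``eps*/eps0``."""
        return self.value / EPS0

    @property
    def eps_rel(self) -> float:
        """Real relative permittivity ``Re(eps*)/eps0``."""
        return self.value.real / EPS0

    @property
    def conductivity(self) -> float:
        """Conductivity ``sigma = -w*Im(eps*)`` [S/m]."""
        return -self.value.imag * 2.0 * np.pi * self.frequency

    @property
    def is_passive(self) -> bool:
        return self.value.imag <= 0.0


@dataclass(frozen=True)
class ComplexCapacitance:
    """Complex capacitance ``C* = eps* * g`` [F] at one frequency."""

    value: complex
    frequency: float


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Two identical rectangular surface electrodes on a half-space.

    ``width_m`` is the electrode dimension along the source-return axis,
    ``length_m`` the transverse dimension and ``separation_m`` the
    edge-to-edge gap between the electrodes.
    """

    width_m: float
    length_m: float
    separation_m: float

    def __post_init__(self) -> None:
        for name in ("width_m", "length_m", "separation_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def area(self) -> float:
        """Single-electrode area A [m^2]."""
        return self.width_m * self.length_m

    @property
    def distance(self) -> float:
        """Centre-to-centre source-return distance d [m]."""
        return self.separation_m + self.width_m

    def parallel_plate_geometric_factor(self) -> float:
        """Naive ``A/d`` factor [m] of the parallel-plate analogy."""
        return self.area / self.distance

    def half_space_geometric_factor(self) -> float:
        """Conformal-mapping estimate of the lower half-space factor [m].

        Treats the pair as a coplanar-strip line of length ``length_m``:
        the material half-space contributes ``C = eps * (L/2) * K(k')/K(k)``
        with modulus ``k = s/(s + 2w)``, so ``g = (L/2) * K(k')/K(k)``.
        Fringing beyond the strip ends is not modelled.
        """
        k = self.separation_m / (self.separation_m + 2.0 * self.width_m)
        # scipy's ellipk takes the parameter m = k**2
        return 0.5 * self.length_m * ellipk(1.0 - k**2) / ellipk(k**2)


# ---------------------------------------------------------------------------
# material models
# ---------------------------------------------------------------------------


class DispersiveMaterial:
    """Base class: a named material with ``eps*(f)`` over a validity range."""

    name: str

    @property
    def bounds(self) -> tuple[float, float]:  # pragma: no cover - abstract
        raise NotImplementedError

    def eval(self, frequency):  # pragma: no cover - abstract
        """Vectorised ``eps*(f)`` [F/m]; raises outside the validity range."""
        raise NotImplementedError

    def dc_conductivity(self) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def _check_range(self, f: np.ndarray) -> None:
        lo, hi = self.bounds
        if np.any(f <= 0):
            raise FrequencyRangeError(
                f"material '{self.name}': frequency must be > 0"
            )
        if np.any(f < lo) or np.any(f > hi):
            raise FrequencyRangeError(
                f"material '{self.name}': frequency outside validity range "
                f"[{lo:g}, {hi:g}] Hz"
            )

    def scaled(self, factor: float) -> "ScaledMaterial":
        """Material whose ``eps*(f)`` is uniformly scaled by ``factor``."""
        return ScaledMaterial(base=self, factor=factor)


@dataclass
class TabulatedMaterial(DispersiveMaterial):
    """Material defined by a measured/tabulated spectrum.

    ``frequencies`` must be strictly increasing and positive; ``eps_rel``
    and ``sigma`` are sampled on that grid.  Evaluation between grid points
    interpolates linearly in log-frequency; evaluation outside the grid is
    an error (no silent extrapolation).
    """

    name: str
    frequencies: np.ndarray
    eps_rel: np.ndarray
    sigma: np.ndarray
    #: set when the material was recovered from data with sigma < 0 somewhere
    negative_sigma_warning: bool = False
    #: relax the eps_rel >= 1 / sigma >= 0 physicality checks (recovered tables)
    strict: bool = True

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.eps_rel = np.asarray(self.eps_rel, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.frequencies.ndim != 1 or len(self.frequencies) < 2:
            raise ValueError("need a 1-D grid of at least two frequencies")
        if np.any(self.frequencies <= 0) or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be positive and strictly increasing")
        if self.eps_rel.shape != self.frequencies.shape or self.sigma.shape != self.frequencies.shape:
            raise ValueError("eps_rel and sigma must match the frequency grid")
        if self.strict:
            if np.any(self.sigma < 0):
                raise ValueError(f"material '{self.name}': sigma must be >= 0")
            if np.any(self.eps_rel < 1):
                raise ValueError(f"material '{self.name}': eps_rel must be >= 1")

    @property
    def bounds(self) -> tuple[float, float]:
        return float(self.frequencies[0]), float(self.frequencies[-1])

    def eval(self, frequency):
        f = np.asarray(frequency, dtype=float)
        self._check_range(f)
        logf = np.log(f)
        grid = np.log(self.frequencies)
        eps = np.interp(logf, grid, self.eps_rel)
        sig = np.interp(logf, grid, self.sigma)
        w = 2.0 * np.pi * f
        out = eps * EPS0 - 1j * sig / w
        return out if out.shape else complex(out)

    def dc_conductivity(self) -> float:
        return float(self.sigma[0])


@dataclass(frozen=True)
class ColeColeTerm:
    """One dispersion term ``delta_eps / (1 + (j*w*tau)^(1-alpha))``."""

    delta_eps: float
    tau_s: float
    alpha: float = 0.0


@dataclass
class ParametricMaterial(DispersiveMaterial):
    """Cole-Cole multi-term dispersive material.

    eps_rel*(w) = eps_inf + sum_n delta_eps_n / (1 + (j*w*tau_n)^(1-alpha_n))
                  - j*sigma_static/(w*eps0)
    """

    name: str
    eps_inf: float
    terms: tuple[ColeColeTerm, ...] = ()
    sigma_static: float = 0.0
    valid_range: tuple[float, float] = (1e-6, 1e9)

    def __post_init__(self) -> None:
        if self.sigma_static < 0:
            raise ValueError("sigma_static must be >= 0")
        if self.eps_inf < 1:
            raise ValueError("eps_inf must be >= 1")

    @property
    def bounds(self) -> tuple[float, float]:
        return self.valid_range

    def eval(self, frequency):
        f = np.asarray(frequency, dtype=float)
        self._check_range(f)
        w = 2.0 * np.pi * f
        eps_rel = np.full_like(f, self.eps_inf, dtype=complex)
        for term in self.terms:
            eps_rel = eps_rel + term.delta_eps / (
                1.0 + (1j * w * term.tau_s) ** (1.0 - term.alpha)
            )
        out = eps_rel * EPS0 - 1j * self.sigma_static / w
        return out if out.shape else complex(out)

    def dc_conductivity(self) -> float:
        return float(self.sigma_static)


@dataclass
class ScaledMaterial(DispersiveMaterial):
    """Uniform multiplicative scaling of another material's eps*(f)."""

    base: DispersiveMaterial
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("scale factor must be > 0")
        self.name = f"{self.base.name}*{self.factor:g}"

    @property
    def bounds(self) -> tuple[float, float]:
        return self.base.bounds

    def eval(self, frequency):
        return self.factor * self.base.eval(frequency)

    def dc_conductivity(self) -> float:
        return self.factor * self.base.dc_conductivity()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def evaluate_permittivity(material: DispersiveMaterial, frequency: float) -> ComplexPermittivity:
    """Evaluate ``eps*(f) = eps - j*sigma/w`` for one material at one frequency."""
    value = material.eval(float(frequency))
    return ComplexPermittivity(value=complex(value), frequency=float(frequency))


def complex_capacitance(eps: ComplexPermittivity, gf: float) -> ComplexCapacitance:
    """``C* = eps* * g`` for a geometric factor ``g > 0`` [m]."""
    if gf <= 0:
        raise ValueError("geometric factor must be > 0")
    return ComplexCapacitance(value=eps.value * gf, frequency=eps.frequency)


def capacitor_impedance(cap: ComplexCapacitance, frequency: float | None = None) -> complex:
    """Impedance ``Z = 1/(j*w*C*)`` of a complex capacitor.

    The computation is done in admittance form ``Y = j*w*C*`` so that the
    conductive part ``sigma*g`` survives as ``w -> 0``; exactly at ``f = 0``
    the admittance of any finite ``C*`` vanishes and a
    :class:`SingularImpedanceError` is raised (the DC resistive limit
    ``1/(sigma*g)`` must be taken through the material's conductivity).
    """
    f = cap.frequency if frequency is None else float(frequency)
    admittance = 1j * 2.0 * np.pi * f * cap.value
    if admittance == 0:
        raise SingularImpedanceError(
            "zero admittance: f = 0 requires a conductive (sigma > 0) path"
        )
    return 1.0 / admittance


def permittivity_from_spectrum(
    frequencies,
    impedances,
    gf: float,
    name: str = "recovered",
) -> TabulatedMaterial:
    """Invert ``Z = 1/(j*w*eps*g)`` per frequency into a tabulated material.

    Returns a :class:`TabulatedMaterial` with ``eps_rel = Re(eps*)/eps0`` and
    ``sigma = -w*Im(eps*)``.  A recovered negative conductivity anywhere sets
    ``negative_sigma_warning`` on the material and emits a warning instead of
    failing silently.
    """
    f = np.asarray(frequencies, dtype=float)
    z = np.asarray(impedances, dtype=complex)
    if gf <= 0:
        raise ValueError("geometric factor must be > 0")
    if np.any(f <= 0):
        raise ValueError("frequencies must be > 0")
    if np.any(z == 0):
        raise ValueError("impedance magnitudes must be > 0")
    w = 2.0 * np.pi * f
    eps = 1.0 / (1j * w * z * gf)
    sigma = -w * eps.imag
    flag = bool(np.any(sigma < 0))
    if flag:
        warnings.warn(
            f"recovered material '{name}' has negative conductivity at some "
            "frequencies; flagged on the material",
            stacklevel=2,
        )
    return TabulatedMaterial(
        name=name,
        frequencies=f,
        eps_rel=eps.real / EPS0,
        sigma=sigma,
        negative_sigma_warning=flag,
        strict=False,
    )


def default_frequency_grid(n: int = 201, f_min: float = 0.1, f_max: float = 1e4) -> np.ndarray:
    """Log-spaced measurement-style grid (default 201 points, 0.1 Hz-10 kHz)."""
    return np.logspace(np.log10(f_min), np.log10(f_max), n)
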