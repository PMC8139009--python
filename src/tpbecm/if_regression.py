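"""Least-squares fitting of interdimensional-factor coefficients.

The IF functional forms are linear in their coefficients once the data are
transformed, so both fits are ordinary least squares on exact designs:

* PPC: response ``I_obs``; regressors ``[1, ln(eps1-eps2), ln(h1)]``
* SPC: response ``I_obs``; regressors ``[1/h1, ln(eps2/eps1)/h1, 1]``

The observed IF of each row is recovered from the total two-layer
capacitance by inverting the composition formulas::

    PPC:  I = (C - eps2*g2) / (eps1 - eps2)
    SPC:  I = (1/eps1 - 1/eps2) / (1/C - 1/(eps2*g2))

All quantities here are in the fitting units of the simulation design:
relative (dimensionless) permittivities, thicknesses in mm, capacitances in
geometric-factor units times relative permittivity.

A surrogate generator reproduces the electrostatic simulation design used to
fit the shipped coefficients: the full factorial of ten relative-permittivity
pairs per class with top-layer thicknesses 2, 4 and 6 mm over an effectively
infinite (50 mm) bottom layer, with optional multiplicative Gaussian noise in
place of discretisation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dielectric import ElectrodeGeometry
from .partial_capacitance import IFCoefficients, ppc_if_value, spc_if_value

#: Relative-permittivity (eps1, eps2) design pairs, eps1 > eps2.
PPC_DESIGN_PAIRS: tuple[tuple[float, float], ...] = (
    (20, 10),
    (30, 10), (30, 20),
    (40, 10), (40, 20), (40, 30),
    (50, 10), (50, 20), (50, 30), (50, 40),
)
#: Relative-permittivity (eps1, eps2) design pairs, eps1 < eps2.
SPC_DESIGN_PAIRS: tuple[tuple[float, float], ...] = (
    (10, 20), (10, 30), (10, 40), (10, 50),
    (20, 30), (20, 40), (20, 50),
    (30, 40), (30, 50),
    (40, 50),
)
#: Top-layer thickness grid [mm].
H1_DESIGN_MM: tuple[float, ...] = (2.0, 4.0, 6.0)

#: Default electrode pair of the simulation design (1 cm x 1 cm, 1 cm apart).
DESIGN_GEOMETRY = ElectrodeGeometry(width_m=0.01, length_m=0.01, separation_m=0.01)


def design_g2() -> float:
    """Bottom-layer geometric factor of the simulation design [m]."""
    return DESIGN_GEOMETRY.half_space_geometric_factor()


@dataclass
class IFDataset:
    """Rows of ``(h1_mm, eps1_rel, eps2_rel, c_total)`` for one class.

    ``c_total`` is in geometric-factor units times relative permittivity
    (i.e. farads divided by eps0).
    """

    kind: str
    rows: pd.DataFrame
    g2: float

    def __post_init__(self) -> None:
        if self.kind not in ("PPC", "SPC"):
            raise ValueError("kind must be 'PPC' or 'SPC'")
        required = {"h1_mm", "eps1_rel", "eps2_rel", "c_total"}
        if not required.issubset(self.rows.columns):
            raise ValueError(f"rows must have columns {sorted(required)}")
        e1, e2 = self.rows["eps1_rel"], self.rows["eps2_rel"]
        if self.kind == "PPC" and not (e1 > e2).all():
            raise ValueError("PPC rows must satisfy eps1 > eps2")
        if self.kind == "SPC" and not (e1 < e2).all():
            raise ValueError("SPC rows must satisfy eps1 < eps2")
        if not (self.rows["h1_mm"] > 0).all():
            raise ValueError("h1_mm must be > 0")

    def to_csv(self, path) -> None:
        df = self.rows.copy()
        df.insert(0, "kind", self.kind)
        df["g2"] = self.g2
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "IFDataset":
        df = pd.read_csv(path)
        kind = str(df["kind"].iloc[0])
        g2 = float(df["g2"].iloc[0]) if "g2" in df.columns else design_g2()
        return cls(kind=kind,
                   rows=df[["h1_mm", "eps1_rel", "eps2_rel", "c_total"]].copy(),
                   g2=g2)


@dataclass
class FitResult:
    """OLS fit of one IF coefficient triple."""

    coefficients: IFCoefficients
    rss: float
    std_errors: tuple[float, float, float]
    n_rows: int

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "rss": self.rss,
            "std_errors": list(self.std_errors),
            "n_rows": self.n_rows,
        }


# ---------------------------------------------------------------------------
# forward model and transform
# ---------------------------------------------------------------------------


def _forward_capacitance(kind, h1_mm, e1, e2, g2, coeffs) -> np.ndarray:
    """Noise-free two-layer total capacitance in relative/GF units."""
    if kind == "PPC":
        i_val = ppc_if_value(e1 - e2, h1_mm, coeffs)
        return (e1 - e2) * i_val + e2 * g2
    i_val = spc_if_value(e2 / e1, h1_mm, coeffs)
    return 1.0 / ((1.0 / e1 - 1.0 / e2) / i_val + 1.0 / (e2 * g2))


def gf1_from_capacitance(h1_mm, eps1_rel, eps2_rel, c_total, g2: float, kind: str):
    """Invert a two-layer capacitance into the observed top-layer IF.

    Vectorised; ``h1_mm`` is accepted for interface symmetry with the
    forward model but does not enter the inversion.  Rows with a vanishing
    permittivity contrast make the inversion singular and raise.
    """
    e1 = np.asarray(eps1_rel, dtype=float)
    e2 = np.asarray(eps2_rel, dtype=float)
    c = np.asarray(c_total, dtype=float)
    if np.any(e1 == e2):
        raise ZeroDivisionError("eps1 == eps2: IF is undefined for a homogeneous row")
    if kind == "PPC":
        return (c - e2 * g2) / (e1 - e2)
    if kind == "SPC":
        denom = 1.0 / c - 1.0 / (e2 * g2)
        if np.any(denom == 0):
            raise ZeroDivisionError("c_total equals the bottom-layer capacitance")
        return (1.0 / e1 - 1.0 / e2) / denom
    raise ValueError("kind must be 'PPC' or 'SPC'")


def transform_dataset(dataset: IFDataset) -> pd.DataFrame:
    """Append the observed-IF response column, dropping singular rows.

    Rows whose inversion is singular (homogeneous permittivities or a
    capacitance equal to the bottom-layer term) are rejected and reported
    in the returned frame's ``rejected`` attribute.
    """
    rows = dataset.rows
    keep = rows["eps1_rel"] != rows["eps2_rel"]
    rejected = rows.index[~keep].tolist()
    rows = rows[keep]
    i_obs = gf1_from_capacitance(
        rows["h1_mm"], rows["eps1_rel"], rows["eps2_rel"], rows["c_total"],
        dataset.g2, dataset.kind,
    )
    out = rows.assign(if_obs=i_obs)
    out.attrs["rejected"] = rejected
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _design_matrix(kind: str, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    h1 = df["h1_mm"].to_numpy(dtype=float)
    e1 = df["eps1_rel"].to_numpy(dtype=float)
    e2 = df["eps2_rel"].to_numpy(dtype=float)
    if kind == "PPC":
        cols = ["1", "ln(eps1-eps2)", "ln(h1)"]
        x = np.column_stack([np.ones_like(h1), np.log(e1 - e2), np.log(h1)])
    else:
        cols = ["1/h1", "ln(eps2/eps1)/h1", "1"]
        x = np.column_stack([1.0 / h1, np.log(e2 / e1) / h1, np.ones_like(h1)])
    return x, cols


def fit_if(dataset: IFDataset) -> FitResult:
    """Ordinary least squares on the exact linear parameterisation of the IF."""
    df = transform_dataset(dataset)
    if len(df) < 3:
        raise ValueError("need at least 3 usable rows to fit 3 coefficients")
    if df["h1_mm"].nunique() < 2:
        raise ValueError("need at least 2 distinct thickness values")
    x, cols = _design_matrix(dataset.kind, df)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(f"rank-deficient design; collinear regressors among {cols}")
    res = sm.OLS(df["if_obs"].to_numpy(dtype=float), x).fit()
    coeffs = IFCoefficients(kind=dataset.kind, values=tuple(res.params),
                            provenance=f"fit:n={len(df)}")
    bse = tuple(float(b) for b in res.bse)
    return FitResult(coefficients=coeffs, rss=float(res.ssr),
                     std_errors=bse, n_rows=int(len(df)))


# ---------------------------------------------------------------------------
# surrogate data generation
# ---------------------------------------------------------------------------


def generate_fem_surrogate(
    kind: str,
    coeffs: IFCoefficients | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    g2: float | None = None,
    noise_on: str = "capacitance",
) -> IFDataset:
    """Model-based surrogate for the electrostatic simulation dataset.

    Produces the full factorial of the ten design permittivity pairs of
    ``kind`` with ``h1`` in {2, 4, 6} mm (30 rows), responses from the
    forward composition model, optionally perturbed by multiplicative
    Gaussian noise of standard deviation ``noise_sd`` (seeded, reproducible).

    ``noise_on`` selects where the noise enters: ``'capacitance'`` perturbs
    the raw total capacitance (solver-output error), ``'gf'`` perturbs the
    layer-1 geometric factor before composing, i.e. the quantity the
    regression actually sees.  The distinction matters for SPC, where the
    capacitance-to-GF transform subtracts two nearly equal reciprocals and
    amplifies capacitance noise by several orders of magnitude.
    """
    if kind not in ("PPC", "SPC"):
        raise ValueError("kind must be 'PPC' or 'SPC'")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_on not in ("capacitance", "gf"):
        raise ValueError("noise_on must be 'capacitance' or 'gf'")
    coeffs = coeffs or IFCoefficients.default(kind)
    if coeffs.kind != kind:
        raise ValueError("coefficient kind does not match dataset kind")
    g2 = design_g2() if g2 is None else float(g2)
    pairs = PPC_DESIGN_PAIRS if kind == "PPC" else SPC_DESIGN_PAIRS

    h1 = np.repeat(H1_DESIGN_MM, len(pairs))
    e1 = np.tile([p[0] for p in pairs], len(H1_DESIGN_MM)).astype(float)
    e2 = np.tile([p[1] for p in pairs], len(H1_DESIGN_MM)).astype(float)
    rng = np.random.default_rng(seed)
    if noise_sd > 0 and noise_on == "gf":
        if kind == "PPC":
            i_val = ppc_if_value(e1 - e2, h1, coeffs)
            i_val = i_val * (1.0 + noise_sd * rng.standard_normal(i_val.shape))
            c = (e1 - e2) * i_val + e2 * g2
        else:
            i_val = spc_if_value(e2 / e1, h1, coeffs)
            i_val = i_val * (1.0 + noise_sd * rng.standard_normal(i_val.shape))
            c = 1.0 / ((1.0 / e1 - 1.0 / e2) / i_val + 1.0 / (e2 * g2))
    else:
        c = _forward_capacitance(kind, h1, e1, e2, g2, coeffs)
        if noise_sd > 0:
            c = c * (1.0 + noise_sd * rng.standard_normal(c.shape))
    rows = pd.DataFrame({"h1_mm": h1, "eps1_rel": e1, "eps2_rel": e2, "c_total": c})
    return IFDataset(kind=kind, rows=rows, g2=g2)
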