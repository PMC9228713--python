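"""Ellipsometric thickness to protein surface mass density.

A dried protein layer of fitted optical thickness ``d`` (nm) is converted
to adsorbed mass per area Γ (mg/m²) by the Cuypers one-component
approach, built on the Lorentz–Lorenz relation

    L(n) = (n² − 1) / (n² + 2)

with a fixed protein refractive index.  For a layer of refractive index
``n_p`` in an ambient of index ``n_a``,

    Γ = d · (L(n_p) − L(n_a)) / (r − v̄·L(n_a))

where ``r`` is the specific refractivity of protein (cm³/g) and ``v̄`` its
partial specific volume (cm³/g).  With d in nm and the bracket in g/cm³
the identity 1 nm·g/cm³ = 1 mg/m² gives Γ directly in mg/m².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CuypersParams",
    "lorentz_lorenz",
    "thickness_to_gamma",
    "gamma_to_thickness",
    "read_thickness_csv",
]


def lorentz_lorenz(n: float) -> float:
    """L(n) = (n² − 1)/(n² + 2), the molar-refraction kernel."""
    return (n * n - 1.0) / (n * n + 2.0)


@dataclass(frozen=True)
class CuypersParams:
    """Optical constants of the one-component conversion.

    Defaults: protein index 1.53, dry layer measured in air (ambient
    index 1.00), specific refractivity 0.254 cm³/g and partial specific
    volume 0.73 cm³/g — the standard literature values for globular
    proteins.  All four are explicit so a user can match any published
    variant of the conversion exactly.
    """

    n_protein: float = 1.53
    n_ambient: float = 1.00
    specific_refractivity: float = 0.254  # cm^3/g
    partial_specific_volume: float = 0.73  # cm^3/g

    def __post_init__(self) -> None:
        if not self.n_protein > self.n_ambient >= 1.0:
            raise ValueError(
                f"need n_protein > n_ambient >= 1, got "
                f"{self.n_protein}, {self.n_ambient}"
            )
        if self.specific_refractivity <= 0 or self.partial_specific_volume <= 0:
            raise ValueError("refractivity and specific volume must be positive")
        if self.denominator <= 0:
            raise ValueError("r - v*L(n_ambient) must be positive")

    @property
    def denominator(self) -> float:
        return self.specific_refractivity - self.partial_specific_volume * lorentz_lorenz(
            self.n_ambient
        )

    @property
    def conversion_factor(self) -> float:
        """C in g/cm³: Γ[mg/m²] = d[nm] · C."""
        return (
            lorentz_lorenz(self.n_protein) - lorentz_lorenz(self.n_ambient)
        ) / self.denominator


def thickness_to_gamma(d_nm, params: CuypersParams = CuypersParams()):
    """Surface mass density Γ (mg/m²) of a layer of thickness ``d_nm``."""
    d = np.asarray(d_nm, dtype=float)
    if np.any(d < 0):
        raise ValueError("thickness must be non-negative")
    out = d * params.conversion_factor
    return float(out) if np.isscalar(d_nm) else out


def gamma_to_thickness(gamma, params: CuypersParams = CuypersParams()):
    """Exact inverse of :func:`thickness_to_gamma` (nm from mg/m²)."""
    g = np.asarray(gamma, dtype=float)
    if np.any(g < 0):
        raise ValueError("surface density must be non-negative")
    out = g / params.conversion_factor
    return float(out) if np.isscalar(gamma) else out


def read_thickness_csv(path) -> pd.DataFrame:
    """Read per-sample thicknesses: columns sample_id, d_nm[, replicate]."""
    df = pd.read_csv(path)
    for col in ("sample_id", "d_nm"):
        if col not in df.columns:
            raise ValueError(f"thickness table missing column {col!r}")
    df["d_nm"] = pd.to_numeric(df["d_nm"])
    if (df["d_nm"] < 0).any():
        bad = df.loc[df["d_nm"] < 0, "sample_id"].iloc[0]
        raise ValueError(f"negative thickness for sample_id {bad!r}")
    return df
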