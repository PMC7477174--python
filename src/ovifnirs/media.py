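"""Optical properties of tissue and layered head geometry.

Internal units throughout the package: lengths in mm, absorption and reduced
scattering coefficients in mm^-1, times in ns. The speed of light in vacuum
is ``C_LIGHT`` mm/ns; the phase velocity in tissue is ``C_LIGHT / n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import quad

C_LIGHT = 299.792458  # mm / ns

__all__ = [
    "C_LIGHT",
    "OpticalProperties",
    "LayeredMedium",
    "ProbeConfig",
    "SpectroscopyResult",
    "boundary_coefficient",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering of a homogeneous tissue.

    Parameters
    ----------
    mua : float
        Absorption coefficient, mm^-1.  Must be > 0.
    musp : float
        Reduced scattering coefficient mu_s' = mu_s (1 - g), mm^-1. Must be > 0.
    wavelength : float, optional
        Wavelength the coefficients refer to, nm.
    """

    mua: float
    musp: float
    wavelength: float | None = None

    def __post_init__(self) -> None:
        if not (self.mua > 0):
            raise ValueError(f"mua must be > 0, got {self.mua}")
        if not (self.musp > 0):
            raise ValueError(f"musp must be > 0, got {self.musp}")

    def perturbed(self, dmua: float) -> "OpticalProperties":
        """Return a copy with absorption changed by ``dmua`` (scattering fixed)."""
        mua = self.mua + dmua
        if mua <= 0:
            raise ValueError(
                f"perturbation dmua={dmua} drives mua={self.mua} non-positive"
            )
        return OpticalProperties(mua, self.musp, self.wavelength)


def _as_props_map(value, name: str) -> dict[float | None, OpticalProperties]:
    if isinstance(value, OpticalProperties):
        return {value.wavelength: value}
    if isinstance(value, Mapping):
        out = {}
        for wl, props in value.items():
            if not isinstance(props, OpticalProperties):
                raise TypeError(f"{name}[{wl}] is not OpticalProperties")
            out[float(wl)] = props
        return out
    raise TypeError(f"{name} must be OpticalProperties or a wavelength mapping")


@dataclass(frozen=True)
class LayeredMedium:
    """Two-layer head model: a slab of extra-cerebral tissue of thickness
    ``s`` (scalp, skull, CSF) over a semi-infinite cerebral layer.

    ``upper`` and ``lower`` may be a single :class:`OpticalProperties` or a
    mapping ``{wavelength: OpticalProperties}``.  When upper == lower the
    medium is homogeneous.
    """

    s: float
    upper: OpticalProperties | Mapping[float, OpticalProperties]
    lower: OpticalProperties | Mapping[float, OpticalProperties]
    n_tissue: float = 1.4
    n_external: float = 1.0

    def __post_init__(self) -> None:
        if not (self.s > 0):
            raise ValueError(f"upper-layer thickness s must be > 0, got {self.s}")
        if self.n_tissue <= 0 or self.n_external <= 0:
            raise ValueError("refractive indices must be > 0")
        _as_props_map(self.upper, "upper")
        _as_props_map(self.lower, "lower")

    def props(self, wavelength: float | None = None) -> tuple[OpticalProperties, OpticalProperties]:
        """(upper, lower) properties at ``wavelength`` (or the single entry)."""
        up = _as_props_map(self.upper, "upper")
        lo = _as_props_map(self.lower, "lower")
        if wavelength is None:
            if len(up) != 1 or len(lo) != 1:
                raise ValueError("wavelength required for multi-wavelength medium")
            return next(iter(up.values())), next(iter(lo.values()))
        wl = float(wavelength)

        def pick(d, name):
            if wl in d:
                return d[wl]
            if len(d) == 1 and next(iter(d)) is None:
                return next(iter(d.values()))
            raise KeyError(f"no {name} properties for wavelength {wl} nm")

        return pick(up, "upper"), pick(lo, "lower")

    def wavelengths(self) -> list[float]:
        up = _as_props_map(self.upper, "upper")
        return [wl for wl in up if wl is not None]

    def perturbed(self, dmua_up: float, dmua_down: float,
                  wavelength: float | None = None) -> "LayeredMedium":
        up, lo = self.props(wavelength)
        return LayeredMedium(self.s, up.perturbed(dmua_up), lo.perturbed(dmua_down),
                             self.n_tissue, self.n_external)


@dataclass(frozen=True)
class ProbeConfig:
    """Source-detector geometry and acquisition settings of the probe."""

    rho_short: float = 10.0
    rho_long: float = 30.0
    wavelengths: Sequence[float] = (751.0, 839.0)
    sampling_rate: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.rho_short < self.rho_long):
            raise ValueError("require 0 < rho_short < rho_long")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))


@dataclass(frozen=True)
class SpectroscopyResult:
    """Baseline optical properties and DPF per wavelength (and distance)."""

    mua0: Mapping[float, float]
    musp0: Mapping[float, float]
    dpf: Mapping[tuple[float, float], float] = field(default_factory=dict)


def _fresnel_unpolarized(cos_i: np.ndarray, n_rel: float) -> np.ndarray:
    """Unpolarized Fresnel reflectance for light going from tissue (index
    n_rel relative to outside) into the outside medium; 1 beyond the
    critical angle."""
    cos_i = np.asarray(cos_i, dtype=float)
    sin_i2 = 1.0 - cos_i**2
    sin_t2 = n_rel**2 * sin_i2  # Snell: n_in sin_i = n_out sin_t, n_rel = n_in/n_out
    r = np.ones_like(cos_i)
    ok = sin_t2 < 1.0
    cos_t = np.sqrt(np.clip(1.0 - sin_t2[ok], 0.0, None))
    ci = cos_i[ok]
    # amplitude coefficients with n_in = n_rel, n_out = 1 (only the ratio matters)
    rs = (n_rel * ci - cos_t) / (n_rel * ci + cos_t)
    rp = (n_rel * cos_t - ci) / (n_rel * cos_t + ci)
    r[ok] = 0.5 * (rs**2 + rp**2)
    return r


@lru_cache(maxsize=64)
def boundary_coefficient(n_tissue: float, n_external: float = 1.0) -> float:
    """Extrapolated-boundary coefficient A for a refractive-index mismatch.

    Computed from the Fresnel-reflection moments (fluence and flux weighted,
    the Haskell/Contini convention): R_eff = (R_phi + R_j) / (2 - R_phi + R_j)
    and A = (1 + R_eff) / (1 - R_eff).  A == 1 for matched indices; the
    extrapolation length is z_b = 2 A D.
    """
    n_rel = n_tissue / n_external
    if abs(n_rel - 1.0) < 1e-12:
        return 1.0

    def integrand_phi(theta):
        c = np.cos(theta)
        return 2.0 * np.sin(theta) * c * _fresnel_unpolarized(np.array([c]), n_rel)[0]

    def integrand_j(theta):
        c = np.cos(theta)
        return 3.0 * np.sin(theta) * c * c * _fresnel_unpolarized(np.array([c]), n_rel)[0]

    r_phi, _ = quad(integrand_phi, 0.0, np.pi / 2, limit=200)
    r_j, _ = quad(integrand_j, 0.0, np.pi / 2, limit=200)
    r_eff = (r_phi + r_j) / (2.0 - r_phi + r_j)
    return (1.0 + r_eff) / (1.0 - r_eff)
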