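"""Photon-diffusion forward models for CW and time-resolved reflectance.

The observable throughout is the flux (Fick) form of the diffuse reflectance,
R = D dPhi/dz at the surface, under the extrapolated-boundary condition:

* homogeneous semi-infinite medium — closed-form dipole (source + image)
  expression, CW and time-resolved;
* two-layer medium (slab of thickness s over a semi-infinite layer) — the
  1-D diffusion boundary-value problem is solved per spatial frequency q and
  the inverse Hankel transform evaluated by Gauss-Legendre quadrature with a
  node-doubling convergence check.

These forward models drive both the synthetic-data generator and the
two-step absorption inversion; the Monte Carlo module provides the
independent check of the physics.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.optimize import least_squares
from scipy.special import j0

from .media import C_LIGHT, LayeredMedium, OpticalProperties, boundary_coefficient

__all__ = [
    "cw_reflectance_homog",
    "cw_reflectance_two_layer",
    "delta_od_forward",
    "tr_reflectance_homog",
    "dpf",
    "fit_dtof",
]

# Isotropic-source depth convention: z0 = 1 / musp (transport mean free path).
# The alternative 1/(mua + musp) differs negligibly for musp >> mua.


def _dipole_geometry(props: OpticalProperties, n_tissue: float, n_external: float):
    # Absorption-independent diffusion coefficient D = 1/(3 musp)
    # (Furutsu-Yamada convention).  This makes the time-resolved solution
    # factorize exactly as R(t) = f(t; musp) exp(-mua v t), so the CW/TR
    # moment identities (DPF, mean time of flight vs CW log-derivative)
    # hold to quadrature precision rather than to O(mua/mutr).
    d = 1.0 / (3.0 * props.musp)
    z0 = 1.0 / props.musp
    a = boundary_coefficient(n_tissue, n_external)
    zb = 2.0 * a * d
    return d, z0, zb


def cw_reflectance_homog(rho, props: OpticalProperties,
                         n_tissue: float = 1.4, n_external: float = 1.0):
    """Steady-state diffuse reflectance of a semi-infinite medium, mm^-2.

    Dipole (extrapolated-boundary) solution: an isotropic source at depth
    z0 = 1/musp and its negative image at -(z0 + 2 zb), with
    zb = 2 A D and mueff = sqrt(mua / D).  Vectorized over ``rho``.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("rho must be > 0")
    d, z0, zb = _dipole_geometry(props, n_tissue, n_external)
    mueff = np.sqrt(props.mua / d)
    r1 = np.sqrt(rho**2 + z0**2)
    r2 = np.sqrt(rho**2 + (z0 + 2.0 * zb) ** 2)
    refl = (z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
            + (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
            ) / (4.0 * np.pi)
    return refl if refl.ndim else float(refl)


@lru_cache(maxsize=64)
def _gauss_legendre(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Composite Gauss-Legendre rule on [-1, 1]: 32-point panels tiled to
    ``n`` total nodes.  Panel tiling keeps node generation O(n) and handles
    the oscillatory Bessel kernel as well as a single high-order rule."""
    order = min(n, 32)
    panels = max(n // order, 1)
    x0, w0 = np.polynomial.legendre.leggauss(order)
    edges = np.linspace(-1.0, 1.0, panels + 1)
    half = 0.5 * (edges[1:] - edges[:-1])
    mid = 0.5 * (edges[1:] + edges[:-1])
    x = (mid[:, None] + half[:, None] * x0).ravel()
    w = (half[:, None] * w0).ravel()
    return x, w


def _two_layer_flux_q(q, mua1, musp1, mua2, musp2, s, n_tissue, n_external):
    """Hankel-space surface flux j(q) of the two-layer medium.

    Solves the two-point boundary problem: extrapolated boundary at
    z = -zb, isotropic source at z0 (inside the slab), continuity of fluence
    and normal flux at z = s, decay at infinity.  Broadcasts over ``q`` and
    the absorption arrays.
    """
    d1 = 1.0 / (3.0 * musp1)
    d2 = 1.0 / (3.0 * musp2)
    z0 = 1.0 / musp1
    a = boundary_coefficient(n_tissue, n_external)
    zb = 2.0 * a * d1
    alpha1 = np.sqrt(q**2 + mua1 / d1)
    alpha2 = np.sqrt(q**2 + mua2 / d2)
    beta = (d2 * alpha2) / (d1 * alpha1)
    # j(q) = cosh(a1 zb) [cosh(a1 (s-z0)) + beta sinh(a1 (s-z0))]
    #        / [cosh(a1 (s+zb)) + beta sinh(a1 (s+zb))]
    # evaluated with exponentials factored to avoid overflow at large q.
    e1 = np.exp(-2.0 * alpha1 * zb)
    e2 = np.exp(-2.0 * alpha1 * (s - z0))
    e3 = np.exp(-2.0 * alpha1 * (s + zb))
    num = 0.25 * (1.0 + e1) * ((1.0 + e2) + beta * (1.0 - e2))
    den = 0.5 * ((1.0 + e3) + beta * (1.0 - e3))
    return np.exp(-alpha1 * z0) * num / den


def _two_layer_reflectance_core(rho, mua1, musp1, mua2, musp2, s,
                                n_tissue, n_external, n_nodes,
                                absolute=False):
    """Inverse Hankel transform R(rho) = (1/2pi) int j(q) J0(q rho) q dq
    on q in [0, q_max], q_max = 10 musp1, with fixed Gauss-Legendre nodes.

    ``mua1``/``mua2`` may be arrays (broadcast against each other); the
    quadrature axis is appended internally.
    """
    # the Hankel-space flux decays like exp(-q z0) with z0 = 1/musp1;
    # q_max = 30/z0 keeps the truncated tail below ~1e-9 of the integral
    # even at rho = 30 mm where oscillatory cancellation is strongest
    q_max = 30.0 * float(np.max(musp1))
    x, w = _gauss_legendre(n_nodes)
    q = 0.5 * q_max * (x + 1.0)
    wq = 0.5 * q_max * w
    mua1 = np.asarray(mua1, dtype=float)
    mua2 = np.asarray(mua2, dtype=float)
    shape = np.broadcast_shapes(mua1.shape, mua2.shape)
    m1 = np.broadcast_to(mua1, shape)[..., None]
    m2 = np.broadcast_to(mua2, shape)[..., None]
    jq = _two_layer_flux_q(q, m1, musp1, m2, musp2, s, n_tissue, n_external)
    kernel = j0(q * rho) * q * wq
    if absolute:  # magnitude of the integrand, for roundoff-floor estimates
        return np.abs(jq * kernel).sum(axis=-1) / (2.0 * np.pi)
    return (jq * kernel).sum(axis=-1) / (2.0 * np.pi)


def cw_reflectance_two_layer(rho: float, medium: LayeredMedium,
                             wavelength: float | None = None,
                             rtol: float = 1e-6, n_nodes_start: int = 256,
                             n_nodes_max: int = 8192):
    """CW diffuse reflectance of a two-layer medium at distance ``rho``, mm^-2.

    The Gauss-Legendre node count is doubled until the result changes by
    less than ``rtol`` (relative); non-convergence raises with diagnostics.
    """
    if rho <= 0:
        raise ValueError("rho must be > 0")
    up, lo = medium.props(wavelength)
    # roundoff floor: the oscillatory Bessel kernel cancels ~|integrand|
    # down to the result, so values below ~1e-13 of the integrand scale
    # cannot converge in relative terms in double precision
    scale = float(_two_layer_reflectance_core(
        rho, up.mua, up.musp, lo.mua, lo.musp, medium.s,
        medium.n_tissue, medium.n_external, n_nodes_start, absolute=True))
    atol = 1e-13 * scale
    n = n_nodes_start
    prev = None
    while n <= n_nodes_max:
        val = float(_two_layer_reflectance_core(
            rho, up.mua, up.musp, lo.mua, lo.musp, medium.s,
            medium.n_tissue, medium.n_external, n))
        if prev is not None and abs(val - prev) <= rtol * abs(prev) + atol:
            return val
        prev = val
        n *= 2
    raise RuntimeError(
        f"two-layer Hankel quadrature did not converge to rtol={rtol} "
        f"within {n_nodes_max} nodes (last value {prev}, rho={rho}, "
        f"roundoff floor {atol:.2e})")


def delta_od_forward(rho: float, model: str, baseline: LayeredMedium,
                     dmua_up, dmua_down=0.0,
                     wavelength: float | None = None,
                     n_nodes: int = 1024):
    """Forward-predicted decadic optical-density change for an absorption
    perturbation of the baseline medium (scattering fixed).

    ``model`` is ``"homogeneous"`` (the perturbation ``dmua_up`` applies to a
    semi-infinite medium with the upper layer's properties; ``dmua_down`` is
    ignored and must be 0) or ``"two_layer"``.  Returns
    DeltaOD = log10[R(baseline) / R(perturbed)]; positive for an absorption
    increase.  Vectorized over the ``dmua`` arrays.
    """
    if rho <= 0:
        raise ValueError("rho must be > 0")
    up, lo = baseline.props(wavelength)
    dmua_up = np.asarray(dmua_up, dtype=float)
    dmua_down = np.asarray(dmua_down, dtype=float)
    if model == "homogeneous":
        if np.any(dmua_down != 0.0):
            raise ValueError("homogeneous model takes a single perturbation dmua_up")
        if np.any(up.mua + dmua_up <= 0):
            raise ValueError("perturbation drives mua non-positive")
        r0 = cw_reflectance_homog(rho, up, baseline.n_tissue, baseline.n_external)
        pert = np.vectorize(
            lambda dm: cw_reflectance_homog(
                rho, OpticalProperties(up.mua + dm, up.musp, up.wavelength),
                baseline.n_tissue, baseline.n_external))(dmua_up)
        out = np.log10(r0 / pert)
    elif model == "two_layer":
        if np.any(up.mua + dmua_up <= 0) or np.any(lo.mua + dmua_down <= 0):
            raise ValueError("perturbation drives mua non-positive")
        r0 = _two_layer_reflectance_core(
            rho, up.mua, up.musp, lo.mua, lo.musp, baseline.s,
            baseline.n_tissue, baseline.n_external, n_nodes)
        pert = _two_layer_reflectance_core(
            rho, up.mua + dmua_up, up.musp, lo.mua + dmua_down, lo.musp,
            baseline.s, baseline.n_tissue, baseline.n_external, n_nodes)
        out = np.log10(r0 / pert)
    else:
        raise ValueError(f"unknown model {model!r}")
    return out if np.ndim(out) else float(out)


def tr_reflectance_homog(rho: float, t, props: OpticalProperties,
                         n_tissue: float = 1.4, n_external: float = 1.0):
    """Time-resolved diffuse reflectance of a semi-infinite medium,
    mm^-2 ns^-1, dipole extrapolated-boundary solution.  ``t`` in ns,
    vectorized.  Its time integral equals :func:`cw_reflectance_homog`.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    if rho <= 0:
        raise ValueError("rho must be > 0")
    d, z0, zb = _dipole_geometry(props, n_tissue, n_external)
    v = C_LIGHT / n_tissue
    dt4 = 4.0 * d * v * t
    z1 = z0
    z2 = z0 + 2.0 * zb
    refl = ((4.0 * np.pi * d * v * t) ** -1.5 / (2.0 * t)
            * np.exp(-props.mua * v * t - rho**2 / dt4)
            * (z1 * np.exp(-z1**2 / dt4) + z2 * np.exp(-z2**2 / dt4)))
    return refl if refl.ndim else float(refl)


def _tr_moments(rho: float, props: OpticalProperties, n_tissue: float,
                n_external: float) -> tuple[float, float]:
    """(integral R dt, mean time of flight) by adaptive quadrature."""
    v = C_LIGHT / n_tissue
    # rough mean time of flight from the MBLL scale sets the breakpoints
    d = 1.0 / (3.0 * props.musp)
    mueff = np.sqrt(props.mua / d)
    t_scale = max(mueff * rho, 1.0) / (2.0 * props.mua * v)
    upper = 50.0 * t_scale
    pts = [t_scale / 30.0, t_scale / 3.0, t_scale, 5.0 * t_scale]

    def f0(t):
        return tr_reflectance_homog(rho, t, props, n_tissue, n_external)

    def f1(t):
        return t * tr_reflectance_homog(rho, t, props, n_tissue, n_external)

    area, _ = quad(f0, 0.0, upper, limit=2000, points=pts, epsabs=0.0, epsrel=1e-10)
    first, _ = quad(f1, 0.0, upper, limit=2000, points=pts, epsabs=0.0, epsrel=1e-10)
    return area, first / area


def dpf(rho: float, props: OpticalProperties, n_tissue: float = 1.4,
        n_external: float = 1.0) -> float:
    """Differential pathlength factor DPF = v <t> / rho.

    <t> is the first moment of the time-resolved reflectance; DPF > 1 in any
    diffusive medium, and converts DeltaOD into absorption change through the
    modified Beer-Lambert law DeltaOD = DPF * rho * Dmua / ln(10).
    """
    v = C_LIGHT / n_tissue
    _, t_mean = _tr_moments(rho, props, n_tissue, n_external)
    return v * t_mean / rho


def fit_dtof(dtof: np.ndarray, t: np.ndarray, rho: float,
             n_tissue: float = 1.4, n_external: float = 1.0,
             musp_init: float = 1.0, mua_init: float = 0.01,
             fit_window: tuple[float, float] = (0.8, 0.01)) -> OpticalProperties:
    """Fit (mua, musp) to a photon distribution of times of flight.

    ``dtof`` is a background-subtracted histogram of photon counts on the
    time grid ``t`` (ns).  Model and data are peak-normalized and compared
    over a window from the rising edge at ``fit_window[0]`` of the peak to
    the tail at ``fit_window[1]`` of the peak (the tail slope carries mua,
    the rising edge musp).  Least-squares via Levenberg-Marquardt on the
    log-parameters to keep the coefficients positive.
    """
    dtof = np.asarray(dtof, dtype=float)
    t = np.asarray(t, dtype=float)
    if dtof.shape != t.shape:
        raise ValueError("dtof and t must have the same shape")
    if np.count_nonzero(dtof > 0) < 50:
        raise ValueError("degenerate DTOF: need >= 50 bins with counts")
    peak = dtof.max()
    i_peak = int(np.argmax(dtof))
    rising = np.nonzero(dtof[: i_peak + 1] >= fit_window[0] * peak)[0]
    i_lo = int(rising[0]) if rising.size else 0
    tail = np.nonzero(dtof[i_peak:] <= fit_window[1] * peak)[0]
    i_hi = i_peak + int(tail[0]) if tail.size else dtof.size
    sel = slice(i_lo, i_hi)
    data = dtof[sel] / peak
    t_sel = t[sel]

    def model_curve(log_params):
        mua, musp = np.exp(log_params)
        props = OpticalProperties(mua, musp)
        curve = tr_reflectance_homog(rho, t_sel, props, n_tissue, n_external)
        return curve / curve.max()

    res = least_squares(
        lambda p: model_curve(p) - data,
        x0=np.log([mua_init, musp_init]),
        method="lm", xtol=1e-12, ftol=1e-12)
    mua, musp = np.exp(res.x)
    return OpticalProperties(float(mua), float(musp))
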