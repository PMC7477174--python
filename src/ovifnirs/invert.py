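"""Two-step model-based inversion of DeltaOD into layered hemoglobin.

Step 1 (short channel): photons at rho = 10 mm are assumed to sample only
the extra-cerebral tissue, so DeltaOD_SHORT is fitted per time sample and
wavelength to the homogeneous semi-infinite forward model, yielding the
upper-layer absorption change Dmua_UP (scattering held at its baseline).

Step 2 (long channel): DeltaOD_LONG is fitted to the two-layer forward model
with the upper layer fixed at mua0 + Dmua_UP from step 1 and the slab
thickness s known a priori, yielding the cerebral absorption change
Dmua_DOWN.

Both fits are scalar nonlinear least squares solved by Levenberg-Marquardt,
batched over time samples (each sample is an independent one-parameter
problem, so the damped normal equation is scalar per sample).  Finally the
absolute coefficients mua0 + Dmua at the two wavelengths are converted to
oxy-/deoxy-hemoglobin by Beer's law with the sheep extinction coefficients,
and re-referenced to the block baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .diffusion import _two_layer_reflectance_core, cw_reflectance_homog
from .media import LayeredMedium, OpticalProperties, ProbeConfig
from .preprocess import Channel, DeltaODSeries

__all__ = [
    "SHEEP_EXTINCTION",
    "ExtinctionMatrix",
    "AbsorptionSeries",
    "HemoglobinSeries",
    "invert_upper",
    "invert_lower",
    "mua_to_hemoglobin",
    "hemoglobin_to_mua",
    "run_block_inversion",
]

# Sheep-blood extinction coefficients, cm^-1 mM^-1.
# rows: wavelength nm -> (eps_O2Hb, eps_HHb)
SHEEP_EXTINCTION: Mapping[float, tuple[float, float]] = {
    751.0: (0.752, 1.672),
    839.0: (1.084, 0.824),
}

MUA_FLOOR = 1e-6  # mm^-1; fits driving mua below this are clamped and flagged


@dataclass(frozen=True)
class ExtinctionMatrix:
    """2x2 extinction matrix, cm^-1 mM^-1; rows = wavelengths, columns =
    (O2Hb, HHb).  ``decadic=True`` divides nothing out: the coefficients are
    applied as mua = eps * c directly (the convention the printed sheep
    values are used in); set ``ln10_scale=True`` to interpret them as
    decadic molar extinction requiring the ln(10) factor.
    """

    wavelengths: tuple[float, float] = (751.0, 839.0)
    coefficients: tuple[tuple[float, float], tuple[float, float]] | None = None
    ln10_scale: bool = False

    def __post_init__(self) -> None:
        if self.coefficients is None:
            coeff = tuple(SHEEP_EXTINCTION[wl] for wl in self.wavelengths)
            object.__setattr__(self, "coefficients", coeff)
        m = np.asarray(self.coefficients, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("extinction matrix must be 2x2")
        if np.any(m <= 0):
            raise ValueError("extinction coefficients must be > 0")
        # independent 2x2 cofactor determinant before trusting any solve
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        if abs(det) < 1e-12:
            raise ValueError("extinction matrix is singular")

    @property
    def matrix(self) -> np.ndarray:
        m = np.asarray(self.coefficients, dtype=float)
        return m * np.log(10.0) if self.ln10_scale else m


def mua_to_hemoglobin(mua: Mapping[float, np.ndarray] | Sequence[float],
                      eps: ExtinctionMatrix = ExtinctionMatrix(),
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Solve Beer's law for concentrations: mua(lambda) = eps @ (c_O2Hb, c_HHb).

    ``mua`` in mm^-1 per wavelength (scalars or time series); returns
    concentrations in uM.  Exact 2x2 linear solve; round-trips with
    :func:`hemoglobin_to_mua` to machine precision.
    """
    if isinstance(mua, Mapping):
        try:
            vals = [np.asarray(mua[wl], dtype=float) for wl in eps.wavelengths]
        except KeyError as e:
            raise ValueError(f"mua missing wavelength {e}") from None
    else:
        vals = [np.asarray(v, dtype=float) for v in mua]
    if len(vals) != 2:
        raise ValueError("Beer's-law step requires exactly 2 wavelengths")
    m = eps.matrix  # cm^-1 mM^-1
    # mua [mm^-1] -> cm^-1 is *10; c in mM -> uM is *1000
    b = np.stack(np.broadcast_arrays(*vals)) * 10.0
    c = np.linalg.solve(m, b.reshape(2, -1)).reshape(b.shape) * 1000.0
    return c[0], c[1]


def hemoglobin_to_mua(o2hb, hhb, eps: ExtinctionMatrix = ExtinctionMatrix(),
                      ) -> dict[float, np.ndarray]:
    """Forward Beer's law: concentrations in uM -> mua per wavelength, mm^-1."""
    m = eps.matrix
    c = np.stack(np.broadcast_arrays(np.asarray(o2hb, dtype=float),
                                     np.asarray(hhb, dtype=float))) / 1000.0
    mua = np.tensordot(m, c, axes=1) / 10.0
    return {wl: mua[i] for i, wl in enumerate(eps.wavelengths)}


@dataclass
class AbsorptionSeries:
    """Per-sample absorption changes of one block, per wavelength, mm^-1."""

    time: np.ndarray
    mua0: Mapping[float, float]
    dmua_up: dict[float, np.ndarray]
    dmua_down: dict[float, np.ndarray] = field(default_factory=dict)
    fit_flags: dict[float, np.ndarray] = field(default_factory=dict)  # bool: clamped/non-converged

    def mua_up(self, wl: float) -> np.ndarray:
        return self.mua0[wl] + self.dmua_up[wl]

    def mua_down(self, wl: float) -> np.ndarray:
        return self.mua0[wl] + self.dmua_down[wl]


@dataclass
class HemoglobinSeries:
    """Layered hemoglobin time courses of one block, uM.

    Layers: ``up`` = extra-cerebral, ``down`` = cerebral.  ``d_*`` series are
    re-referenced to the block baseline (zero baseline mean).
    """

    subject_id: str
    index: int
    time: np.ndarray
    o2hb: dict[str, np.ndarray]
    hhb: dict[str, np.ndarray]
    d_o2hb: dict[str, np.ndarray]
    d_hhb: dict[str, np.ndarray]
    baseline_window: tuple[float, float]
    hemisphere: str | None = None
    label: str | None = None       # move | stand for startle strata
    flags: list[str] = field(default_factory=list)


def _lm_scalar(forward: Callable[[np.ndarray], np.ndarray], y: np.ndarray,
               x0: float = 0.0, x_min: float | None = None,
               tol: float = 1e-10, max_iter: int = 100,
               fd_step: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    """Batched scalar Levenberg-Marquardt.

    Minimizes ``(y_i - forward(x)_i)^2`` independently for every element
    ``i``; ``forward`` must be vectorized.  Returns ``(x, converged)``.
    The damped update is ``dx = J r / (J^2 + lam)`` with per-element
    adaptive damping — the scalar specialization of the LM normal equations.
    """
    y = np.asarray(y, dtype=float)
    x = np.full_like(y, float(x0))
    lam = np.full_like(y, 1e-4)
    r = y - forward(x)
    obj = r * r
    for _ in range(max_iter):
        active = obj > tol
        if not np.any(active):
            break
        jac = (forward(x + fd_step) - (y - r)) / fd_step
        step = jac * r / (jac * jac + lam)
        x_new = x + np.where(active, step, 0.0)
        if x_min is not None:
            np.clip(x_new, x_min, None, out=x_new)
        r_new = y - forward(x_new)
        obj_new = r_new * r_new
        better = obj_new <= obj
        accept = active & better
        x = np.where(accept, x_new, x)
        r = np.where(accept, r_new, r)
        obj = np.where(accept, obj_new, obj)
        lam = np.where(better, lam * 0.3, lam * 10.0)
        np.clip(lam, 1e-12, 1e8, out=lam)
    return x, obj <= tol


def invert_upper(dod_short: DeltaODSeries, baseline: LayeredMedium,
                 rho_short: float = 10.0,
                 hemisphere: str | None = None) -> AbsorptionSeries:
    """Fit the homogeneous model to short-channel DeltaOD per sample and
    wavelength -> upper-layer absorption change Dmua_UP (mm^-1).

    Samples whose best fit would need mua <= 0 are clamped at ``MUA_FLOOR``
    and flagged; scattering stays at its baseline value.
    """
    out_dm: dict[float, np.ndarray] = {}
    out_flags: dict[float, np.ndarray] = {}
    mua0: dict[float, float] = {}
    for ch, y in sorted(dod_short.delta_od.items()):
        if ch.distance != "short":
            continue
        if hemisphere is not None and ch.hemisphere != hemisphere:
            continue
        wl = ch.wavelength
        up, _ = baseline.props(wl)
        mua0[wl] = up.mua
        if not np.all(np.isfinite(y)):
            raise ValueError(f"non-finite DeltaOD in channel {ch.column}")
        r0 = cw_reflectance_homog(rho_short, up, baseline.n_tissue,
                                  baseline.n_external)
        musp, nt, ne = up.musp, baseline.n_tissue, baseline.n_external

        def forward(dm, _r0=r0, _musp=musp, _mua0=up.mua):
            d = 1.0 / (3.0 * _musp)
            z0 = 1.0 / _musp
            from .media import boundary_coefficient
            zb = 2.0 * boundary_coefficient(nt, ne) * d
            mua = _mua0 + dm
            mueff = np.sqrt(mua / d)
            r1 = np.sqrt(rho_short**2 + z0**2)
            r2 = np.sqrt(rho_short**2 + (z0 + 2 * zb) ** 2)
            r = (z0 * (mueff + 1 / r1) * np.exp(-mueff * r1) / r1**2
                 + (z0 + 2 * zb) * (mueff + 1 / r2) * np.exp(-mueff * r2) / r2**2
                 ) / (4 * np.pi)
            return np.log10(_r0 / r)

        x_min = MUA_FLOOR - up.mua
        dm, converged = _lm_scalar(forward, y, 0.0, x_min=x_min, tol=1e-16)
        clamped = dm <= x_min + 1e-15
        out_dm[wl] = dm
        out_flags[wl] = clamped | ~converged
    if not out_dm:
        raise ValueError("no short-distance channels found in DeltaOD series")
    return AbsorptionSeries(time=dod_short.time, mua0=mua0,
                            dmua_up=out_dm, fit_flags=out_flags)


def invert_lower(dod_long: DeltaODSeries, dmua_up: AbsorptionSeries,
                 baseline: LayeredMedium, rho_long: float = 30.0,
                 hemisphere: str | None = None,
                 n_nodes: int = 1024) -> AbsorptionSeries:
    """Fit the two-layer model to long-channel DeltaOD with the upper layer
    fixed at the step-1 result -> cerebral absorption change Dmua_DOWN.
    """
    if dod_long.time.shape != dmua_up.time.shape or \
            not np.allclose(dod_long.time, dmua_up.time):
        raise ValueError("long-channel DeltaOD and Dmua_UP time bases differ")
    out_dm: dict[float, np.ndarray] = {}
    out_flags: dict[float, np.ndarray] = {}
    mua0: dict[float, float] = {}
    for ch, y in sorted(dod_long.delta_od.items()):
        if ch.distance != "long":
            continue
        if hemisphere is not None and ch.hemisphere != hemisphere:
            continue
        wl = ch.wavelength
        up, lo = baseline.props(wl)
        mua0[wl] = lo.mua
        if not np.all(np.isfinite(y)):
            raise ValueError(f"non-finite DeltaOD in channel {ch.column}")
        mua_up_t = dmua_up.mua0[wl] + dmua_up.dmua_up[wl]
        r0 = _two_layer_reflectance_core(
            rho_long, up.mua, up.musp, lo.mua, lo.musp, baseline.s,
            baseline.n_tissue, baseline.n_external, n_nodes)

        def forward(dm, _mu=mua_up_t, _r0=r0):
            r = _two_layer_reflectance_core(
                rho_long, _mu, up.musp, lo.mua + dm, lo.musp, baseline.s,
                baseline.n_tissue, baseline.n_external, n_nodes)
            return np.log10(_r0 / r)

        x_min = MUA_FLOOR - lo.mua
        dm, converged = _lm_scalar(forward, y, 0.0, x_min=x_min, tol=1e-16)
        clamped = dm <= x_min + 1e-15
        out_dm[wl] = dm
        out_flags[wl] = clamped | ~converged
    if not out_dm:
        raise ValueError("no long-distance channels found in DeltaOD series")
    return AbsorptionSeries(time=dod_long.time, mua0=mua0,
                            dmua_down=out_dm, dmua_up=dmua_up.dmua_up,
                            fit_flags=out_flags)


def run_block_inversion(dod: DeltaODSeries, baseline: LayeredMedium,
                        probe: ProbeConfig = ProbeConfig(),
                        eps: ExtinctionMatrix = ExtinctionMatrix(),
                        hemisphere: str = "left") -> HemoglobinSeries:
    """Full chain for one block and one hemisphere:
    invert_upper -> invert_lower -> Beer's law -> baseline re-referencing.
    """
    for dist in ("short", "long"):
        for wl in probe.wavelengths:
            ch = Channel(hemisphere, dist, wl)
            if ch not in dod.delta_od:
                raise ValueError(f"missing channel {ch.column}")
    absorb_up = invert_upper(dod, baseline, probe.rho_short, hemisphere)
    absorb = invert_lower(dod, absorb_up, baseline, probe.rho_long, hemisphere)

    o2hb: dict[str, np.ndarray] = {}
    hhb: dict[str, np.ndarray] = {}
    d_o2hb: dict[str, np.ndarray] = {}
    d_hhb: dict[str, np.ndarray] = {}
    b0, b1 = dod.baseline_window
    bsel = (dod.time >= b0 - 1e-9) & (dod.time < b1 - 1e-9)
    for layer, mua_t in (("up", {wl: absorb_up.mua0[wl] + absorb_up.dmua_up[wl]
                                 for wl in probe.wavelengths}),
                         ("down", {wl: absorb.mua0[wl] + absorb.dmua_down[wl]
                                   for wl in probe.wavelengths})):
        c_o2, c_hhb = mua_to_hemoglobin(mua_t, eps)
        o2hb[layer] = c_o2
        hhb[layer] = c_hhb
        d_o2hb[layer] = c_o2 - c_o2[bsel].mean()
        d_hhb[layer] = c_hhb - c_hhb[bsel].mean()

    flags = list(dod.flags)
    for wl in probe.wavelengths:
        n_bad = int(absorb_up.fit_flags[wl].sum() + absorb.fit_flags[wl].sum())
        if n_bad:
            flags.append(f"fit_flags_{int(wl)}nm:{n_bad}")
    return HemoglobinSeries(
        subject_id=dod.subject_id, index=dod.index, time=dod.time,
        o2hb=o2hb, hhb=hhb, d_o2hb=d_o2hb, d_hhb=d_hhb,
        baseline_window=dod.baseline_window, hemisphere=hemisphere,
        flags=flags)
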