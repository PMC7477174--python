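"""Seeded Monte Carlo photon transport in a plane-layered semi-infinite medium.

This is the independent physics oracle for the diffusion models and the
engine of the photon-penetration study: for each detected photon it tallies
the pathlength spent in every layer and the maximum depth reached, so the
short-channel "photons stay in the extra-cerebral tissue" assumption can be
quantified rather than assumed.

Transport model: exponential step sampling at mu_t = mu_a + mu_s, absorption
by weight attenuation (albedo multiplication at each scattering event),
isotropic scattering under the similarity reduction (g = 0, mu_s <- mu_s'),
unpolarized Fresnel reflection/refraction at the top surface, Russian
roulette below a weight threshold, and a total-pathlength cap.  The kernel
is strictly sequential and seeded once, so a given seed reproduces tallies
bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .media import LayeredMedium

__all__ = ["MCConfig", "MCResult", "run_mc", "penetration_summary"]

_MAX_LAYERS = 8


@dataclass(frozen=True)
class MCConfig:
    """Configuration of one Monte Carlo run.

    The source is a pencil beam entering at the origin along +z; the
    detector is an annulus centered on the source with mean radius
    ``detector_rho`` and half-width ``detector_halfwidth`` (mm).
    """

    medium: LayeredMedium
    detector_rho: float
    detector_halfwidth: float = 1.0
    n_photons: int = 100_000
    seed: int = 0
    wavelength: float | None = None
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_pathlength: float = 1e4

    def __post_init__(self) -> None:
        if self.n_photons <= 0:
            raise ValueError("n_photons must be > 0")
        if self.detector_halfwidth <= 0:
            raise ValueError("detector halfwidth must be > 0")
        if not (0 < self.roulette_survival < 1):
            raise ValueError("roulette_survival must be in (0, 1)")
        if self.detector_rho <= self.detector_halfwidth:
            raise ValueError("detector annulus must not include the source")


@dataclass
class MCResult:
    """Tallies of one Monte Carlo run (weights are per launched photon)."""

    config: MCConfig
    n_detected: int
    detected_weight_sum: float
    reflectance: float            # mm^-2, detected weight / (N * annulus area)
    reflectance_se: float         # standard error of the above
    partial_pathlength: np.ndarray  # weight-averaged mm per layer, detected photons
    total_pathlength: float       # weight-averaged total mm, detected photons
    max_depth_mean: float
    max_depth_median: float
    max_depth_quantiles: dict[float, float]
    # energy accounting, total weight per launched photon
    weight_escaped: float
    weight_absorbed: float
    weight_roulette: float
    weight_capped: float
    flags: list[str] = field(default_factory=list)

    @property
    def layer_fractions(self) -> np.ndarray:
        """Fraction of the detected-photon pathlength spent in each layer."""
        tot = self.partial_pathlength.sum()
        if tot <= 0:
            return np.zeros_like(self.partial_pathlength)
        return self.partial_pathlength / tot


@njit(cache=True)
def _fresnel_r(cos_i: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance, tissue -> outside, n_rel = n_in/n_out."""
    sin_t2 = n_rel * n_rel * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _mc_kernel(seed, n_photons, n_layers, z_bot, mua, mus, n_rel,
               r_in, r_out, w_thresh, w_surv, max_path):
    """Sequential photon loop.  Returns per-photon detection arrays and
    global energy tallies.  ``z_bot[k]`` is the depth of the bottom of layer
    k (z_bot[n_layers-1] = inf for the semi-infinite last layer)."""
    np.random.seed(seed)
    det_weight = np.zeros(n_photons)
    det_depth = np.zeros(n_photons)
    det_total_path = np.zeros(n_photons)
    det_layer_path = np.zeros((n_photons, n_layers))
    n_detected = 0
    w_escaped = 0.0
    w_absorbed = 0.0
    w_roulette = 0.0
    w_capped = 0.0
    eps = 1e-12

    layer_path = np.zeros(_MAX_LAYERS)
    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        layer = 0
        max_depth = 0.0
        total_path = 0.0
        for k in range(n_layers):
            layer_path[k] = 0.0
        alive = True
        while alive:
            mut = mua[layer] + mus[layer]
            step = -np.log(np.random.random()) / mut
            while True:
                # distance to the next layer interface along the flight
                z_top = 0.0 if layer == 0 else z_bot[layer - 1]
                if uz > eps:
                    db = (z_bot[layer] - z) / uz
                elif uz < -eps:
                    db = (z_top - z) / uz
                else:
                    db = np.inf
                if step < db:
                    # interaction inside the current layer
                    x += step * ux
                    y += step * uy
                    z += step * uz
                    total_path += step
                    layer_path[layer] += step
                    if z > max_depth:
                        max_depth = z
                    # absorb a fraction of the weight, then scatter
                    w_absorbed += w * mua[layer] / mut
                    w *= mus[layer] / mut
                    # isotropic new direction
                    uz = 2.0 * np.random.random() - 1.0
                    phi = 2.0 * np.pi * np.random.random()
                    sin_th = np.sqrt(1.0 - uz * uz)
                    ux = sin_th * np.cos(phi)
                    uy = sin_th * np.sin(phi)
                    if w < w_thresh:
                        if np.random.random() < w_surv:
                            w /= w_surv
                        else:
                            w_roulette += w
                            alive = False
                    break
                # move to the interface
                x += db * ux
                y += db * uy
                z += db * uz
                total_path += db
                layer_path[layer] += db
                if z > max_depth:
                    max_depth = z
                step -= db
                if uz > 0.0:
                    layer += 1  # matched internal indices: straight through
                    z = z_bot[layer - 1]
                else:
                    if layer > 0:
                        layer -= 1
                        z = z_bot[layer]
                    else:
                        # top surface: Fresnel reflect or escape
                        z = 0.0
                        r = _fresnel_r(-uz, n_rel)
                        if np.random.random() < r:
                            uz = -uz
                        else:
                            w_escaped += w
                            rad = np.sqrt(x * x + y * y)
                            if r_in <= rad < r_out:
                                det_weight[n_detected] = w
                                det_depth[n_detected] = max_depth
                                det_total_path[n_detected] = total_path
                                for k in range(n_layers):
                                    det_layer_path[n_detected, k] = layer_path[k]
                                n_detected += 1
                            alive = False
                            break
            if alive and total_path > max_path:
                w_capped += w
                alive = False
    return (det_weight[:n_detected], det_depth[:n_detected],
            det_total_path[:n_detected], det_layer_path[:n_detected],
            n_detected, w_escaped, w_absorbed, w_roulette, w_capped)


def _medium_arrays(medium: LayeredMedium, wavelength):
    up, lo = medium.props(wavelength)
    z_bot = np.array([medium.s, np.inf])
    mua = np.array([up.mua, lo.mua])
    mus = np.array([up.musp, lo.musp])  # similarity: g=0, mus <- musp
    return z_bot, mua, mus


def run_mc(config: MCConfig) -> MCResult:
    """Run the photon transport and summarize the tallies.

    Zero detected photons is not an error: the result carries NaN summary
    statistics and a ``"no_detected_photons"`` flag.
    """
    med = config.medium
    z_bot, mua, mus = _medium_arrays(med, config.wavelength)
    n_layers = mua.size
    r_in = config.detector_rho - config.detector_halfwidth
    r_out = config.detector_rho + config.detector_halfwidth
    (w_det, depth, total_path, layer_path, n_det,
     w_esc, w_abs, w_rou, w_cap) = _mc_kernel(
        config.seed, config.n_photons, n_layers, z_bot, mua, mus,
        med.n_tissue / med.n_external, r_in, r_out,
        config.roulette_threshold, config.roulette_survival,
        config.max_pathlength)

    area = np.pi * (r_out**2 - r_in**2)
    n = config.n_photons
    refl = w_det.sum() / (n * area)
    # per-photon estimator variance (undetected photons contribute 0)
    mean_w = w_det.sum() / n
    var_w = (np.sum(w_det**2) - n * mean_w**2) / max(n - 1, 1)
    refl_se = np.sqrt(var_w / n) / area

    flags: list[str] = []
    if n_det == 0:
        flags.append("no_detected_photons")
        ppl = np.full(n_layers, np.nan)
        tot = np.nan
        d_mean = d_med = np.nan
        quants = {q: np.nan for q in (0.1, 0.25, 0.75, 0.9)}
    else:
        wsum = w_det.sum()
        ppl = (w_det[:, None] * layer_path).sum(axis=0) / wsum
        tot = float((w_det * total_path).sum() / wsum)
        d_mean = float(np.average(depth, weights=w_det))
        order = np.argsort(depth)
        cumw = np.cumsum(w_det[order]) / wsum
        d_med = float(depth[order][np.searchsorted(cumw, 0.5)])
        quants = {q: float(depth[order][min(np.searchsorted(cumw, q),
                                            n_det - 1)])
                  for q in (0.1, 0.25, 0.75, 0.9)}
    return MCResult(
        config=config, n_detected=int(n_det),
        detected_weight_sum=float(w_det.sum()),
        reflectance=float(refl), reflectance_se=float(refl_se),
        partial_pathlength=ppl, total_pathlength=tot,
        max_depth_mean=d_mean, max_depth_median=d_med,
        max_depth_quantiles=quants,
        weight_escaped=float(w_esc / n), weight_absorbed=float(w_abs / n),
        weight_roulette=float(w_rou / n), weight_capped=float(w_cap / n),
        flags=flags)


@dataclass(frozen=True)
class PenetrationComparison:
    """Depth statistics of a long- vs short-distance detector pair."""

    rho_long: float
    rho_short: float
    max_depth_mean_long: float
    max_depth_mean_short: float
    max_depth_median_long: float
    max_depth_median_short: float
    lower_fraction_long: float
    lower_fraction_short: float
    depth_ordering_ok: bool
    short_stays_superficial: bool
    superficial_threshold: float


def penetration_summary(result: MCResult, short: MCResult,
                        superficial_threshold: float = 0.05) -> PenetrationComparison:
    """Compare photon penetration between a long- and a short-distance run.

    Both runs must share the same medium.  ``short_stays_superficial`` is
    True when the lower-layer pathlength fraction of the short channel is
    below ``superficial_threshold`` — the quantitative version of the
    short-channel design assumption.
    """
    if result.config.medium != short.config.medium:
        raise ValueError("penetration comparison requires the same medium")
    frac_long = float(result.layer_fractions[-1])
    frac_short = float(short.layer_fractions[-1])
    return PenetrationComparison(
        rho_long=result.config.detector_rho,
        rho_short=short.config.detector_rho,
        max_depth_mean_long=result.max_depth_mean,
        max_depth_mean_short=short.max_depth_mean,
        max_depth_median_long=result.max_depth_median,
        max_depth_median_short=short.max_depth_median,
        lower_fraction_long=frac_long,
        lower_fraction_short=frac_short,
        depth_ordering_ok=bool(result.max_depth_mean > short.max_depth_mean),
        short_stays_superficial=bool(frac_short < superficial_threshold),
        superficial_threshold=superficial_threshold)
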