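"""Ground-truthed synthetic cohorts for the sheep fNIRS pipeline.

The generator builds what the analysis assumes it is measuring: a cortical
(lower-layer) hemodynamic response locked to the task blocks, superficial
(upper-layer) systemic components (Mayer-type oscillation and slow drift),
and Gaussian optical-density noise.  Concentration time courses per layer
are converted to absorption changes through the sheep extinction
coefficients and forward-propagated to both source-detector distances with
the *two-layer* diffusion model — never the homogeneous short-channel
approximation the analysis itself uses — so the pipeline's approximation
bias is measured by the tests rather than hidden by an inverse crime.

Cohorts also carry behavior annotations: planted head-shake/chewing
intervals drive the exclusion logic, and flight/freezing labels drive the
Move/Stand stratification of the startle test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .diffusion import _two_layer_reflectance_core
from .invert import ExtinctionMatrix, hemoglobin_to_mua
from .media import LayeredMedium, OpticalProperties, ProbeConfig
from .preprocess import (BehaviorAnnotation, BlockSchedule, Channel,
                         ODRecording)

__all__ = [
    "HRFParams",
    "LayerTruth",
    "GroundTruth",
    "SyntheticCohort",
    "canonical_hrf",
    "generate_block",
    "generate_cohort",
]


@dataclass(frozen=True)
class HRFParams:
    """Shape of one chromophore's hemodynamic response.

    ``peak`` is the signed amplitude in uM reached at ``time_to_peak``
    seconds after ``onset``; ``fwhm`` the width of the main lobe;
    ``undershoot`` the fractional amplitude of the late inverted lobe.
    Generic canonical values; the study species provides no amplitude
    calibration, so defaults are order-of-magnitude fNIRS-typical.
    """

    peak: float
    onset: float = 1.0
    time_to_peak: float = 6.0
    fwhm: float = 6.0
    undershoot: float = 0.2

    def __post_init__(self) -> None:
        if self.time_to_peak <= 0 or self.fwhm <= 0:
            raise ValueError("time_to_peak and fwhm must be > 0")
        if self.undershoot < 0:
            raise ValueError("undershoot must be >= 0")


from functools import lru_cache


@lru_cache(maxsize=128)
def _gamma_shape_from_fwhm(mode: float, fwhm: float) -> tuple[float, float]:
    """Gamma-density (shape k, scale theta) with the given mode and FWHM."""
    from scipy.optimize import brentq

    def pdf_fwhm(k: float) -> float:
        theta = mode / (k - 1.0)
        t = np.linspace(mode * 1e-4, mode * 8.0, 4000)
        log_y = (k - 1.0) * np.log(t) - t / theta
        log_y -= log_y.max()
        above = t[log_y >= np.log(0.5)]
        return above[-1] - above[0]

    k = brentq(lambda k: pdf_fwhm(k) - fwhm, 1.05, 500.0, xtol=1e-10)
    return k, mode / (k - 1.0)


def _hrf_base(t: np.ndarray, p: HRFParams) -> np.ndarray:
    """Unnormalized difference-of-gammas; zero before onset."""
    k1, th1 = _gamma_shape_from_fwhm(p.time_to_peak, p.fwhm)
    # undershoot lobe: later and broader than the main lobe
    k2, th2 = _gamma_shape_from_fwhm(2.5 * p.time_to_peak, 2.0 * p.fwhm)
    tt = np.maximum(t - p.onset, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lg1 = (k1 - 1.0) * np.log(tt) - tt / th1
        lg2 = (k2 - 1.0) * np.log(tt) - tt / th2
    # peak-normalize each lobe at its analytic mode
    lg1 -= (k1 - 1.0) * np.log((k1 - 1.0) * th1) - (k1 - 1.0)
    lg2 -= (k2 - 1.0) * np.log((k2 - 1.0) * th2) - (k2 - 1.0)
    g1 = np.where(tt > 0, np.exp(lg1), 0.0)
    g2 = np.where(tt > 0, np.exp(lg2), 0.0)
    out = g1 - p.undershoot * g2
    out[t < p.onset] = 0.0
    return out


def canonical_hrf(t: np.ndarray, params: HRFParams) -> np.ndarray:
    """Canonical difference-of-gammas hemodynamic response, uM.

    The waveform is zero before ``onset``, its extremum equals ``peak``
    exactly (to normalization precision) at ``onset + time_to_peak``, and it
    relaxes back to ~0 within tens of seconds.
    """
    t = np.asarray(t, dtype=float)
    if params.peak == 0.0:
        return np.zeros_like(t)
    # normalize on a fine grid so the sampled peak value is exact wherever
    # the user's grid lands on t_peak
    tf = np.linspace(0.0, params.onset + params.time_to_peak + 6.0 * params.fwhm,
                     20000)
    base_f = _hrf_base(tf, params)
    i_max = int(np.argmax(np.abs(base_f)))
    scale = base_f[i_max]
    t_star = tf[i_max]
    # shift so the true extremum lands exactly at onset + time_to_peak
    shift = (params.onset + params.time_to_peak) - t_star
    shifted = replace(params, peak=1.0)
    out = _hrf_base(t - shift, shifted) / scale * params.peak
    return out


@dataclass(frozen=True)
class LayerTruth:
    """Planted signal content of one tissue layer."""

    o2hb: HRFParams | None = None
    hhb: HRFParams | None = None
    mayer_amplitude: float = 0.0   # uM, ~0.1 Hz superficial oscillation
    mayer_freq: float = 0.1        # Hz
    drift: float = 0.0             # uM / min


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator plants, stored alongside the data."""

    lower: LayerTruth
    upper: LayerTruth = LayerTruth()
    noise_od: float = 1e-3         # Gaussian OD noise sigma per sample
    reaction: str | None = None    # flight | freezing, startle blocks

    def concentration(self, t: np.ndarray, layer: str,
                      rng: np.random.Generator | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
        """(DO2Hb, DHHb) time courses in uM on grid ``t`` (s, rel. onset)."""
        lt = getattr(self, layer)
        o2 = canonical_hrf(t, lt.o2hb) if lt.o2hb else np.zeros_like(t)
        hb = canonical_hrf(t, lt.hhb) if lt.hhb else np.zeros_like(t)
        if lt.mayer_amplitude:
            phase = rng.uniform(0, 2 * np.pi) if rng is not None else 0.0
            wave = lt.mayer_amplitude * np.sin(2 * np.pi * lt.mayer_freq * t + phase)
            o2 = o2 + wave
        if lt.drift:
            o2 = o2 + lt.drift * (t - t[0]) / 60.0
        return o2, hb


def _delta_od_two_layer(rho: float, baseline: LayeredMedium, wl: float,
                        dmua_up: np.ndarray, dmua_down: np.ndarray,
                        n_nodes: int = 1024) -> np.ndarray:
    up, lo = baseline.props(wl)
    r0 = _two_layer_reflectance_core(rho, up.mua, up.musp, lo.mua, lo.musp,
                                     baseline.s, baseline.n_tissue,
                                     baseline.n_external, n_nodes)
    r = _two_layer_reflectance_core(rho, up.mua + dmua_up, up.musp,
                                    lo.mua + dmua_down, lo.musp, baseline.s,
                                    baseline.n_tissue, baseline.n_external,
                                    n_nodes)
    return np.log10(r0 / r)


def generate_block(truth: GroundTruth, baseline: LayeredMedium,
                   probe: ProbeConfig = ProbeConfig(), seed: int = 0,
                   task: str = "motor", hemispheres: Sequence[str] = ("left", "right"),
                   eps: ExtinctionMatrix = ExtinctionMatrix(),
                   od0: float = 1.0,
                   n_nodes: int = 1024) -> tuple[dict[Channel, np.ndarray], np.ndarray, dict]:
    """Synthesize one block's OD time series at both distances/wavelengths.

    Returns ``(od, t, truth_series)`` where ``t`` is seconds relative to
    task onset over the block analysis window and ``truth_series`` holds the
    planted concentration and DeltaOD ground truth.  OD = od0 + DeltaOD +
    noise; the forward model is the full two-layer solution at both rho.
    """
    rng = np.random.default_rng(seed)
    sched = BlockSchedule(task, (0.0,))
    off0, off1 = sched.analysis_span
    dt = 1.0 / probe.sampling_rate
    t = np.arange(off0, off1 - dt / 2, dt)

    truth_series: dict = {"time": t}
    od: dict[Channel, np.ndarray] = {}
    for hemi in hemispheres:
        o2_up, hb_up = truth.concentration(t, "upper", rng)
        o2_dn, hb_dn = truth.concentration(t, "lower", rng)
        mua_up = hemoglobin_to_mua(o2_up, hb_up, eps)
        mua_dn = hemoglobin_to_mua(o2_dn, hb_dn, eps)
        truth_series[hemi] = {"o2hb": {"up": o2_up, "down": o2_dn},
                              "hhb": {"up": hb_up, "down": hb_dn},
                              "delta_od": {}}
        for wl in probe.wavelengths:
            up0, _ = baseline.props(wl)
            if np.any(up0.mua + mua_up[wl] <= 0):
                raise ValueError("planted truth drives upper-layer mua <= 0")
            for dist, rho in (("short", probe.rho_short), ("long", probe.rho_long)):
                dod = _delta_od_two_layer(rho, baseline, wl,
                                          mua_up[wl], mua_dn[wl], n_nodes)
                truth_series[hemi]["delta_od"][(dist, wl)] = dod
                noise = rng.normal(0.0, truth.noise_od, t.size) \
                    if truth.noise_od > 0 else 0.0
                od[Channel(hemi, dist, wl)] = od0 + dod + noise
    return od, t, truth_series


@dataclass
class SyntheticCohort:
    """A full synthetic experiment: recordings + schedules + annotations +
    the planted truth, deterministic given ``seed``."""

    task: str
    recordings: dict[str, ODRecording]
    schedules: dict[str, BlockSchedule]
    annotations: list[BehaviorAnnotation]
    truth: dict[str, dict[int, GroundTruth]]   # subject -> block -> truth
    baseline: LayeredMedium
    probe: ProbeConfig
    seed: int

    def subjects(self) -> list[str]:
        return sorted(self.recordings)


# default planted response: canonical activation confined to the cortex
DEFAULT_CORTICAL = LayerTruth(
    o2hb=HRFParams(peak=1.0), hhb=HRFParams(peak=-0.3))


def generate_cohort(n_subjects: int = 10, task: str = "motor",
                    behavior_mix: Mapping[str, float] | None = None,
                    seed: int = 0,
                    baseline: LayeredMedium | None = None,
                    probe: ProbeConfig = ProbeConfig(),
                    lower_truth: LayerTruth = DEFAULT_CORTICAL,
                    upper_truth: LayerTruth = LayerTruth(),
                    noise_od: float = 1e-3,
                    n_blocks: int | None = None,
                    artifact_blocks_per_subject: int = 0,
                    frequent_shaker_subjects: Sequence[int] = (),
                    eps: ExtinctionMatrix = ExtinctionMatrix(),
                    n_nodes: int = 1024,
                    ) -> SyntheticCohort:
    """Build a seeded cohort with the study's block design.

    ``behavior_mix`` (startle only) gives the per-block probability of
    flight vs freezing among blocks that get a reaction, e.g.
    ``{"flight": 0.7, "freezing": 0.3}``.  ``artifact_blocks_per_subject``
    plants a head-shake or chewing interval inside that many block windows
    per subject; subjects listed in ``frequent_shaker_subjects`` get head
    shakes in well over half their blocks, triggering subject-level
    exclusion.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if task not in ("motor", "startle"):
        raise ValueError("task must be motor or startle")
    if behavior_mix is not None:
        total = sum(behavior_mix.values())
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in behavior_mix.values()):
            raise ValueError("behavior_mix fractions must be >= 0 and sum to 1")
        unknown = set(behavior_mix) - {"flight", "freezing"}
        if unknown:
            raise ValueError(f"behavior_mix codes must be flight/freezing, got {unknown}")
    if baseline is None:
        props = {wl: OpticalProperties(0.015, 1.0, wl) for wl in probe.wavelengths}
        baseline = LayeredMedium(10.0, props, props, 1.4, 1.0)
    rng = np.random.default_rng(seed)
    if n_blocks is None:
        n_blocks = 10 if task == "motor" else 5
    # block spacing: motor = 30 s walk + 30 s rest; startle = 30 s baseline
    # + 3 s stimulus + 60 s reaction, contiguous blocks
    period = 60.0 if task == "motor" else 93.0
    lead_in = 30.0
    onsets = tuple(lead_in + i * period for i in range(n_blocks))
    sched = BlockSchedule(task, onsets)
    off0, off1 = sched.analysis_span
    dt = 1.0 / probe.sampling_rate
    total_t = lead_in + n_blocks * period
    time = np.arange(0.0, total_t, dt)

    recordings: dict[str, ODRecording] = {}
    schedules: dict[str, BlockSchedule] = {}
    annotations: list[BehaviorAnnotation] = []
    truths: dict[str, dict[int, GroundTruth]] = {}

    mix_codes, mix_probs = (("flight",), (1.0,))
    if behavior_mix is not None:
        mix_codes = tuple(sorted(behavior_mix))
        mix_probs = tuple(behavior_mix[c] for c in mix_codes)

    for i_subj in range(n_subjects):
        subj = f"sheep{i_subj + 1:02d}"
        block_truths: dict[int, GroundTruth] = {}
        channels = {Channel(h, d, wl): np.full(time.size, 1.0)
                    for h in ("left", "right") for d in ("short", "long")
                    for wl in probe.wavelengths}
        # continuous instrument noise over the whole recording
        for ch in channels:
            channels[ch] = channels[ch] + rng.normal(0.0, noise_od, time.size)

        artifact_targets = set(
            rng.choice(n_blocks, size=min(artifact_blocks_per_subject, n_blocks),
                       replace=False)) if artifact_blocks_per_subject else set()
        shaker = i_subj in frequent_shaker_subjects
        if shaker:
            n_shake = int(np.ceil(0.8 * n_blocks))
            shake_blocks = set(rng.choice(n_blocks, size=n_shake, replace=False))

        for i_blk, onset in enumerate(onsets):
            reaction = None
            if task == "startle":
                reaction = str(rng.choice(mix_codes, p=mix_probs))
            truth = GroundTruth(lower=lower_truth, upper=upper_truth,
                                noise_od=0.0, reaction=reaction)
            block_truths[i_blk] = replace(truth, noise_od=noise_od)
            od_blk, t_blk, _ = generate_block(
                truth, baseline, probe,
                seed=int(rng.integers(2**31)), task=task, eps=eps,
                n_nodes=n_nodes)
            sel = np.nonzero((time >= onset + off0 - 1e-9)
                             & (time < onset + off1 - 1e-9))[0]
            for ch, series in od_blk.items():
                channels[ch][sel] += series - 1.0  # add DeltaOD on top of noise

            if task == "startle" and reaction is not None:
                r_start = onset + float(rng.uniform(1.0, 5.0))
                annotations.append(BehaviorAnnotation(
                    subj, reaction, r_start, r_start + float(rng.uniform(5.0, 20.0))))
            if i_blk in artifact_targets and not shaker:
                code = str(rng.choice(("head_shake", "chewing")))
                a_start = onset + float(rng.uniform(0.0, 10.0))
                annotations.append(BehaviorAnnotation(
                    subj, code, a_start, a_start + float(rng.uniform(1.0, 3.0))))
            if shaker and i_blk in shake_blocks:
                a_start = onset + float(rng.uniform(0.0, 10.0))
                annotations.append(BehaviorAnnotation(
                    subj, "head_shake", a_start, a_start + float(rng.uniform(1.0, 3.0))))

        recordings[subj] = ODRecording(time, channels, subj)
        schedules[subj] = sched
        truths[subj] = block_truths

    return SyntheticCohort(task=task, recordings=recordings, schedules=schedules,
                           annotations=annotations, truth=truths,
                           baseline=baseline, probe=probe, seed=seed)


def write_cohort(cohort: SyntheticCohort, out_dir) -> "Path":
    """Write a cohort to disk in the pipeline's input formats.

    Produces per-subject OD CSVs, one annotation CSV, a truth JSON and a
    ready-to-run pipeline config YAML; returns the config path.
    """
    import json
    from pathlib import Path

    import pandas as pd
    import yaml

    from .preprocess import write_od_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec_entries = []
    for subj in cohort.subjects():
        path = out / f"od_{subj}.csv"
        write_od_csv(cohort.recordings[subj], path)
        rec_entries.append({"path": str(path), "subject": subj,
                            "block_starts": list(cohort.schedules[subj].block_starts)})
    ann_path = out / "annotations.csv"
    pd.DataFrame([(a.subject_id, a.behavior, a.start, a.end)
                  for a in cohort.annotations],
                 columns=["subject", "behavior", "start", "end"]
                 ).to_csv(ann_path, index=False)

    truth_json = {
        subj: {str(i): {"reaction": t.reaction, "noise_od": t.noise_od,
                        "lower_peak_o2hb": t.lower.o2hb.peak if t.lower.o2hb else 0.0,
                        "lower_peak_hhb": t.lower.hhb.peak if t.lower.hhb else 0.0,
                        "upper_peak_o2hb": t.upper.o2hb.peak if t.upper.o2hb else 0.0,
                        "upper_mayer": t.upper.mayer_amplitude}
               for i, t in blocks.items()}
        for subj, blocks in cohort.truth.items()}
    with open(out / "truth.json", "w") as fh:
        json.dump({"seed": cohort.seed, "task": cohort.task,
                   "blocks": truth_json}, fh, indent=2, sort_keys=True)

    up, _ = cohort.baseline.props(cohort.probe.wavelengths[0])
    cfg = {
        "task": cohort.task,
        "probe": {"rho_short": cohort.probe.rho_short,
                  "rho_long": cohort.probe.rho_long,
                  "wavelengths": list(cohort.probe.wavelengths),
                  "sampling_rate": cohort.probe.sampling_rate},
        "optics": {"mua0": up.mua, "musp0": up.musp, "s": cohort.baseline.s,
                   "n_tissue": cohort.baseline.n_tissue,
                   "n_external": cohort.baseline.n_external},
        "data": {"recordings": rec_entries, "annotations": [str(ann_path)]},
    }
    cfg_path = out / "pipeline.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return cfg_path
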