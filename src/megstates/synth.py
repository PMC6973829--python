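"""Synthetic MEG-like recordings with perceptual-switch structure.

This module emulates the statistical structure the decoding pipeline
assumes: multichannel sensor recordings (160 axial-gradiometer-like
sensors by default, 1000 Hz, 60 s blocks) with a band-limited 1/f
background, spontaneous perceptual-switch events reported with a jittered
reaction time, and state-dependent modulation of alpha/beta/gamma power
in a fixed parieto-occipital sensor subset.  Six experimental conditions
are modelled: three bistable stimulus types (Necker cube NC, stroboscopic
alternative motion SAM, structure-from-motion SFM), each presented
continuously (suffix C) or with 3 s on / 3 s off blanking (suffix B).

A parallel source-space generator produces 89 labelled anatomical region
time series (an AAL-style parcellation with motor-related regions
removed) with effects planted in parietal / occipital / cerebellar
regions, so that feature-selection analyses have ground truth.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence``; identical configurations produce identical
datasets.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "STIMULI",
    "AAL89_REGIONS",
    "SensorLayout",
    "SwitchEvent",
    "RecordingBlock",
    "SourceBlock",
    "GenConfig",
    "generate_layout",
    "generate_block",
    "generate_source_block",
    "generate_dataset",
    "planted_sensor_indices",
    "default_planted_regions",
    "region_group",
    "save_dataset",
    "load_dataset",
    "events_to_frame",
    "export_events_tsv",
]

#: Condition codes: stimulus type x presentation mode.
CONDITIONS = ("NCC", "SAMC", "SFMC", "NCB", "SAMB", "SFMB")
#: The three stimulus factors (presentation mode pooled).
STIMULI = ("NC", "SAM", "SFM")

_CONDITION_STIMULUS = {c: ("NC" if c.startswith("NC") else "SAM" if c.startswith("SAM") else "SFM") for c in CONDITIONS}


def condition_stimulus(condition: str) -> str:
    """Stimulus factor (NC/SAM/SFM) of a condition code."""
    return _CONDITION_STIMULUS[condition]


def condition_is_blanking(condition: str) -> bool:
    return condition.endswith("B")


# ---------------------------------------------------------------------------
# Sensor layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorLayout:
    """Identities and 3-D positions of a whole-head sensor array.

    Coordinates follow the usual head convention: +x right, +y anterior,
    +z superior, in arbitrary length units on an upper-hemisphere shell.
    ``motor_excluded`` flags sensors over the sensorimotor strip that are
    dropped before any feature computation; ``region_cluster`` optionally
    holds a 1..k cluster id per sensor (0 = unset / excluded).
    """

    sensor_id: tuple[str, ...]
    positions: np.ndarray            # (n, 3)
    hemisphere: tuple[str, ...]      # left / right / midline
    motor_excluded: np.ndarray       # (n,) bool
    region_cluster: np.ndarray | None = None
    midline_tol: float = 0.05

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_id)

    @property
    def retained(self) -> np.ndarray:
        """Boolean mask of sensors kept for analysis (non motor-excluded)."""
        return ~self.motor_excluded

    def hemisphere_mask(self, side: str) -> np.ndarray:
        """Mask of retained sensors on one side ('left'/'right')."""
        tags = np.asarray(self.hemisphere)
        return (tags == side) & self.retained

    def with_clusters(self, assignment: np.ndarray) -> "SensorLayout":
        return dataclasses.replace(self, region_cluster=np.asarray(assignment))


def generate_layout(n_sensors: int = 160, n_motor_excluded: int = 36,
                    seed: int = 0, midline_tol: float = 0.05) -> SensorLayout:
    """Place sensors quasi-uniformly on an upper-hemisphere shell.

    A Fibonacci lattice on the upper hemisphere gives an even whole-head
    coverage; a small seeded jitter breaks exact symmetry.  The
    ``n_motor_excluded`` sensors nearest the central (sensorimotor)
    coronal band at the top of the head are flagged ``motor_excluded``.
    """
    if n_sensors <= 0:
        raise ValueError(f"n_sensors must be positive, got {n_sensors}")
    if n_motor_excluded < 0:
        raise ValueError(f"n_motor_excluded must be nonnegative, got {n_motor_excluded}")
    if n_motor_excluded >= n_sensors:
        raise ValueError("n_motor_excluded must be smaller than n_sensors "
                         f"({n_motor_excluded} >= {n_sensors})")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xA1,)))
    n = n_sensors
    if n == 1:
        pts = np.array([[0.0, 0.0, 1.0]])
    elif n == 2:
        pts = np.array([[1.0, 0.0, 0.3], [-1.0, 0.0, 0.3]])
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    else:
        golden = (1 + 5 ** 0.5) / 2
        i = np.arange(n)
        z = (i + 0.5) / n                       # upper hemisphere only
        theta = 2 * np.pi * i / golden
        r = np.sqrt(1 - z ** 2)
        pts = np.c_[r * np.cos(theta), r * np.sin(theta), z]
        pts += rng.normal(scale=0.01, size=pts.shape)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    radius = 10.0                               # ~head radius, arbitrary units
    pts = pts * radius

    # sensorimotor strip: a central band across the vertex, |y| small and z high
    score = np.abs(pts[:, 1]) + 0.5 * np.maximum(0.0, radius * 0.4 - pts[:, 2])
    order = np.argsort(score, kind="stable")
    motor = np.zeros(n, dtype=bool)
    motor[order[:n_motor_excluded]] = True

    tol = midline_tol * radius
    hemi = tuple(
        "midline" if abs(x) <= tol else ("right" if x > 0 else "left")
        for x in pts[:, 0]
    )
    ids = tuple(f"MEG{i:03d}" for i in range(n))
    return SensorLayout(ids, pts, hemi, motor, None, midline_tol=tol)


def planted_sensor_indices(layout: SensorLayout, fraction: float = 0.25) -> np.ndarray:
    """Indices of the posterior (parieto-occipital) sensors carrying effects.

    The most posterior ``fraction`` of the retained sensors (smallest y)
    form a fixed topography, mirroring the parieto-occipital areas where
    transition/maintenance differences are expected.
    """
    idx = np.flatnonzero(layout.retained)
    order = idx[np.argsort(layout.positions[idx, 1], kind="stable")]
    k = max(1, int(round(fraction * len(idx))))
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# Events and blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchEvent:
    """One spontaneous perceptual switch and its button-press report."""
    true_switch_time: float     # s, endogenous change of percept
    press_time: float           # s, behavioural report
    percept_after: str          # 'P1' or 'P2'

    def __post_init__(self):
        if not self.press_time > self.true_switch_time:
            raise ValueError("press_time must follow true_switch_time")


@dataclass
class RecordingBlock:
    """One continuous multichannel recording of a single condition."""
    data: np.ndarray            # (n_channels, n_samples)
    fs: float
    duration: float
    condition: str
    events: list[SwitchEvent]
    subject_id: str
    planted_sensors: np.ndarray | None = None   # generator ground truth

    def __post_init__(self):
        n = self.data.shape[-1]
        if n != int(round(self.fs * self.duration)):
            raise ValueError("n_samples must equal fs * duration")
        presses = [e.press_time for e in self.events]
        if any(not (0 < p < self.duration) for p in presses):
            raise ValueError("press times must lie strictly inside the block")
        if any(b <= a for a, b in zip(presses, presses[1:])):
            raise ValueError("events must be strictly increasing in press_time")


@dataclass
class SourceBlock:
    """89 anatomical-region time series standing in for source reconstruction."""
    data: np.ndarray                    # (89, n_samples)
    region_labels: tuple[str, ...]
    planted_regions: tuple[str, ...]
    fs: float
    duration: float
    condition: str
    events: list[SwitchEvent]
    subject_id: str

    def __post_init__(self):
        if self.data.shape[0] != len(self.region_labels):
            raise ValueError("one time series per region label required")


# 89 AAL-style region labels: a 116-region parcellation minus 27
# motor-related regions (pre/post-central, SMA, rolandic operculum,
# paracentral lobule, basal ganglia, thalamus, anterior cerebellum and
# vermis).  The exact exclusion list is this package's own choice.
_AAL_BILATERAL = (
    "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid", "Frontal_Mid_Orb",
    "Frontal_Inf_Oper", "Frontal_Inf_Tri", "Frontal_Inf_Orb", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Parietal_Sup", "Parietal_Inf", "SupraMarginal", "Angular", "Precuneus",
    "Heschl", "Temporal_Sup", "Temporal_Pole_Sup", "Temporal_Mid",
    "Temporal_Pole_Mid", "Temporal_Inf",
    "Cerebelum_Crus1", "Cerebelum_Crus2", "Cerebelum_6", "Cerebelum_7b",
    "Cerebelum_8", "Cerebelum_9",
)
_AAL_MIDLINE = ("Vermis_6", "Vermis_7", "Vermis_8", "Vermis_9", "Vermis_10")

AAL89_REGIONS: tuple[str, ...] = tuple(
    f"{name}_{side}" for name in _AAL_BILATERAL for side in ("L", "R")
) + _AAL_MIDLINE
assert len(AAL89_REGIONS) == 89

_GROUP_PREFIXES = (
    ("cerebellum", ("Cerebelum", "Vermis")),
    ("occipital", ("Calcarine", "Cuneus", "Lingual", "Occipital", "Fusiform")),
    ("parietal", ("Parietal", "SupraMarginal", "Angular", "Precuneus")),
    ("temporal", ("Heschl", "Temporal")),
    ("frontal", ("Frontal", "Olfactory", "Rectus")),
    ("limbic", ("Cingulum", "Hippocampus", "ParaHippocampal", "Amygdala", "Insula")),
)


def region_group(label: str) -> str:
    """Coarse lobe grouping of an anatomical region label."""
    for group, prefixes in _GROUP_PREFIXES:
        if label.startswith(prefixes):
            return group
    return "other"


def default_planted_regions() -> tuple[str, ...]:
    """Parietal / occipital / cerebellar regions carrying planted effects."""
    wanted = ("Parietal_Sup", "Parietal_Inf", "Precuneus", "Cuneus",
              "Calcarine", "Occipital_Sup", "Occipital_Mid",
              "Cerebelum_Crus1")
    return tuple(r for r in AAL89_REGIONS if r.rsplit("_", 1)[0] in wanted)


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

# mean inter-switch intervals (s), from per-condition switch totals over
# eleven subjects x three 60 s repetitions (1980 s per condition)
_DEFAULT_MEAN_ISI = {
    "NCC": 5.4, "SAMC": 23.0, "SFMC": 11.6,
    "NCB": 8.7, "SAMB": 37.0, "SFMB": 25.0,
}

_DEFAULT_EFFECTS = {"alpha": 0.8, "beta": 1.0, "lower_gamma": 1.0, "upper_gamma": 0.8}

# band edges in Hz, used by the generator to gate state-dependent power
_BAND_EDGES = {
    "delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0), "lower_gamma": (30.0, 50.0), "upper_gamma": (50.0, 80.0),
}


@dataclass(frozen=True)
class GenConfig:
    """Full parameterisation of the synthetic study.

    Defaults mirror the study design: 11 subjects, 18 blocks each
    (3 stimuli x 2 presentation modes x 3 repetitions), 60 s blocks at
    1000 Hz from 160 sensors (36 motor-excluded), heavy per-subject
    switch-rate variability, lognormal reaction times with ~300 ms
    median, and fractional power increases in alpha/beta/gamma bands of
    posterior sensors while a switch is underway.
    """

    seed: int = 0
    n_subjects: int = 11
    n_repetitions: int = 3
    n_sensors: int = 160
    n_motor_excluded: int = 36
    fs: float = 1000.0
    duration: float = 60.0
    mean_isi: dict = field(default_factory=lambda: dict(_DEFAULT_MEAN_ISI))
    isi_shape: float = 2.0                  # gamma shape of inter-switch intervals
    subject_rate_sigma: float = 0.8         # lognormal spread of per-subject rates
    rt_median: float = 0.3                  # s
    rt_sigma: float = 0.35                  # lognormal sigma of reaction times
    rt_max: float = 0.6                     # s; capped below shortest window (600 ms)
    effect_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_EFFECTS))
    tau_post: float = 0.1                   # s of effect persisting past the press
    background_exponent: float = 1.0        # 1/f^beta background
    band_limits: tuple = (1.0, 80.0)
    planted_fraction: float = 0.25          # posterior sensors carrying effects
    stim_band: tuple = (5.0, 7.0)           # Hz, stimulus-driven component
    stim_amplitude: float = 1.0             # relative to background RMS
    blank_period: float = 3.0               # s on / s off in blanking conditions
    effect_mode: str = "window"             # 'window' or 'drift'
    drift_len: float = 1.5                  # s of pre-switch ramp ('drift' mode)
    jolt_hold: float = 0.5                  # s of full post-press jolt ('drift' mode)
    jolt_tau: float = 0.5                   # s decay after the hold ('drift' mode)
    planted_regions: tuple | None = None    # source-space override

    def __post_init__(self):
        if any(v < 0 for v in self.effect_sizes.values()):
            raise ValueError("effect sizes must be nonnegative")
        if any(v <= 0 for v in self.mean_isi.values()):
            raise ValueError("mean inter-switch intervals must be positive")
        if self.effect_mode not in ("window", "drift"):
            raise ValueError(f"unknown effect_mode {self.effect_mode!r}")

    def subject_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_subjects))


def _block_seed(cfg: GenConfig, subject_index: int, condition: str,
                repetition: int, source: bool) -> np.random.SeedSequence:
    ckey = CONDITIONS.index(condition)
    return np.random.SeedSequence(
        entropy=cfg.seed,
        spawn_key=(subject_index, ckey, repetition, int(source)))


def _subject_rate_factor(cfg: GenConfig, subject_index: int) -> float:
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0xFACE, subject_index))
    rng = np.random.default_rng(ss)
    return float(np.exp(rng.normal(0.0, cfg.subject_rate_sigma)))


def _draw_events(rng: np.random.Generator, cfg: GenConfig, condition: str,
                 rate_factor: float) -> list[SwitchEvent]:
    mean_isi = cfg.mean_isi[condition] * rate_factor
    shape = cfg.isi_shape
    scale = mean_isi / shape
    events: list[SwitchEvent] = []
    t = float(rng.gamma(shape, scale))
    margin = 0.1
    while t < cfg.duration - margin:
        rt = float(np.exp(rng.normal(np.log(cfg.rt_median), cfg.rt_sigma)))
        rt = min(max(rt, 0.05), cfg.rt_max)
        press = t + rt
        if margin < t and press < cfg.duration - margin:
            # a long RT after a short inter-switch interval could invert
            # report order; such a report would mask the previous one
            if not events or press > events[-1].press_time:
                percept = "P1" if rng.random() < 0.5 else "P2"
                events.append(SwitchEvent(t, press, percept))
        t += float(rng.gamma(shape, scale))
    return events


def _effect_profile(cfg: GenConfig, events: Sequence[SwitchEvent],
                    n_samples: int) -> np.ndarray:
    """Per-sample state-modulation weight w(t) in [0, 1].

    'window' mode: w = 1 on [true_switch, press + tau_post).
    'drift' mode: linear ramp over ``drift_len`` s before the switch,
    1 through the press and for ``jolt_hold`` s after it, then an
    exponential tail with time constant ``jolt_tau`` s — emulating
    switch-related activity that builds up before the report and a
    post-press 'jolt' that decays after ~500 ms.
    """
    t = np.arange(n_samples) / cfg.fs
    w = np.zeros(n_samples)
    for ev in events:
        if cfg.effect_mode == "window":
            seg = (t >= ev.true_switch_time) & (t < ev.press_time + cfg.tau_post)
            w[seg] = 1.0
        else:
            ramp = (t >= ev.true_switch_time - cfg.drift_len) & (t < ev.true_switch_time)
            w[ramp] = np.maximum(
                w[ramp], 1.0 - (ev.true_switch_time - t[ramp]) / cfg.drift_len)
            hold_end = ev.press_time + cfg.jolt_hold
            core = (t >= ev.true_switch_time) & (t < hold_end)
            w[core] = 1.0
            tail = t >= hold_end
            w[tail] = np.maximum(w[tail], np.exp(-(t[tail] - hold_end) / cfg.jolt_tau))
    return w


def _shaped_noise_fft(rng: np.random.Generator, n_channels: int, n_samples: int,
                      fs: float, exponent: float,
                      band: tuple[float, float]) -> np.ndarray:
    """rFFT spectrum of band-limited 1/f^exponent Gaussian noise."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    amp[sel] = freqs[sel] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size)))
    return spec * amp


def _band_masks(n_samples: int, fs: float, lo: float, hi: float) -> dict[str, np.ndarray]:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    masks = {}
    for name, (b_lo, b_hi) in _BAND_EDGES.items():
        b_lo, b_hi = max(b_lo, lo), min(b_hi, hi)
        masks[name] = (freqs >= b_lo) & (freqs < b_hi)
    # keep the upper edge inclusive so [1, 80] is fully covered
    masks["upper_gamma"] |= np.isclose(freqs, hi)
    return masks


def _synth_channels(rng: np.random.Generator, cfg: GenConfig, n_channels: int,
                    planted: np.ndarray, n_samples: int,
                    w: np.ndarray) -> np.ndarray:
    """Background for all channels; planted channels get per-band state gains.

    Every channel's background is the same band-limited 1/f process.  For
    planted channels the spectrum is split into the six canonical bands,
    each band's time series is scaled by sqrt(1 + e_b * w(t)), and the
    bands are summed — so with w == 0 the planted and non-planted
    constructions are identical, and the in-window power of a planted
    band is (1 + e_b) times its baseline power in expectation.
    """
    lo, hi = cfg.band_limits
    spec = _shaped_noise_fft(rng, n_channels, n_samples, cfg.fs,
                             cfg.background_exponent, (lo, hi))
    planted_mask = np.zeros(n_channels, dtype=bool)
    planted_mask[planted] = True
    data = np.empty((n_channels, n_samples))
    data[~planted_mask] = np.fft.irfft(spec[~planted_mask], n=n_samples, axis=-1)
    if planted_mask.any():
        masks = _band_masks(n_samples, cfg.fs, lo, hi)
        out = np.zeros((int(planted_mask.sum()), n_samples))
        for band, bmask in masks.items():
            comp = np.fft.irfft(spec[planted_mask] * bmask, n=n_samples, axis=-1)
            e = cfg.effect_sizes.get(band, 0.0)
            gain = np.sqrt(1.0 + e * w) if e > 0 else 1.0
            out += comp * gain
        data[planted_mask] = out
    # normalize to unit-ish RMS so amplitudes are comparable across n_samples
    rms = np.sqrt(np.mean(data ** 2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return data / rms


def _stimulus_component(rng: np.random.Generator, cfg: GenConfig,
                        n_channels: int, n_samples: int,
                        condition: str) -> np.ndarray:
    spec = _shaped_noise_fft(rng, n_channels, n_samples, cfg.fs, 0.0, cfg.stim_band)
    comp = np.fft.irfft(spec, n=n_samples, axis=-1)
    rms = np.sqrt(np.mean(comp ** 2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    comp = comp / rms * cfg.stim_amplitude
    if condition_is_blanking(condition):
        t = np.arange(n_samples) / cfg.fs
        gate = (np.floor(t / cfg.blank_period) % 2) == 0   # on 3 s, off 3 s
        comp = comp * gate
    return comp


def generate_block(layout: SensorLayout, condition: str, cfg: GenConfig,
                   subject_index: int = 0, repetition: int = 0) -> RecordingBlock:
    """Generate one 60 s sensor-space recording block.

    The block is fully determined by (cfg.seed, subject_index, condition,
    repetition).  Posterior planted sensors receive the state-dependent
    band-power modulation and the (possibly blanked) stimulus-band
    component.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if layout.n_sensors == 0:
        raise ValueError("layout has no sensors")
    if cfg.duration < 1.0:
        raise ValueError("block duration too short to contain a switch event")
    rng = np.random.default_rng(_block_seed(cfg, subject_index, condition, repetition, False))
    rate = _subject_rate_factor(cfg, subject_index)
    events = _draw_events(rng, cfg, condition, rate)
    n_samples = int(round(cfg.fs * cfg.duration))
    planted = planted_sensor_indices(layout, cfg.planted_fraction)
    w = _effect_profile(cfg, events, n_samples)
    data = _synth_channels(rng, cfg, layout.n_sensors, planted, n_samples, w)
    stim = _stimulus_component(rng, cfg, len(planted), n_samples, condition)
    data[planted] += stim
    return RecordingBlock(data=data, fs=cfg.fs, duration=cfg.duration,
                          condition=condition, events=events,
                          subject_id=cfg.subject_ids()[subject_index]
                          if subject_index < cfg.n_subjects else f"S{subject_index + 1:02d}",
                          planted_sensors=planted)


def generate_source_block(condition: str, cfg: GenConfig,
                          subject_index: int = 0, repetition: int = 0) -> SourceBlock:
    """Generate one block of 89 anatomical-region time series.

    Stands in for beamformer source reconstruction: same event and
    spectral model as the sensor generator, with effects planted in
    parietal / occipital / cerebellar regions (or ``cfg.planted_regions``).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if cfg.duration < 1.0:
        raise ValueError("block duration too short to contain a switch event")
    rng = np.random.default_rng(_block_seed(cfg, subject_index, condition, repetition, True))
    rate = _subject_rate_factor(cfg, subject_index)
    events = _draw_events(rng, cfg, condition, rate)
    n_samples = int(round(cfg.fs * cfg.duration))
    labels = AAL89_REGIONS
    planted_labels = tuple(cfg.planted_regions) if cfg.planted_regions is not None \
        else default_planted_regions()
    unknown = set(planted_labels) - set(labels)
    if unknown:
        raise ValueError(f"unknown planted regions: {sorted(unknown)}")
    planted = np.array([labels.index(r) for r in planted_labels], dtype=int)
    w = _effect_profile(cfg, events, n_samples)
    data = _synth_channels(rng, cfg, len(labels), planted, n_samples, w)
    stim = _stimulus_component(rng, cfg, len(planted), n_samples, condition)
    data[planted] += stim
    return SourceBlock(data=data, region_labels=labels,
                       planted_regions=planted_labels, fs=cfg.fs,
                       duration=cfg.duration, condition=condition,
                       events=events,
                       subject_id=f"S{subject_index + 1:02d}")


def generate_dataset(cfg: GenConfig, space: str = "sensor",
                     layout: SensorLayout | None = None
                     ) -> Iterator[RecordingBlock | SourceBlock]:
    """Stream the full study: n_subjects x 6 conditions x n_repetitions blocks.

    Yields blocks one at a time (a default-size dataset does not fit in
    memory all at once).  Iteration order is subject-major, then
    condition in ``CONDITIONS`` order, then repetition.
    """
    if space not in ("sensor", "source"):
        raise ValueError("space must be 'sensor' or 'source'")
    if space == "sensor" and layout is None:
        layout = generate_layout(cfg.n_sensors, cfg.n_motor_excluded, seed=cfg.seed)
    for s in range(cfg.n_subjects):
        for cond in CONDITIONS:
            for rep in range(cfg.n_repetitions):
                if space == "sensor":
                    yield generate_block(layout, cond, cfg, s, rep)
                else:
                    yield generate_source_block(cond, cfg, s, rep)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def events_to_frame(blocks: Sequence[RecordingBlock | SourceBlock]) -> pd.DataFrame:
    """Tidy event table: one row per switch event across blocks."""
    rows = []
    for b_idx, blk in enumerate(blocks):
        for ev in blk.events:
            rows.append({
                "subject": blk.subject_id, "condition": blk.condition,
                "block": b_idx, "true_switch_time_s": ev.true_switch_time,
                "press_time_s": ev.press_time, "percept_after": ev.percept_after,
            })
    return pd.DataFrame(rows, columns=["subject", "condition", "block",
                                       "true_switch_time_s", "press_time_s",
                                       "percept_after"])


def export_events_tsv(blocks: Sequence[RecordingBlock | SourceBlock], path) -> None:
    events_to_frame(blocks).to_csv(path, sep="\t", index=False)


def save_dataset(cfg: GenConfig, path, space: str = "sensor") -> None:
    """Write a whole synthetic dataset to one HDF5 file, streaming blocks.

    Layout table, per-block data and event tables, and the generating
    configuration (JSON) are all embedded, so the file is self-describing.
    """
    layout = None
    if space == "sensor":
        layout = generate_layout(cfg.n_sensors, cfg.n_motor_excluded, seed=cfg.seed)
    with h5py.File(path, "w") as f:
        cfg_json = json.dumps(dataclasses.asdict(cfg), default=lambda o: list(o))
        f.attrs["gen_config"] = cfg_json
        f.attrs["space"] = space
        if layout is not None:
            g = f.create_group("layout")
            g.create_dataset("sensor_id", data=np.array(layout.sensor_id, dtype="S"))
            g.create_dataset("positions", data=layout.positions)
            g.create_dataset("hemisphere", data=np.array(layout.hemisphere, dtype="S"))
            g.create_dataset("motor_excluded", data=layout.motor_excluded)
        for i, blk in enumerate(generate_dataset(cfg, space=space, layout=layout)):
            g = f.create_group(f"blocks/{i:04d}")
            g.create_dataset("data", data=blk.data.astype(np.float32),
                             compression="gzip", compression_opts=1)
            g.attrs["fs"] = blk.fs
            g.attrs["duration"] = blk.duration
            g.attrs["condition"] = blk.condition
            g.attrs["subject_id"] = blk.subject_id
            ev = np.array([(e.true_switch_time, e.press_time, e.percept_after)
                           for e in blk.events],
                          dtype=[("true_switch_time", "f8"), ("press_time", "f8"),
                                 ("percept_after", "S2")])
            g.create_dataset("events", data=ev)
            if isinstance(blk, SourceBlock):
                g.create_dataset("region_labels",
                                 data=np.array(blk.region_labels, dtype="S"))


def load_dataset(path) -> tuple[SensorLayout | None, list[RecordingBlock | SourceBlock]]:
    """Read back a dataset written by :func:`save_dataset`."""
    blocks: list[RecordingBlock | SourceBlock] = []
    with h5py.File(path, "r") as f:
        space = f.attrs.get("space", "sensor")
        layout = None
        if "layout" in f:
            g = f["layout"]
            layout = SensorLayout(
                tuple(s.decode() for s in g["sensor_id"][()]),
                g["positions"][()],
                tuple(s.decode() for s in g["hemisphere"][()]),
                g["motor_excluded"][()].astype(bool))
        for key in sorted(f["blocks"]):
            g = f[f"blocks/{key}"]
            ev = [SwitchEvent(float(r["true_switch_time"]), float(r["press_time"]),
                              r["percept_after"].decode())
                  for r in g["events"][()]]
            common = dict(fs=float(g.attrs["fs"]), duration=float(g.attrs["duration"]),
                          condition=str(g.attrs["condition"]),
                          subject_id=str(g.attrs["subject_id"]), events=ev)
            data = g["data"][()].astype(np.float64)
            if space == "source":
                labels = tuple(s.decode() for s in g["region_labels"][()])
                blocks.append(SourceBlock(data=data, region_labels=labels,
                                          planted_regions=(), **common))
            else:
                blocks.append(RecordingBlock(data=data, **common))
    return layout, blocks
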