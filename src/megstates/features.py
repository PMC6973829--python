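"""Time-frequency band-energy features at several spatial scales.

The feature path: each channel is convolved with complex Morlet wavelets
on a logarithmic frequency grid spanning 1-80 Hz; squared coefficient
magnitudes are averaged over the frequency bins of each canonical band
(delta 1-4, theta 4-8, alpha 8-13, beta 13-30, lower gamma 30-50, upper
gamma 50-80 Hz); band energies are averaged over sensors at one of
several spatial scopes (all retained sensors, per hemisphere, or per
each of 10 Ward position clusters — source-region series skip spatial
averaging); and the time course is collapsed into L contiguous segment
means.  Motor-strip sensors are excluded before any averaging.

A Welch power-spectral-density feature set over the same bands and the
10 local clusters (no temporal segmentation) serves as a baseline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.cluster.hierarchy import fcluster, linkage

from .epochs import Epoch
from .synth import SensorLayout

__all__ = [
    "BAND_TABLE", "SENSOR_BANDS", "ALL_BANDS", "WaveletSpec", "FeatureVector",
    "morlet_kernel", "wavelet_transform", "band_energy",
    "ward_cluster_sensors", "spatial_average", "segment_average",
    "extract_features", "psd_features", "feature_matrix", "features_to_tsv",
]

#: Canonical band edges in Hz (half-open [lo, hi), last band closed at 80).
BAND_TABLE: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "lower_gamma": (30.0, 50.0),
    "upper_gamma": (50.0, 80.0),
}
ALL_BANDS: tuple[str, ...] = tuple(BAND_TABLE)
#: The four bands used for sensor-space classification.
SENSOR_BANDS: tuple[str, ...] = ("alpha", "beta", "lower_gamma", "upper_gamma")

SCOPES = ("global", "left-hemi", "right-hemi", "local-10", "source-89")


@dataclass(frozen=True)
class WaveletSpec:
    """Complex Morlet family: log-spaced frequencies and Gaussian widths.

    The kernel at frequency f is ``A * exp(-t^2 / 2 s^2) * exp(i 2 pi f t)``
    with ``A = 1 / (s sqrt(pi))^(1/2)`` and ``s = n_cycles / (2 pi f)``;
    seven cycles balance time and frequency resolution across 1-80 Hz.
    """

    fs: float = 1000.0
    f_min: float = 1.0
    f_max: float = 80.0
    n_freqs: int = 40
    n_cycles: float = 7.0
    support_sd: float = 4.0     # kernel covers +/- support_sd * s(f)
    frequencies: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.frequencies is None:
            freqs = np.logspace(np.log10(self.f_min), np.log10(self.f_max),
                                self.n_freqs)
            object.__setattr__(self, "frequencies", tuple(freqs))
        f = np.asarray(self.frequencies)
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be strictly increasing")

    def sd(self, f: float) -> float:
        """Gaussian width s(f) in seconds."""
        return self.n_cycles / (2 * np.pi * f)

    def amplitude(self, f: float) -> float:
        """Peak magnitude A = 1/(s sqrt(pi))^(1/2)."""
        return 1.0 / np.sqrt(self.sd(f) * np.sqrt(np.pi))

    def half_length(self, f: float) -> int:
        """Half kernel length in samples (support_sd standard deviations)."""
        return int(np.ceil(self.support_sd * self.sd(f) * self.fs))

    def band_bins(self, band: str) -> np.ndarray:
        """Indices of grid frequencies falling in a canonical band."""
        lo, hi = BAND_TABLE[band]
        f = np.asarray(self.frequencies)
        sel = (f >= lo) & (f < hi)
        if band == "upper_gamma":
            sel |= np.isclose(f, hi)
        return np.flatnonzero(sel)

    def band_counts(self) -> dict[str, int]:
        return {b: len(self.band_bins(b)) for b in BAND_TABLE}


def morlet_kernel(f: float, spec: WaveletSpec) -> np.ndarray:
    """Discrete complex Morlet kernel at frequency f, centred on t = 0."""
    if f <= 0:
        raise ValueError(f"wavelet frequency must be positive, got {f}")
    s = spec.sd(f)
    half = spec.half_length(f)
    t = np.arange(-half, half + 1) / spec.fs
    return spec.amplitude(f) * np.exp(-t ** 2 / (2 * s ** 2)) * np.exp(2j * np.pi * f * t)


def wavelet_transform(x: np.ndarray, spec: WaveletSpec,
                      frequencies: Sequence[float] | None = None) -> np.ndarray:
    """Sliding inner product of a signal with the Morlet family.

    Parameters
    ----------
    x : array, shape (..., n_samples)
        One or more channels; the transform runs along the last axis.
    frequencies : optional subset of ``spec.frequencies`` to compute.

    Returns
    -------
    Y : complex array, shape (n_freqs, ..., n_samples)
        Same time length as the input.  Samples within
        ``spec.half_length(f)`` of either edge see a truncated kernel;
        callers that care pad beforehand (see :func:`extract_features`).
    """
    x = np.asarray(x, dtype=float)
    freqs = spec.frequencies if frequencies is None else tuple(frequencies)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("signal too short for wavelet transform")
    out = np.empty((len(freqs),) + x.shape, dtype=complex)
    for i, f in enumerate(freqs):
        k = morlet_kernel(f, spec)
        # correlation with the kernel == convolution with its conjugate reverse
        kc = np.conj(k[::-1])
        shape = (1,) * (x.ndim - 1) + (len(kc),)
        out[i] = signal.fftconvolve(x, kc.reshape(shape), mode="same", axes=-1)
    return out


def band_energy(Y: np.ndarray, spec: WaveletSpec,
                bands: Sequence[str] = ALL_BANDS) -> np.ndarray:
    """Mean squared coefficient magnitude per band: Z(t, b).

    ``Y`` has frequencies on axis 0 (as produced by
    :func:`wavelet_transform` over the full grid); the result has shape
    ``(n_bands, ...) + time``.
    """
    power = np.abs(Y) ** 2
    out = np.empty((len(bands),) + Y.shape[1:])
    for i, b in enumerate(bands):
        bins = spec.band_bins(b)
        if bins.size == 0:
            raise ValueError(
                f"band {b!r} has no frequency bins on this grid; "
                "increase WaveletSpec.n_freqs")
        out[i] = power[bins].mean(axis=0)
    return out


def _band_energy_subset(x: np.ndarray, spec: WaveletSpec,
                        bands: Sequence[str]) -> np.ndarray:
    """Band energies computed only at the grid bins the bands need."""
    needed: list[float] = []
    slices: list[np.ndarray] = []
    for b in bands:
        bins = spec.band_bins(b)
        if bins.size == 0:
            raise ValueError(
                f"band {b!r} has no frequency bins on this grid; "
                "increase WaveletSpec.n_freqs")
        idx = np.arange(len(needed), len(needed) + bins.size)
        needed.extend(np.asarray(spec.frequencies)[bins])
        slices.append(idx)
    Y = wavelet_transform(x, spec, frequencies=needed)
    power = np.abs(Y) ** 2
    return np.stack([power[idx].mean(axis=0) for idx in slices])


def ward_cluster_sensors(layout: SensorLayout, k: int = 10) -> np.ndarray:
    """Group retained sensors into k clusters by Ward linkage on position.

    Returns an integer array over *all* layout sensors: cluster ids 1..k
    for retained sensors, 0 for motor-excluded ones.  Agglomeration uses
    Euclidean distances between 3-D positions with the Lance-Williams
    variance-minimising update; the result is deterministic for a given
    layout.
    """
    idx = np.flatnonzero(layout.retained)
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > idx.size:
        raise ValueError(f"cannot form {k} clusters from {idx.size} retained sensors")
    assign = np.zeros(layout.n_sensors, dtype=int)
    if k == idx.size:
        assign[idx] = np.arange(1, k + 1)
        return assign
    Z = linkage(layout.positions[idx], method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    assign[idx] = labels
    return assign


def spatial_average(Z: np.ndarray, layout: SensorLayout, scope: str,
                    clusters: np.ndarray | None = None) -> np.ndarray:
    """Average per-channel band energies over a spatial scope.

    ``Z`` has channels on axis -2 (shape ``(..., n_channels, n_time)``),
    aligned with ``layout``.  Motor-excluded sensors never enter any
    average.  Scope 'source-89' is the identity (region series are kept
    individually).
    """
    if scope == "source-89":
        return Z
    if Z.shape[-2] != layout.n_sensors:
        raise ValueError("channel axis does not match layout")
    retained = layout.retained
    if scope == "global":
        return Z[..., retained, :].mean(axis=-2, keepdims=True)
    if scope in ("left-hemi", "right-hemi"):
        side = "left" if scope == "left-hemi" else "right"
        mask = layout.hemisphere_mask(side)
        if not mask.any():
            raise ValueError(f"no retained sensors in hemisphere {side!r}")
        return Z[..., mask, :].mean(axis=-2, keepdims=True)
    if scope == "local-10":
        if clusters is None:
            clusters = layout.region_cluster
        if clusters is None:
            clusters = ward_cluster_sensors(layout, 10)
        k = int(clusters.max())
        out = [Z[..., clusters == c, :].mean(axis=-2) for c in range(1, k + 1)]
        return np.stack(out, axis=-2)
    raise ValueError(f"unknown scope {scope!r}")


def segment_average(Z: np.ndarray, L: int) -> np.ndarray:
    """Collapse the time axis into L contiguous equal segment means."""
    n = Z.shape[-1]
    if L <= 0:
        raise ValueError("L must be positive")
    if n % L:
        raise ValueError(f"{n} samples not divisible into {L} equal segments")
    return Z.reshape(Z.shape[:-1] + (L, n // L)).mean(axis=-1)


@dataclass
class FeatureVector:
    """Band x scope-element x segment energies with a coordinate index.

    Ordering contract: band-major, then scope element, then segment —
    ``values[(b * n_elem + e) * L + s]`` is (band b, element e, segment s).
    """
    values: np.ndarray
    index: list[tuple[str, str, int]]
    scope: str
    T: float
    L: int

    def __post_init__(self):
        if len(self.values) != len(self.index):
            raise ValueError("values and index lengths differ")

    def __len__(self) -> int:
        return len(self.values)


def _scope_element_names(scope: str, layout: SensorLayout | None,
                         n_elems: int, region_labels=None) -> list[str]:
    if scope == "global":
        return ["all"]
    if scope in ("left-hemi", "right-hemi"):
        return [scope.split("-")[0]]
    if scope == "local-10":
        return [f"cluster{c:02d}" for c in range(1, n_elems + 1)]
    if region_labels is not None:
        return list(region_labels)
    return [f"region{c:02d}" for c in range(n_elems)]


def extract_features(epoch: Epoch, layout: SensorLayout | None = None,
                     scope: str = "local-10",
                     bands: Sequence[str] = SENSOR_BANDS,
                     L: int = 4, spec: WaveletSpec | None = None,
                     clusters: np.ndarray | None = None,
                     region_labels: Sequence[str] | None = None) -> FeatureVector:
    """Full wavelet feature path for one epoch.

    The epoch is reflection-padded by the longest kernel half-length
    needed (capped at one sample short of the epoch length), transformed,
    band-averaged, spatially averaged at the requested scope, stripped of
    the padding, and segment-averaged into L values per (band, element).
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    if spec is None:
        spec = WaveletSpec(fs=epoch.fs)
    x = epoch.data
    n = x.shape[-1]
    if n % L:
        raise ValueError(f"epoch of {n} samples not divisible into L={L} segments")
    if scope != "source-89":
        if layout is None:
            raise ValueError("sensor scopes require a layout")
        keep = layout.retained
        # compute wavelets only on channels that can enter an average
        if scope == "local-10" and clusters is None:
            clusters = layout.region_cluster
            if clusters is None:
                clusters = ward_cluster_sensors(layout, 10)
    # pad by the longest kernel half-length among the requested bands,
    # capped so reflection padding stays valid on short epochs
    f_lo = min(float(np.asarray(spec.frequencies)[spec.band_bins(b)].min()) for b in bands)
    pad = min(spec.half_length(f_lo), n - 1)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    Z = _band_energy_subset(xp, spec, bands)          # (n_bands, n_ch, n_t+2p)
    Zs = spatial_average(Z, layout, scope, clusters) if scope != "source-89" else Z
    if pad:
        Zs = Zs[..., pad:-pad]
    seg = segment_average(Zs, L)                      # (n_bands, n_elem, L)
    n_elem = seg.shape[1]
    names = _scope_element_names(scope, layout, n_elem, region_labels)
    values = seg.reshape(-1)
    index = [(b, e, s) for b in bands for e in names for s in range(L)]
    return FeatureVector(values, index, scope, epoch.T, L)


def psd_features(epoch: Epoch, layout: SensorLayout,
                 bands: Sequence[str] = SENSOR_BANDS,
                 nperseg_ms: float = 500.0, overlap: float = 0.5,
                 clusters: np.ndarray | None = None) -> FeatureVector:
    """Welch-PSD baseline: band power per local cluster, no segmentation."""
    nperseg = int(round(nperseg_ms * epoch.fs / 1000.0))
    if nperseg > epoch.data.shape[-1]:
        raise ValueError("Welch segment length exceeds the epoch")
    noverlap = int(round(nperseg * overlap))
    freqs, pxx = signal.welch(epoch.data, fs=epoch.fs, nperseg=nperseg,
                              noverlap=noverlap, axis=-1)
    band_power = []
    for b in bands:
        lo, hi = BAND_TABLE[b]
        sel = (freqs >= lo) & (freqs < hi) if b != "upper_gamma" \
            else (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {b!r} empty on the Welch frequency grid")
        band_power.append(pxx[:, sel].mean(axis=-1))
    Z = np.stack(band_power)[..., None]               # (n_bands, n_ch, 1)
    Zs = spatial_average(Z, layout, "local-10", clusters)[..., 0]
    names = _scope_element_names("local-10", layout, Zs.shape[1])
    values = Zs.reshape(-1)
    index = [(b, e, 0) for b in bands for e in names]
    return FeatureVector(values, index, "local-10", epoch.T, 1)


def feature_matrix(epoch_set, layout: SensorLayout | None = None,
                   scope: str = "local-10", bands: Sequence[str] = SENSOR_BANDS,
                   L: int = 4, spec: WaveletSpec | None = None,
                   kind: str = "wavelet",
                   region_labels: Sequence[str] | None = None):
    """Stack per-epoch feature vectors into (X, y, index, meta).

    ``y`` is 1 for transition epochs, 0 for maintenance.  ``meta`` is a
    list of (condition, subject, label, offset) tuples aligned with rows.
    """
    clusters = None
    if scope == "local-10" and layout is not None:
        clusters = layout.region_cluster
        if clusters is None:
            clusters = ward_cluster_sensors(layout, 10)
    rows, labels, meta = [], [], []
    index = None
    for e in epoch_set:
        if kind == "wavelet":
            fv = extract_features(e, layout, scope, bands, L, spec,
                                  clusters=clusters, region_labels=region_labels)
        elif kind == "psd":
            fv = psd_features(e, layout, bands, clusters=clusters)
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
        rows.append(fv.values)
        labels.append(1 if e.label == "transition" else 0)
        meta.append((e.condition, e.subject_id, e.label, e.offset))
        index = fv.index
    X = np.asarray(rows) if rows else np.empty((0, 0))
    return X, np.asarray(labels, dtype=int), index, meta


def features_to_tsv(X: np.ndarray, index: Sequence[tuple], path,
                    spec: WaveletSpec | None = None,
                    layout: SensorLayout | None = None) -> None:
    """Write a feature matrix as TSV plus a JSON sidecar.

    Columns are named ``band|element|segment`` in the matrix's own order
    (the ordering contract: band-major, then scope element, then
    segment).  The sidecar records the wavelet family, band table,
    a layout hash, and the ordering contract, so a written matrix is
    self-describing.
    """
    path = Path(path)
    cols = [f"{b}|{e}|{s}" for b, e, s in index]
    pd.DataFrame(np.asarray(X), columns=cols).to_csv(path, sep="\t", index=False)
    sidecar = {
        "ordering": "band-major, then scope element, then segment",
        "bands": {b: list(r) for b, r in BAND_TABLE.items()},
    }
    if spec is not None:
        sidecar["wavelet"] = {"fs": spec.fs, "n_cycles": spec.n_cycles,
                              "frequencies": list(spec.frequencies)}
    if layout is not None:
        h = hashlib.sha256()
        h.update(layout.positions.tobytes())
        h.update(layout.motor_excluded.tobytes())
        sidecar["layout_sha256"] = h.hexdigest()
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
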