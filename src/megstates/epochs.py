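"""Epoch extraction around perceptual-switch reports.

Each retained button press contributes a *transition* epoch — the T ms
window immediately before the press — and a *maintenance* epoch — a T ms
window starting ``offset`` ms after the press.  Events whose maintenance
window overlaps the next event's transition window (or vice versa) are
rejected, and both implicated events are dropped so the two classes stay
paired.  Windows are half-open ``[start, end)`` in sample space; the
press sample belongs to the maintenance side, and a shared endpoint does
not count as overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synth import RecordingBlock, SourceBlock

__all__ = ["Epoch", "EpochSet", "extract_epochs", "retained_event_indices",
           "maintenance_subwindows", "pool_epochs", "epochs_manifest"]

log = logging.getLogger(__name__)

TRANSITION = "transition"
MAINTENANCE = "maintenance"


@dataclass
class Epoch:
    """A fixed-length labelled window of multichannel data."""
    data: np.ndarray          # (n_channels, n_samples)
    label: str                # transition / maintenance
    T: float                  # window length, ms
    offset: float             # window start relative to press, ms (signed)
    condition: str
    subject_id: str
    event_index: int = 0
    fs: float = 1000.0

    def __post_init__(self):
        expected = int(round(self.T * self.fs / 1000.0))
        if self.data.shape[-1] != expected:
            raise ValueError(
                f"epoch has {self.data.shape[-1]} samples, expected {expected}")
        if self.label not in (TRANSITION, MAINTENANCE):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class EpochSet:
    """A collection of epochs with provenance."""
    epochs: list[Epoch] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @property
    def T(self) -> float | None:
        return self.epochs[0].T if self.epochs else None

    def count(self, label: str) -> int:
        return sum(1 for e in self.epochs if e.label == label)

    def subset(self, condition: str | None = None,
               label: str | None = None) -> "EpochSet":
        keep = [e for e in self.epochs
                if (condition is None or e.condition == condition)
                and (label is None or e.label == label)]
        return EpochSet(keep, list(self.provenance))


def _overlaps(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """Strict positive-measure intersection of half-open intervals."""
    return max(a[0], b[0]) < min(a[1], b[1])


def retained_event_indices(press_times: Sequence[float], T_ms: float,
                           maintenance_offset_ms: float = 0.0,
                           duration_s: float | None = None,
                           rejection_horizon_ms: float | None = None
                           ) -> list[int]:
    """Indices of events surviving overlap and boundary rejection.

    ``rejection_horizon_ms`` widens the maintenance interval used in the
    overlap test (the temporal-evolution framework pools maintenance
    subwindows out to a horizon; all of them must be clean, so rejection
    is computed against ``[press + 0, press + horizon)``).  By default
    the tested maintenance interval is ``[press + offset, press + offset + T)``.
    """
    T = T_ms / 1000.0
    off = maintenance_offset_ms / 1000.0
    if rejection_horizon_ms is None:
        m_lo, m_hi = off, off + T
    else:
        m_lo, m_hi = 0.0, rejection_horizon_ms / 1000.0
    press = np.asarray(press_times, dtype=float)
    n = len(press)
    rejected = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        maint_i = (press[i] + m_lo, press[i] + m_hi)
        trans_next = (press[i + 1] - T, press[i + 1])
        if _overlaps(maint_i, trans_next):
            rejected[i] = rejected[i + 1] = True
    if duration_s is not None:
        for i in range(n):
            if press[i] - T < 0 or press[i] + max(m_hi, off + T) > duration_s:
                rejected[i] = True
    return [i for i in range(n) if not rejected[i]]


def extract_epochs(block: RecordingBlock | SourceBlock, T_ms: float,
                   maintenance_offset_ms: float = 0.0,
                   rejection_horizon_ms: float | None = None) -> EpochSet:
    """Cut paired transition/maintenance epochs out of one block.

    Transition epoch: ``[press - T, press)``; maintenance epoch:
    ``[press + offset, press + offset + T)``.  Overlap-rejected and
    boundary-exceeding events contribute nothing (both their epochs are
    dropped).
    """
    if T_ms <= 0:
        raise ValueError("T must be positive")
    n_win = T_ms * block.fs / 1000.0
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError(f"T = {T_ms} ms is not integral at fs = {block.fs} Hz")
    n_win = int(round(n_win))
    if T_ms / 1000.0 > block.duration:
        log.warning("window length %.0f ms exceeds block duration %.1f s; "
                    "returning empty epoch set", T_ms, block.duration)
        return EpochSet([], [f"{block.subject_id}:{block.condition}"])
    press = [e.press_time for e in block.events]
    keep = retained_event_indices(press, T_ms, maintenance_offset_ms,
                                  duration_s=block.duration,
                                  rejection_horizon_ms=rejection_horizon_ms)
    epochs: list[Epoch] = []
    for i in keep:
        p = int(round(press[i] * block.fs))
        o = int(round(maintenance_offset_ms * block.fs / 1000.0))
        trans = block.data[:, p - n_win:p]
        maint = block.data[:, p + o:p + o + n_win]
        common = dict(T=T_ms, condition=block.condition,
                      subject_id=block.subject_id, event_index=i, fs=block.fs)
        epochs.append(Epoch(np.array(trans), TRANSITION, offset=-T_ms, **common))
        epochs.append(Epoch(np.array(maint), MAINTENANCE,
                            offset=maintenance_offset_ms, **common))
    return EpochSet(epochs, [f"{block.subject_id}:{block.condition}"])


def maintenance_subwindows(T_ms: float, step_ms: float, horizon_ms: float) -> list[float]:
    """Offsets of shifted maintenance subwindows covering [press, horizon).

    Offsets are 0, step, 2*step, ... with ``offset + T <= horizon``.
    The canonical temporal-evolution setting (1200, 100, 1800) yields the
    seven offsets 0..600 ms.
    """
    if step_ms <= 0:
        raise ValueError("step must be positive")
    if T_ms > horizon_ms:
        raise ValueError(f"window T = {T_ms} ms exceeds horizon {horizon_ms} ms")
    n = int(np.floor((horizon_ms - T_ms) / step_ms + 1e-9)) + 1
    return [i * step_ms for i in range(n)]


def pool_epochs(sets: Sequence[EpochSet], condition: str | None = None) -> EpochSet:
    """Concatenate epoch sets (the 'ACT' pool), optionally filtering.

    Percept identity (P1/P2) was never attached to epochs — only the
    transition/maintenance label matters downstream.
    """
    lengths = {s.T for s in sets if len(s)}
    if len(lengths) > 1:
        raise ValueError(f"cannot pool epoch sets with mixed window lengths {sorted(lengths)}")
    pooled = EpochSet()
    for s in sets:
        for e in s.epochs:
            if condition is None or e.condition == condition:
                pooled.epochs.append(e)
        pooled.provenance.extend(s.provenance)
    return pooled


def epochs_manifest(epoch_set: EpochSet) -> pd.DataFrame:
    """TSV-ready manifest: one row per epoch."""
    rows = [{"epoch_id": i, "subject": e.subject_id, "condition": e.condition,
             "label": e.label, "offset_ms": e.offset, "event_index": e.event_index}
            for i, e in enumerate(epoch_set.epochs)]
    return pd.DataFrame(rows, columns=["epoch_id", "subject", "condition",
                                       "label", "offset_ms", "event_index"])
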