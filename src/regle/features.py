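"""Expert-defined features (EDFs) for spirograms and PPG pulses.

Spirometry: FEV1 (volume exhaled in the first second), FVC (total forced
volume), FEV1/FVC, PEF (peak flow) and FEF25–75% (mean flow over the
middle half of FVC).  PPG: presence/position of the dicrotic notch,
systolic peak position, shoulder (inflection) position, and
peak-to-peak distance to the dicrotic peak.  Biobank pipelines source
these from device fields; the extraction here follows the standard
conventions for discrete traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .core import WaveformRecord, volume_in_liters

__all__ = ["SpiroEDFs", "PPGEDFs", "spirogram_edfs", "ppg_edfs",
           "spirogram_edf_table", "ppg_edf_table"]

#: Minimum notch prominence as a fraction of pulse amplitude; makes
#: "absence of notch" decidable on noisy pulses.
NOTCH_PROMINENCE_FRACTION = 0.02


@dataclass
class SpiroEDFs:
    individual_id: str
    fev1: float
    fvc: float
    fev1_fvc: float
    pef: float
    fef25_75: float

    def __post_init__(self) -> None:
        if not (0.0 < self.fev1 <= self.fvc):
            raise ValueError("need 0 < fev1 <= fvc")
        if not (0.0 < self.fev1_fvc <= 1.0 + 1e-9):
            raise ValueError("fev1/fvc out of (0, 1]")
        if self.pef <= 0:
            raise ValueError("pef must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.fev1, self.fvc, self.fev1_fvc, self.pef, self.fef25_75])


@dataclass
class PPGEDFs:
    individual_id: str
    notch_absent: bool
    notch_pos: Optional[float]
    peak_pos: float
    shoulder_pos: Optional[float]
    peak_to_peak: Optional[float]

    def __post_init__(self) -> None:
        if self.notch_absent != (self.notch_pos is None):
            raise ValueError("notch_pos defined iff notch present")

    def as_array(self) -> np.ndarray:
        nan = float("nan")
        return np.array(
            [
                float(self.notch_absent),
                nan if self.notch_pos is None else self.notch_pos,
                self.peak_pos,
                nan if self.shoulder_pos is None else self.shoulder_pos,
                nan if self.peak_to_peak is None else self.peak_to_peak,
            ]
        )


def spirogram_edfs(volume: WaveformRecord, flow: WaveformRecord) -> SpiroEDFs:
    """Extract the five spirometry EDFs from paired normalized curves.

    FEV1 is the volume at t = 1 s (linear interpolation); FEF25–75% is
    the mean instantaneous flow over the interval where volume lies in
    [0.25 FVC, 0.75 FVC] — equivalent to the volume-over-time definition
    on exact traces and robust on discrete ones.
    """
    if volume.dt is None:
        raise ValueError("volume record lacks a sampling step")
    vol = volume_in_liters(volume)
    fvc = float(vol.max())
    if fvc <= 0:
        raise ValueError("nonpositive FVC")
    t = np.arange(len(vol)) * volume.dt
    fev1 = float(np.interp(1.0, t, vol))
    pef = float(flow.values.max())
    mid = (vol >= 0.25 * fvc) & (vol <= 0.75 * fvc)
    fef = float(flow.values[mid].mean()) if np.any(mid) else float("nan")
    return SpiroEDFs(
        individual_id=volume.individual_id,
        fev1=fev1,
        fvc=fvc,
        fev1_fvc=fev1 / fvc,
        pef=pef,
        fef25_75=fef,
    )


def _interior_minima(pulse: np.ndarray, start: int, prominence: float):
    """Indices and prominences of local minima of pulse[start:] (interior)."""
    seg = -pulse[start:]
    idx, props = find_peaks(seg, prominence=prominence)
    return idx + start, props["prominences"]


def ppg_edfs(pulse: WaveformRecord) -> PPGEDFs:
    """Landmark features of a single 100-point pulse.

    The notch is the most prominent interior local minimum after the
    systolic peak (absent when none reaches 2% of pulse amplitude); the
    dicrotic peak is the largest local maximum after the notch; the
    shoulder is the inflection (second-difference zero crossing) between
    systolic peak and notch.  When no notch exists, notch-dependent
    positions are undefined and the shoulder is the first inflection
    after the peak.
    """
    raw = pulse.values
    if len(raw) != 100:
        raise ValueError("PPG pulses must have exactly 100 points")
    amplitude = float(raw.max() - raw.min())
    if amplitude <= 0:
        raise ValueError("flat pulse has no landmarks")
    # light smoothing stabilizes landmark detection on noisy pulses
    v = savgol_filter(raw, window_length=7, polyorder=2)
    peak_pos = int(np.argmax(v))

    floor = NOTCH_PROMINENCE_FRACTION * amplitude
    min_idx, prominences = _interior_minima(v, peak_pos + 1, floor)
    if len(min_idx) == 0:
        notch_pos = None
        peak_to_peak = None
        search_end = len(v) - 1
    else:
        notch_pos = int(min_idx[np.argmax(prominences)])
        after = v[notch_pos:]
        max_idx, _ = find_peaks(after)
        if len(max_idx) == 0:  # plateau or monotone tail: take segment argmax
            dicrotic = notch_pos + int(np.argmax(after))
        else:
            dicrotic = notch_pos + int(max_idx[np.argmax(after[max_idx])])
        peak_to_peak = float(dicrotic - peak_pos)
        search_end = notch_pos

    d2 = np.diff(v, 2)  # second difference; index i covers v[i:i+3]
    shoulder_pos = None
    for i in range(peak_pos, min(search_end - 1, len(d2) - 1)):
        if d2[i] <= 0.0 <= d2[i + 1] or d2[i] >= 0.0 >= d2[i + 1]:
            if d2[i] != d2[i + 1]:
                shoulder_pos = float(i + 1)
                break

    return PPGEDFs(
        individual_id=pulse.individual_id,
        notch_absent=notch_pos is None,
        notch_pos=None if notch_pos is None else float(notch_pos),
        peak_pos=float(peak_pos),
        shoulder_pos=shoulder_pos,
        peak_to_peak=peak_to_peak,
    )


def spirogram_edf_table(edfs) -> pd.DataFrame:
    """Stack SpiroEDFs into an id-indexed table (fev1..fef25_75)."""
    rows = {
        e.individual_id: [e.fev1, e.fvc, e.fev1_fvc, e.pef, e.fef25_75] for e in edfs
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["fev1", "fvc", "fev1_fvc", "pef", "fef25_75"]
    )


def ppg_edf_table(edfs) -> pd.DataFrame:
    """Stack PPGEDFs into an id-indexed table (notch_absent..peak_to_peak)."""
    rows = {e.individual_id: e.as_array() for e in edfs}
    return pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["notch_absent", "notch_pos", "peak_pos", "shoulder_pos", "peak_to_peak"],
    )
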