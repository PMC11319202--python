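"""Spirogram and PPG quality control and normalization.

Implements the standard biobank preparation for forced-expiration
curves: finite-difference flow, truncation/right-padding to 1,000 time
points, cohort-percentile tail filtering of FEV1/FVC/PEF, hard range
gates on flow (−10, 20) L/s and volume (−5, 10) L, a ≥20% nonzero-flow
requirement, first-acceptable-blow selection, and flow–volume
interpolation onto 1,000 evenly spaced volumes in [0, 6.58] L.  PPG
pulses are filtered on min/max/mean/median falling inside the cohort's
[0.1, 99.9] percentile bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import WaveformRecord, volume_in_liters

__all__ = [
    "QCReport",
    "CohortStats",
    "volume_to_flow",
    "normalize_length",
    "qc_spirogram",
    "qc_ppg",
    "select_first_acceptable",
    "flow_volume_interpolate",
    "split_cohort",
    "spirogram_cohort_stats",
    "ppg_cohort_stats",
]

#: QC failure reasons
REASONS = (
    "edf_tail",
    "flow_range",
    "volume_range",
    "nonzero_fraction",
    "acceptability",
    "ppg_stat_tail",
)

FLOW_RANGE = (-10.0, 20.0)  # L/s, open interval
VOLUME_RANGE = (-5.0, 10.0)  # L, open interval
NONZERO_MIN_FRACTION = 0.20
SPIRO_TAIL = 0.005  # top/bottom 0.5% of FEV1, FVC, PEF
PPG_TAIL = 0.001  # top/bottom 0.1% of min/max/mean/median


@dataclass
class QCReport:
    individual_id: str
    passed: bool
    reasons: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = self.reasons - set(REASONS)
        if bad:
            raise ValueError(f"unknown QC reasons: {bad}")
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed flag inconsistent with reasons")


@dataclass
class CohortStats:
    """Central percentile bands per summary statistic.

    ``bands`` maps a statistic name (fev1/fvc/pef for spirograms;
    min/max/mean/median for PPG) to its inclusive [lower, upper]
    acceptance interval, computed from the cohort's empirical
    distribution with linear-interpolation quantiles.
    """

    bands: Dict[str, Tuple[float, float]]

    def within(self, stat: str, value: float) -> bool:
        lo, hi = self.bands[stat]
        return lo <= value <= hi


def _central_band(values: Sequence[float], tail: float) -> Tuple[float, float]:
    # order-statistic bounds, inclusive: reproducible at ties
    v = np.asarray(values, dtype=float)
    lo = np.quantile(v, tail, method="lower")
    hi = np.quantile(v, 1.0 - tail, method="higher")
    return float(lo), float(hi)


def spirogram_cohort_stats(
    fev1: Sequence[float], fvc: Sequence[float], pef: Sequence[float]
) -> CohortStats:
    """Acceptance bands excluding the top/bottom 0.5% of each statistic."""
    return CohortStats(
        bands={
            "fev1": _central_band(fev1, SPIRO_TAIL),
            "fvc": _central_band(fvc, SPIRO_TAIL),
            "pef": _central_band(pef, SPIRO_TAIL),
        }
    )


def ppg_cohort_stats(pulses: np.ndarray) -> CohortStats:
    """Bands excluding the top/bottom 0.1% of min/max/mean/median."""
    pulses = np.asarray(pulses, dtype=float)
    stats = {
        "min": pulses.min(axis=1),
        "max": pulses.max(axis=1),
        "mean": pulses.mean(axis=1),
        "median": np.median(pulses, axis=1),
    }
    return CohortStats(
        bands={k: _central_band(v, PPG_TAIL) for k, v in stats.items()}
    )


def volume_to_flow(v: WaveformRecord) -> WaveformRecord:
    """Forward finite-difference flow (L/s) from a volume–time curve.

    Raw biobank volumes are in milliliters at 10-ms steps; records with
    ``units == "mL"`` are converted so the flow is always in L/s.  The
    last difference is repeated to preserve length.
    """
    if v.channel != "volume_time":
        raise ValueError("volume_to_flow expects a volume_time record")
    if v.dt is None:
        raise ValueError("volume record lacks a sampling step")
    if len(v) < 2:
        raise ValueError("need at least two samples to differentiate")
    vol_l = volume_in_liters(v)
    flow = np.diff(vol_l) / v.dt
    flow = np.concatenate([flow, flow[-1:]])
    return WaveformRecord(
        individual_id=v.individual_id,
        channel="flow_time",
        values=flow,
        dt=v.dt,
        acceptability=v.acceptability,
        blow_index=v.blow_index,
    )


def normalize_length(w: WaveformRecord, n: int = 1000) -> WaveformRecord:
    """Truncate or right-pad to exactly ``n`` points.

    Longer curves keep their first ``n`` values.  Shorter flow–time
    curves are right-padded with zeros; shorter volume–time curves with
    their final value (the blow has ended, volume stays at FVC).
    """
    if w.channel not in ("volume_time", "flow_time"):
        raise ValueError("normalize_length applies to time-domain curves")
    if len(w) == 0:
        raise ValueError("empty waveform")
    if len(w) == n:
        return w
    if len(w) > n:
        return w.with_values(w.values[:n])
    pad_value = 0.0 if w.channel == "flow_time" else float(w.values[-1])
    padded = np.concatenate([w.values, np.full(n - len(w), pad_value)])
    return w.with_values(padded)


def qc_spirogram(
    flow: WaveformRecord,
    volume: WaveformRecord,
    edfs,
    stats: CohortStats,
) -> QCReport:
    """Apply all spirogram gates; every violated reason is reported.

    Gate order: acceptability flag, hard flow/volume ranges, nonzero-flow
    fraction, cohort EDF tails (FEV1/FVC/PEF within the central 99%).
    """
    if flow.individual_id != volume.individual_id:
        raise ValueError("flow/volume records belong to different individuals")
    reasons: Set[str] = set()
    if not flow.acceptability or not volume.acceptability:
        reasons.add("acceptability")
    lo, hi = FLOW_RANGE
    if np.any(flow.values <= lo) or np.any(flow.values >= hi):
        reasons.add("flow_range")
    vol_l = volume_in_liters(volume)
    lo, hi = VOLUME_RANGE
    if np.any(vol_l <= lo) or np.any(vol_l >= hi):
        reasons.add("volume_range")
    if np.mean(flow.values != 0.0) < NONZERO_MIN_FRACTION:
        reasons.add("nonzero_fraction")
    for stat, value in (("fev1", edfs.fev1), ("fvc", edfs.fvc), ("pef", edfs.pef)):
        if not stats.within(stat, value):
            reasons.add("edf_tail")
    return QCReport(
        individual_id=flow.individual_id, passed=not reasons, reasons=reasons
    )


def qc_ppg(pulse: WaveformRecord, stats: CohortStats) -> QCReport:
    """Keep a pulse only when min/max/mean/median all sit inside the bands."""
    if len(pulse) != 100:
        raise ValueError("PPG pulses must have exactly 100 points")
    v = pulse.values
    observed = {
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "median": float(np.median(v)),
    }
    reasons: Set[str] = set()
    if any(not stats.within(k, x) for k, x in observed.items()):
        reasons.add("ppg_stat_tail")
    return QCReport(
        individual_id=pulse.individual_id, passed=not reasons, reasons=reasons
    )


def select_first_acceptable(
    blows: Sequence[WaveformRecord],
) -> Optional[WaveformRecord]:
    """First blow (by blow_index order) with a true acceptability flag.

    Returns None when no blow is acceptable — the individual is excluded
    rather than an error raised.
    """
    if len(blows) == 0:
        raise ValueError("no blows supplied")
    for blow in sorted(blows, key=lambda b: b.blow_index):
        if blow.acceptability:
            return blow
    return None


def flow_volume_interpolate(
    flow: WaveformRecord,
    volume: WaveformRecord,
    n: int = 1000,
    v_max: float = 6.58,
) -> WaveformRecord:
    """Flow–volume curve on ``n`` evenly spaced volumes in [0, v_max] L.

    The volume trace is made nondecreasing by a cumulative maximum before
    inversion; grid volumes beyond the blow's final volume get flow 0.
    """
    vol_l = volume_in_liters(volume)
    if np.all(vol_l == 0.0):
        raise ValueError("all-zero volume trace")
    if len(flow) != len(vol_l):
        raise ValueError("flow and volume lengths differ")
    vol_mono = np.maximum.accumulate(vol_l)
    grid = np.linspace(0.0, v_max, n)
    interp = np.interp(grid, vol_mono, flow.values)
    interp[grid > vol_mono[-1]] = 0.0
    return WaveformRecord(
        individual_id=flow.individual_id,
        channel="flow_volume",
        values=interp,
        dt=None,
        acceptability=flow.acceptability,
        blow_index=flow.blow_index,
    )


def split_cohort(
    ids: Sequence[str],
    frac: float = 0.8,
    exclusions: Optional[Iterable[str]] = None,
    seed: int = 0,
) -> Tuple[List[str], List[str]]:
    """Deterministic train/validation split after removing exclusions.

    ``exclusions`` stands in for related-individual removal, which is
    supplied externally as an id list rather than computed from kinship.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError("frac must lie in (0, 1)")
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    excl = set(exclusions or ())
    kept = [i for i in ids if i not in excl]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(kept))
    n_train = int(round(frac * len(kept)))
    train = [kept[i] for i in sorted(order[:n_train])]
    valid = [kept[i] for i in sorted(order[n_train:])]
    return train, valid
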