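"""Shared containers for waveforms and genotype panels."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Recognised waveform channels.
CHANNELS = ("volume_time", "flow_time", "flow_volume", "ppg")


@dataclass
class WaveformRecord:
    """One individual's curve on a uniform grid.

    ``values`` for spirometry channels are volume (mL or L, see ``units``)
    or flow (L/s); PPG pulses are in arbitrary units.  ``dt`` is the
    sampling step in seconds (10 ms for spirograms); it is absent for
    flow–volume curves, which live on a volume grid.
    """

    individual_id: str
    channel: str
    values: np.ndarray
    dt: Optional[float] = None
    acceptability: bool = True
    blow_index: int = 0
    units: str = "L"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("waveform values must be finite")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray, **overrides) -> "WaveformRecord":
        kw = dict(
            individual_id=self.individual_id,
            channel=self.channel,
            values=values,
            dt=self.dt,
            acceptability=self.acceptability,
            blow_index=self.blow_index,
            units=self.units,
        )
        kw.update(overrides)
        return WaveformRecord(**kw)


VARIANT_COLUMNS = [
    "chromosome",
    "position",
    "id",
    "ref",
    "alt",
    "frequency",
    "info",
    "missing_rate",
]


@dataclass
class GenotypePanel:
    """n x M additive dosage matrix with per-variant metadata.

    Dosages count copies of the ``alt`` allele and lie in [0, 2].
    ``variants`` carries chromosome, position, id, ref, alt, alt-allele
    frequency, imputation INFO and missing call fraction.  Positions are
    sorted within chromosome.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variants table missing columns: {missing}")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage columns and variant rows disagree")
        if len(self.sample_ids) == 0:
            self.sample_ids = [f"ind_{i}" for i in range(self.dosages.shape[0])]
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def M(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, mask_or_idx) -> "GenotypePanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def column(self, variant_id: str) -> np.ndarray:
        j = self.variants.index[self.variants["id"] == variant_id]
        if len(j) == 0:
            raise KeyError(variant_id)
        return self.dosages[:, int(j[0])]


def volume_in_liters(record: WaveformRecord) -> np.ndarray:
    """Volume trace converted to liters regardless of stored units."""
    if record.channel not in ("volume_time",):
        raise ValueError("expected a volume_time record")
    if record.units == "mL":
        return record.values / 1000.0
    return record.values
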