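"""Readers and writers for the plain-text interchange formats.

Curves travel as long-format CSV (id, channel, index, value); genotypes
as TSV dosage matrices with a variant metadata sidecar, or VCF with a DS
FORMAT field; summary statistics, effect files, scores and QC reports as
TSV; loci as BED (0-based half-open) plus a richer TSV.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenotypePanel
from .assoc import Locus, loci_table

__all__ = [
    "read_curves_long",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "read_vcf_dosage",
    "write_effects_tsv",
    "read_effects_tsv",
    "write_loci_bed",
]


def read_curves_long(path) -> Dict[str, pd.DataFrame]:
    """Long CSV -> {channel: wide DataFrame (ids x index)}."""
    long = pd.read_csv(path)
    required = {"id", "channel", "index", "value"}
    if not required.issubset(long.columns):
        raise ValueError(f"curve file must have columns {sorted(required)}")
    out = {}
    for channel, grp in long.groupby("channel"):
        wide = grp.pivot(index="id", columns="index", values="value")
        out[str(channel)] = wide.sort_index(axis=1)
    return out


def write_dosage_tsv(panel: GenotypePanel, dosage_path, variants_path) -> None:
    pd.DataFrame(
        panel.dosages, index=list(panel.sample_ids), columns=panel.variants["id"]
    ).to_csv(dosage_path, sep="\t")
    panel.variants.to_csv(variants_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path, variants_path) -> GenotypePanel:
    dosages = pd.read_csv(dosage_path, sep="\t", index_col=0)
    variants = pd.read_csv(variants_path, sep="\t")
    return GenotypePanel(
        dosages=dosages.to_numpy(dtype=float),
        variants=variants,
        sample_ids=list(dosages.index.astype(str)),
    )


def read_vcf_dosage(path) -> GenotypePanel:
    """Genotype panel from a VCF carrying a DS (dosage) FORMAT field.

    Falls back to summing GT allele counts when DS is absent.
    """
    from cyvcf2 import VCF  # deferred: only needed for this dialect

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    cols = []
    for var in vcf:
        try:
            ds = var.format("DS")
            dose = np.asarray(ds, dtype=float).reshape(-1)
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2/3(unknown)
            dose = np.where(gt == 3, np.nan, np.where(gt == 2, 2.0, gt))
        cols.append(dose)
        rows.append(
            {
                "chromosome": int(str(var.CHROM).lstrip("chr") or 0),
                "position": int(var.POS),
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "frequency": float(np.nanmean(dose)) / 2.0,
                "info": float(var.INFO.get("INFO", 1.0)),
                "missing_rate": float(np.mean(np.isnan(dose))),
            }
        )
    dosages = np.column_stack(cols) if cols else np.zeros((len(samples), 0))
    return GenotypePanel(
        dosages=np.nan_to_num(dosages),
        variants=pd.DataFrame(rows),
        sample_ids=samples,
    )


def write_effects_tsv(effects, path) -> None:
    effects.table.to_csv(path, sep="\t", index=False)


def read_effects_tsv(path):
    from .prs import CoordinateEffects

    return CoordinateEffects(pd.read_csv(path, sep="\t"))


def write_loci_bed(loci: Sequence[Locus], bed_path, tsv_path=None) -> None:
    """Loci as BED (0-based half-open) and optionally a rich TSV."""
    with open(bed_path, "w") as fh:
        for l in loci:
            fh.write(f"chr{l.chromosome}\t{l.start - 1}\t{l.end}\t{l.lead_id}\n")
    if tsv_path is not None:
        loci_table(loci).to_csv(tsv_path, sep="\t", index=False)
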