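"""Per-bin count validation and copy-number normalization.

GC correction uses stratified medians over 2%-wide GC strata with linear
interpolation between stratum centers — deterministic and dependency
light.  After correction the profile is scaled so the autosomal median
copy number is 2; a euploid XY sample therefore lands near 1 on chrX.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nics.genome import GenomeModel

GC_STRATUM_WIDTH = 0.02


@dataclass(frozen=True)
class BinCounts:
    sample_id: str
    counts: np.ndarray = field(repr=False)
    n_bins: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        if self.n_bins and counts.size != self.n_bins:
            raise ValueError(f"expected {self.n_bins} bins, got {counts.size}")


@dataclass(frozen=True)
class CopyProfile:
    sample_id: str
    copy_number: np.ndarray = field(repr=False)
    weight: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cn = np.asarray(self.copy_number, dtype=float)
        if (cn < 0).any() or not np.isfinite(cn).all():
            raise ValueError("copy_number must be finite and non-negative")


def load_bin_counts(path: str | Path, genome: GenomeModel) -> BinCounts:
    """Read and validate a bin-counts TSV against the genome's bins.

    The file must match the genome bin-for-bin (count, order and
    coordinates); the first discrepancy is named in the error.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) != genome.n_bins:
        raise ValueError(
            f"{path}: expected {genome.n_bins} bins, found {len(df)}"
        )
    for col, ref in (("chrom", genome.bin_chrom), ("start", genome.bin_start), ("end", genome.bin_end)):
        vals = df[col].to_numpy()
        mismatch = np.flatnonzero(vals != ref)
        if mismatch.size:
            i = int(mismatch[0])
            raise ValueError(
                f"{path}: bin {i} ({genome.bin_chrom[i]}:{genome.bin_start[i]}-"
                f"{genome.bin_end[i]}) has {col}={vals[i]!r}, expected {ref[i]!r}"
            )
    counts = df["count"].to_numpy()
    if (counts < 0).any():
        i = int(np.flatnonzero(counts < 0)[0])
        raise ValueError(f"{path}: negative count at bin {i}")
    sample_id = Path(path).stem
    return BinCounts(sample_id=sample_id, counts=counts, n_bins=genome.n_bins)


def _gc_expected(rates: np.ndarray, gc: np.ndarray, fit_mask: np.ndarray) -> np.ndarray:
    """Expected rate per bin from stratified GC medians, linearly smoothed."""
    edges = np.arange(0.0, 1.0 + GC_STRATUM_WIDTH, GC_STRATUM_WIDTH)
    centers = (edges[:-1] + edges[1:]) / 2
    idx = np.clip(np.digitize(gc, edges) - 1, 0, len(centers) - 1)
    med_centers, med_values = [], []
    for s in range(len(centers)):
        sel = fit_mask & (idx == s)
        if sel.sum() >= 3:
            med_centers.append(centers[s])
            med_values.append(np.median(rates[sel]))
    if not med_centers:
        return np.full_like(rates, np.median(rates[fit_mask]))
    return np.interp(gc, med_centers, med_values)


def gc_normalize(counts: BinCounts, genome: GenomeModel) -> CopyProfile:
    """GC-corrected copy-number profile scaled to autosomal median 2."""
    raw = counts.counts.astype(float)
    if raw.sum() <= 0:
        raise ValueError("all-zero counts: cannot normalize")
    width = genome.bin_width_frac
    usable = (genome.mappability > 0) & (width > 0)
    rates = np.zeros_like(raw)
    rates[usable] = raw[usable] / (width[usable] * np.maximum(genome.mappability[usable], 1e-12))
    fit_mask = usable & genome.is_autosome
    expected = _gc_expected(rates, genome.gc, fit_mask)
    corrected = np.divide(rates, expected, out=np.zeros_like(rates), where=expected > 0)
    autosomal_median = np.median(corrected[fit_mask])
    if autosomal_median <= 0:
        raise ValueError("degenerate profile: autosomal median is zero")
    cn = corrected * (2.0 / autosomal_median)
    return CopyProfile(sample_id=counts.sample_id, copy_number=cn, weight=width * usable)


def reference_normalize(
    profile: CopyProfile, reference: list[CopyProfile], genome: GenomeModel
) -> CopyProfile:
    """Divide by a euploid panel's per-bin median to remove recurrent
    positional bias; output rescaled to autosomal median 2.

    A panel of >= 5 euploid profiles is recommended; an empty panel is
    rejected.  Only autosomes are corrected: a mixed-sex panel's per-bin
    median on chrX/chrY is a meaningless mixture of one- and two-copy
    baselines, so sex chromosomes pass through unchanged.
    """
    if not reference:
        raise ValueError("reference panel is empty")
    panel = np.vstack([r.copy_number for r in reference])
    if panel.shape[1] != profile.copy_number.size:
        raise ValueError("reference profiles are on a different genome")
    med = np.median(panel, axis=0)
    factor = np.where(genome.is_autosome & (med > 0.4), med / 2.0, 1.0)
    factor = np.clip(factor, 0.3, 3.0)
    cn = profile.copy_number / factor
    auto = genome.is_autosome & (profile.weight > 0)
    m = np.median(cn[auto])
    if m <= 0:
        raise ValueError("degenerate profile after reference normalization")
    return CopyProfile(
        sample_id=profile.sample_id, copy_number=cn * (2.0 / m), weight=profile.weight
    )
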