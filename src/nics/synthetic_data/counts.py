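"""Negative-binomial read-count simulation over genome bins.

Per-bin expected counts are proportional to
``local copy number x gc_bias(gc) x mappability x bin width``, where the
local copy number under an event with mosaic fraction ``m`` and copy
change ``d`` is ``base*(1-m) + (base+d)*m = base + d*m`` (autosomal base
2; chrX/chrY base from the embryo sex).  The embryo profile is mixed with
a diploid XX contamination profile at the truth's contamination fraction,
then scaled so the expected total equals the requested depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from nics._util import as_rng
from nics.genome import GenomeModel
from nics.synthetic_data.karyotype import EmbryoTruth


@dataclass(frozen=True)
class GCBias:
    """Unimodal quadratic coverage-rate curve: rate = 1 - a*(gc - peak)^2."""

    peak: float = 0.45
    curvature: float = 8.0
    floor: float = 0.1

    def __call__(self, gc: np.ndarray) -> np.ndarray:
        return np.maximum(self.floor, 1.0 - self.curvature * (np.asarray(gc) - self.peak) ** 2)

    @classmethod
    def flat(cls) -> "GCBias":
        return cls(peak=0.45, curvature=0.0)


def _baseline_copy(genome: GenomeModel, sex: str) -> np.ndarray:
    base = np.full(genome.n_bins, 2.0)
    x = genome.bin_chrom == "chrX"
    y = genome.bin_chrom == "chrY"
    if sex == "XX":
        base[y] = 0.0
    else:
        base[x] = 1.0
        base[y] = 1.0
    return base


def expected_copy_number(truth: EmbryoTruth, genome: GenomeModel) -> np.ndarray:
    """Per-bin local copy number implied by the truth's events (no mixing)."""
    cn = _baseline_copy(genome, truth.sex)
    for ev in truth.events:
        bins = genome.bins_in(ev.chromosome, ev.start, ev.end)
        cn[bins] += ev.copy_change * ev.mosaic_fraction
    return np.maximum(cn, 0.0)


def simulate_read_counts(
    truth: EmbryoTruth,
    genome: GenomeModel,
    depth: int = 2_000_000,
    gc_bias: GCBias | None = None,
    dispersion: float = 0.05,
    rng: np.random.Generator | int | None = None,
):
    """Draw one sample's per-bin counts; returns a ``BinCounts``.

    ``dispersion`` is the negative-binomial alpha (variance = mu + alpha*mu^2);
    must be positive.  ``depth`` is the expected library size; depth 0 yields
    all-zero counts.
    """
    from nics.cnv_calling.profiles import BinCounts

    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = as_rng(rng)
    if gc_bias is None:
        gc_bias = GCBias()

    embryo_cn = expected_copy_number(truth, genome)
    c = truth.contamination_fraction
    if c > 0:
        contaminant = _baseline_copy(genome, "XX")
        cn = (1 - c) * embryo_cn + c * contaminant
    else:
        cn = embryo_cn

    rel = cn * gc_bias(genome.gc) * genome.mappability * genome.bin_width_frac
    total = rel.sum()
    if depth == 0 or total <= 0:
        counts = np.zeros(genome.n_bins, dtype=np.int64)
    else:
        mu = depth * rel / total
        size = 1.0 / dispersion
        p = size / (size + np.maximum(mu, 1e-300))
        counts = np.where(mu > 0, rng.negative_binomial(size, p), 0).astype(np.int64)
    return BinCounts(sample_id=truth.embryo_id, counts=counts, n_bins=genome.n_bins)


def write_bin_counts(counts, genome: GenomeModel, path: str | Path) -> None:
    """TSV with header ``chrom start end gc count`` (0-based half-open)."""
    df = pd.DataFrame(
        {
            "chrom": genome.bin_chrom,
            "start": genome.bin_start,
            "end": genome.bin_end,
            "gc": np.round(genome.gc, 6),
            "count": counts.counts,
        }
    )
    df.to_csv(path, sep="\t", index=False)
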