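"""Genome geometry: chromosomes, 1 Mb bins, arms, and per-bin GC.

The :class:`GenomeModel` is the shared coordinate frame for simulation,
normalization, segmentation and feature extraction.  Bins tile each
chromosome in order with no overlap; the final bin of a chromosome may be
shorter than ``bin_size``.  Arm membership (p/q) is a pure function of the
bin midpoint relative to the centromere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

DEFAULT_BIN_SIZE = 1_000_000

SEX_CHROMOSOMES = ("chrX", "chrY")


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: name, total length and centromere midpoint (bp)."""

    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if not 0 < self.centromere < self.length:
            raise ValueError(
                f"{self.name}: centromere {self.centromere} outside chromosome "
                f"(0, {self.length})"
            )


@dataclass(frozen=True)
class GenomeModel:
    """Tiled-bin view of a genome.

    Per-bin arrays are parallel and genome-ordered (chromosomes in the
    configured order, bins left to right within a chromosome).
    """

    chromosomes: tuple[Chromosome, ...]
    bin_size: int
    bin_chrom: np.ndarray = field(repr=False)  # str per bin
    bin_start: np.ndarray = field(repr=False)  # int bp, 0-based
    bin_end: np.ndarray = field(repr=False)  # int bp, half-open
    gc: np.ndarray = field(repr=False)  # fraction in [0, 1]
    mappability: np.ndarray = field(repr=False)  # weight >= 0
    arm: np.ndarray = field(repr=False)  # 'p' or 'q' per bin

    @property
    def n_bins(self) -> int:
        return int(self.bin_start.size)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.chromosomes)

    @property
    def is_autosome(self) -> np.ndarray:
        return ~np.isin(self.bin_chrom, SEX_CHROMOSOMES)

    @property
    def bin_width_frac(self) -> np.ndarray:
        """Bin width as a fraction of bin_size (< 1 for trailing bins)."""
        return (self.bin_end - self.bin_start) / self.bin_size

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def chrom_slice(self, name: str) -> slice:
        idx = np.flatnonzero(self.bin_chrom == name)
        if idx.size == 0:
            raise KeyError(name)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def bins_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of bins whose midpoint falls in [start, end)."""
        mid = (self.bin_start + self.bin_end) / 2
        return np.flatnonzero((self.bin_chrom == chrom) & (mid >= start) & (mid < end))

    def arm_bounds(self, chrom: str, arm: str) -> tuple[int, int]:
        c = self.chromosome(chrom)
        if arm == "p":
            return 0, c.centromere
        if arm == "q":
            return c.centromere, c.length
        raise ValueError(f"unknown arm {arm!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.bin_chrom,
                "start": self.bin_start,
                "end": self.bin_end,
                "gc": self.gc,
                "mappability": self.mappability,
                "arm": self.arm,
            }
        )


def _smooth_gc(chrom_index: int, n: int) -> np.ndarray:
    """Deterministic smooth GC profile along one chromosome.

    A low-frequency sinusoid mixture with a chromosome-specific phase;
    purely synthetic but smooth, bounded and reproducible.
    """
    t = (np.arange(n) + 0.5) / max(n, 1)
    phase = 2.0 * np.pi * (chrom_index % 24) / 24.0
    gc = (
        0.42
        + 0.05 * np.sin(2 * np.pi * 2 * t + phase)
        + 0.03 * np.cos(2 * np.pi * 5 * t + 0.7 * phase)
    )
    return np.clip(gc, 0.30, 0.58)


def _default_config() -> dict:
    with resources.files("nics").joinpath("data/default_genome.yaml").open() as fh:
        return yaml.safe_load(fh)


def make_genome(
    config: dict | str | Path | None = None, bin_size: int | None = None
) -> GenomeModel:
    """Build a :class:`GenomeModel` from a config mapping / YAML path.

    ``config`` may be ``None`` (bundled human-like default), a path to a
    YAML file, or a mapping with keys ``chromosomes`` (list of
    ``{name, length, centromere}``) and optionally ``bin_size``.
    Deterministic given the config.
    """
    if config is None:
        cfg = _default_config()
    elif isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    if bin_size is None:
        bin_size = int(cfg.get("bin_size", DEFAULT_BIN_SIZE))
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")

    chroms = tuple(
        Chromosome(str(c["name"]), int(c["length"]), int(c["centromere"]))
        for c in cfg["chromosomes"]
    )
    if len({c.name for c in chroms}) != len(chroms):
        raise ValueError("duplicate chromosome names")

    chrom_col: list[str] = []
    start_col: list[int] = []
    end_col: list[int] = []
    gc_col: list[np.ndarray] = []
    arm_col: list[str] = []
    for ci, c in enumerate(chroms):
        n = int(np.ceil(c.length / bin_size))
        starts = np.arange(n, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, c.length)
        chrom_col.extend([c.name] * n)
        start_col.extend(starts.tolist())
        end_col.extend(ends.tolist())
        gc_col.append(_smooth_gc(ci, n))
        mids = (starts + ends) / 2
        arm_col.extend(["p" if m < c.centromere else "q" for m in mids])

    return GenomeModel(
        chromosomes=chroms,
        bin_size=bin_size,
        bin_chrom=np.asarray(chrom_col, dtype=object),
        bin_start=np.asarray(start_col, dtype=np.int64),
        bin_end=np.asarray(end_col, dtype=np.int64),
        gc=np.concatenate(gc_col) if gc_col else np.empty(0),
        mappability=np.ones(len(chrom_col)),
        arm=np.asarray(arm_col, dtype=object),
    )
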