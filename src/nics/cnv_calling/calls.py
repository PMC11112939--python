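"""Mosaicism estimation, sex calling, resolution classing and CNV calls.

Under the single-aberrant-copy model a segment at mean copy number c on
an autosome corresponds to a mosaic fraction min(|c - 2|, 1).  Segments
whose fraction clears ``call_margin`` and whose span is at least
``min_size_mb`` (default 10, the analysis resolution floor) become calls.

Per-chromosome resolution class (coverage rule): whole_chromosome when
calls cover >= 90% of the chromosome's bins, arm when they cover >= 90%
of exactly one arm, segmental otherwise, euploid with no calls.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from nics.cnv_calling.cbs import Segment
from nics.cnv_calling.profiles import CopyProfile
from nics.genome import GenomeModel

DEFAULT_CALL_MARGIN = 0.3
DEFAULT_MIN_SIZE_MB = 10.0
SEX_DEVIATION_LIMIT = 0.35
COVERAGE_RULE_FRACTION = 0.9

RESOLUTION_EUPLOID = "euploid"
RESOLUTION_SEGMENTAL = "segmental"
RESOLUTION_ARM = "arm"
RESOLUTION_WHOLE = "whole_chromosome"

_SEX_EXPECTATIONS = {"XX": {"chrX": 2.0, "chrY": 0.0}, "XY": {"chrX": 1.0, "chrY": 1.0}}


def estimate_mosaicism(
    mean_copy_number: float,
    expected: float = 2.0,
    call_margin: float = DEFAULT_CALL_MARGIN,
) -> tuple[float, str]:
    """(mosaic fraction, direction) for a segment mean.

    fraction = min(|mean - expected|, 1); direction is gain/loss only when
    the deviation clears the call margin, neutral otherwise.
    """
    dev = mean_copy_number - expected
    frac = min(abs(dev), 1.0)
    if dev > call_margin:
        return frac, "gain"
    if dev < -call_margin:
        return frac, "loss"
    return frac, "neutral"


@dataclass(frozen=True)
class Call:
    """A reported (non-neutral, size-filtered) copy-number event."""

    chromosome: str
    start_bin: int
    end_bin: int
    mean_copy_number: float
    mosaic_fraction: float
    direction: str
    length_mb: float
    scope: str  # resolution class of its chromosome


@dataclass(frozen=True)
class CNVCallSet:
    sample_id: str
    calls: tuple[Call, ...]
    resolution_class: dict = field(default_factory=dict)  # chrom -> class
    sex_call: str = "XX"  # XX / XY / abnormal

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "calls": [asdict(c) for c in self.calls],
            "resolution_class": dict(self.resolution_class),
            "sex_call": self.sex_call,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CNVCallSet":
        return cls(
            sample_id=d["sample_id"],
            calls=tuple(Call(**c) for c in d.get("calls", [])),
            resolution_class=dict(d.get("resolution_class", {})),
            sex_call=d.get("sex_call", "XX"),
        )


def infer_sex_call(
    segments: list[Segment], genome: GenomeModel
) -> tuple[str, dict[str, float], str]:
    """(sex_call, per-chromosome medians, best-fit baseline sex).

    The call is abnormal when the chrX/chrY medians deviate by more than
    0.35 copies from both the XX and the XY expectation.
    """
    medians: dict[str, float] = {}
    for chrom in ("chrX", "chrY"):
        if chrom not in genome.chrom_names:
            continue
        segs = [s for s in segments if s.chromosome == chrom]
        if not segs:
            medians[chrom] = 0.0
            continue
        vals = np.concatenate(
            [np.full(s.n_bins, s.mean_copy_number) for s in segs]
        )
        medians[chrom] = float(np.median(vals))
    devs = {
        sex: sum(abs(medians.get(ch, exp[ch]) - exp[ch]) for ch in exp if ch in medians)
        for sex, exp in _SEX_EXPECTATIONS.items()
    }
    fits = {
        sex: all(
            abs(medians.get(ch, exp[ch]) - exp[ch]) <= SEX_DEVIATION_LIMIT
            for ch in exp
            if ch in medians
        )
        for sex, exp in _SEX_EXPECTATIONS.items()
    }
    best = min(devs, key=lambda s: devs[s])  # ties resolve to XX (dict order)
    if fits["XX"] and (not fits["XY"] or devs["XX"] <= devs["XY"]):
        return "XX", medians, "XX"
    if fits["XY"]:
        return "XY", medians, "XY"
    return "abnormal", medians, best


def _resolution_class(
    chrom_calls: list[Call], genome: GenomeModel, chrom: str
) -> str:
    if not chrom_calls:
        return RESOLUTION_EUPLOID
    sl = genome.chrom_slice(chrom)
    covered = np.zeros(sl.stop - sl.start, dtype=bool)
    for c in chrom_calls:
        covered[c.start_bin - sl.start : c.end_bin - sl.start] = True
    if covered.mean() >= COVERAGE_RULE_FRACTION:
        return RESOLUTION_WHOLE
    arms = genome.arm[sl]
    arm_cov = []
    for arm in ("p", "q"):
        mask = arms == arm
        if mask.sum() == 0:
            continue
        arm_cov.append(covered[mask].mean() >= COVERAGE_RULE_FRACTION)
    if sum(arm_cov) == 1:
        return RESOLUTION_ARM
    return RESOLUTION_SEGMENTAL


def call_cnvs(
    segments: list[Segment],
    genome: GenomeModel,
    call_margin: float = DEFAULT_CALL_MARGIN,
    min_size_mb: float = DEFAULT_MIN_SIZE_MB,
    sample_id: str = "sample",
) -> CNVCallSet:
    """Filter segments into calls and class each chromosome's resolution."""
    sex_call, _, baseline_sex = infer_sex_call(segments, genome)
    expectations = _SEX_EXPECTATIONS[baseline_sex]

    prelim: dict[str, list[Call]] = {}
    for seg in segments:
        expected = expectations.get(seg.chromosome, 2.0)
        frac, direction = estimate_mosaicism(
            seg.mean_copy_number, expected=expected, call_margin=call_margin
        )
        if direction == "neutral" or seg.length_mb < min_size_mb:
            continue
        prelim.setdefault(seg.chromosome, []).append(
            Call(
                chromosome=seg.chromosome,
                start_bin=seg.start_bin,
                end_bin=seg.end_bin,
                mean_copy_number=seg.mean_copy_number,
                mosaic_fraction=frac,
                direction=direction,
                length_mb=seg.length_mb,
                scope=RESOLUTION_SEGMENTAL,
            )
        )

    calls: list[Call] = []
    resolution: dict[str, str] = {}
    for chrom in genome.chrom_names:
        chrom_calls = prelim.get(chrom, [])
        cls = _resolution_class(chrom_calls, genome, chrom)
        resolution[chrom] = cls
        scope = cls if cls != RESOLUTION_EUPLOID else RESOLUTION_SEGMENTAL
        for c in chrom_calls:
            calls.append(
                Call(
                    chromosome=c.chromosome,
                    start_bin=c.start_bin,
                    end_bin=c.end_bin,
                    mean_copy_number=c.mean_copy_number,
                    mosaic_fraction=c.mosaic_fraction,
                    direction=c.direction,
                    length_mb=c.length_mb,
                    scope=scope,
                )
            )
    return CNVCallSet(
        sample_id=sample_id,
        calls=tuple(calls),
        resolution_class=resolution,
        sex_call=sex_call,
    )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_bins", "mean_cn", "mosaic_est", "direction"]


def write_seg(
    segments: list[Segment], genome: GenomeModel, sample_id: str, path: str | Path
) -> None:
    """SEG-style TSV of all segments (bp coordinates, half-open)."""
    rows = [
        {
            "sample": sample_id,
            "chrom": s.chromosome,
            "start": int(genome.bin_start[s.start_bin]),
            "end": int(genome.bin_end[s.end_bin - 1]),
            "n_bins": s.n_bins,
            "mean_cn": round(s.mean_copy_number, 4),
            "mosaic_est": round(s.mosaic_fraction_estimate, 4),
            "direction": s.direction,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing SEG columns {missing}")
    return df


def write_callsets(callsets: list[CNVCallSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([cs.to_dict() for cs in callsets], fh, indent=1, sort_keys=True)


def read_callsets(path: str | Path) -> list[CNVCallSet]:
    with open(path) as fh:
        return [CNVCallSet.from_dict(d) for d in json.load(fh)]
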