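"""The 11-feature vector consumed by the euploidy-probability classifier.

Per resolution (10 Mb segmental, arm, whole chromosome) there is a raw
ordinal call and a call redefined by a 50% mosaicism threshold; the
remaining features count euploid resolutions and abnormal chromosomes,
summarize the highest mosaic fraction and its largest fragment, and flag
sex-chromosome abnormality.

Ordinal encoding: euploid = 0, mosaic_abnormal = 1, full_abnormal = 2.
The boundary at exactly the redefinition threshold counts as abnormal
(inclusive >= rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from nics.cnv_calling.calls import (
    CNVCallSet,
    RESOLUTION_ARM,
    RESOLUTION_SEGMENTAL,
    RESOLUTION_WHOLE,
)

EUPLOID = 0
MOSAIC_ABNORMAL = 1
FULL_ABNORMAL = 2

#: fraction at/above which an (un-redefined) call counts as a full abnormality
DEFAULT_FULL_THRESHOLD = 0.8
#: the redefinition threshold: below -> euploid, at/above -> full abnormality
DEFAULT_REDEFINE_THRESHOLD = 0.5

RESOLUTIONS = (RESOLUTION_SEGMENTAL, RESOLUTION_ARM, RESOLUTION_WHOLE)

FEATURE_NAMES = [
    "f1_cnv_10mb",
    "f2_cnv_10mb_redef",
    "f3_cnv_arm",
    "f4_cnv_arm_redef",
    "f5_cnv_chrom",
    "f6_cnv_chrom_redef",
    "f7_euploid_resolution_count",
    "f8_abnormal_chrom_count",
    "f9_max_mosaic_fraction",
    "f10_largest_fragment_at_max_mosaic_mb",
    "f11_sex_chrom_abnormal",
]


@dataclass(frozen=True)
class EmbryoFeatures:
    embryo_id: str
    f1_cnv_10mb: int
    f2_cnv_10mb_redef: int
    f3_cnv_arm: int
    f4_cnv_arm_redef: int
    f5_cnv_chrom: int
    f6_cnv_chrom_redef: int
    f7_euploid_resolution_count: int
    f8_abnormal_chrom_count: int
    f9_max_mosaic_fraction: float
    f10_largest_fragment_at_max_mosaic_mb: float
    f11_sex_chrom_abnormal: bool

    def as_array(self) -> np.ndarray:
        vec = np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)
        if vec.size != 11 or not np.isfinite(vec).all():
            raise ValueError("feature vector must have 11 finite entries")
        return vec


def _fractions_at(callset: CNVCallSet, resolution: str) -> list[float]:
    if resolution not in RESOLUTIONS:
        raise ValueError(f"unknown resolution {resolution!r}")
    return [c.mosaic_fraction for c in callset.calls if c.scope == resolution]


def calls_at_resolution(
    callset: CNVCallSet,
    resolution: str,
    full_threshold: float = DEFAULT_FULL_THRESHOLD,
) -> int:
    """Worst ordinal call among events at the given resolution."""
    fracs = _fractions_at(callset, resolution)
    if any(f >= full_threshold for f in fracs):
        return FULL_ABNORMAL
    if fracs:
        return MOSAIC_ABNORMAL
    return EUPLOID


def redefine_by_threshold(
    callset: CNVCallSet,
    resolution: str,
    threshold: float = DEFAULT_REDEFINE_THRESHOLD,
) -> int:
    """Resolution call after the mosaicism redefinition.

    Events below the threshold are treated as euploid, events at/above it
    as full abnormalities; idempotent by construction.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    fracs = _fractions_at(callset, resolution)
    if any(f >= threshold for f in fracs):
        return FULL_ABNORMAL
    return EUPLOID


def extract_features(
    callset: CNVCallSet,
    full_threshold: float = DEFAULT_FULL_THRESHOLD,
    redefine_threshold: float = DEFAULT_REDEFINE_THRESHOLD,
) -> EmbryoFeatures:
    raw = {r: calls_at_resolution(callset, r, full_threshold) for r in RESOLUTIONS}
    redef = {r: redefine_by_threshold(callset, r, redefine_threshold) for r in RESOLUTIONS}
    f7 = sum(1 for r in RESOLUTIONS if redef[r] == EUPLOID)
    chroms = {c.chromosome for c in callset.calls}
    f8 = len(chroms)
    if callset.calls:
        f9 = max(c.mosaic_fraction for c in callset.calls)
        at_max = [c for c in callset.calls if c.mosaic_fraction >= f9 - 1e-12]
        f10 = max(c.length_mb for c in at_max)
    else:
        f9 = 0.0
        f10 = 0.0
    return EmbryoFeatures(
        embryo_id=callset.sample_id,
        f1_cnv_10mb=raw[RESOLUTION_SEGMENTAL],
        f2_cnv_10mb_redef=redef[RESOLUTION_SEGMENTAL],
        f3_cnv_arm=raw[RESOLUTION_ARM],
        f4_cnv_arm_redef=redef[RESOLUTION_ARM],
        f5_cnv_chrom=raw[RESOLUTION_WHOLE],
        f6_cnv_chrom_redef=redef[RESOLUTION_WHOLE],
        f7_euploid_resolution_count=f7,
        f8_abnormal_chrom_count=f8,
        f9_max_mosaic_fraction=float(f9),
        f10_largest_fragment_at_max_mosaic_mb=float(f10),
        f11_sex_chrom_abnormal=callset.sex_call == "abnormal",
    )


def features_to_frame(features: list[EmbryoFeatures]) -> pd.DataFrame:
    rows = [
        {"embryo_id": f.embryo_id, **{n: getattr(f, n) for n in FEATURE_NAMES}}
        for f in features
    ]
    df = pd.DataFrame(rows, columns=["embryo_id", *FEATURE_NAMES])
    df["f11_sex_chrom_abnormal"] = df["f11_sex_chrom_abnormal"].astype(int)
    return df


def write_features_csv(features: list[EmbryoFeatures], path: str | Path) -> None:
    features_to_frame(features).to_csv(path, index=False)


def read_features_csv(path: str | Path) -> list[EmbryoFeatures]:
    df = pd.read_csv(path)
    missing = [c for c in ("embryo_id", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature columns {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            EmbryoFeatures(
                embryo_id=str(row["embryo_id"]),
                f1_cnv_10mb=int(row["f1_cnv_10mb"]),
                f2_cnv_10mb_redef=int(row["f2_cnv_10mb_redef"]),
                f3_cnv_arm=int(row["f3_cnv_arm"]),
                f4_cnv_arm_redef=int(row["f4_cnv_arm_redef"]),
                f5_cnv_chrom=int(row["f5_cnv_chrom"]),
                f6_cnv_chrom_redef=int(row["f6_cnv_chrom_redef"]),
                f7_euploid_resolution_count=int(row["f7_euploid_resolution_count"]),
                f8_abnormal_chrom_count=int(row["f8_abnormal_chrom_count"]),
                f9_max_mosaic_fraction=float(row["f9_max_mosaic_fraction"]),
                f10_largest_fragment_at_max_mosaic_mb=float(
                    row["f10_largest_fragment_at_max_mosaic_mb"]
                ),
                f11_sex_chrom_abnormal=bool(row["f11_sex_chrom_abnormal"]),
            )
        )
    return out
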