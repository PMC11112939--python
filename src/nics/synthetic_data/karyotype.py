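"""Embryo karyotype simulation.

Events are single-copy gains/losses (copy_change in {-1, +1}) at one of
three scopes: whole chromosome, one arm, or a segmental span of at least
10 Mb.  Each event carries a mosaic fraction in (0, 1]; a fraction of 1
means a non-mosaic (full) event.

Labeling rule: an embryo is labeled aneuploid iff it carries any event
with mosaic fraction >= 0.5; lower-fraction mosaics are treated as
euploid-compatible for training purposes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from nics._util import as_rng
from nics.genome import GenomeModel, SEX_CHROMOSOMES

SCOPE_WHOLE = "whole_chromosome"
SCOPE_ARM = "arm"
SCOPE_SEGMENTAL = "segmental"
SCOPES = (SCOPE_WHOLE, SCOPE_ARM, SCOPE_SEGMENTAL)

MIN_SEGMENTAL_MB = 10.0

#: mosaic fraction at/above which an embryo is labeled aneuploid
ANEUPLOID_LABEL_THRESHOLD = 0.5


@dataclass(frozen=True)
class KaryotypeEvent:
    """One copy-number event on one chromosome (bp, half-open)."""

    chromosome: str
    start: int
    end: int
    copy_change: int  # -1 loss, +1 gain
    mosaic_fraction: float  # (0, 1]
    scope: str

    def __post_init__(self) -> None:
        if self.copy_change not in (-1, 1):
            raise ValueError("copy_change must be -1 or +1")
        if not 0 < self.mosaic_fraction <= 1:
            raise ValueError("mosaic_fraction must be in (0, 1]")
        if self.scope not in SCOPES:
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.scope == SCOPE_SEGMENTAL and self.span_mb < MIN_SEGMENTAL_MB:
            raise ValueError(
                f"segmental event spans {self.span_mb:.1f} Mb < {MIN_SEGMENTAL_MB} Mb"
            )

    @property
    def span_mb(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass(frozen=True)
class EmbryoTruth:
    embryo_id: str
    sex: str  # "XX" or "XY"
    events: tuple[KaryotypeEvent, ...]
    contamination_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.sex not in ("XX", "XY"):
            raise ValueError("sex must be XX or XY")
        if not 0 <= self.contamination_fraction < 1:
            raise ValueError("contamination_fraction must be in [0, 1)")
        by_chrom: dict[str, list[KaryotypeEvent]] = {}
        for ev in self.events:
            by_chrom.setdefault(ev.chromosome, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping events on {chrom}")

    @property
    def label_euploid(self) -> bool:
        return not any(
            ev.mosaic_fraction >= ANEUPLOID_LABEL_THRESHOLD for ev in self.events
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["events"] = [asdict(ev) for ev in self.events]
        d["label_euploid"] = self.label_euploid
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EmbryoTruth":
        events = tuple(
            KaryotypeEvent(
                chromosome=e["chromosome"],
                start=int(e["start"]),
                end=int(e["end"]),
                copy_change=int(e["copy_change"]),
                mosaic_fraction=float(e["mosaic_fraction"]),
                scope=e["scope"],
            )
            for e in d.get("events", ())
        )
        return cls(
            embryo_id=d["embryo_id"],
            sex=d["sex"],
            events=events,
            contamination_fraction=float(d.get("contamination_fraction", 0.0)),
        )


def write_truths(truths: list[EmbryoTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in truths], fh, indent=1, sort_keys=True)


def read_truths(path: str | Path) -> list[EmbryoTruth]:
    with open(path) as fh:
        return [EmbryoTruth.from_dict(d) for d in json.load(fh)]


@dataclass(frozen=True)
class KaryotypeParams:
    """Event-rate configuration for :func:`simulate_karyotype`."""

    p_euploid: float = 0.45
    #: relative weights of whole-chromosome / arm / segmental events
    scope_weights: tuple[float, float, float] = (0.55, 0.2, 0.25)
    #: probability that an event is non-mosaic (fraction exactly 1)
    p_full: float = 0.45
    mosaic_range: tuple[float, float] = (0.1, 0.95)
    p_second_event: float = 0.25
    p_xx: float = 0.5
    segment_span_mb: tuple[float, float] = (10.0, 45.0)
    contamination_range: tuple[float, float] = (0.0, 0.0)
    p_sex_chrom_event: float = 0.08

    def __post_init__(self) -> None:
        if not 0 <= self.p_euploid <= 1:
            raise ValueError("p_euploid must be in [0, 1]")
        if min(self.scope_weights) < 0 or sum(self.scope_weights) <= 0:
            raise ValueError("scope_weights must be non-negative, not all zero")
        if self.segment_span_mb[0] < MIN_SEGMENTAL_MB:
            raise ValueError(
                f"segmental spans below {MIN_SEGMENTAL_MB} Mb are not representable"
            )
        lo, hi = self.mosaic_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("mosaic_range must satisfy 0 < lo <= hi <= 1")


def _draw_fraction(rng: np.random.Generator, params: KaryotypeParams) -> float:
    if rng.random() < params.p_full:
        return 1.0
    lo, hi = params.mosaic_range
    return float(rng.uniform(lo, hi))


def _draw_event(
    rng: np.random.Generator,
    params: KaryotypeParams,
    genome: GenomeModel,
    chrom: str,
) -> KaryotypeEvent:
    c = genome.chromosome(chrom)
    w = np.asarray(params.scope_weights, dtype=float)
    scope = str(rng.choice(list(SCOPES), p=w / w.sum()))
    # chromosomes too short for a legal segmental/arm event fall back to whole
    if scope == SCOPE_SEGMENTAL and c.length < MIN_SEGMENTAL_MB * 1e6:
        scope = SCOPE_WHOLE
    change = -1 if rng.random() < 0.5 else 1
    frac = _draw_fraction(rng, params)
    if scope == SCOPE_WHOLE:
        start, end = 0, c.length
    elif scope == SCOPE_ARM:
        arm = "p" if rng.random() < 0.5 else "q"
        start, end = genome.arm_bounds(chrom, arm)
    else:
        lo, hi = params.segment_span_mb
        hi = min(hi, c.length / 1e6)
        span = int(rng.uniform(lo, hi) * 1e6)
        start = int(rng.integers(0, c.length - span + 1))
        end = start + span
    return KaryotypeEvent(chrom, start, end, change, frac, scope)


def simulate_karyotype(
    rng: np.random.Generator | int | None,
    params: KaryotypeParams,
    genome: GenomeModel,
    embryo_id: str = "embryo",
) -> EmbryoTruth:
    """Draw one embryo's karyotype; reproducible given the rng state."""
    rng = as_rng(rng)
    sex = "XX" if rng.random() < params.p_xx else "XY"
    clo, chi = params.contamination_range
    contamination = float(rng.uniform(clo, chi)) if chi > clo else float(clo)
    events: list[KaryotypeEvent] = []
    if rng.random() >= params.p_euploid:
        n_events = 1 + int(rng.random() < params.p_second_event)
        autos = [c.name for c in genome.chromosomes if c.name not in SEX_CHROMOSOMES]
        sexes = [c.name for c in genome.chromosomes if c.name in SEX_CHROMOSOMES]
        pool = list(autos)
        if sexes and rng.random() < params.p_sex_chrom_event:
            pool = sexes  # first event lands on a sex chromosome
        chroms = list(rng.choice(autos, size=n_events, replace=False))
        if pool is not autos:
            chroms[0] = str(rng.choice(pool))
        for chrom in dict.fromkeys(chroms):  # de-dup, order-preserving
            events.append(_draw_event(rng, params, genome, str(chrom)))
    return EmbryoTruth(
        embryo_id=embryo_id,
        sex=sex,
        events=tuple(events),
        contamination_fraction=contamination,
    )


def truth_to_callset(
    truth: EmbryoTruth,
    genome: GenomeModel,
    fraction_noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    call_margin: float = 0.3,
    min_size_mb: float = 10.0,
):
    """Convert a simulated truth directly into a CNV call set.

    Shortcut used for generating large labeled training cohorts without
    read-level simulation: each event becomes a call with an optionally
    noised mosaic-fraction estimate, filtered with the same margin and
    size floor the calling pipeline applies.
    """
    from nics.cnv_calling.calls import Call, CNVCallSet

    rng = as_rng(rng)
    calls: list[Call] = []
    classes: dict[str, str] = {c.name: "euploid" for c in genome.chromosomes}
    sex_abnormal = False
    for ev in truth.events:
        frac = ev.mosaic_fraction
        if fraction_noise_sd > 0:
            frac = float(np.clip(frac + rng.normal(0, fraction_noise_sd), 0.0, 1.0))
        if ev.chromosome in SEX_CHROMOSOMES and frac >= call_margin:
            sex_abnormal = True
        if frac < call_margin or ev.span_mb < min_size_mb:
            continue
        bins = genome.bins_in(ev.chromosome, ev.start, ev.end)
        if bins.size == 0:
            continue
        calls.append(
            Call(
                chromosome=ev.chromosome,
                start_bin=int(bins[0]),
                end_bin=int(bins[-1]) + 1,
                mean_copy_number=2.0 + ev.copy_change * frac,
                mosaic_fraction=frac,
                direction="gain" if ev.copy_change > 0 else "loss",
                length_mb=ev.span_mb,
                scope=ev.scope,
            )
        )
        classes[ev.chromosome] = ev.scope if ev.scope != SCOPE_SEGMENTAL else "segmental"
    sex_call = "abnormal" if sex_abnormal else truth.sex
    return CNVCallSet(
        sample_id=truth.embryo_id,
        calls=tuple(calls),
        resolution_class=classes,
        sex_call=sex_call,
    )
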