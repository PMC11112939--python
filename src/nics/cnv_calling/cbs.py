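"""Circular binary segmentation on the copy-number scale.

At each step the arc (i, j) maximizing the two-sample t-statistic between
the arc and its complement (within the current segment, treated as a
circle) is found by exhaustive scan over all arcs; the split is accepted
if its permutation p-value is below ``alpha`` and the recursion continues
on the resulting pieces.  Adjacent segments whose means differ by less
than ``undo_sd`` pooled within-segment standard deviations are re-merged.

The permutation test is seeded and early-stopped: once enough permuted
maxima exceed the observed statistic that the p-value cannot fall below
``alpha``, the split is rejected without running the remaining
permutations (the accept/reject decision is unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nics._util import as_rng
from nics.cnv_calling.profiles import CopyProfile
from nics.genome import GenomeModel

_PERM_BATCH = 24


@dataclass(frozen=True)
class Segment:
    """Constant-mean run of bins (half-open global bin indices)."""

    chromosome: str
    start_bin: int
    end_bin: int
    mean_copy_number: float
    mosaic_fraction_estimate: float
    direction: str  # gain / loss / neutral
    length_mb: float

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


class _ArcSet:
    """Precomputed arc index/constant arrays for one segment length.

    Arcs (i, j) and their complements yield the same t, so only arcs with
    width <= n/2 are enumerated.
    """

    def __init__(self, n: int, min_width: int):
        i_all, j_all = np.triu_indices(n + 1, k=max(min_width, 1))
        width = j_all - i_all
        keep = (width >= min_width) & (n - width >= min_width) & (2 * width <= n)
        self.n = n
        self.i = i_all[keep]
        self.j = j_all[keep]
        k = (self.j - self.i).astype(float)
        m = n - k
        self.inv_k = 1.0 / k
        self.inv_m = 1.0 / m
        self.k = k
        self.m = m
        # t^2 = diff^2 / (pooled_var * (1/k + 1/m)); fold the constants
        self.scale = (self.inv_k + self.inv_m) / max(n - 2, 1)

    @property
    def size(self) -> int:
        return int(self.i.size)


def _arc_t2(x2d: np.ndarray, arcs: _ArcSet) -> np.ndarray:
    """Squared two-sample t for every arc, per row of ``x2d`` (B x n)."""
    s = np.cumsum(x2d, axis=1)
    total = s[:, [-1]]
    total_sq = np.sum(x2d * x2d, axis=1, keepdims=True)
    sum_a = np.concatenate([np.zeros((x2d.shape[0], 1)), s], axis=1)
    sum_a = sum_a[:, arcs.j] - sum_a[:, arcs.i]
    mean_a = sum_a * arcs.inv_k
    mean_c = (total - sum_a) * arcs.inv_m
    diff = mean_a - mean_c
    within = total_sq - arcs.k * mean_a**2 - arcs.m * mean_c**2
    denom = np.maximum(within, 1e-300) * arcs.scale
    t2 = diff * diff / denom
    return np.where(np.isfinite(t2), t2, 0.0)


def _best_arc(x: np.ndarray, min_width: int) -> tuple[float, int, int, "_ArcSet"] | None:
    n = x.size
    if n < 2 * min_width:
        return None
    arcs = _ArcSet(n, min_width)
    if arcs.size == 0:
        return None
    t2 = _arc_t2(x[None, :], arcs)[0]
    best = int(np.argmax(t2))
    return float(t2[best]), int(arcs.i[best]), int(arcs.j[best]), arcs


def _split_accepted(
    x: np.ndarray,
    t2_obs: float,
    arcs: _ArcSet,
    alpha: float,
    n_perm: int,
    rng: np.random.Generator,
) -> bool:
    """Permutation test: p = (1 + #exceed) / (1 + n_perm) < alpha?

    Early-stops (reject) once the exceedance count makes p < alpha
    impossible; acceptance always runs the full n_perm permutations.
    """
    n = x.size
    reject_at = alpha * (1 + n_perm) - 1  # exceedances > this => p >= alpha
    exceed = 0
    done = 0
    batch = _PERM_BATCH
    while done < n_perm:
        b = min(batch, n_perm - done)
        perms = rng.permuted(np.broadcast_to(x, (b, n)).copy(), axis=1)
        tmax = _arc_t2(perms, arcs).max(axis=1)
        exceed += int((tmax >= t2_obs).sum())
        done += b
        if exceed > reject_at:
            return False
        batch = min(4 * batch, 256)  # likely significant: larger batches
    return (1 + exceed) / (1 + n_perm) < alpha


def _segment_values(
    x: np.ndarray,
    alpha: float,
    n_perm: int,
    min_bins: int,
    rng: np.random.Generator,
) -> list[int]:
    """Sorted internal breakpoints of ``x`` found by recursive CBS."""
    breakpoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        found = _best_arc(seg, min_bins)
        if found is None:
            return
        t2_obs, i, j, arcs = found
        if t2_obs <= 0 or not _split_accepted(seg, t2_obs, arcs, alpha, n_perm, rng):
            return
        cuts = [c for c in (i, j) if 0 < c < hi - lo]
        for c in cuts:
            breakpoints.append(lo + c)
        for a, b in zip([lo, *[lo + c for c in cuts]], [*[lo + c for c in cuts], hi]):
            if b - a < 2 * min_bins:
                continue
            recurse(a, b)

    recurse(0, x.size)
    return sorted(set(breakpoints))


def _refine_breakpoints(x: np.ndarray, breakpoints: list[int], min_seg: int) -> list[int]:
    """Locally re-optimize each breakpoint between its neighbors.

    The greedy arc search can misplace a boundary when three or more
    levels interact; each breakpoint is moved to the least-squares
    optimal split of its flanking window until stable.
    """
    bps = sorted(breakpoints)
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def rss(a: int, b: int) -> float:
        s = prefix[b] - prefix[a]
        return float(prefix2[b] - prefix2[a] - s * s / (b - a))

    for _ in range(10):
        moved = False
        for m in range(len(bps)):
            lo = bps[m - 1] if m > 0 else 0
            hi = bps[m + 1] if m + 1 < len(bps) else x.size
            candidates = range(lo + min_seg, hi - min_seg + 1)
            if not len(candidates):
                continue
            best = min(candidates, key=lambda c: rss(lo, c) + rss(c, hi))
            if best != bps[m]:
                bps[m] = best
                moved = True
        bps = sorted(set(bps))
        if not moved:
            break
    return bps


def _undo_merge(x: np.ndarray, breakpoints: list[int], undo_sd: float) -> list[int]:
    """Re-merge adjacent segments with mean difference < undo_sd * pooled SD."""
    bps = list(breakpoints)
    while bps:
        bounds = [0, *bps, x.size]
        means = [x[a:b].mean() for a, b in zip(bounds, bounds[1:])]
        within = sum(float(((x[a:b] - m) ** 2).sum()) for (a, b), m in zip(zip(bounds, bounds[1:]), means))
        dof = x.size - len(means)
        sd = np.sqrt(within / dof) if dof > 0 else 0.0
        diffs = [abs(m2 - m1) for m1, m2 in zip(means, means[1:])]
        worst = int(np.argmin(diffs))
        if sd > 0 and diffs[worst] < undo_sd * sd:
            bps.pop(worst)
        else:
            break
    return bps


def segment_chromosome_values(
    x: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_bins: int = 3,
    undo_sd: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> list[int]:
    """Breakpoints for a single chromosome's values (exposed for testing)."""
    rng = as_rng(rng)
    x = np.asarray(x, dtype=float)
    bps = _segment_values(x, alpha, n_perm, min_bins, rng)
    bps = _refine_breakpoints(x, bps, min_bins)
    if undo_sd and undo_sd > 0:
        bps = _undo_merge(x, bps, undo_sd)
        bps = _refine_breakpoints(x, bps, min_bins)
    return bps


def segment_cbs(
    profile: CopyProfile,
    genome: GenomeModel,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_bins: int = 3,
    undo_sd: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> list[Segment]:
    """Segment a copy-number profile chromosome by chromosome.

    Chromosomes shorter than ``min_bins`` become a single segment.
    Deterministic for a fixed seed.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_perm <= 0 or min_bins < 1:
        raise ValueError("n_perm and min_bins must be positive")
    rng = as_rng(rng)
    from nics.cnv_calling.calls import estimate_mosaicism

    segments: list[Segment] = []
    for chrom in genome.chrom_names:
        sl = genome.chrom_slice(chrom)
        x = profile.copy_number[sl]
        bps = segment_chromosome_values(
            x, alpha=alpha, n_perm=n_perm, min_bins=min_bins, undo_sd=undo_sd, rng=rng
        )
        bounds = [0, *bps, x.size]
        for a, b in zip(bounds, bounds[1:]):
            mean = float(x[a:b].mean())
            frac, direction = estimate_mosaicism(mean)
            start_bin = sl.start + a
            end_bin = sl.start + b
            length_mb = (
                genome.bin_end[end_bin - 1] - genome.bin_start[start_bin]
            ) / 1e6
            segments.append(
                Segment(
                    chromosome=chrom,
                    start_bin=start_bin,
                    end_bin=end_bin,
                    mean_copy_number=mean,
                    mosaic_fraction_estimate=frac,
                    direction=direction,
                    length_mb=float(length_mb),
                )
            )
    return segments
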