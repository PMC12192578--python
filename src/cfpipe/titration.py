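"""Binomial depth titration of variant detectability.

Emulates gradual downsampling of a deep-sequencing run at the allele-count
level: a 20% reduction per step from 147x reaches 117x, 94x, 75x and 60x
(each depth is the floored compounded product, not a per-step floor).
Keeping each read independently with probability ``target/current`` makes
the retained total binomial and the retained alt reads hypergeometric given
the total — the same statistical contract as read-level BAM subsampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DepthSchedule",
    "downsample_schedule",
    "thin_counts",
    "detection_probability",
    "min_depth_for_detection",
    "vaf_across_depths",
]


@dataclass(frozen=True)
class DepthSchedule:
    start_depth: int
    reduction: float
    steps: int
    depths: tuple[int, ...]  # strictly decreasing, excludes start


def downsample_schedule(
    start: int = 147, reduction: float = 0.2, steps: int = 4
) -> DepthSchedule:
    """Depths after k compounded reductions: floor(start * (1-r)^k)."""
    if not 0.0 < reduction < 1.0:
        raise ValueError("reduction must be in (0, 1)")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if start < 1:
        raise ValueError("start depth must be >= 1")
    depths = tuple(
        math.floor(start * (1.0 - reduction) ** k) for k in range(1, steps + 1)
    )
    return DepthSchedule(start_depth=start, reduction=reduction, steps=steps, depths=depths)


def thin_counts(
    alt: int, total: int, ratio: float, seed
) -> tuple[int, int]:
    """Subsample an (alt, total) read pair, keeping each read independently
    with probability ``ratio``. Returns (alt', total')."""
    if not 0.0 < ratio <= 1.0:
        raise ValueError("ratio must be in (0, 1]")
    if alt > total or alt < 0:
        raise ValueError("need 0 <= alt <= total")
    if ratio == 1.0:
        return alt, total
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total_kept = int(rng.binomial(total, ratio))
    alt_kept = int(rng.hypergeometric(alt, total - alt, total_kept)) if total_kept else 0
    return alt_kept, total_kept


def detection_probability(depth: int, vaf: float, min_reads: int = 8) -> float:
    """P[at least ``min_reads`` alt reads], alt ~ Binomial(depth, vaf)."""
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must be in [0, 1]")
    if min_reads <= 0:
        return 1.0
    return float(stats.binom.sf(min_reads - 1, depth, vaf))


def min_depth_for_detection(
    vaf: float, min_reads: int = 8, prob: float = 0.95, max_depth: int = 1_000_000
) -> int:
    """Smallest depth at which detection_probability reaches ``prob``.

    Detection probability is nondecreasing in depth, so a linear scan from
    ``min_reads`` upward terminates at the answer.
    """
    if vaf <= 0:
        raise ValueError("vaf must be positive")
    for depth in range(min_reads, max_depth + 1):
        if detection_probability(depth, vaf, min_reads) >= prob:
            return depth
    raise ValueError("no depth below max_depth reaches the target probability")


def vaf_across_depths(
    tracks: dict[str, tuple[int, int]],
    schedule: DepthSchedule,
    seed,
    min_reads: int = 8,
) -> pd.DataFrame:
    """Thin each variant's (alt, total) counts to every scheduled depth.

    ``tracks`` maps a variant label to its (alt_reads, total_reads) at the
    schedule's start depth. Rows report depth, retained counts, VAF and
    whether the ``min_reads`` support rule still holds; the start depth is
    included as the first row per variant. Deterministic per seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for label, (alt, total) in tracks.items():
        rows.append(
            {
                "variant": label,
                "depth": schedule.start_depth,
                "alt_reads": alt,
                "total_reads": total,
                "vaf": alt / total if total else 0.0,
                "detected": alt >= min_reads,
            }
        )
        for depth in schedule.depths:
            ratio = depth / schedule.start_depth
            alt_k, total_k = thin_counts(alt, total, ratio, rng)
            rows.append(
                {
                    "variant": label,
                    "depth": depth,
                    "alt_reads": alt_k,
                    "total_reads": total_k,
                    "vaf": alt_k / total_k if total_k else 0.0,
                    "detected": alt_k >= min_reads,
                }
            )
    return pd.DataFrame(rows)
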