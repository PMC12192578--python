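"""Simplified tumor-fraction and clonality inference from binned coverage.

The model: a copy-number event with tumor copy number c and cellular
prevalence phi, in a sample of tumor fraction TF, shifts the tumor/normal
log2 coverage ratio to

    log2( (TF*phi*c + TF*(1-phi)*2 + (1-TF)*2) / 2 ).

Bins are normalized against a matched normal, segmented by recursive
binary splitting on mean shift, and segments are fit over a grid of
(TF, c, phi) by length-weighted least squares. Clonal states (phi = 1) are
preferred over subclonal alternatives unless the subclonal fit is a clear
improvement — the parsimony rule that counters false-subclonal inflation
at low sequencing depth.

This is a deliberately transparent stand-in for HMM-based callers: no GC or
mappability correction and no transition priors, just the mixture algebra
that carries the clonality logic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinProfile",
    "Segment",
    "TumorFractionEstimate",
    "model_log2r",
    "normalize_bins",
    "estimate_noise_sd",
    "segment_profile",
    "estimate_tf",
    "classify_segments",
    "concordance",
    "state_of",
    "read_bins_tsv",
    "write_bins_tsv",
    "write_segments_tsv",
]

STATES = ("neutral", "clonal gain", "clonal loss", "subclonal gain", "subclonal loss")

DEFAULT_TF_GRID = np.round(np.arange(0.01, 0.601, 0.01), 2)
DEFAULT_PHI_GRID = (0.25, 0.5, 0.75, 1.0)
DEFAULT_C_MAX = 8

#: Relative fit improvement a subclonal state must achieve over the best
#: clonal (or neutral) state to be called subclonal.
DEFAULT_DELTA = 0.1

#: Complexity charges, in units of the segment-mean sampling variance, that
#: a state must overcome: one for invoking a copy-number event at all, a
#: larger one for invoking subclonality (an extra free parameter, and the
#: state family whose dense lattice otherwise absorbs noise). Zero effect
#: on noise-free data.
RHO_EVENT = 2.0
RHO_SUBCLONAL = 5.0

#: The sampling variance entering the complexity charges is capped at this
#: value (log2R^2 units). The charges play the role of the fixed state
#: priors of an HMM caller: they do not keep growing when the data get
#: noisier, which is exactly why low-coverage profiles inflate false
#: subclonal calls while clean deep profiles do not.
CHARGE_VAR_CAP = 0.02**2

#: Segments below this |log2R| carry no usable event signal: they neither
#: enter the TF objective nor, alone, support a nonzero TF call.
DEFAULT_MIN_EVENT_LOG2R = 0.05


@dataclass
class BinProfile:
    """Genome-binned read counts: columns chrom, start, end (0-based
    half-open) and count. Bins must be sorted and non-overlapping."""

    bins: pd.DataFrame
    depth: float | None = None

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "count"}
        if not required <= set(self.bins.columns):
            raise ValueError(f"bins must have columns {sorted(required)}")
        if (self.bins["count"] < 0).any():
            raise ValueError("counts must be nonnegative")
        for _, sub in self.bins.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(ends <= starts):
                raise ValueError("bins must have end > start")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError("bins must be sorted and non-overlapping")


@dataclass
class Segment:
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_log2r: float
    state: str | None = None
    c: int | None = None
    phi: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TumorFractionEstimate:
    tumor_fraction: float
    frac_genome_subclonal: float


def model_log2r(c: int, phi: float, tf: float) -> float:
    """Expected log2 ratio of a (c, phi) event at tumor fraction tf."""
    return math.log2((tf * phi * c + tf * (1.0 - phi) * 2.0 + (1.0 - tf) * 2.0) / 2.0)


def state_of(c: int, phi: float) -> str:
    if c == 2:
        return "neutral"
    kind = "gain" if c > 2 else "loss"
    return f"{'clonal' if phi >= 1.0 else 'subclonal'} {kind}"


# ---------------------------------------------------------------------------
# normalization


def normalize_bins(tumor: BinProfile, normal: BinProfile) -> pd.DataFrame:
    """Per-bin log2 of depth-normalized tumor/normal count ratios,
    median-centered. Bins with a zero count in either profile are dropped.

    Depth normalization divides each profile by its total count, so the
    result is invariant to overall sequencing throughput.
    """
    t, n = tumor.bins, normal.bins
    same = (
        len(t) == len(n)
        and (t["chrom"].to_numpy() == n["chrom"].to_numpy()).all()
        and (t["start"].to_numpy() == n["start"].to_numpy()).all()
        and (t["end"].to_numpy() == n["end"].to_numpy()).all()
    )
    if not same:
        raise ValueError("tumor and normal bin grids differ")
    tc = t["count"].to_numpy(dtype=float)
    nc = n["count"].to_numpy(dtype=float)
    keep = (tc > 0) & (nc > 0)
    out = t.loc[keep, ["chrom", "start", "end"]].copy()
    lr = np.log2((tc[keep] / tc[keep].sum()) / (nc[keep] / nc[keep].sum()))
    lr -= np.median(lr)
    out["log2r"] = lr
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# segmentation


def _noise_variance(log2r: pd.DataFrame) -> float:
    """Robust per-bin noise variance from successive differences within
    chromosomes (each difference carries twice the bin variance; the MAD
    makes true copy-number steps, which are few, negligible)."""
    diffs = []
    for _, sub in log2r.groupby("chrom", sort=False):
        v = sub["log2r"].to_numpy()
        if v.size >= 2:
            diffs.append(np.diff(v))
    if not diffs:
        return 0.0
    d = np.concatenate(diffs)
    mad = np.median(np.abs(d - np.median(d)))
    sd = 1.4826 * mad / math.sqrt(2.0)
    return sd * sd


def estimate_noise_sd(log2r: pd.DataFrame) -> float:
    """Per-bin noise SD of a log2-ratio profile (robust, from successive
    differences); feed to :func:`estimate_tf` / :func:`classify_segments`."""
    return math.sqrt(_noise_variance(log2r))


def _best_split(x: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Best single changepoint of a segment: returns (index, SSE reduction)
    where the left part is x[:index]. (-1, 0) when no admissible split."""
    n = x.size
    if n < 2 * min_bins:
        return -1, 0.0
    csum = np.cumsum(x)
    total = csum[-1]
    k = np.arange(min_bins, n - min_bins + 1)
    left = csum[k - 1]
    right = total - left
    # SSE reduction of splitting at k: between-group sum of squares
    reduction = left**2 / k + right**2 / (n - k) - total**2 / n
    i = int(np.argmax(reduction))
    return int(k[i]), float(reduction[i])


def _segment_indices(
    x: np.ndarray, min_bins: int, threshold: float
) -> list[tuple[int, int]]:
    """Recursive binary segmentation; a split is accepted when its SSE
    reduction exceeds ``threshold``."""
    out: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        split, reduction = _best_split(x[lo:hi], min_bins)
        if split < 0 or reduction <= threshold:
            out.append((lo, hi))
            return
        recurse(lo, lo + split)
        recurse(lo + split, hi)

    recurse(0, x.size)
    pieces = _merge_indices(x, sorted(out), threshold)
    return _refine_boundaries(x, pieces, min_bins)


def _refine_boundaries(
    x: np.ndarray, pieces: list[tuple[int, int]], min_bins: int, max_rounds: int = 10
) -> list[tuple[int, int]]:
    """Coordinate-descent polish of the greedy solution: re-place each
    internal boundary at the SSE-optimal split of its two adjacent pieces,
    holding the others fixed, until no boundary moves."""
    pieces = list(pieces)
    for _ in range(max_rounds):
        moved = False
        for i in range(len(pieces) - 1):
            lo = pieces[i][0]
            hi = pieces[i + 1][1]
            seg = x[lo:hi]
            n = seg.size
            csum = np.cumsum(seg)
            total = csum[-1]
            k = np.arange(min_bins, n - min_bins + 1)
            left = csum[k - 1]
            right = total - left
            scores = left**2 / k + right**2 / (n - k)
            best = int(k[int(np.argmax(scores))]) + lo
            if best != pieces[i][1]:
                pieces[i] = (pieces[i][0], best)
                pieces[i + 1] = (best, pieces[i + 1][1])
                moved = True
        if not moved:
            break
    return pieces


def _merge_indices(
    x: np.ndarray, pieces: list[tuple[int, int]], threshold: float
) -> list[tuple[int, int]]:
    """Bottom-up pruning: repeatedly merge the adjacent pair whose merge
    cost (the SSE increase n1*n2/(n1+n2) * (m1-m2)^2) is smallest, while it
    stays at or below ``threshold``. Counters greedy-split artifacts where
    a noise-placed boundary survives with no real step behind it."""
    pieces = list(pieces)
    while len(pieces) > 1:
        costs = []
        for i in range(len(pieces) - 1):
            lo1, hi1 = pieces[i]
            lo2, hi2 = pieces[i + 1]
            n1, n2 = hi1 - lo1, hi2 - lo2
            dm = x[lo1:hi1].mean() - x[lo2:hi2].mean()
            costs.append(n1 * n2 / (n1 + n2) * dm * dm)
        i = int(np.argmin(costs))
        if costs[i] > threshold:
            break
        pieces[i] = (pieces[i][0], pieces[i + 1][1])
        del pieces[i + 1]
    return pieces


def segment_profile(
    log2r: pd.DataFrame,
    min_bins: int = 10,
    penalty: float = 12.0,
) -> list[Segment]:
    """Segment per-bin log2 ratios into constant-mean pieces.

    ``penalty`` scales the estimated per-bin noise variance: a split must
    reduce the squared error by more than ``penalty * sigma2``. Segments
    shorter than ``min_bins`` are never produced.
    """
    if log2r.empty:
        raise ValueError("empty profile")
    sigma2 = max(_noise_variance(log2r), 1e-12)
    threshold = penalty * sigma2
    segments: list[Segment] = []
    for chrom, sub in log2r.groupby("chrom", sort=False):
        x = sub["log2r"].to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if x.size < min_bins:
            continue
        for lo, hi in _segment_indices(x, min_bins, threshold):
            segments.append(
                Segment(
                    chrom=str(chrom),
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    n_bins=hi - lo,
                    mean_log2r=float(x[lo:hi].mean()),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# tumor-fraction / clonality fit


def _state_grid(c_max: int, phi_grid: Sequence[float]) -> list[tuple[int, float]]:
    # clonal candidates ordered by |c-2| so parsimony falls out of strict
    # improvement comparisons; neutral (c=2) is the first clonal candidate
    clonal = sorted(range(c_max + 1), key=lambda c: (abs(c - 2), c))
    states = [(c, 1.0) for c in clonal]
    for phi in sorted((p for p in phi_grid if p < 1.0), reverse=True):
        for c in clonal:
            if c != 2:
                states.append((c, phi))
    return states


def _fit_segment(
    mean: float,
    tf: float,
    states: Sequence[tuple[int, float]],
    delta: float,
    var_mean: float = 0.0,
) -> tuple[float, int, float]:
    """Best (cost, c, phi) for one segment mean at fixed TF.

    The cost of a state is its squared error plus a complexity charge
    scaled by ``var_mean``, the sampling variance of the segment mean:
    RHO_EVENT for any non-neutral state, RHO_SUBCLONAL for a subclonal one.
    A subclonal state must additionally beat the best clonal state by
    ``delta`` relative squared error (the clonal-preference rule, which is
    all that remains when ``var_mean`` is zero).
    """
    var_mean = min(var_mean, CHARGE_VAR_CAP)
    best_clonal: tuple[float, float, int, float] | None = None  # (cost, err, c, phi)
    best_sub: tuple[float, float, int, float] | None = None
    for c, phi in states:
        err = (mean - model_log2r(c, phi, tf)) ** 2
        if phi >= 1.0:
            cost = err + (0.0 if c == 2 else RHO_EVENT * var_mean)
            if best_clonal is None or cost < best_clonal[0]:
                best_clonal = (cost, err, c, phi)
        else:
            cost = err + RHO_SUBCLONAL * var_mean
            if best_sub is None or cost < best_sub[0]:
                best_sub = (cost, err, c, phi)
    assert best_clonal is not None
    if (
        best_sub is not None
        and best_sub[0] < best_clonal[0]
        and best_sub[1] < (1.0 - delta) * best_clonal[1]
    ):
        return (best_sub[0], best_sub[2], best_sub[3])
    return (best_clonal[0], best_clonal[2], best_clonal[3])


def estimate_tf(
    segments: Sequence[Segment],
    tf_grid: Sequence[float] = DEFAULT_TF_GRID,
    c_max: int = DEFAULT_C_MAX,
    phi_grid: Sequence[float] = DEFAULT_PHI_GRID,
    delta: float = DEFAULT_DELTA,
    min_event_log2r: float = DEFAULT_MIN_EVENT_LOG2R,
    eps: float = 1e-4,
    bin_noise_sd: float | None = None,
) -> tuple[TumorFractionEstimate, list[Segment]]:
    """Grid-search the tumor fraction and per-segment (c, phi).

    ``bin_noise_sd`` is the per-bin noise SD of the log2 ratios (as
    estimated during segmentation); it activates the complexity charges of
    :func:`_fit_segment`, which suppress copy-number states that a
    segment's sampling noise could explain. Omit it for noise-free data.

    The grid search minimizes the length-weighted squared error between
    segment means and the mixture model over the segments that show a clear
    event (|mean| >= ``min_event_log2r``); sub-threshold segments cannot
    inform the aneuploidy scale and would otherwise pull TF toward small
    values whose finer state lattice fits their noise. All segments are
    then state-classified at the selected TF.

    TF = 0 (all-neutral) is returned when no segment reaches the event
    threshold, or when the all-neutral fit of the event segments is within
    ``eps`` (per unit length) of the best alternative.

    Ties in fit error are broken by parsimony — the smallest length-weighted
    sum of |c - 2| + 4(1 - phi) — then by the larger TF. This resolves the
    exact degeneracies between (TF, c) and (TF/2, 2(c-2)+2), and between a
    clonal event at TF and a subclonal one at TF/phi.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no segments")
    states = _state_grid(c_max, phi_grid)

    def neutral_result() -> tuple[TumorFractionEstimate, list[Segment]]:
        fitted = [
            Segment(s.chrom, s.start, s.end, s.n_bins, s.mean_log2r,
                    state="neutral", c=2, phi=1.0)
            for s in segments
        ]
        return TumorFractionEstimate(0.0, 0.0), fitted

    events = [s for s in segments if abs(s.mean_log2r) >= min_event_log2r]
    if not events:
        return neutral_result()
    means = np.array([s.mean_log2r for s in events])
    weights = np.array([float(s.length) for s in events])
    var_means = [
        (bin_noise_sd**2 / s.n_bins if bin_noise_sd else 0.0) for s in events
    ]
    wtotal = weights.sum()
    sse_neutral = float(weights @ means**2)

    best = None  # (sse, parsimony, -tf, tf)
    for tf in tf_grid:
        fits = [
            _fit_segment(m, float(tf), states, delta, v)
            for m, v in zip(means, var_means)
        ]
        sse = float(sum(w * f[0] for w, f in zip(weights, fits)))
        parsimony = float(
            sum(w * (abs(f[1] - 2) + 4.0 * (1.0 - f[2])) for w, f in zip(weights, fits))
        )
        if best is None:
            best = (sse, parsimony, -float(tf), float(tf))
            continue
        tol = 1e-9 * max(best[0], sse) + 1e-15 * wtotal
        if sse < best[0] - tol:
            best = (sse, parsimony, -float(tf), float(tf))
        elif abs(sse - best[0]) <= tol and (parsimony, -float(tf)) < (best[1], best[2]):
            best = (best[0], parsimony, -float(tf), float(tf))
    assert best is not None
    best_sse, _, _, best_tf = best

    if sse_neutral <= best_sse + eps * wtotal:
        return neutral_result()

    fitted = classify_segments(segments, best_tf, c_max=c_max,
                               phi_grid=phi_grid, delta=delta,
                               bin_noise_sd=bin_noise_sd)
    total_length = float(sum(s.length for s in fitted))
    sub_length = float(
        sum(s.length for s in fitted if s.state and s.state.startswith("subclonal"))
    )
    return (
        TumorFractionEstimate(best_tf, sub_length / total_length),
        fitted,
    )


def classify_segments(
    segments: Sequence[Segment],
    tf: float,
    c_max: int = DEFAULT_C_MAX,
    phi_grid: Sequence[float] = DEFAULT_PHI_GRID,
    delta: float = DEFAULT_DELTA,
    bin_noise_sd: float | None = None,
) -> list[Segment]:
    """Assign (c, phi) states to segments at a fixed tumor fraction."""
    if tf <= 0.0:
        return [
            Segment(s.chrom, s.start, s.end, s.n_bins, s.mean_log2r,
                    state="neutral", c=2, phi=1.0)
            for s in segments
        ]
    states = _state_grid(c_max, phi_grid)
    out = []
    for s in segments:
        var_mean = bin_noise_sd**2 / s.n_bins if bin_noise_sd else 0.0
        _, c, phi = _fit_segment(s.mean_log2r, tf, states, delta, var_mean)
        out.append(
            Segment(s.chrom, s.start, s.end, s.n_bins, s.mean_log2r,
                    state=state_of(c, phi), c=c, phi=phi)
        )
    return out


# ---------------------------------------------------------------------------
# cross-depth concordance


def _overlap(a: Segment, b: Segment) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _reciprocal(a: Segment, b: Segment, min_frac: float) -> bool:
    ov = _overlap(a, b)
    return ov >= min_frac * a.length and ov >= min_frac * b.length


def _direction(state: str) -> str:
    return state.split()[-1]  # "gain" | "loss"


def concordance(
    calls_a: Sequence[Segment],
    calls_b: Sequence[Segment],
    min_reciprocal_overlap: float = 0.5,
) -> dict:
    """Score call set B against reference call set A.

    Events (non-neutral segments) are matched by reciprocal overlap.
    Reports the fraction of A's clonal events found as clonal events of the
    same direction in B, subclonal events unique to B (false subclonal when
    B is the lower-depth test set), subclonal events of A missing from B,
    and matched pairs whose clonality label swapped.
    """
    ev_a = [s for s in calls_a if s.state and s.state != "neutral"]
    ev_b = [s for s in calls_b if s.state and s.state != "neutral"]

    pairs = []
    for i, a in enumerate(ev_a):
        for j, b in enumerate(ev_b):
            if _reciprocal(a, b, min_reciprocal_overlap):
                pairs.append((_overlap(a, b), i, j))
    pairs.sort(reverse=True)
    matched_a: dict[int, int] = {}
    matched_b: dict[int, int] = {}
    for _, i, j in pairs:
        if i not in matched_a and j not in matched_b:
            matched_a[i] = j
            matched_b[j] = i

    clonal_a = [i for i, s in enumerate(ev_a) if s.state.startswith("clonal")]
    concordant = 0
    for i in clonal_a:
        j = matched_a.get(i)
        if j is not None:
            b = ev_b[j]
            if b.state.startswith("clonal") and _direction(b.state) == _direction(ev_a[i].state):
                concordant += 1
    clonal_concordance = concordant / len(clonal_a) if clonal_a else 1.0

    false_subclonal = sum(
        1 for j, s in enumerate(ev_b)
        if s.state.startswith("subclonal") and j not in matched_b
    )
    missed_subclonal = sum(
        1 for i, s in enumerate(ev_a)
        if s.state.startswith("subclonal") and i not in matched_a
    )
    swaps = sum(
        1 for i, j in matched_a.items()
        if ev_a[i].state.split()[0] != ev_b[j].state.split()[0]
    )
    return {
        "clonal_concordance": clonal_concordance,
        "false_subclonal": false_subclonal,
        "missed_subclonal": missed_subclonal,
        "clonality_swaps": swaps,
    }


# ---------------------------------------------------------------------------
# I/O


def read_bins_tsv(path: str | Path, depth: float | None = None) -> BinProfile:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return BinProfile(df[["chrom", "start", "end", "count"]], depth=depth)


def write_bins_tsv(profile: BinProfile, path: str | Path) -> None:
    profile.bins.to_csv(path, sep="\t", index=False)


def write_segments_tsv(segments: Sequence[Segment], path: str | Path) -> None:
    rows = [
        {
            "chrom": s.chrom, "start": s.start, "end": s.end, "n_bins": s.n_bins,
            "mean_log2r": s.mean_log2r, "state": s.state, "c": s.c, "phi": s.phi,
        }
        for s in segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_json(
    estimate: TumorFractionEstimate, path: str | Path
) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "tumor_fraction": estimate.tumor_fraction,
                "frac_genome_subclonal": estimate.frac_genome_subclonal,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
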