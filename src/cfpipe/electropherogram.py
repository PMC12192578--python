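"""cfDNA quantification from Bioanalyzer-style electropherogram traces.

A trace is a fragment-size grid (bp) with a signal density (pg/uL per bp).
Fragment mass in a size window is the trapezoidal integral of the density.
cfDNA is quantified as the 50-550 bp mass (mono-, di-, tri-nucleosomes),
summed over the four column eluates and normalized to plasma volume (ng/mL).
Samples are classified gDNA-contaminated when the pooled >5000 bp signal
exceeds 50 pg/uL (strict), expressed as a per-uL equivalent of eluate 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SIZE_BINS",
    "CFDNA_RANGE",
    "GDNA_PURITY_THRESHOLD",
    "Electropherogram",
    "SizeBinQuant",
    "SampleQuant",
    "integrate_trace",
    "bin_quantities",
    "cfdna_concentration",
    "classify_purity",
    "gdna_estimate",
    "elution_recovery",
    "mean_fragment_size",
    "compute_sample_quant",
    "read_trace_csv",
    "write_trace_csv",
]

#: Size windows (bp, inclusive-low / exclusive-high). The last window is
#: open-ended; integration stops at the end of the grid (upper marker).
SIZE_BINS: tuple[tuple[float, float], ...] = (
    (50.0, 250.0),
    (250.0, 350.0),
    (350.0, 550.0),
    (550.0, 5000.0),
    (5000.0, math.inf),
)

#: Fragment-size range summed to quantify cfDNA (mono- to tri-nucleosomes).
CFDNA_RANGE: tuple[float, float] = (50.0, 550.0)

#: Pooled >5000 bp concentration (pg/uL) above which a sample is called
#: gDNA-contaminated. Strictly greater-than.
GDNA_PURITY_THRESHOLD: float = 50.0


@dataclass
class Electropherogram:
    """One eluate's size-vs-density trace plus sample metadata.

    Parameters
    ----------
    grid
        Strictly increasing fragment sizes in bp.
    density
        Signal density in pg/uL per bp, aligned to ``grid``, nonnegative.
    eluate_volume_ul
        Volume of this eluate in uL.
    plasma_volume_ml
        Plasma volume the sample was purified from, in mL.
    qubit_total_ng_per_ml
        Optional total-DNA reading (Qubit), already normalized to plasma
        volume (ng/mL); used for gDNA estimation.
    """

    sample_id: str
    eluate_index: int
    grid: np.ndarray
    density: np.ndarray
    eluate_volume_ul: float
    plasma_volume_ml: float
    qubit_total_ng_per_ml: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 2:
            raise ValueError("grid must be 1-D with at least two points")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.density.shape != self.grid.shape:
            raise ValueError("density must align with grid")
        if not np.all(np.isfinite(self.density)):
            raise ValueError("density must be finite")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")
        if not 1 <= int(self.eluate_index) <= 4:
            raise ValueError("eluate_index must be in 1..4")
        if self.eluate_volume_ul <= 0:
            raise ValueError("eluate_volume_ul must be positive")
        if self.plasma_volume_ml <= 0:
            raise ValueError("plasma_volume_ml must be positive")


@dataclass
class SizeBinQuant:
    """Integrated amounts (pg/uL) in the five size windows of one trace."""

    amounts: np.ndarray  # aligned with SIZE_BINS

    @property
    def cfdna(self) -> float:
        """Sum of the three windows inside the 50-550 bp cfDNA range."""
        return float(self.amounts[:3].sum())

    @property
    def gdna(self) -> float:
        """Amount in the >5000 bp window (gDNA contamination)."""
        return float(self.amounts[4])


@dataclass
class SampleQuant:
    """Per-sample quantification summary across the four eluates."""

    sample_id: str
    per_eluate: list[SizeBinQuant]
    cfdna_ng_per_ml_plasma: float
    purity: str  # "pure" | "contaminated"
    gdna_pooled_pg_per_ul: float
    gdna_estimate_ng_per_ml: float | None
    recovery_fractions: np.ndarray | None
    first_elution_pct: float | None
    mean_mono_size_bp: float | None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "per_eluate_pg_per_ul": [list(map(float, q.amounts)) for q in self.per_eluate],
            "cfdna_ng_per_ml_plasma": self.cfdna_ng_per_ml_plasma,
            "purity": self.purity,
            "gdna_pooled_pg_per_ul": self.gdna_pooled_pg_per_ul,
            "gdna_estimate_ng_per_ml": self.gdna_estimate_ng_per_ml,
            "recovery_fractions": None
            if self.recovery_fractions is None
            else list(map(float, self.recovery_fractions)),
            "first_elution_pct": self.first_elution_pct,
            "mean_mono_size_bp": self.mean_mono_size_bp,
        }


def integrate_trace(trace: Electropherogram, lo: float, hi: float) -> float:
    """Trapezoidal integral of the density over [lo, hi) in pg/uL.

    Partial intervals at the window edges are linearly interpolated; an
    infinite ``hi`` integrates to the end of the grid.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    x, y = trace.grid, trace.density
    lo = max(lo, float(x[0]))
    hi = float(x[-1]) if math.isinf(hi) else min(hi, float(x[-1]))
    if hi <= lo:
        return 0.0
    inner = (x > lo) & (x < hi)
    xs = np.concatenate(([lo], x[inner], [hi]))
    ys = np.concatenate(([np.interp(lo, x, y)], y[inner], [np.interp(hi, x, y)]))
    return float(np.trapezoid(ys, xs))


def bin_quantities(trace: Electropherogram) -> SizeBinQuant:
    """Integrate one trace over the five standard size windows."""
    return SizeBinQuant(
        amounts=np.array([integrate_trace(trace, lo, hi) for lo, hi in SIZE_BINS])
    )


def _check_sample(eluates: Sequence[Electropherogram]) -> None:
    if not eluates:
        raise ValueError("need at least one eluate")
    sid = eluates[0].sample_id
    pv = eluates[0].plasma_volume_ml
    for e in eluates:
        if e.sample_id != sid:
            raise ValueError("eluates belong to different samples")
        if e.plasma_volume_ml != pv:
            raise ValueError("inconsistent plasma volume across eluates")


def cfdna_concentration(eluates: Sequence[Electropherogram]) -> float:
    """cfDNA concentration in ng per mL plasma.

    Sums the 50-550 bp mass (pg/uL x eluate volume uL) across eluates and
    divides by 1000 (pg->ng) and the plasma volume (mL).
    """
    _check_sample(eluates)
    lo, hi = CFDNA_RANGE
    total_pg = sum(integrate_trace(e, lo, hi) * e.eluate_volume_ul for e in eluates)
    return total_pg / 1000.0 / eluates[0].plasma_volume_ml


def _pooled_gdna_pg_per_ul(eluates: Sequence[Electropherogram]) -> float:
    """Pooled >5000 bp signal, volume-weighted to a per-uL equivalent of
    eluate 1 (so a single-eluate sample reduces to its own bin amount)."""
    lo, hi = SIZE_BINS[4]
    mass_pg = sum(integrate_trace(e, lo, hi) * e.eluate_volume_ul for e in eluates)
    ref_volume = eluates[0].eluate_volume_ul
    return mass_pg / ref_volume


def classify_purity(
    eluates: Sequence[Electropherogram], threshold: float = GDNA_PURITY_THRESHOLD
) -> str:
    """Call a sample "contaminated" when the pooled >5000 bp concentration
    strictly exceeds ``threshold`` pg/uL, else "pure"."""
    _check_sample(eluates)
    return "contaminated" if _pooled_gdna_pg_per_ul(eluates) > threshold else "pure"


def gdna_estimate(qubit_ng_per_ml: float, bioanalyzer_ng_per_ml: float) -> float:
    """Plasma gDNA concentration estimated as Qubit minus Bioanalyzer.

    Qubit measures total double-stranded DNA while the electropherogram sum
    counts only 50-550 bp fragments; the difference approximates the
    high-molecular-weight contamination. Clamped at zero.
    """
    if qubit_ng_per_ml < 0 or bioanalyzer_ng_per_ml < 0:
        raise ValueError("concentrations must be nonnegative")
    return max(0.0, qubit_ng_per_ml - bioanalyzer_ng_per_ml)


def elution_recovery(
    eluates: Sequence[Electropherogram],
) -> tuple[np.ndarray, float]:
    """Per-eluate fractions of the total cfDNA mass, plus the first-elution
    recovery as a percentage.

    Raises
    ------
    ValueError
        If the total cfDNA mass is zero (recovery undefined).
    """
    _check_sample(eluates)
    lo, hi = CFDNA_RANGE
    masses = np.array(
        [integrate_trace(e, lo, hi) * e.eluate_volume_ul for e in eluates]
    )
    total = masses.sum()
    if total <= 0:
        raise ValueError("total cfDNA mass is zero; recovery undefined")
    fractions = masses / total
    return fractions, float(fractions[0] * 100.0)


def mean_fragment_size(trace: Electropherogram) -> float:
    """Density-weighted mean fragment size (bp) over the mono-nucleosome
    window [50, 250)."""
    lo, hi = SIZE_BINS[0]
    x, y = trace.grid, trace.density
    inner = (x >= lo) & (x < hi)
    xs, ys = x[inner], y[inner]
    mass = np.trapezoid(ys, xs)
    if mass <= 0:
        raise ValueError("no signal in the mono-nucleosome window")
    return float(np.trapezoid(ys * xs, xs) / mass)


def compute_sample_quant(eluates: Sequence[Electropherogram]) -> SampleQuant:
    """Full quantification of one sample from its eluate traces."""
    _check_sample(eluates)
    per_eluate = [bin_quantities(e) for e in eluates]
    conc = cfdna_concentration(eluates)
    purity = classify_purity(eluates)
    pooled_gdna = _pooled_gdna_pg_per_ul(eluates)
    qubit = eluates[0].qubit_total_ng_per_ml
    gdna_est = gdna_estimate(qubit, conc) if qubit is not None else None
    try:
        fractions, first_pct = elution_recovery(eluates)
    except ValueError:
        fractions, first_pct = None, None
    try:
        mono = mean_fragment_size(eluates[0])
    except ValueError:
        mono = None
    return SampleQuant(
        sample_id=eluates[0].sample_id,
        per_eluate=per_eluate,
        cfdna_ng_per_ml_plasma=conc,
        purity=purity,
        gdna_pooled_pg_per_ul=pooled_gdna,
        gdna_estimate_ng_per_ml=gdna_est,
        recovery_fractions=fractions,
        first_elution_pct=first_pct,
        mean_mono_size_bp=mono,
    )


# ---------------------------------------------------------------------------
# trace CSV dialect: '#key=value' metadata header lines, then
# size_bp,density_pg_per_ul_per_bp rows.

def write_trace_csv(trace: Electropherogram, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"#sample_id={trace.sample_id}",
        f"#eluate_index={trace.eluate_index}",
        f"#eluate_volume_ul={float(trace.eluate_volume_ul)!r}",
        f"#plasma_volume_ml={float(trace.plasma_volume_ml)!r}",
    ]
    if trace.qubit_total_ng_per_ml is not None:
        lines.append(f"#qubit_total_ng_per_ml={float(trace.qubit_total_ng_per_ml)!r}")
    lines.append("size_bp,density_pg_per_ul_per_bp")
    for x, y in zip(trace.grid, trace.density):
        lines.append(f"{float(x)!r},{float(y)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_trace_csv(path: str | Path) -> Electropherogram:
    meta: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
            elif line[0].isdigit() or line[0] in "+-.":
                a, _, b = line.partition(",")
                xs.append(float(a))
                ys.append(float(b))
    qubit = meta.get("qubit_total_ng_per_ml")
    return Electropherogram(
        sample_id=meta["sample_id"],
        eluate_index=int(meta["eluate_index"]),
        grid=np.array(xs),
        density=np.array(ys),
        eluate_volume_ul=float(meta["eluate_volume_ul"]),
        plasma_volume_ml=float(meta["plasma_volume_ml"]),
        qubit_total_ng_per_ml=None if qubit is None else float(qubit),
    )


def write_sample_quant_json(quant: SampleQuant, path: str | Path) -> None:
    Path(path).write_text(json.dumps(quant.to_dict(), indent=2, sort_keys=True) + "\n")
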