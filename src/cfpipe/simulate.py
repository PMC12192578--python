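"""Synthetic data with known ground truth for every pipeline stage.

Emulates, with explicit calibration to published summary statistics where
available: nucleosomal electropherogram ladders (~167/~340/~510 bp peaks,
optional >5000 bp genomic-DNA contamination), a four-group clinical cohort
(healthy, radical-prostatectomy, disease-free, mCRPC) with a negative
size-concentration correlation in the advanced group, four-caller somatic
callsets with germline contaminants and population-frequency annotations,
and genome-binned read-count profiles carrying clonal and subclonal
copy-number segments at a specified tumor fraction.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .electropherogram import Electropherogram

__all__ = [
    "TraceSpec",
    "GroupSpec",
    "CohortSpec",
    "TrueVariant",
    "CallsetSpec",
    "CallsetBundle",
    "CNSegment",
    "ProfileSpec",
    "gen_trace",
    "gen_elution_series",
    "gen_cohort",
    "gen_callsets",
    "gen_bin_profile",
    "expected_log2_ratio",
    "truth_segments",
    "DEFAULT_ELUATE_VOLUMES_UL",
    "DEFAULT_PLASMA_VOLUME_ML",
]

#: Elution volumes of the four sequential column eluates (uL).
DEFAULT_ELUATE_VOLUMES_UL: tuple[float, float, float, float] = (85.0, 40.0, 20.0, 20.0)
#: Plasma input volume per sample (mL).
DEFAULT_PLASMA_VOLUME_ML: float = 3.6


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _children(seed, n: int) -> list[np.random.SeedSequence]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(n)


# ---------------------------------------------------------------------------
# electropherogram traces


@dataclass
class TraceSpec:
    """Component amounts and shapes of a synthetic electropherogram.

    Amounts are total pg/uL per component; each component is a truncated
    normal renormalized on the grid, so its integral over the grid equals
    its amount exactly (mass conservation is testable).
    """

    mono_amount: float = 0.0
    di_amount: float = 0.0
    tri_amount: float = 0.0
    gdna_amount: float = 0.0
    mono_mean: float = 167.0
    di_mean: float = 340.0
    tri_mean: float = 510.0
    gdna_mean: float = 8000.0
    # default widths keep >99.8% of each nucleosomal component inside its
    # size window (the tri peak at 510 bp must not leak past the 550 bp
    # quantification edge)
    peak_sds: tuple[float, float, float, float] = (20.0, 30.0, 14.0, 400.0)
    noise_sd: float = 0.0
    grid: np.ndarray = field(default_factory=lambda: np.arange(35.0, 10381.0, 1.0))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        amounts = (self.mono_amount, self.di_amount, self.tri_amount, self.gdna_amount)
        if not all(math.isfinite(a) and a >= 0 for a in amounts):
            raise ValueError("component amounts must be finite and nonnegative")
        if self.grid.size < 2 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing with >= 2 points")
        for mu in (self.mono_mean, self.di_mean, self.tri_mean, self.gdna_mean):
            if not self.grid[0] <= mu <= self.grid[-1]:
                raise ValueError("peak means must lie inside the grid range")
        if any(sd <= 0 for sd in self.peak_sds):
            raise ValueError("peak SDs must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @property
    def amounts(self) -> tuple[float, float, float, float]:
        return (self.mono_amount, self.di_amount, self.tri_amount, self.gdna_amount)

    @property
    def means(self) -> tuple[float, float, float, float]:
        return (self.mono_mean, self.di_mean, self.tri_mean, self.gdna_mean)


def gen_trace(
    spec: TraceSpec,
    seed,
    *,
    sample_id: str = "S1",
    eluate_index: int = 1,
    eluate_volume_ul: float = DEFAULT_ELUATE_VOLUMES_UL[0],
    plasma_volume_ml: float = DEFAULT_PLASMA_VOLUME_ML,
    qubit_total_ng_per_ml: float | None = None,
) -> Electropherogram:
    """Render a trace: renormalized-truncated-normal components plus
    zero-mean Gaussian baseline noise, clipped at zero."""
    rng = _rng(seed)
    x = spec.grid
    density = np.zeros_like(x)
    for amount, mean, sd in zip(spec.amounts, spec.means, spec.peak_sds):
        if amount == 0:
            continue
        pdf = stats.norm.pdf(x, loc=mean, scale=sd)
        mass = np.trapezoid(pdf, x)
        if mass <= 0:
            raise ValueError("component has no mass on the grid")
        density += amount * pdf / mass
    if spec.noise_sd > 0:
        density = density + rng.normal(0.0, spec.noise_sd, size=x.shape)
    np.clip(density, 0.0, None, out=density)
    return Electropherogram(
        sample_id=sample_id,
        eluate_index=eluate_index,
        grid=x.copy(),
        density=density,
        eluate_volume_ul=eluate_volume_ul,
        plasma_volume_ml=plasma_volume_ml,
        qubit_total_ng_per_ml=qubit_total_ng_per_ml,
    )


def gen_elution_series(
    total_ng: float,
    fractions: Sequence[float],
    eluate_volumes: Sequence[float] = DEFAULT_ELUATE_VOLUMES_UL,
    trace_spec: TraceSpec | None = None,
    seed=0,
    *,
    gdna_total_ng: float = 0.0,
    sample_id: str = "S1",
    plasma_volume_ml: float = DEFAULT_PLASMA_VOLUME_ML,
    qubit_total_ng_per_ml: float | None = None,
) -> list[Electropherogram]:
    """Distribute a total cfDNA mass (ng) over four eluates.

    ``fractions`` (summing to 1) give the mass recovered at each elution
    step; each eluate's concentration follows from its elution volume.
    ``trace_spec`` supplies the nucleosomal peak proportions (mono:di:tri);
    gDNA contamination mass, if any, follows the same fractions.
    """
    fractions = np.asarray(fractions, dtype=float)
    volumes = np.asarray(eluate_volumes, dtype=float)
    if fractions.shape != (4,) or volumes.shape != (4,):
        raise ValueError("need exactly four fractions and four volumes")
    if np.any(fractions < 0):
        raise ValueError("fractions must be nonnegative")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if total_ng < 0 or gdna_total_ng < 0:
        raise ValueError("masses must be nonnegative")
    spec = trace_spec if trace_spec is not None else TraceSpec(mono_amount=0.75, di_amount=0.15, tri_amount=0.10)
    cf_props = np.array([spec.mono_amount, spec.di_amount, spec.tri_amount])
    if cf_props.sum() <= 0:
        raise ValueError("trace_spec must carry nonzero cfDNA proportions")
    cf_props = cf_props / cf_props.sum()

    traces = []
    for k, child in enumerate(_children(seed, 4)):
        cf_pg_per_ul = total_ng * 1000.0 * fractions[k] / volumes[k]
        gdna_pg_per_ul = gdna_total_ng * 1000.0 * fractions[k] / volumes[k]
        eluate_spec = replace(
            spec,
            mono_amount=cf_pg_per_ul * cf_props[0],
            di_amount=cf_pg_per_ul * cf_props[1],
            tri_amount=cf_pg_per_ul * cf_props[2],
            gdna_amount=gdna_pg_per_ul,
        )
        traces.append(
            gen_trace(
                eluate_spec,
                np.random.default_rng(child),
                sample_id=sample_id,
                eluate_index=k + 1,
                eluate_volume_ul=float(volumes[k]),
                plasma_volume_ml=plasma_volume_ml,
                qubit_total_ng_per_ml=qubit_total_ng_per_ml,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# clinical cohort


@dataclass
class GroupSpec:
    """Sampling distributions for one clinical group.

    Concentration (ng/mL plasma) is log-normal; mean mono-nucleosome
    fragment size (bp) is normal; ``size_conc_corr`` couples the two via a
    Gaussian copula (correlation on the latent normal scale, hence the
    rank correlation of the generated pairs).
    """

    n: int
    conc_median_ng_per_ml: float
    conc_log_sd: float
    size_mean_bp: float
    size_sd_bp: float
    size_conc_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if self.conc_log_sd <= 0 or self.size_sd_bp <= 0:
            raise ValueError("scale parameters must be positive")
        if not -1.0 <= self.size_conc_corr <= 1.0:
            raise ValueError("correlation must be in [-1, 1]")


def _default_groups() -> dict[str, GroupSpec]:
    # Calibrated to the published group medians: Bioanalyzer concentrations
    # (healthy 7.6, RP 5.8, disease-free 8.3, mCRPC 22.2 ng/mL without
    # outliers) and mono-nucleosome size medians/ranges (158/160/154/150 bp).
    # SDs back out of the reported min-max ranges via the expected range of a
    # normal sample (d2 factor) at each group's n.
    return {
        "healthy": GroupSpec(14, 7.6, 0.55, 158.0, 13.5),
        "RP": GroupSpec(17, 5.8, 0.55, 160.0, 7.0),
        "disease-free": GroupSpec(10, 8.3, 0.55, 154.0, 7.5),
        "mCRPC": GroupSpec(19, 22.2, 0.55, 150.0, 7.0, size_conc_corr=-0.56),
    }


@dataclass
class CohortSpec:
    """Cohort layout: per-group sampling specs plus mCRPC survival."""

    groups: Mapping[str, GroupSpec] = field(default_factory=_default_groups)
    survival_median_months: float = 30.0
    censor_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.survival_median_months <= 0:
            raise ValueError("survival median must be positive")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValueError("censor fraction must be in [0, 1)")


def gen_cohort(spec: CohortSpec, seed) -> pd.DataFrame:
    """Sample a cohort table.

    Columns: sample_id, group, concentration_ng_per_ml,
    mean_fragment_size_bp, age, survival_months (mCRPC only, NaN elsewhere),
    event (bool). Size-concentration coupling is induced on the latent
    bivariate-normal scale, so the within-group rank correlation tracks the
    spec correlation up to sampling error.
    """
    rng = _rng(seed)
    rows = []
    idx = 0
    for group, g in spec.groups.items():
        rho = g.size_conc_corr
        cov = np.array([[1.0, rho], [rho, 1.0]])
        z = rng.multivariate_normal(np.zeros(2), cov, size=g.n)
        size = g.size_mean_bp + g.size_sd_bp * z[:, 0]
        conc = np.exp(np.log(g.conc_median_ng_per_ml) + g.conc_log_sd * z[:, 1])
        age = rng.uniform(55, 80, size=g.n)
        for i in range(g.n):
            idx += 1
            row = {
                "sample_id": f"P{idx:04d}",
                "group": group,
                "concentration_ng_per_ml": conc[i],
                "mean_fragment_size_bp": float(np.clip(size[i], 50.0, 250.0)),
                "age": age[i],
                "survival_months": np.nan,
                "event": False,
            }
            if group == "mCRPC":
                rate = math.log(2) / spec.survival_median_months
                t = rng.exponential(1.0 / rate)
                censored = rng.random() < spec.censor_fraction
                row["survival_months"] = t * rng.random() if censored else t
                row["event"] = not censored
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# four-caller somatic callsets

DEFAULT_CALLERS = ("mutect2", "vardict", "varscan", "strelka2")

#: Default true somatic variants: the four consensus loci of the worked
#: mCRPC case (ACOX1, STYK1, LGI4, GABRE), with invented VAFs on the low
#: side so depth titration is informative.
def _default_true_variants() -> list["TrueVariant"]:
    return [
        TrueVariant("17", 75957554, "C", "T", 0.08),
        TrueVariant("X", 151962597, "C", "T", 0.10),
        TrueVariant("19", 35125216, "G", "C", 0.06),
        TrueVariant("12", 10622651, "C", "G", 0.065),
    ]


@dataclass(frozen=True)
class TrueVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vaf: float

    def __post_init__(self) -> None:
        if not 0.0 < self.vaf <= 1.0:
            raise ValueError("VAF must be in (0, 1]")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CallsetSpec:
    """Ground truth for a four-caller simulation.

    True somatics appear in each caller independently with that caller's
    sensitivity and have zero germline alt reads. False positives are unique
    to a single caller (they deterministically fail the two-caller rule).
    Germline contaminants are seen by all callers but carry germline support
    and common population frequencies.
    """

    true_variants: list[TrueVariant] = field(default_factory=_default_true_variants)
    depth: int = 147
    sensitivities: Mapping[str, float] = field(
        default_factory=lambda: {
            "mutect2": 0.95,
            "vardict": 0.90,
            "varscan": 0.85,
            "strelka2": 0.90,
        }
    )
    fp_per_caller: int = 3
    germline_contaminants: int = 2
    germline_depth: int = 40
    contaminant_pop_af: float = 0.01

    def __post_init__(self) -> None:
        keys = [v.key for v in self.true_variants]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate variant keys in spec")
        if self.depth <= 0 or self.germline_depth <= 0:
            raise ValueError("depths must be positive")
        for caller, s in self.sensitivities.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"sensitivity for {caller} must be in [0, 1]")
        if self.fp_per_caller < 0 or self.germline_contaminants < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class CallsetBundle:
    """Generated callsets plus the side tables the consensus filter reads."""

    callsets: dict[str, list]  # caller -> list[consensus.CallerVariant]
    germline: pd.DataFrame  # chrom,pos,ref,alt,germline_alt_reads
    annotations: pd.DataFrame  # chrom,pos,ref,alt,max_pop_af,significance
    truth: pd.DataFrame  # chrom,pos,ref,alt,category,true_vaf

    def write(self, outdir) -> dict[str, object]:
        """Write caller VCFs and the germline/annotation TSVs; returns paths."""
        from pathlib import Path

        from .consensus import write_caller_vcf

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, object] = {"vcf": {}}
        for caller, variants in self.callsets.items():
            p = outdir / f"{caller}.vcf"
            write_caller_vcf(variants, p, sample=caller)
            paths["vcf"][caller] = p
        g = outdir / "germline_counts.tsv"
        a = outdir / "annotations.tsv"
        t = outdir / "truth.tsv"
        self.germline.to_csv(g, sep="\t", index=False)
        self.annotations.to_csv(a, sep="\t", index=False)
        self.truth.to_csv(t, sep="\t", index=False)
        paths.update({"germline": g, "annotations": a, "truth": t})
        return paths


_BASES = "ACGT"


def gen_callsets(spec: CallsetSpec, seed) -> CallsetBundle:
    """Simulate per-caller variant lists and matched side tables."""
    from .consensus import CallerVariant

    rng = _rng(seed)
    callers = list(spec.sensitivities)
    callsets: dict[str, list] = {c: [] for c in callers}
    germline_rows, annot_rows, truth_rows = [], [], []

    def _add_annot(key, pop_af, significance):
        annot_rows.append(
            {"chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
             "max_pop_af": pop_af, "significance": significance}
        )

    def _add_germline(key, alt_reads):
        germline_rows.append(
            {"chrom": key[0], "pos": key[1], "ref": key[2], "alt": key[3],
             "germline_alt_reads": int(alt_reads)}
        )

    used = {v.key[:2] for v in spec.true_variants}

    for v in spec.true_variants:
        alt_reads = int(rng.binomial(spec.depth, v.vaf))
        for caller in callers:
            if rng.random() < spec.sensitivities[caller]:
                callsets[caller].append(
                    CallerVariant(caller, v.chrom, v.pos, v.ref, v.alt,
                                  spec.depth, alt_reads)
                )
        _add_germline(v.key, 0)
        _add_annot(v.key, 0.0, "uncertain_significance")
        truth_rows.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                           "alt": v.alt, "category": "somatic", "true_vaf": v.vaf})

    def _novel_site():
        while True:
            chrom = str(rng.integers(1, 23))
            pos = int(rng.integers(1_000_000, 200_000_000))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos

    # caller-specific false positives: plausible counts, unique to one caller
    for caller in callers:
        for _ in range(spec.fp_per_caller):
            chrom, pos = _novel_site()
            ref = _BASES[rng.integers(4)]
            alt = rng.choice([b for b in _BASES if b != ref])
            vaf = float(rng.uniform(0.05, 0.15))
            alt_reads = max(8, int(rng.binomial(spec.depth, vaf)))
            callsets[caller].append(
                CallerVariant(caller, chrom, pos, ref, str(alt), spec.depth, alt_reads)
            )
            key = (chrom, pos, ref, str(alt))
            _add_germline(key, 0)
            _add_annot(key, 0.0, "uncertain_significance")
            truth_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": str(alt),
                               "category": "false_positive", "true_vaf": np.nan})

    # germline contaminants: in every caller, nonzero germline support,
    # common population frequency, half labelled benign
    for i in range(spec.germline_contaminants):
        chrom, pos = _novel_site()
        ref = _BASES[rng.integers(4)]
        alt = rng.choice([b for b in _BASES if b != ref])
        alt_reads = int(rng.binomial(spec.depth, 0.5))
        for caller in callers:
            callsets[caller].append(
                CallerVariant(caller, chrom, pos, ref, str(alt), spec.depth, alt_reads)
            )
        key = (chrom, pos, ref, str(alt))
        g_alt = max(1, int(rng.binomial(spec.germline_depth, 0.5)))
        _add_germline(key, g_alt)
        _add_annot(key, spec.contaminant_pop_af,
                   "benign" if i % 2 == 0 else "likely_benign")
        truth_rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": str(alt),
                           "category": "germline", "true_vaf": np.nan})

    cols_g = ["chrom", "pos", "ref", "alt", "germline_alt_reads"]
    cols_a = ["chrom", "pos", "ref", "alt", "max_pop_af", "significance"]
    cols_t = ["chrom", "pos", "ref", "alt", "category", "true_vaf"]
    return CallsetBundle(
        callsets=callsets,
        germline=pd.DataFrame(germline_rows, columns=cols_g),
        annotations=pd.DataFrame(annot_rows, columns=cols_a),
        truth=pd.DataFrame(truth_rows, columns=cols_t),
    )


# ---------------------------------------------------------------------------
# binned copy-number profiles


@dataclass(frozen=True)
class CNSegment:
    """A copy-number event: tumor copy number ``c`` at cellular prevalence
    ``phi`` over [start, end) (0-based, bp). c=2/phi=1 outside all events."""

    chrom: str
    start: int
    end: int
    c: int
    phi: float = 1.0

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("copy number must be >= 0")
        if not 0.0 < self.phi <= 1.0:
            raise ValueError("prevalence must be in (0, 1]")
        if self.end <= self.start:
            raise ValueError("end must exceed start")


def _default_layout() -> dict[str, int]:
    return {f"chr{i}": 150_000_000 for i in range(1, 21)}


def _default_segments() -> list[CNSegment]:
    # An mCRPC-like truth: clonal loss, clonal gains, a high-level
    # amplification, and two subclonal events.
    return [
        CNSegment("chr8", 30_000_000, 110_000_000, c=1, phi=1.0),
        CNSegment("chr10", 40_000_000, 100_000_000, c=4, phi=1.0),
        CNSegment("chr12", 20_000_000, 70_000_000, c=4, phi=1.0),
        CNSegment("chr13", 60_000_000, 90_000_000, c=6, phi=1.0),
        # off the clonal lattice: TF*phi*(c-2) not a multiple of TF,
        # so subclonality is identifiable from the log2 ratio
        CNSegment("chr16", 30_000_000, 130_000_000, c=3, phi=0.5),
        CNSegment("chr4", 50_000_000, 90_000_000, c=1, phi=0.5),
    ]


@dataclass
class ProfileSpec:
    """Genome layout, copy-number truth, and read-count noise model.

    Counts are negative binomial with mean mu and variance mu + mu^2/r
    (dispersion ``dispersion`` = r). ``mean_reads_per_bin`` sets mu for a
    copy-neutral bin at this profile's depth; the default treats a 1 Mb bin
    as ~10 informative counts per fold-coverage (residual correlation and
    duplication make the effective count far smaller than the raw read
    count), with r = 500 as the depth-independent systematic-noise floor
    (~4.5% CV, the GC/mappability residual scale of corrected data).
    """

    bin_size: int = 1_000_000
    chrom_lengths: Mapping[str, int] = field(default_factory=_default_layout)
    segments: list[CNSegment] = field(default_factory=_default_segments)
    tumor_fraction: float = 0.25
    mean_reads_per_bin: float = 1470.0
    dispersion: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction < 1.0:
            raise ValueError("tumor fraction must be in [0, 1)")
        if self.bin_size <= 0 or self.mean_reads_per_bin <= 0 or self.dispersion <= 0:
            raise ValueError("bin size, mean reads, and dispersion must be positive")
        by_chrom: dict[str, list[CNSegment]] = {}
        for seg in self.segments:
            if seg.chrom not in self.chrom_lengths:
                raise ValueError(f"segment chromosome {seg.chrom} not in layout")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for segs in by_chrom.values():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValueError("overlapping segments within a chromosome")


def expected_log2_ratio(c: int, phi: float, tf: float) -> float:
    """Expected log2 ratio of a (c, phi) event at tumor fraction ``tf``.

    The tumor/normal coverage ratio mixes three cell populations: tumor
    cells carrying the event (TF*phi, copy number c), tumor cells without
    it (TF*(1-phi), diploid), and normal cells (1-TF, diploid):

        log2( (TF*phi*c + TF*(1-phi)*2 + (1-TF)*2) / 2 )
    """
    return math.log2((tf * phi * c + tf * (1.0 - phi) * 2.0 + (1.0 - tf) * 2.0) / 2.0)


def _bin_table(spec: ProfileSpec) -> pd.DataFrame:
    rows = []
    for chrom, length in spec.chrom_lengths.items():
        starts = np.arange(0, length, spec.bin_size)
        ends = np.minimum(starts + spec.bin_size, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _multipliers(spec: ProfileSpec, bins: pd.DataFrame) -> np.ndarray:
    m = np.ones(len(bins))
    tf = spec.tumor_fraction
    for seg in spec.segments:
        mult = (tf * seg.phi * seg.c + tf * (1 - seg.phi) * 2 + (1 - tf) * 2) / 2.0
        mask = (
            (bins["chrom"] == seg.chrom)
            & (bins["start"] >= seg.start)
            & (bins["end"] <= seg.end)
        )
        m[mask.to_numpy()] = mult
    return m


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, r: float) -> np.ndarray:
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def gen_bin_profile(spec: ProfileSpec, seed, *, sample_noise: bool = True):
    """Simulate matched tumor and normal binned read-count profiles.

    Returns ``(tumor, normal)`` as :class:`cfpipe.cnv.BinProfile`. With
    ``sample_noise=False`` counts equal their expectations (noise-free
    profiles for closed-form checks).
    """
    from .cnv import BinProfile

    rng = _rng(seed)
    bins = _bin_table(spec)
    mu_t = spec.mean_reads_per_bin * _multipliers(spec, bins)
    mu_n = np.full(len(bins), spec.mean_reads_per_bin)
    if sample_noise:
        count_t = _nb_draw(rng, mu_t, spec.dispersion).astype(float)
        count_n = _nb_draw(rng, mu_n, spec.dispersion).astype(float)
    else:
        count_t, count_n = mu_t, mu_n
    tumor = bins.assign(count=count_t)
    normal = bins.assign(count=count_n)
    return BinProfile(tumor), BinProfile(normal)


def truth_segments(spec: ProfileSpec):
    """Ground-truth event calls implied by a profile spec, as
    :class:`cfpipe.cnv.Segment` records (for concordance scoring)."""
    from .cnv import Segment, state_of

    out = []
    for seg in spec.segments:
        out.append(
            Segment(
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                n_bins=(seg.end - seg.start) // spec.bin_size,
                mean_log2r=expected_log2_ratio(seg.c, seg.phi, spec.tumor_fraction),
                state=state_of(seg.c, seg.phi),
                c=seg.c,
                phi=seg.phi,
            )
        )
    return out
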