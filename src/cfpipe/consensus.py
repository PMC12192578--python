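"""Five-criterion consensus filtering of four-caller somatic callsets.

A candidate variant passes when it is (I) reported by at least two of the
four callers, (II) covered at >= 10x, (III) has VAF >= 5% (recomputed as
alt/depth from the deepest supporting caller), (IV) has >= 8 alt-supporting
reads in cfDNA and 0 in matched germline DNA, and (V) has a population
allele frequency strictly below 0.01% — and is not annotated benign or
likely benign. Every candidate is kept in an audit table with
per-criterion booleans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "VariantKey",
    "CallerVariant",
    "SiteAnnotation",
    "Candidate",
    "ConsensusVariant",
    "FilterParams",
    "CRITERIA",
    "normalize_variant",
    "merge_callers",
    "apply_criteria",
    "filter_callset",
    "read_caller_vcf",
    "write_caller_vcf",
    "write_passing_vcf",
    "read_annotations_tsv",
    "read_germline_tsv",
]

VariantKey = tuple[str, int, str, str]

#: Criterion identifiers used in failure reasons and the audit table.
CRITERIA = ("I", "II", "III", "IV", "V", "significance")

_ALLOWED = set("ACGT")


@dataclass(frozen=True)
class CallerVariant:
    """One caller's record of a variant with its read support."""

    caller: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.alt_reads > self.depth:
            raise ValueError("alt_reads cannot exceed depth")
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be nonnegative")

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth else 0.0


@dataclass(frozen=True)
class SiteAnnotation:
    """Germline support and population-frequency/significance annotation."""

    germline_alt_reads: int
    max_pop_af: float
    significance: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_pop_af <= 1.0:
            raise ValueError("max_pop_af must be in [0, 1]")
        if self.germline_alt_reads < 0:
            raise ValueError("germline_alt_reads must be nonnegative")


@dataclass
class Candidate:
    """A merged cross-caller candidate keyed by its normalized variant."""

    key: VariantKey
    supporting_callers: tuple[str, ...]
    depth: int
    alt_reads: int

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.depth if self.depth else 0.0


@dataclass
class ConsensusVariant:
    key: VariantKey
    supporting_callers: tuple[str, ...]
    depth: int
    alt_reads: int
    vaf: float
    verdict: str  # "pass" | "fail"
    failure_reasons: tuple[str, ...]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the five consensus criteria.

    ``max_pop_af`` is a fraction: 1e-4 corresponds to "below 0.01%", applied
    strictly (<). Significance matching is case-insensitive with underscores
    treated as spaces.
    """

    min_callers: int = 2
    min_depth: int = 10
    min_vaf: float = 0.05
    min_alt_reads: int = 8
    max_germline_alt: int = 0
    max_pop_af: float = 1e-4
    excluded_significance: tuple[str, ...] = ("benign", "likely benign")

    def __post_init__(self) -> None:
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        if min(self.min_depth, self.min_alt_reads) < 0 or self.min_vaf < 0:
            raise ValueError("thresholds must be nonnegative")
        if not 0.0 <= self.max_pop_af <= 1.0:
            raise ValueError("max_pop_af must be in [0, 1]")


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Canonical representation: trim the shared suffix, then the shared
    prefix (advancing the position), keeping at least one base on each
    allele. SNVs are unchanged."""
    if not ref or not alt:
        raise ValueError("ref and alt must be nonempty")
    if not (set(ref) <= _ALLOWED and set(alt) <= _ALLOWED):
        raise ValueError("alleles must be over A, C, G, T")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:
        raise ValueError("ref and alt are identical after normalization")
    return (str(chrom), int(pos), ref, alt)


def merge_callers(
    callsets: Mapping[str, Iterable[CallerVariant]],
) -> list[Candidate]:
    """Merge per-caller variant lists into one candidate per normalized key.

    Consensus depth and alt reads come from the supporting caller with the
    greatest depth (ties broken by caller name for determinism).
    """
    names = list(callsets)
    if len(set(names)) != len(names):
        raise ValueError("caller names must be distinct")
    merged: dict[VariantKey, list[CallerVariant]] = {}
    for caller, variants in callsets.items():
        seen: set[VariantKey] = set()
        for v in variants:
            if v.caller != caller:
                raise ValueError("variant caller does not match callset name")
            key = normalize_variant(v.chrom, v.pos, v.ref, v.alt)
            if key in seen:
                continue  # a caller reports each site once
            seen.add(key)
            merged.setdefault(key, []).append(v)
    out = []
    for key in sorted(merged, key=lambda k: (k[0], k[1], k[2], k[3])):
        records = merged[key]
        best = max(records, key=lambda v: (v.depth, v.caller))
        out.append(
            Candidate(
                key=key,
                supporting_callers=tuple(sorted(v.caller for v in records)),
                depth=best.depth,
                alt_reads=best.alt_reads,
            )
        )
    return out


def _significance_excluded(label: str, params: FilterParams) -> bool:
    canon = label.strip().lower().replace("_", " ")
    return canon in {s.lower() for s in params.excluded_significance}


def apply_criteria(
    candidate: Candidate,
    annotation: SiteAnnotation | None,
    params: FilterParams = FilterParams(),
) -> ConsensusVariant:
    """Evaluate criteria I-V and the significance exclusion on one candidate.

    A missing annotation fails criterion V conservatively (population
    frequency unknown). The failure list names every violated criterion.
    """
    reasons = []
    if len(candidate.supporting_callers) < params.min_callers:
        reasons.append("I")
    if candidate.depth < params.min_depth:
        reasons.append("II")
    vaf = candidate.vaf
    if vaf < params.min_vaf:
        reasons.append("III")
    germline_alt = annotation.germline_alt_reads if annotation is not None else 0
    if candidate.alt_reads < params.min_alt_reads or germline_alt > params.max_germline_alt:
        reasons.append("IV")
    if annotation is None or not annotation.max_pop_af < params.max_pop_af:
        reasons.append("V")
    if annotation is not None and _significance_excluded(annotation.significance, params):
        reasons.append("significance")
    return ConsensusVariant(
        key=candidate.key,
        supporting_callers=candidate.supporting_callers,
        depth=candidate.depth,
        alt_reads=candidate.alt_reads,
        vaf=vaf,
        verdict="pass" if not reasons else "fail",
        failure_reasons=tuple(reasons),
    )


def filter_callset(
    callsets: Mapping[str, Iterable[CallerVariant]],
    annotations: Mapping[VariantKey, SiteAnnotation],
    params: FilterParams = FilterParams(),
) -> tuple[list[ConsensusVariant], pd.DataFrame]:
    """Run the full consensus filter.

    Returns the passing variants (sorted by chrom, pos) and an audit table
    holding every candidate with per-criterion booleans.
    """
    candidates = merge_callers(callsets)
    results = [apply_criteria(c, annotations.get(c.key), params) for c in candidates]
    rows = []
    for r in results:
        chrom, pos, ref, alt = r.key
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "n_callers": len(r.supporting_callers),
                "callers": ",".join(r.supporting_callers),
                "depth": r.depth,
                "alt_reads": r.alt_reads,
                "vaf": r.vaf,
                **{f"crit_{c}": (c not in r.failure_reasons) for c in CRITERIA},
                "verdict": r.verdict,
                "failure_reasons": ",".join(r.failure_reasons),
            }
        )
    audit = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "n_callers", "callers", "depth",
            "alt_reads", "vaf", *[f"crit_{c}" for c in CRITERIA],
            "verdict", "failure_reasons",
        ],
    )
    passing = [r for r in results if r.verdict == "pass"]
    return passing, audit


# ---------------------------------------------------------------------------
# I/O: VCF v4.2 with FORMAT DP and AD, plus germline/annotation TSVs


def _vcf_header(sample: str, contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##FILTER=<ID=PASS,Description="All filters passed">')
    header.add_meta(
        "FORMAT",
        items=[("ID", "DP"), ("Number", "1"), ("Type", "Integer"),
               ("Description", "Read depth")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
               ("Description", "Allelic depths (ref, alt)")],
    )
    for contig in contigs:
        header.contigs.add(contig)
    header.add_sample(sample)
    return header


def write_caller_vcf(
    variants: Iterable[CallerVariant], path: str | Path, sample: str = "TUMOR"
) -> None:
    """Write one caller's variants as an uncompressed VCF v4.2."""
    variants = list(variants)
    contigs = sorted({v.chrom for v in variants}, key=lambda c: (len(c), c))
    header = _vcf_header(sample, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            rec = vcf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            rec.samples[sample]["DP"] = v.depth
            rec.samples[sample]["AD"] = (v.depth - v.alt_reads, v.alt_reads)
            vcf.write(rec)


def read_caller_vcf(path: str | Path, caller: str) -> list[CallerVariant]:
    """Read a single-sample VCF with FORMAT DP/AD into caller variants."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sample = rec.samples[0]
            depth = int(sample["DP"])
            ad = sample["AD"]
            for i, alt in enumerate(rec.alts or ()):
                out.append(
                    CallerVariant(
                        caller=caller,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        depth=depth,
                        alt_reads=int(ad[i + 1]),
                    )
                )
    return out


def write_passing_vcf(
    passing: Sequence[ConsensusVariant], path: str | Path, sample: str = "CONSENSUS"
) -> None:
    """Write passing consensus variants with caller support in INFO."""
    contigs = sorted({r.key[0] for r in passing}, key=lambda c: (len(c), c))
    header = _vcf_header(sample, contigs)
    header.add_meta(
        "INFO",
        items=[("ID", "CALLERS"), ("Number", "."), ("Type", "String"),
               ("Description", "Supporting callers")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "NCALLERS"), ("Number", "1"), ("Type", "Integer"),
               ("Description", "Number of supporting callers")],
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in passing:
            chrom, pos, ref, alt = r.key
            rec = vcf.new_record(contig=chrom, start=pos - 1, alleles=(ref, alt))
            rec.samples[sample]["DP"] = r.depth
            rec.samples[sample]["AD"] = (r.depth - r.alt_reads, r.alt_reads)
            rec.info["CALLERS"] = ",".join(r.supporting_callers)
            rec.info["NCALLERS"] = len(r.supporting_callers)
            vcf.write(rec)


def read_annotations_tsv(
    annotations_path: str | Path, germline_path: str | Path | None = None
) -> dict[VariantKey, SiteAnnotation]:
    """Assemble per-site annotations from the annotation TSV (chrom, pos,
    ref, alt, max_pop_af, significance) and an optional germline-counts TSV.

    Sites absent from the germline table get 0 germline alt reads (no
    evidence of germline support); sites absent from the annotation table
    stay unannotated and fail criterion V downstream.
    """
    annot = pd.read_csv(annotations_path, sep="\t", dtype={"chrom": str})
    germ: dict[VariantKey, int] = {}
    if germline_path is not None:
        gdf = pd.read_csv(germline_path, sep="\t", dtype={"chrom": str})
        for row in gdf.itertuples(index=False):
            germ[(row.chrom, int(row.pos), row.ref, row.alt)] = int(row.germline_alt_reads)
    out: dict[VariantKey, SiteAnnotation] = {}
    for row in annot.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        out[key] = SiteAnnotation(
            germline_alt_reads=germ.get(key, 0),
            max_pop_af=float(row.max_pop_af),
            significance=str(row.significance),
        )
    return out


def read_germline_tsv(path: str | Path) -> dict[VariantKey, int]:
    gdf = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {
        (row.chrom, int(row.pos), row.ref, row.alt): int(row.germline_alt_reads)
        for row in gdf.itertuples(index=False)
    }


def annotations_from_frames(
    annotations: pd.DataFrame, germline: pd.DataFrame | None = None
) -> dict[VariantKey, SiteAnnotation]:
    """Same assembly as :func:`read_annotations_tsv` but from in-memory
    DataFrames (the synthetic generator's output)."""
    germ: dict[VariantKey, int] = {}
    if germline is not None:
        for row in germline.itertuples(index=False):
            germ[(str(row.chrom), int(row.pos), row.ref, row.alt)] = int(
                row.germline_alt_reads
            )
    out: dict[VariantKey, SiteAnnotation] = {}
    for row in annotations.itertuples(index=False):
        key = (str(row.chrom), int(row.pos), row.ref, row.alt)
        out[key] = SiteAnnotation(
            germline_alt_reads=germ.get(key, 0),
            max_pop_af=float(row.max_pop_af),
            significance=str(row.significance),
        )
    return out
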