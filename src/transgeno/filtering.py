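"""Reliability and marker-suitability filtering of a merged multi-sample VCF.

The cascade reflects how RNA-Seq derived genotypes are turned into a marker
panel for inbred germplasm:

1. depth      — per-sample calls supported by fewer than ``min_reads`` reads
                are set to missing (low-coverage RNA-Seq calls are unreliable;
                a single read cannot support a heterozygote at all);
2. singleton  — sites whose non-reference allele is observed in exactly one
                strain are discarded, as are monomorphic leftovers;
3. conflict   — sites where two libraries of the same strain disagree are
                discarded (replicate inconsistency);
4. multi      — loci with two or more alternate alleles are tallied but kept
                out of the marker panel;
5. neighbor   — sites with another polymorphism within ``neighbor_window`` bp
                on either side are dropped (both members of a close pair), so
                every surviving marker has clean flanking sequence for assay
                or primer design.

Stage order matters and is fixed: depth -> singleton -> conflict -> multi ->
neighbor.  Each stage operates on the survivors of the previous one.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantSite",
    "SampleCall",
    "FilterConfig",
    "FilterReport",
    "CascadeResult",
    "UnsupportedAlleleError",
    "classify_site",
    "depth_filter",
    "singleton_filter",
    "conflict_filter",
    "neighbor_filter",
    "select_library",
    "read_metadata",
    "run_cascade",
    "write_filtered_vcf",
]

SNP = "SNP"
INDEL = "INDEL"
MULTI = "MULTI"

_VALID_BASES = frozenset("ACGT")


class UnsupportedAlleleError(ValueError):
    """Symbolic, breakend or otherwise non-sequence allele."""


@dataclass(frozen=True)
class VariantSite:
    """One VCF site: 1-based position, REF and ALT alleles, and its class."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    vtype: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "vtype", classify_site(self.ref, self.alts))

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


@dataclass
class SampleCall:
    """Per-library genotype at one site.

    ``gt`` is a pair of allele indices into ``(ref, *alts)`` or ``None`` when
    missing; ``depth`` is the total supporting read count.
    """

    strain_id: str
    library_id: str
    gt: tuple[int, int] | None
    depth: int | None = None

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"negative depth {self.depth} for {self.library_id}")

    @property
    def is_missing(self) -> bool:
        return self.gt is None

    @property
    def is_het(self) -> bool:
        return self.gt is not None and self.gt[0] != self.gt[1]

    @property
    def carries_alt(self) -> bool:
        return self.gt is not None and any(a > 0 for a in self.gt)


@dataclass
class FilterConfig:
    """Thresholds and toggles for the cascade.

    ``min_reads=2`` encodes the "more than one read" depth rule and
    ``neighbor_window=60`` the flanking-polymorphism exclusion window.
    ``neighbor_inclusive`` controls the boundary: when True (default) a pair
    at distance exactly ``neighbor_window`` is removed; when False only
    strictly closer pairs are.  ``min_reads_hets_only`` restricts the depth
    rule to heterozygous calls.
    """

    min_reads: int = 2
    neighbor_window: int = 60
    drop_singletons: bool = True
    drop_conflicts: bool = True
    drop_multiallelic_from_panel: bool = True
    neighbor_inclusive: bool = True
    min_reads_hets_only: bool = False
    preference_tissues: tuple[str, ...] = ("shoot_root",)

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.neighbor_window < 0:
            raise ValueError("neighbor_window must be >= 0")


@dataclass
class FilterReport:
    """Site accounting across the cascade stages."""

    n_detected: int = 0
    n_reliable_snp: int = 0
    n_reliable_indel: int = 0
    n_final_snp: int = 0
    n_final_indel: int = 0
    n_multi: int = 0
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_reliable(self) -> int:
        return self.n_reliable_snp + self.n_reliable_indel

    @property
    def n_final(self) -> int:
        return self.n_final_snp + self.n_final_indel

    def to_dict(self) -> dict:
        return {
            "n_detected": self.n_detected,
            "n_reliable": self.n_reliable,
            "n_reliable_snp": self.n_reliable_snp,
            "n_reliable_indel": self.n_reliable_indel,
            "n_final": self.n_final,
            "n_final_snp": self.n_final_snp,
            "n_final_indel": self.n_final_indel,
            "n_multi": self.n_multi,
            "stage_counts": dict(self.stage_counts),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")


def classify_site(ref: str, alts: Sequence[str]) -> str:
    """SNP (single same-length-1 alt), INDEL (single length-changing alt) or MULTI."""
    if not alts:
        raise ValueError("site must have at least one ALT allele")
    for allele in (ref, *alts):
        if not allele or not set(allele.upper()) <= _VALID_BASES:
            raise UnsupportedAlleleError(f"unsupported allele {allele!r}")
    if len(alts) >= 2:
        return MULTI
    alt = alts[0]
    if len(ref) == 1 and len(alt) == 1:
        return SNP
    return INDEL


def depth_filter(call: SampleCall, min_reads: int = 2) -> bool:
    """True when the call's read depth supports keeping it.

    A failing call is set to missing by the cascade, not removed site-wide.
    """
    if call.is_missing:
        raise ValueError("depth_filter requires a non-missing call")
    if call.depth is None or call.depth == 0:
        raise ValueError(
            f"non-missing call without positive depth ({call.library_id})"
        )
    return call.depth >= min_reads


def singleton_filter(site_calls: Sequence[SampleCall]) -> bool:
    """Pass iff >= 2 strains carry a non-reference allele among non-missing calls.

    Fails for singletons (exactly one carrier strain), monomorphic sites
    (zero carriers) and all-missing sites.
    """
    carriers = {c.strain_id for c in site_calls if c.carries_alt}
    return len(carriers) >= 2


def conflict_filter(site_calls: Sequence[SampleCall]) -> bool:
    """Pass unless some strain's replicate libraries make unequal non-missing calls."""
    by_strain: dict[str, set[tuple[int, int]]] = defaultdict(set)
    for c in site_calls:
        if not c.is_missing:
            by_strain[c.strain_id].add(tuple(sorted(c.gt)))
    return all(len(gts) <= 1 for gts in by_strain.values())


def neighbor_filter(
    sites: Sequence[VariantSite], window: int = 60, inclusive: bool = True
) -> list[VariantSite]:
    """Keep only sites with no other site within ``window`` bp on the same chromosome.

    Both members of a too-close pair are dropped.  A single sorted sweep
    suffices: a violation with any site implies one with an adjacent site.
    Input is sorted internally if needed.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    ordered = sorted(sites, key=lambda s: (s.chrom, s.pos))

    def too_close(a: VariantSite, b: VariantSite) -> bool:
        if a.chrom != b.chrom:
            return False
        d = abs(b.pos - a.pos)
        return d <= window if inclusive else d < window

    kept = []
    n = len(ordered)
    for i, s in enumerate(ordered):
        if i > 0 and too_close(ordered[i - 1], s):
            continue
        if i < n - 1 and too_close(s, ordered[i + 1]):
            continue
        kept.append(s)
    return kept


def select_library(
    libraries: Mapping[str, str] | Sequence[tuple[str, str]],
    preference_tissues: Sequence[str] = ("shoot_root",),
) -> str:
    """Pick one library for a strain: first preferred tissue, else smallest id.

    ``libraries`` maps library_id -> tissue tag.  The choice is deterministic:
    tissues are tried in preference order, ties broken lexicographically.
    """
    items = dict(libraries)
    if not items:
        raise ValueError("strain has no libraries")
    for tissue in preference_tissues:
        matches = sorted(lib for lib, t in items.items() if t == tissue)
        if matches:
            return matches[0]
    return min(items)


def read_metadata(source: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with columns strain_id, library_id, tissue, row_type."""
    meta = pd.read_csv(source, sep="\t", dtype=str)
    required = {"strain_id", "library_id", "tissue", "row_type"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["library_id"].duplicated().any():
        dups = meta.loc[meta["library_id"].duplicated(), "library_id"].tolist()
        raise ValueError(f"duplicate library ids in metadata: {dups}")
    return meta


@dataclass
class CascadeResult:
    """Everything the cascade produces: the marker panel and its accounting."""

    sites: list[VariantSite]
    matrix: "GenotypeMatrix"  # noqa: F821 - imported lazily to avoid a cycle
    report: FilterReport
    primary_library: dict[str, str]
    surviving_keys: set[tuple[str, int]]


@dataclass
class _SiteRecord:
    site: VariantSite
    calls: list[SampleCall]  # all libraries, depth-masked

    def primary_calls(self, primary: Mapping[str, str]) -> list[SampleCall]:
        return [c for c in self.calls if primary[c.strain_id] == c.library_id]


def _parse_vcf_sites(
    vcf_path: str | Path, lib_to_strain: Mapping[str, str]
) -> Iterable[_SiteRecord]:
    import pysam

    with pysam.VariantFile(str(vcf_path)) as vcf:
        unmapped = [s for s in vcf.header.samples if s not in lib_to_strain]
        if unmapped:
            raise ValueError(
                "VCF samples absent from metadata: " + ", ".join(sorted(unmapped))
            )
        for rec in vcf:
            if rec.alts is None:
                continue
            site = VariantSite(rec.chrom, rec.pos, rec.ref, tuple(rec.alts))
            calls = []
            for lib in rec.samples:
                s = rec.samples[lib]
                gt = s.get("GT")
                if gt is None or any(a is None for a in gt):
                    parsed = None
                else:
                    parsed = (gt[0], gt[-1]) if len(gt) >= 2 else (gt[0], gt[0])
                depth = s.get("DP")
                if depth is None and "AD" in s and s["AD"] is not None:
                    depth = sum(a for a in s["AD"] if a is not None)
                calls.append(
                    SampleCall(
                        strain_id=lib_to_strain[lib],
                        library_id=lib,
                        gt=parsed,
                        depth=int(depth) if depth is not None else None,
                    )
                )
            yield _SiteRecord(site, calls)


def run_cascade(
    vcf_path: str | Path,
    metadata: pd.DataFrame | str | Path,
    config: FilterConfig | None = None,
) -> CascadeResult:
    """Run the five-stage filter cascade over a merged multi-sample VCF.

    Returns the surviving marker sites, the sites-by-strains genotype matrix
    (built from each strain's preferred library) and the stage accounting.
    Sites that are homozygous-reference in every strain never enter the
    cascade and are not counted as detected polymorphisms.
    """
    from .matrix import GenotypeMatrix

    config = config or FilterConfig()
    if not isinstance(metadata, pd.DataFrame):
        metadata = read_metadata(metadata)
    lib_to_strain = dict(zip(metadata["library_id"], metadata["strain_id"]))
    primary: dict[str, str] = {}
    for strain, grp in metadata.groupby("strain_id"):
        primary[strain] = select_library(
            dict(zip(grp["library_id"], grp["tissue"])), config.preference_tissues
        )

    report = FilterReport()
    detected: list[_SiteRecord] = []
    for rec in _parse_vcf_sites(vcf_path, lib_to_strain):
        prim = rec.primary_calls(primary)
        if not any(c.carries_alt for c in prim):
            continue  # homozygous-reference (or missing) across all strains
        detected.append(rec)
    report.n_detected = len(detected)
    report.stage_counts["detected"] = len(detected)

    # Stage 1: depth — mask unsupported calls to missing.
    for rec in detected:
        for c in rec.calls:
            if c.is_missing:
                continue
            if config.min_reads_hets_only and not c.is_het:
                continue
            if not depth_filter(c, config.min_reads):
                c.gt = None
    after_depth = [
        r for r in detected if any(c.carries_alt for c in r.primary_calls(primary))
    ]
    report.stage_counts["after_depth"] = len(after_depth)

    # Stage 2: singleton (evaluated on one call per strain).
    if config.drop_singletons:
        after_singleton = [
            r for r in after_depth if singleton_filter(r.primary_calls(primary))
        ]
    else:
        after_singleton = list(after_depth)
    report.stage_counts["after_singleton"] = len(after_singleton)

    # Stage 3: within-strain replicate conflicts (all libraries).
    if config.drop_conflicts:
        after_conflict = [r for r in after_singleton if conflict_filter(r.calls)]
    else:
        after_conflict = list(after_singleton)
    report.stage_counts["after_conflict"] = len(after_conflict)

    report.n_multi = sum(1 for r in after_conflict if r.site.vtype == MULTI)
    for r in after_conflict:
        if r.site.vtype == SNP:
            report.n_reliable_snp += 1
        elif r.site.vtype == INDEL:
            report.n_reliable_indel += 1

    # Stage 4: multi-allele exclusion from the panel.
    if config.drop_multiallelic_from_panel:
        panel_candidates = [r for r in after_conflict if r.site.vtype != MULTI]
    else:
        panel_candidates = list(after_conflict)
    report.stage_counts["after_multi"] = len(panel_candidates)

    # Stage 5: neighbor window.
    kept_sites = neighbor_filter(
        [r.site for r in panel_candidates],
        config.neighbor_window,
        config.neighbor_inclusive,
    )
    kept_keys = {s.key for s in kept_sites}
    final = [r for r in panel_candidates if r.site.key in kept_keys]
    final.sort(key=lambda r: (r.site.chrom, r.site.pos))
    report.stage_counts["after_neighbor"] = len(final)
    for r in final:
        if r.site.vtype == SNP:
            report.n_final_snp += 1
        elif r.site.vtype == INDEL:
            report.n_final_indel += 1

    strains = sorted(primary)
    rows = []
    for r in final:
        row = {}
        for c in r.primary_calls(primary):
            if c.is_missing:
                row[c.strain_id] = "."
            else:
                alleles = r.site.alleles
                row[c.strain_id] = "/".join(alleles[i] for i in sorted(c.gt))
        rows.append([row.get(s, ".") for s in strains])
    matrix = GenotypeMatrix(
        sites=[r.site for r in final],
        strains=strains,
        calls=pd.DataFrame(rows, columns=strains, dtype=object),
        groups=dict(zip(metadata["strain_id"], metadata["row_type"])),
    )
    return CascadeResult(
        sites=[r.site for r in final],
        matrix=matrix,
        report=report,
        primary_library=primary,
        surviving_keys={r.site.key for r in final},
    )


def write_filtered_vcf(
    in_vcf: str | Path,
    out_vcf: str | Path,
    result: CascadeResult,
    config: FilterConfig | None = None,
) -> None:
    """Write the surviving sites back out as a VCF, with depth-failed calls masked."""
    import pysam

    config = config or FilterConfig()
    with pysam.VariantFile(str(in_vcf)) as vcf:
        with pysam.VariantFile(str(out_vcf), "w", header=vcf.header) as out:
            for rec in vcf:
                if (rec.chrom, rec.pos) not in result.surviving_keys:
                    continue
                for lib in rec.samples:
                    s = rec.samples[lib]
                    gt = s.get("GT")
                    if gt is None or any(a is None for a in gt):
                        continue
                    depth = s.get("DP")
                    is_het = gt[0] != gt[-1]
                    if config.min_reads_hets_only and not is_het:
                        continue
                    if depth is not None and depth < config.min_reads:
                        s["GT"] = (None, None)
                out.write(rec)
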