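"""Analytics over the filtered sites-by-strains genotype matrix.

Covers the three downstream questions a breeder asks of a marker panel:
how many markers separate any two strains (pairwise differences), which
markers remain informative within a germplasm group after minor-allele-
frequency and missingness thresholds, and where the panel leaves long
polymorphism-free stretches of the genome (marker deserts).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .filtering import INDEL, SNP, VariantSite

__all__ = [
    "GenotypeMatrix",
    "PairwiseCell",
    "GapRegion",
    "pairwise_diff",
    "pairwise_tables",
    "group_filter",
    "scan_gaps",
    "chromosome_distribution",
]

MISSING = "."


@dataclass
class GenotypeMatrix:
    """Sites x strains genotype call table.

    Calls are allele-string genotypes like ``"A/G"`` (allele order follows
    ascending allele index, so homozygotes read ``"A/A"``) with ``"."`` for
    missing.  ``groups`` optionally maps each strain to a germplasm group
    (here: barley row type).
    """

    sites: list[VariantSite]
    strains: list[str]
    calls: pd.DataFrame
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.sites), len(self.strains)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.strains)} strains"
            )
        keys = [(s.chrom, s.pos) for s in self.sites]
        if keys != sorted(keys):
            raise ValueError("sites must be sorted by (chrom, pos)")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def positions_by_chrom(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for s in self.sites:
            out.setdefault(s.chrom, []).append(s.pos)
        return out

    def subset(self, site_indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(site_indices)
        return GenotypeMatrix(
            sites=[self.sites[i] for i in idx],
            strains=list(self.strains),
            calls=self.calls.iloc[idx].reset_index(drop=True),
            groups=None if self.groups is None else dict(self.groups),
        )

    def to_tsv(self, path: str | Path) -> None:
        meta = pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "ref": [s.ref for s in self.sites],
                "alt": [",".join(s.alts) for s in self.sites],
                "vtype": [s.vtype for s in self.sites],
            }
        )
        pd.concat([meta, self.calls], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str | Path, groups: Mapping[str, str] | None = None
    ) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str)
        fixed = ["chrom", "pos", "ref", "alt", "vtype"]
        strains = [c for c in df.columns if c not in fixed]
        sites = [
            VariantSite(r.chrom, int(r.pos), r.ref, tuple(r.alt.split(",")))
            for r in df.itertuples()
        ]
        calls = df[strains].fillna(MISSING).astype(object).reset_index(drop=True)
        return cls(
            sites=sites,
            strains=strains,
            calls=calls,
            groups=None if groups is None else dict(groups),
        )


@dataclass(frozen=True)
class PairwiseCell:
    """Counts of sites where two strains differ, split by variant class."""

    snp_count: int
    indel_count: int

    @property
    def total(self) -> int:
        return self.snp_count + self.indel_count


@dataclass(frozen=True)
class GapRegion:
    """Interval between adjacent markers with no polymorphism inside.

    Length is the plain difference of the flanking 1-based marker positions,
    endpoints exclusive.
    """

    chrom: str
    left_pos: int
    right_pos: int

    def __post_init__(self) -> None:
        if self.right_pos <= self.left_pos:
            raise ValueError("right_pos must exceed left_pos")

    @property
    def length(self) -> int:
        return self.right_pos - self.left_pos


def pairwise_diff(matrix: GenotypeMatrix) -> dict[tuple[str, str], PairwiseCell]:
    """Count differing sites for every unordered strain pair.

    A site counts when both strains are called (non-missing) and the genotype
    strings differ; het-vs-hom is a difference.  Missing-vs-anything is not,
    so missingness never inflates a distance.
    """
    calls = matrix.calls.to_numpy(dtype=object)
    is_snp = np.array([s.vtype == SNP for s in matrix.sites])
    is_indel = np.array([s.vtype == INDEL for s in matrix.sites])
    called = calls != MISSING
    out: dict[tuple[str, str], PairwiseCell] = {}
    n = len(matrix.strains)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                cell = PairwiseCell(0, 0)
            else:
                both = called[:, i] & called[:, j]
                diff = both & (calls[:, i] != calls[:, j])
                cell = PairwiseCell(
                    int(np.count_nonzero(diff & is_snp)),
                    int(np.count_nonzero(diff & is_indel)),
                )
            a, b = matrix.strains[i], matrix.strains[j]
            out[(a, b)] = cell
            out[(b, a)] = cell
    return out


def pairwise_tables(
    matrix: GenotypeMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise differences as two square DataFrames (SNP counts, indel counts)."""
    cells = pairwise_diff(matrix)
    strains = matrix.strains
    snp = pd.DataFrame(
        [[cells[(a, b)].snp_count for b in strains] for a in strains],
        index=strains,
        columns=strains,
    )
    indel = pd.DataFrame(
        [[cells[(a, b)].indel_count for b in strains] for a in strains],
        index=strains,
        columns=strains,
    )
    return snp, indel


def _allele_counts(gt: str) -> list[str]:
    return gt.split("/")


def group_filter(
    matrix: GenotypeMatrix,
    group_label: str,
    maf_min: float = 0.1,
    miss_max: float = 0.5,
) -> list[int]:
    """Indices of sites informative within one strain group.

    Restricted to the group's strains, a site is dropped when its minor
    allele frequency is below ``maf_min`` or its missing-call fraction is at
    least ``miss_max``.  MAF is computed over called alleles: a homozygote
    contributes two copies of its allele, a heterozygote one of each; the
    minor allele is the second most frequent one.
    """
    if matrix.groups is None:
        raise ValueError("matrix has no strain-group assignment")
    members = [s for s in matrix.strains if matrix.groups.get(s) == group_label]
    if not members:
        raise ValueError(f"unknown or empty group {group_label!r}")
    if len(members) < 2:
        raise ValueError(f"group {group_label!r} needs >= 2 strains")
    sub = matrix.calls[members]
    kept: list[int] = []
    for i in range(matrix.n_sites):
        row = sub.iloc[i]
        n_missing = int((row == MISSING).sum())
        miss_frac = n_missing / len(members)
        counts: dict[str, int] = {}
        for gt in row:
            if gt == MISSING:
                continue
            for allele in _allele_counts(gt):
                counts[allele] = counts.get(allele, 0) + 1
        total = sum(counts.values())
        if total == 0:
            continue
        freqs = sorted((c / total for c in counts.values()), reverse=True)
        maf = freqs[1] if len(freqs) > 1 else 0.0
        if maf >= maf_min and miss_frac < miss_max:
            kept.append(i)
    return kept


def scan_gaps(
    marker_positions: Mapping[str, Sequence[int]],
    min_len: int = 1_000_000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[GapRegion]:
    """Find polymorphism-free stretches longer than ``min_len`` bp.

    ``marker_positions`` maps chromosome -> 1-based marker positions.  A gap
    is an interval between adjacent markers whose position difference is
    strictly greater than ``min_len``.  Chromosome-end gaps (before the first
    or after the last marker) are included only when ``chrom_sizes`` is
    given.  Results are sorted by length, longest first.
    """
    gaps: list[GapRegion] = []
    for chrom, positions in marker_positions.items():
        ps = sorted(positions)
        bounds = list(ps)
        if chrom_sizes is not None:
            bounds = [1] + bounds + [chrom_sizes[chrom]]
        for left, right in zip(bounds, bounds[1:]):
            if right - left > min_len:
                gaps.append(GapRegion(chrom, left, right))
    gaps.sort(key=lambda g: (-g.length, g.chrom, g.left_pos))
    return gaps


def chromosome_distribution(
    matrix: GenotypeMatrix, bin_size: int = 10_000_000
) -> pd.DataFrame:
    """Marker counts per chromosome bin (bin start = floor(pos/bin)*bin + 1)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if matrix.n_sites == 0:
        return pd.DataFrame(columns=["chrom", "bin_start", "count"])
    rows: dict[tuple[str, int], int] = {}
    for s in matrix.sites:
        start = ((s.pos - 1) // bin_size) * bin_size + 1
        rows[(s.chrom, start)] = rows.get((s.chrom, start), 0) + 1
    df = pd.DataFrame(
        [(c, b, n) for (c, b), n in sorted(rows.items())],
        columns=["chrom", "bin_start", "count"],
    )
    return df
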