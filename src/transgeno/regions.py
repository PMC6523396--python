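"""Transcribed-region construction from gene models.

A "transcribed region" is the full genomic span of a gene locus (exons plus
introns) extended by a fixed flank on both sides, after which overlapping or
book-ended spans are concatenated into a single region.  The merged region set
is the target space for read mapping and genotyping in an RNA-Seq based
marker pipeline: it is far smaller than a large crop genome while still
containing essentially all positions a transcriptome read can cover.

Coordinates are 0-based half-open everywhere inside this package; GFF3
(1-based closed) is converted at the parsing boundary and BED output needs no
conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "GeneLocus",
    "TranscribedRegion",
    "RegionStats",
    "GffParseError",
    "read_gene_models",
    "read_chrom_sizes",
    "extend_locus",
    "merge_intervals",
    "build_transcribed_regions",
    "region_stats",
    "write_regions_bed",
    "read_regions_bed",
    "extract_region_fasta",
    "write_regions_fasta",
]

DEFAULT_FLANK_BP = 3000


class GffParseError(ValueError):
    """Raised for a malformed GFF3 line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open coordinate span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval [{self.start},{self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass(frozen=True)
class GeneLocus:
    """A gene-level feature: full genomic span including introns.

    ``source`` distinguishes high-confidence reference annotation ("HC") from
    novel loci assembled from RNA-Seq evidence ("novel").
    """

    locus_id: str
    interval: GenomicInterval
    strand: str = "unknown"  # one of "+", "-", "unknown"
    source: str = "novel"  # "HC" or "novel"


@dataclass(frozen=True)
class TranscribedRegion:
    """A merged locus span plus flanks, carrying its member locus ids."""

    interval: GenomicInterval
    member_locus_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.member_locus_ids:
            raise ValueError("TranscribedRegion requires at least one member locus")


@dataclass(frozen=True)
class RegionStats:
    n_regions: int
    total_bp: int
    ratio_vs_reference: float

    def render_ratio(self) -> str:
        return f"{self.ratio_vs_reference:.2f}"


def _open_maybe(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "rt"), True
    return source, False


def read_gene_models(
    gff3: str | Path | IO[str], confidence_tag: str = "HC"
) -> list[GeneLocus]:
    """Read gene-level features from a GFF3 stream or path.

    One :class:`GeneLocus` is produced per feature of type ``gene``.
    The GFF source column equal to ``confidence_tag`` marks a locus as
    high-confidence; any other source is treated as a novel locus.
    1-based closed GFF coordinates become 0-based half-open.
    """
    handle, close = _open_maybe(gff3)
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffParseError(
                    f"expected 9 tab-separated columns, got {len(cols)}", lineno
                )
            chrom, source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GffParseError(
                    f"non-integer coordinates {start_s!r}/{end_s!r}", lineno
                ) from None
            if end1 < start1:
                raise GffParseError(
                    f"rejected record: end {end1} < start {start1}", lineno
                )
            locus_id = _attr(attrs, "ID", lineno)
            if locus_id in seen:
                raise GffParseError(f"duplicate locus id {locus_id!r}", lineno)
            seen.add(locus_id)
            loci.append(
                GeneLocus(
                    locus_id=locus_id,
                    interval=GenomicInterval(chrom, start1 - 1, end1),
                    strand=strand if strand in ("+", "-") else "unknown",
                    source="HC" if source == confidence_tag else "novel",
                )
            )
    finally:
        if close:
            handle.close()
    return loci


def _attr(attrs: str, key: str, lineno: int) -> str:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    raise GffParseError(f"attribute {key!r} missing", lineno)


def read_chrom_sizes(source: str | Path | IO[str]) -> dict[str, int]:
    """Two-column TSV (chromosome name, length in bp) -> dict."""
    handle, close = _open_maybe(source)
    sizes: dict[str, int] = {}
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"chrom-sizes line {lineno}: expected 2 columns")
            sizes[parts[0]] = int(parts[1])
    finally:
        if close:
            handle.close()
    return sizes


def extend_locus(
    locus: GeneLocus, flank_bp: int = DEFAULT_FLANK_BP, chrom_len: int | None = None
) -> GenomicInterval:
    """Extend a locus span by ``flank_bp`` on both sides, clipped to the chromosome.

    Flanks are symmetric and strand-agnostic: upstream and downstream are both
    extended regardless of strand, which is the only well-defined behaviour
    for strand-unknown novel loci.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    iv = locus.interval
    if chrom_len is not None and chrom_len < iv.end:
        raise ValueError(
            f"chromosome length {chrom_len} shorter than locus end {iv.end} "
            f"({locus.locus_id} on {iv.chrom})"
        )
    start = max(0, iv.start - flank_bp)
    end = iv.end + flank_bp
    if chrom_len is not None:
        end = min(chrom_len, end)
    return GenomicInterval(iv.chrom, start, end)


def merge_intervals(
    intervals: Sequence[GenomicInterval],
    member_ids: Sequence[str] | None = None,
) -> list[TranscribedRegion]:
    """Concatenate overlapping or book-ended intervals into sorted regions.

    Input order is irrelevant; output is sorted by (chrom, start) and
    pairwise non-overlapping.  Touching intervals (``[0,100)`` + ``[100,200)``)
    are merged.  Each output region carries the ids of all merged members.
    """
    if member_ids is None:
        member_ids = [f"iv{i}" for i in range(len(intervals))]
    if len(member_ids) != len(intervals):
        raise ValueError("member_ids length must match intervals")
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].chrom,
                                                         intervals[i].start,
                                                         intervals[i].end))
    regions: list[TranscribedRegion] = []
    cur_iv: GenomicInterval | None = None
    cur_ids: list[str] = []
    for i in order:
        iv = intervals[i]
        if cur_iv is not None and iv.chrom == cur_iv.chrom and iv.start <= cur_iv.end:
            if iv.end > cur_iv.end:
                cur_iv = GenomicInterval(cur_iv.chrom, cur_iv.start, iv.end)
            cur_ids.append(member_ids[i])
        else:
            if cur_iv is not None:
                regions.append(TranscribedRegion(cur_iv, tuple(cur_ids)))
            cur_iv = iv
            cur_ids = [member_ids[i]]
    if cur_iv is not None:
        regions.append(TranscribedRegion(cur_iv, tuple(cur_ids)))
    return regions


def build_transcribed_regions(
    loci: Iterable[GeneLocus],
    flank_bp: int = DEFAULT_FLANK_BP,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[TranscribedRegion]:
    """Extend every locus by the flank and merge the results."""
    loci = list(loci)
    extended = [
        extend_locus(
            locus,
            flank_bp,
            None if chrom_sizes is None else chrom_sizes[locus.interval.chrom],
        )
        for locus in loci
    ]
    return merge_intervals(extended, [l.locus_id for l in loci])


def region_stats(
    regions: Sequence[TranscribedRegion], reference_total_bp: int
) -> RegionStats:
    """Count regions and total bp; ratio against a reference region set total."""
    if reference_total_bp <= 0:
        raise ValueError("reference_total_bp must be > 0")
    total = sum(r.interval.length for r in regions)
    return RegionStats(
        n_regions=len(regions),
        total_bp=total,
        ratio_vs_reference=total / reference_total_bp,
    )


def write_regions_bed(regions: Iterable[TranscribedRegion], out: str | Path | IO[str]) -> None:
    """BED4: chrom, 0-based start, end, comma-joined member locus ids."""
    handle, close = (open(out, "wt"), True) if isinstance(out, (str, Path)) else (out, False)
    try:
        for r in regions:
            iv = r.interval
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{','.join(r.member_locus_ids)}\n")
    finally:
        if close:
            handle.close()


def read_regions_bed(source: str | Path | IO[str]) -> list[TranscribedRegion]:
    handle, close = _open_maybe(source)
    regions = []
    try:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, start, end, names = line.split("\t")[:4]
            regions.append(
                TranscribedRegion(
                    GenomicInterval(chrom, int(start), int(end)),
                    tuple(names.split(",")),
                )
            )
    finally:
        if close:
            handle.close()
    return regions


def extract_region_fasta(
    regions: Iterable[TranscribedRegion], genome_fasta: str | Path
) -> list[tuple[str, str]]:
    """Extract region sequences; record ids are ``chrom:start-end`` (0-based half-open)."""
    from pyfaidx import Fasta

    genome = Fasta(str(genome_fasta), as_raw=True, rebuild=True)
    records: list[tuple[str, str]] = []
    for r in regions:
        iv = r.interval
        if iv.chrom not in genome:
            raise ValueError(f"chromosome {iv.chrom!r} absent from {genome_fasta}")
        records.append((f"{iv.chrom}:{iv.start}-{iv.end}", str(genome[iv.chrom][iv.start:iv.end])))
    return records


def write_regions_fasta(
    regions: Iterable[TranscribedRegion],
    genome_fasta: str | Path,
    out: str | Path | IO[str],
    width: int = 80,
) -> None:
    records = extract_region_fasta(regions, genome_fasta)
    handle, close = (open(out, "wt"), True) if isinstance(out, (str, Path)) else (out, False)
    try:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()
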