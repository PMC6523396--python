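"""Genotype agreement statistics, within and across platforms.

Two independent quality checks for an RNA-Seq derived genotype panel:

* **replicate agreement** — where a strain was sequenced as two (or three)
  RNA libraries, genotype calls shared by both libraries either agree or
  disagree; sites seen in only one library are excluded from the rate.
* **cross-platform concordance** — genotypes at a targeted marker panel are
  re-determined by high-depth amplicon resequencing and compared per strain
  and per marker, stratified by SNP vs indel.  Markers whose amplicon mean
  depth falls below a threshold (default 100x) are gated out first.

Rates follow the contingency conventions of a strain-by-strain comparison
table: per-strain rates are percentages rounded half-up to three decimals,
and panel-level SNP/indel summaries are means of the per-strain rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Hashable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ReplicateAgreement",
    "MarkerPanelEntry",
    "ConcordanceRow",
    "ConcordanceSummary",
    "MarkerSummary",
    "round_half_up",
    "rate_percent",
    "normalize_genotype",
    "replicate_agreement",
    "depth_gate",
    "strain_concordance",
    "summarize",
    "marker_summary",
    "load_table2",
    "rows_from_counts",
]


def round_half_up(x: float | Decimal, ndigits: int) -> float:
    """Decimal half-up rounding (0.0005 -> 0.001), unlike banker's ``round``."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def rate_percent(numerator: int, denominator: int, ndigits: int = 3) -> float | None:
    """``100 * numerator / denominator`` rounded half-up; None when undefined."""
    if denominator == 0:
        return None
    exact = Decimal(numerator) * 100 / Decimal(denominator)
    return float(exact.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


def _trim_alleles(alleles: tuple[str, ...]) -> tuple[str, ...]:
    """Jointly trim shared trailing then leading bases, keeping one anchor base.

    Callers on different platforms pad indel alleles differently; trimming the
    bases common to every allele of a genotype yields a canonical minimal
    representation so that e.g. ATCC/AC and ATC/A describe the same deletion.
    """
    alleles = tuple(a.upper() for a in alleles)
    if len(set(alleles)) < 2:
        # a homozygous genotype carries no internal length contrast to trim
        return alleles
    while all(len(a) > 1 for a in alleles) and len({a[-1] for a in alleles}) == 1:
        alleles = tuple(a[:-1] for a in alleles)
    while all(len(a) > 1 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = tuple(a[1:] for a in alleles)
    return alleles


def normalize_genotype(gt: str) -> str:
    """Canonical form of an allele-string genotype like ``"ATCC/AC"``.

    Allele order is made irrelevant (sorted) and shared padding removed, so
    platform-specific indel representations compare equal.
    """
    alleles = _trim_alleles(tuple(gt.split("/")))
    return "/".join(sorted(alleles))


@dataclass(frozen=True)
class ReplicateAgreement:
    """Agreement between two libraries of one strain."""

    strain_id: str
    agreed: int
    disagreed: int
    one_library_only: int

    @property
    def total_compared(self) -> int:
        return self.agreed + self.disagreed

    @property
    def rate(self) -> float | None:
        """Percent agreement over sites called in both libraries; None if none."""
        return rate_percent(self.agreed, self.total_compared)


def replicate_agreement(
    calls_lib1: Mapping[Hashable, str],
    calls_lib2: Mapping[Hashable, str],
    strain_id: str = "",
) -> ReplicateAgreement:
    """Compare two site-indexed call sets from replicate libraries.

    Sites present in exactly one library go to ``one_library_only`` and are
    excluded from the rate; identical genotypes (after normalization) count
    as agreed, different ones as disagreed.
    """
    shared = calls_lib1.keys() & calls_lib2.keys()
    agreed = sum(
        1
        for k in shared
        if normalize_genotype(calls_lib1[k]) == normalize_genotype(calls_lib2[k])
    )
    return ReplicateAgreement(
        strain_id=strain_id,
        agreed=agreed,
        disagreed=len(shared) - agreed,
        one_library_only=len(calls_lib1.keys() ^ calls_lib2.keys()),
    )


@dataclass(frozen=True)
class MarkerPanelEntry:
    marker_id: str
    chrom: str
    pos: int
    vtype: str  # SNP or INDEL
    mean_depth: float


def depth_gate(
    panel: Sequence[MarkerPanelEntry], min_mean_depth: float = 100.0
) -> list[MarkerPanelEntry]:
    """Retain markers whose amplicon mean depth is at least the threshold.

    "Less than" is strict: a marker at exactly the threshold is retained.
    """
    return [m for m in panel if m.mean_depth >= min_mean_depth]


@dataclass(frozen=True)
class ConcordanceRow:
    """Per-strain platform-comparison contingency counts and rates."""

    strain_id: str
    true_snp: int
    true_indel: int
    false_snp: int
    false_indel: int
    not_detected: int

    @property
    def rate_total(self) -> float | None:
        return rate_percent(
            self.true_snp + self.true_indel,
            self.true_snp + self.true_indel + self.false_snp + self.false_indel,
        )

    @property
    def rate_snp(self) -> float | None:
        return rate_percent(self.true_snp, self.true_snp + self.false_snp)

    @property
    def rate_indel(self) -> float | None:
        return rate_percent(self.true_indel, self.true_indel + self.false_indel)


def strain_concordance(
    rnaseq_calls: Mapping[str, str],
    amplicon_calls: Mapping[str, str],
    panel: Sequence[MarkerPanelEntry],
    strain_id: str = "",
) -> ConcordanceRow:
    """Compare one strain's genotypes across platforms over a gated marker panel.

    Both call sets are keyed by marker_id.  A marker missing a call on either
    platform is "not detected"; otherwise normalized genotype equality decides
    true vs false, stratified by the panel's SNP/indel class.  Calls for
    markers outside the panel are skipped with a warning.
    """
    panel_ids = {m.marker_id: m for m in panel}
    for source, calls in (("rnaseq", rnaseq_calls), ("amplicon", amplicon_calls)):
        stray = set(calls) - set(panel_ids)
        if stray:
            warnings.warn(
                f"{source} calls for {len(stray)} markers outside the panel "
                f"were skipped (strain {strain_id or '?'})",
                stacklevel=2,
            )
    counts = {"true_snp": 0, "true_indel": 0, "false_snp": 0, "false_indel": 0}
    not_detected = 0
    for mid, entry in panel_ids.items():
        rn = rnaseq_calls.get(mid)
        am = amplicon_calls.get(mid)
        if rn is None or am is None:
            not_detected += 1
            continue
        match = normalize_genotype(rn) == normalize_genotype(am)
        kind = "snp" if entry.vtype == "SNP" else "indel"
        counts[("true_" if match else "false_") + kind] += 1
    return ConcordanceRow(strain_id=strain_id, not_detected=not_detected, **counts)


@dataclass(frozen=True)
class ConcordanceSummary:
    """Panel-level aggregation of per-strain concordance rows."""

    n_strains: int
    mean_rate_snp: float | None
    mean_rate_indel: float | None
    min_rate_total: float | None
    max_rate_total: float | None
    n_at_least_threshold: int
    threshold: float
    pooled_rate_snp: float | None = None
    pooled_rate_indel: float | None = None


def summarize(
    rows: Sequence[ConcordanceRow], threshold: float = 90.0
) -> ConcordanceSummary:
    """Mean-of-per-strain SNP/indel rates, total-rate range, and threshold count.

    The threshold comparison is ``>=``.  Pooled-count rates (sum of trues over
    sum of trues+falses across strains) are reported alongside as an
    alternative aggregation.
    """
    if not rows:
        raise ValueError("summarize requires at least one row")
    snp_rates = [r.rate_snp for r in rows if r.rate_snp is not None]
    indel_rates = [r.rate_indel for r in rows if r.rate_indel is not None]
    totals = [r.rate_total for r in rows if r.rate_total is not None]
    pooled_ts = sum(r.true_snp for r in rows)
    pooled_fs = sum(r.false_snp for r in rows)
    pooled_ti = sum(r.true_indel for r in rows)
    pooled_fi = sum(r.false_indel for r in rows)
    return ConcordanceSummary(
        n_strains=len(rows),
        mean_rate_snp=sum(snp_rates) / len(snp_rates) if snp_rates else None,
        mean_rate_indel=sum(indel_rates) / len(indel_rates) if indel_rates else None,
        min_rate_total=min(totals) if totals else None,
        max_rate_total=max(totals) if totals else None,
        n_at_least_threshold=sum(1 for t in totals if t >= threshold),
        threshold=threshold,
        pooled_rate_snp=rate_percent(pooled_ts, pooled_ts + pooled_fs),
        pooled_rate_indel=rate_percent(pooled_ti, pooled_ti + pooled_fi),
    )


@dataclass(frozen=True)
class MarkerSummary:
    """Per-marker aggregation of cross-platform matches."""

    n_markers: int
    n_missing_data: int
    n_complete_match: int
    n_lt5_mismatch: int

    @property
    def pct_complete_of_all(self) -> float | None:
        return rate_percent(self.n_complete_match, self.n_markers, 1)

    @property
    def pct_complete_of_complete_data(self) -> float | None:
        return rate_percent(
            self.n_complete_match, self.n_markers - self.n_missing_data, 1
        )


def marker_summary(
    call_table: Mapping[str, Sequence[tuple[str | None, str | None]]],
) -> MarkerSummary:
    """Aggregate accuracy per marker over all strains.

    ``call_table`` maps marker_id -> per-strain (rnaseq_call, amplicon_call)
    pairs, with None for an absent call.  A marker has missing data when any
    strain lacks a call on either platform; over strains with both calls it
    matches completely at zero mismatches, and is a "<5 mismatches" marker
    at one to four.
    """
    n_missing = n_complete = n_lt5 = 0
    for pairs in call_table.values():
        if any(rn is None or am is None for rn, am in pairs):
            n_missing += 1
        mismatches = sum(
            1
            for rn, am in pairs
            if rn is not None
            and am is not None
            and normalize_genotype(rn) != normalize_genotype(am)
        )
        if mismatches == 0:
            n_complete += 1
        elif mismatches < 5:
            n_lt5 += 1
    return MarkerSummary(
        n_markers=len(call_table),
        n_missing_data=n_missing,
        n_complete_match=n_complete,
        n_lt5_mismatch=n_lt5,
    )


def load_table2() -> pd.DataFrame:
    """Packaged 38-strain platform-comparison table (printed rates and counts)."""
    with resources.files("transgeno.data").joinpath("table2_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def rows_from_counts(df: pd.DataFrame) -> list[ConcordanceRow]:
    """Build ConcordanceRows from a count table like the packaged one."""
    return [
        ConcordanceRow(
            strain_id=str(r.strain),
            true_snp=int(r.true_snp),
            true_indel=int(r.true_indel),
            false_snp=int(r.false_snp),
            false_indel=int(r.false_indel),
            not_detected=int(r.not_detected),
        )
        for r in df.itertuples()
    ]
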