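"""End-to-end run orchestration and report rendering.

``run_pipeline`` chains the downstream stages — transcribed-region
construction, the VCF filter cascade, genotype-matrix analytics and
(optionally) cross-platform concordance — over a config-named input bundle,
writes every stage's artifacts, and collates a deterministic JSON + text run
report with a checksummed file manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .concordance import (
    ConcordanceRow,
    ConcordanceSummary,
    MarkerPanelEntry,
    depth_gate,
    strain_concordance,
    summarize,
)
from .filtering import FilterConfig, FilterReport, run_cascade, read_metadata, write_filtered_vcf
from .matrix import pairwise_tables, scan_gaps
from .regions import (
    RegionStats,
    build_transcribed_regions,
    read_chrom_sizes,
    read_gene_models,
    region_stats,
    write_regions_bed,
    write_regions_fasta,
)

logger = logging.getLogger("transgeno")

__all__ = ["RunReport", "ConfigError", "DataError", "run_pipeline", "render_tables",
           "render_table1", "render_table2"]


class ConfigError(ValueError):
    """Bad or incomplete run configuration (exit code 2 at the CLI)."""


class DataError(ValueError):
    """Well-configured run that failed on its data (exit code 3 at the CLI)."""


@dataclass
class RunReport:
    version: str
    config: dict[str, Any]
    region_stats: RegionStats | None = None
    filter_report: FilterReport | None = None
    concordance_rows: list[ConcordanceRow] = field(default_factory=list)
    concordance_summary: ConcordanceSummary | None = None
    n_gaps: int | None = None
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256
    errors: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "version": self.version,
            "config": self.config,
            "files": dict(sorted(self.files.items())),
            "errors": list(self.errors),
        }
        if self.region_stats is not None:
            out["region_stats"] = {
                "n_regions": self.region_stats.n_regions,
                "total_bp": self.region_stats.total_bp,
                "ratio_vs_reference": round(self.region_stats.ratio_vs_reference, 4),
            }
        if self.filter_report is not None:
            out["filter_report"] = self.filter_report.to_dict()
        if self.n_gaps is not None:
            out["n_gaps"] = self.n_gaps
        if self.concordance_summary is not None:
            s = self.concordance_summary
            out["concordance_summary"] = {
                "n_strains": s.n_strains,
                "mean_rate_snp": s.mean_rate_snp,
                "mean_rate_indel": s.mean_rate_indel,
                "min_rate_total": s.min_rate_total,
                "max_rate_total": s.max_rate_total,
                "n_at_least_threshold": s.n_at_least_threshold,
                "threshold": s.threshold,
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _register(report: RunReport, path: Path) -> None:
    if not path.exists():
        raise DataError(f"expected output file missing: {path}")
    report.files[path.name] = _sha256(path)


def run_pipeline(config: str | Path | dict[str, Any], out_dir: str | Path | None = None) -> RunReport:
    """Execute regions -> filter -> matrix (-> concordance) from a config.

    ``config`` is a YAML path or a dict with keys: ``gff``, ``chrom_sizes``,
    ``vcf``, ``metadata``; optional ``genome_fasta``, ``flank_bp``,
    ``ref_total_bp``, ``min_reads``, ``neighbor_window``, ``min_gap``,
    ``amplicon`` (sub-keys ``panel``, ``calls``, ``min_depth``, ``threshold``)
    and ``out_dir``.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)

    for key in ("gff", "chrom_sizes", "vcf", "metadata"):
        if key not in config:
            raise ConfigError(f"config key {key!r} is required")
        if not Path(config[key]).exists():
            raise ConfigError(f"input file for {key!r} not found: {config[key]}")

    echo = {k: (str(v) if isinstance(v, Path) else v) for k, v in config.items()}
    report = RunReport(version=__version__, config=echo)

    # Stage 1: transcribed regions.
    loci = read_gene_models(config["gff"])
    sizes = read_chrom_sizes(config["chrom_sizes"])
    flank = int(config.get("flank_bp", 3000))
    regions = build_transcribed_regions(loci, flank, sizes)
    ref_total = int(config.get("ref_total_bp", 0)) or sum(
        l.interval.length for l in loci if l.source == "HC"
    ) or sum(l.interval.length for l in loci)
    report.region_stats = region_stats(regions, ref_total)
    bed = out / "regions.bed"
    write_regions_bed(regions, bed)
    _register(report, bed)
    if config.get("genome_fasta"):
        fasta = out / "regions.fa"
        write_regions_fasta(regions, config["genome_fasta"], fasta)
        _register(report, fasta)
    logger.info(
        "regions: %d loci -> %d regions, %d bp",
        len(loci), report.region_stats.n_regions, report.region_stats.total_bp,
    )

    # Stage 2: filter cascade.
    fc = FilterConfig(
        min_reads=int(config.get("min_reads", 2)),
        neighbor_window=int(config.get("neighbor_window", 60)),
    )
    metadata = read_metadata(config["metadata"])
    try:
        result = run_cascade(config["vcf"], metadata, fc)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    fr = result.report
    report.filter_report = fr
    filtered_vcf = out / "filtered.vcf"
    write_filtered_vcf(config["vcf"], filtered_vcf, result, fc)
    _register(report, filtered_vcf)
    matrix_tsv = out / "genotype_matrix.tsv"
    result.matrix.to_tsv(matrix_tsv)
    _register(report, matrix_tsv)
    report_json = out / "filter_report.json"
    fr.to_json(report_json)
    _register(report, report_json)
    logger.info(
        "filter: %d detected -> %d reliable -> %d final (SNP %d, indel %d)",
        fr.n_detected, fr.n_reliable, fr.n_final, fr.n_final_snp, fr.n_final_indel,
    )

    # Stage 3: matrix analytics.
    snp_tab, indel_tab = pairwise_tables(result.matrix)
    pw_snp = out / "pairwise_snp.tsv"
    pw_indel = out / "pairwise_indel.tsv"
    snp_tab.to_csv(pw_snp, sep="\t")
    indel_tab.to_csv(pw_indel, sep="\t")
    _register(report, pw_snp)
    _register(report, pw_indel)
    gaps = scan_gaps(result.matrix.positions_by_chrom(), int(config.get("min_gap", 1_000_000)))
    gaps_tsv = out / "gaps.tsv"
    pd.DataFrame(
        [(g.chrom, g.left_pos, g.right_pos, g.length) for g in gaps],
        columns=["chrom", "left_pos", "right_pos", "length"],
    ).to_csv(gaps_tsv, sep="\t", index=False)
    _register(report, gaps_tsv)
    report.n_gaps = len(gaps)
    logger.info("matrix: %d final sites, %d gap regions", result.matrix.n_sites, len(gaps))

    # Stage 4 (optional): cross-platform concordance.
    amp = config.get("amplicon")
    if amp:
        panel_df = pd.read_csv(amp["panel"], sep="\t")
        panel = [
            MarkerPanelEntry(str(r.marker_id), str(r.chrom), int(r.pos),
                             str(r.vtype), float(r.mean_depth))
            for r in panel_df.itertuples()
        ]
        gated = depth_gate(panel, float(amp.get("min_depth", 100)))
        gated_ids = {m.marker_id for m in gated}
        calls_df = pd.read_csv(amp["calls"], sep="\t", dtype={"genotype": str})
        calls_df = calls_df[calls_df["marker_id"].isin(gated_ids)]
        pos_to_marker = {(m.chrom, m.pos): m.marker_id for m in gated}
        rn_by_strain: dict[str, dict[str, str]] = {s: {} for s in result.matrix.strains}
        for i, site in enumerate(result.matrix.sites):
            mid = pos_to_marker.get((site.chrom, site.pos))
            if mid is None:
                continue
            for s in result.matrix.strains:
                gt = result.matrix.calls.iloc[i][s]
                if gt != ".":
                    rn_by_strain[s][mid] = gt
        rows = []
        for strain, grp in calls_df.groupby("strain_id"):
            am_calls = dict(zip(grp["marker_id"], grp["genotype"]))
            rows.append(
                strain_concordance(rn_by_strain.get(str(strain), {}), am_calls, gated, str(strain))
            )
        rows.sort(key=lambda r: (-(r.rate_total or -1.0), r.strain_id))
        report.concordance_rows = rows
        report.concordance_summary = summarize(rows, float(amp.get("threshold", 90.0)))
        logger.info(
            "concordance: %d strains, %d markers after depth gate",
            len(rows), len(gated),
        )

    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(render_tables(report))
    return report


def _fmt(n: int | None) -> str:
    return "" if n is None else f"{n:,}"


def render_table1(fr: FilterReport) -> str:
    """Site-accounting table: Type / Total / No. of SNPs / No. of indels."""
    lines = ["Type\tTotal\tNo. of SNPs\tNo. of indels"]
    lines.append(f"Detected polymorphisms\t{_fmt(fr.n_detected)}\t\t")
    lines.append(
        f"Reliable polymorphisms\t{_fmt(fr.n_reliable)}\t"
        f"{_fmt(fr.n_reliable_snp)}\t{_fmt(fr.n_reliable_indel)}"
    )
    lines.append(
        f"Polymorphisms after processing\t{_fmt(fr.n_final)}\t"
        f"{_fmt(fr.n_final_snp)}\t{_fmt(fr.n_final_indel)}"
    )
    return "\n".join(lines) + "\n"


def _fmt_rate(r: float | None) -> str:
    return "NA" if r is None else f"{r:.3f}"


def render_table2(rows: list[ConcordanceRow]) -> str:
    """Per-strain platform-comparison table: three rates then five counts."""
    lines = [
        "strain\trate_total\trate_snp\trate_indel\ttrue_snp\ttrue_indel\t"
        "false_snp\tfalse_indel\tnot_detected"
    ]
    for r in rows:
        lines.append(
            f"{r.strain_id}\t{_fmt_rate(r.rate_total)}\t{_fmt_rate(r.rate_snp)}\t"
            f"{_fmt_rate(r.rate_indel)}\t{r.true_snp}\t{r.true_indel}\t"
            f"{r.false_snp}\t{r.false_indel}\t{r.not_detected}"
        )
    return "\n".join(lines) + "\n"


def render_tables(report: RunReport) -> str:
    """Human-readable run summary with the two accounting tables."""
    parts = [f"transgeno {report.version} run report", ""]
    if report.region_stats is not None:
        rs = report.region_stats
        parts += [
            f"Transcribed regions: {rs.n_regions:,} regions, {rs.total_bp:,} bp "
            f"({rs.render_ratio()}x the reference locus set)",
            "",
        ]
    if report.filter_report is not None:
        parts += [render_table1(report.filter_report)]
    if report.n_gaps is not None:
        parts += [f"Polymorphism-free regions over threshold: {report.n_gaps:,}", ""]
    if report.concordance_rows:
        parts += [render_table2(report.concordance_rows)]
    if report.concordance_summary is not None:
        s = report.concordance_summary
        parts += [
            f"Concordance over {s.n_strains} strains: "
            f"mean SNP rate {s.mean_rate_snp:.1f}%, mean indel rate {s.mean_rate_indel:.1f}%, "
            f"total rate range {s.min_rate_total:.1f}-{s.max_rate_total:.1f}%, "
            f"{s.n_at_least_threshold} strains >= {s.threshold:g}%",
            "",
        ]
    if report.errors:
        parts += ["Errors:"] + [f"  - {e}" for e in report.errors] + [""]
    return "\n".join(parts)
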