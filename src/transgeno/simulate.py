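"""Deterministic synthetic data with a planted-truth manifest.

Generates a toy genome, gene annotation, merged multi-sample VCF, replicate
libraries and amplicon call tables that mimic the statistical structure of an
RNA-Seq genotyping study of inbred crop strains: mostly homozygous calls,
overdispersed per-call read depths (expression-dependent coverage), missing
genotypes at lowly expressed loci, replicate libraries that occasionally
disagree, and a high-depth amplicon platform with its own error and dropout
rates.

Planted variants fall into four mutually exclusive categories that exercise
each rule of the filter cascade:

* ``clean``        — polymorphic in >=2 strains, well supported, isolated;
                     these are the markers the cascade should keep;
* ``singleton``    — the non-reference allele appears in exactly one strain;
* ``close_pair``   — two clean-like sites planted within the neighbor window
                     of each other, so both must fall to the neighbor filter;
* ``multiallelic`` — two alternate alleles, excluded from the panel.

All randomness flows from ``SimConfig.seed``; the same seed yields
byte-identical output files.  The truth manifest (:class:`SimTruth`) is the
oracle for parameter-recovery tests downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "PlantedVariant", "SimTruth", "SimBundle", "simulate_genome",
           "simulate_annotation", "simulate_strain_vcf", "simulate_amplicon",
           "simulate_all"]

_BASES = np.array(list("ACGT"))

CLEAN = "clean"
SINGLETON = "singleton"
CLOSE_PAIR = "close_pair"
MULTIALLELIC = "multiallelic"


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the generator; defaults are a desk-scale analogue of a
    ~100-strain inbred RNA-Seq genotyping study."""

    seed: int = 1
    n_chrom: int = 2
    chrom_len: int = 400_000
    n_loci: int = 60
    locus_len: int = 4_000
    hc_fraction: float = 0.7
    n_strains: int = 12
    n_replicate_strains: int = 4
    n_clean_markers: int = 40
    n_singletons: int = 10
    n_close_pairs: int = 6
    n_multiallelic: int = 4
    close_pair_spacing: int = 40
    site_spacing: int = 200
    indel_fraction: float = 0.2
    het_rate: float = 0.02
    missing_rate: float = 0.08
    depth_mean: float = 20.0
    depth_shape: float = 4.0
    replicate_discordance_rate: float = 0.09
    amplicon_error_rate: float = 0.07
    amplicon_missing_rate: float = 0.30
    amplicon_low_depth_fraction: float = 11 / 384
    amplicon_depth_mean: float = 1_000.0

    def __post_init__(self) -> None:
        for name in ("hc_fraction", "indel_fraction", "het_rate", "missing_rate",
                     "replicate_discordance_rate", "amplicon_error_rate",
                     "amplicon_missing_rate", "amplicon_low_depth_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_chrom", "chrom_len", "n_loci", "locus_len", "n_strains"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_replicate_strains > self.n_strains:
            raise ValueError("n_replicate_strains cannot exceed n_strains")
        if self.site_spacing <= 2 * self.close_pair_spacing:
            raise ValueError("site_spacing must exceed twice close_pair_spacing")

    def noise_free(self) -> "SimConfig":
        """Same layout with every stochastic corruption switched off."""
        return replace(
            self,
            het_rate=0.0,
            missing_rate=0.0,
            replicate_discordance_rate=0.0,
            amplicon_error_rate=0.0,
            amplicon_missing_rate=0.0,
        )

    @property
    def n_planted(self) -> int:
        return (self.n_clean_markers + self.n_singletons
                + 2 * self.n_close_pairs + self.n_multiallelic)


@dataclass
class PlantedVariant:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alts: tuple[str, ...]
    category: str
    vtype: str
    true_gt: dict[str, str]  # strain -> allele-string genotype

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}"


@dataclass
class SimTruth:
    """Planted ground truth: the oracle every downstream test checks against."""

    config: SimConfig
    variants: list[PlantedVariant]
    strains: list[str]
    libraries: dict[str, list[str]]  # strain -> library ids (primary first)
    library_calls: dict[str, dict[str, str]]  # library -> {chrom:pos -> gt}
    amplicon_truth: dict[str, dict[str, str]] = field(default_factory=dict)
    amplicon_observed: dict[str, dict[str, str]] = field(default_factory=dict)
    marker_ids: dict[str, str] = field(default_factory=dict)  # marker_id -> chrom:pos

    def by_category(self, category: str) -> list[PlantedVariant]:
        return [v for v in self.variants if v.category == category]

    @property
    def clean_keys(self) -> set[tuple[str, int]]:
        return {(v.chrom, v.pos) for v in self.variants if v.category == CLEAN}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "variants": [
                {**asdict(v), "alts": list(v.alts)} for v in self.variants
            ],
            "strains": self.strains,
            "libraries": self.libraries,
            "library_calls": self.library_calls,
            "amplicon_truth": self.amplicon_truth,
            "amplicon_observed": self.amplicon_observed,
            "marker_ids": self.marker_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            config=SimConfig(**payload["config"]),
            variants=[
                PlantedVariant(**{**v, "alts": tuple(v["alts"])})
                for v in payload["variants"]
            ],
            strains=payload["strains"],
            libraries=payload["libraries"],
            library_calls=payload["library_calls"],
            amplicon_truth=payload["amplicon_truth"],
            amplicon_observed=payload["amplicon_observed"],
            marker_ids=payload["marker_ids"],
        )


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _chrom_names(cfg: SimConfig) -> list[str]:
    return [f"chr{i + 1}H" for i in range(cfg.n_chrom)]


def simulate_genome(cfg: SimConfig) -> dict[str, str]:
    """Uniform-base random chromosomes; same seed, same bytes."""
    rng = _rng(cfg, 0)
    return {
        name: "".join(_BASES[rng.integers(0, 4, size=cfg.chrom_len)])
        for name in _chrom_names(cfg)
    }


@dataclass(frozen=True)
class _Locus:
    locus_id: str
    chrom: str
    start0: int  # 0-based inclusive
    end0: int  # 0-based exclusive
    strand: str
    source: str


def simulate_annotation(cfg: SimConfig, genome: dict[str, str]) -> list[_Locus]:
    """Evenly spaced, pairwise disjoint gene loci with HC/novel source tags."""
    rng = _rng(cfg, 1)
    chroms = _chrom_names(cfg)
    per_chrom = [cfg.n_loci // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_loci % cfg.n_chrom):
        per_chrom[i] += 1
    loci: list[_Locus] = []
    idx = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        gap = (cfg.chrom_len - n * cfg.locus_len) // (n + 1)
        if gap < 1:
            raise ValueError(
                f"cannot fit {n} loci of {cfg.locus_len} bp on a "
                f"{cfg.chrom_len} bp chromosome"
            )
        for k in range(n):
            start = gap + k * (cfg.locus_len + gap)
            loci.append(
                _Locus(
                    locus_id=f"LOC{idx:05d}",
                    chrom=chrom,
                    start0=start,
                    end0=start + cfg.locus_len,
                    strand="+" if rng.random() < 0.5 else "-",
                    source="HC" if rng.random() < cfg.hc_fraction else "novel",
                )
            )
            idx += 1
    return loci


def annotation_to_gff3(loci: list[_Locus]) -> str:
    lines = ["##gff-version 3"]
    for l in loci:
        lines.append(
            f"{l.chrom}\t{l.source}\tgene\t{l.start0 + 1}\t{l.end0}\t.\t"
            f"{l.strand}\t.\tID={l.locus_id}"
        )
    return "\n".join(lines) + "\n"


def _candidate_slots(cfg: SimConfig, loci: list[_Locus]) -> list[tuple[str, int]]:
    """1-based positions on a spacing grid inside loci, margin 100 bp from edges."""
    margin = 100
    slots = []
    for l in loci:
        p = l.start0 + margin
        while p + cfg.close_pair_spacing + 5 < l.end0 - margin:
            slots.append((l.chrom, p + 1))
            p += cfg.site_spacing
    return slots


def _draw_alt(rng: np.random.Generator, ref_base: str, exclude: set[str] = frozenset()) -> str:
    options = [b for b in "ACGT" if b != ref_base and b not in exclude]
    return options[rng.integers(0, len(options))]


def _gt_string(alleles: tuple[str, ...], gt: tuple[int, int]) -> str:
    return "/".join(alleles[i] for i in sorted(gt))


def simulate_strain_vcf(
    cfg: SimConfig, loci: list[_Locus], genome: dict[str, str]
) -> tuple[str, pd.DataFrame, SimTruth]:
    """Plant variants, realize per-library calls, and render the merged VCF.

    Returns (vcf_text, metadata_dataframe, truth).  Strains are inbred:
    true genotypes are homozygous; heterozygous calls only ever arise as
    library-level noise (``het_rate``).
    """
    rng = _rng(cfg, 2)
    slots = _candidate_slots(cfg, loci)
    n_base_sites = (cfg.n_clean_markers + cfg.n_singletons
                    + cfg.n_close_pairs + cfg.n_multiallelic)
    if n_base_sites > len(slots):
        raise ValueError(
            f"planted counts need {n_base_sites} slots but the annotation "
            f"offers only {len(slots)}"
        )
    chosen = [slots[i] for i in rng.choice(len(slots), size=n_base_sites, replace=False)]
    categories = ([CLEAN] * cfg.n_clean_markers + [SINGLETON] * cfg.n_singletons
                  + [CLOSE_PAIR] * cfg.n_close_pairs + [MULTIALLELIC] * cfg.n_multiallelic)

    strains = [f"ST{i:03d}" for i in range(cfg.n_strains)]
    two_row = {s: ("two_row" if i % 2 == 0 else "six_row") for i, s in enumerate(strains)}
    replicate_strains = strains[: cfg.n_replicate_strains]

    variants: list[PlantedVariant] = []
    for (chrom, pos), category in zip(chosen, categories):
        positions = [pos]
        if category == CLOSE_PAIR:
            positions.append(pos + cfg.close_pair_spacing)
        for p in positions:
            ref_base = genome[chrom][p - 1]
            if category == MULTIALLELIC:
                a1 = _draw_alt(rng, ref_base)
                a2 = _draw_alt(rng, ref_base, exclude={a1})
                ref, alts = ref_base, (a1, a2)
                vtype = "MULTI"
            elif rng.random() < cfg.indel_fraction:
                if rng.random() < 0.5:  # insertion
                    ins = "".join(_BASES[rng.integers(0, 4, size=rng.integers(1, 4))])
                    ref, alts = ref_base, (ref_base + ins,)
                else:  # deletion of 1-3 bp
                    k = int(rng.integers(1, 4))
                    ref = genome[chrom][p - 1 : p + k]
                    alts = (ref_base,)
                vtype = "INDEL"
            else:
                ref, alts = ref_base, (_draw_alt(rng, ref_base),)
                vtype = "SNP"

            alleles = (ref,) + alts
            if category == SINGLETON:
                carriers = {strains[rng.integers(0, cfg.n_strains)]: 1}
            elif category == MULTIALLELIC:
                k = int(rng.integers(2, max(3, cfg.n_strains // 2) + 1))
                picked = rng.choice(cfg.n_strains, size=k, replace=False)
                carriers = {}
                for j, si in enumerate(picked):
                    # guarantee each alt has at least one carrier
                    carriers[strains[si]] = (j % 2) + 1 if j < 2 else int(rng.integers(1, 3))
            else:  # clean or close_pair member
                k = int(rng.integers(2, max(3, cfg.n_strains // 2) + 1))
                picked = rng.choice(cfg.n_strains, size=k, replace=False)
                carriers = {strains[si]: 1 for si in picked}
            true_gt = {
                s: _gt_string(alleles, (carriers.get(s, 0), carriers.get(s, 0)))
                for s in strains
            }
            variants.append(
                PlantedVariant(chrom, p, ref, alts, category, vtype, true_gt)
            )
    variants.sort(key=lambda v: (v.chrom, v.pos))

    libraries = {
        s: ([f"{s}_sr"] + ([f"{s}_sp"] if s in replicate_strains else []))
        for s in strains
    }
    lib_order = [lib for s in strains for lib in libraries[s]]

    # Realize calls.  Protected carriers keep clean/close-pair/singleton sites
    # detectable regardless of noise: their primary call is never masked.
    def depth_draw(floor: int = 1) -> int:
        p = cfg.depth_shape / (cfg.depth_shape + cfg.depth_mean)
        return max(floor, int(rng.negative_binomial(cfg.depth_shape, p)))

    vcf_rows: list[str] = []
    library_calls: dict[str, dict[str, str]] = {lib: {} for lib in lib_order}
    lib_gt_idx: dict[str, dict[str, tuple[int, int] | None]] = {
        lib: {} for lib in lib_order
    }
    lib_dp: dict[str, dict[str, int]] = {lib: {} for lib in lib_order}

    for v in variants:
        alleles = (v.ref,) + v.alts
        carriers_sorted = sorted(
            s for s in strains if v.true_gt[s] != _gt_string(alleles, (0, 0))
        )
        protected = set(carriers_sorted[:2]) if v.category != SINGLETON else set(
            carriers_sorted[:1]
        )
        for s in strains:
            truth_idx = next(
                i for i, a in enumerate(alleles)
                if _gt_string(alleles, (i, i)) == v.true_gt[s]
            )
            primary = libraries[s][0]
            gt: tuple[int, int] | None = (truth_idx, truth_idx)
            if s not in protected:
                if rng.random() < cfg.het_rate and len(v.alts) == 1:
                    gt = (0, 1)
                if rng.random() < cfg.missing_rate:
                    gt = None
            dp = depth_draw(floor=2 if s in protected else 1)
            lib_gt_idx[primary][v.key] = gt
            lib_dp[primary][v.key] = dp
            if gt is not None:
                library_calls[primary][v.key] = _gt_string(alleles, gt)
            if len(libraries[s]) > 1:
                rep = libraries[s][1]
                rep_gt = gt
                if rep_gt is not None:
                    if rng.random() < cfg.missing_rate:
                        rep_gt = None
                    elif rng.random() < cfg.replicate_discordance_rate:
                        # flip to the "other" homozygote
                        flipped = 0 if any(i > 0 for i in rep_gt) else 1
                        rep_gt = (flipped, flipped)
                lib_gt_idx[rep][v.key] = rep_gt
                lib_dp[rep][v.key] = depth_draw()
                if rep_gt is not None:
                    library_calls[rep][v.key] = _gt_string(alleles, rep_gt)

        fields = []
        for lib in lib_order:
            gt = lib_gt_idx[lib].get(v.key)
            if gt is None:
                fields.append("./.:.")
            else:
                fields.append(f"{gt[0]}/{gt[1]}:{lib_dp[lib][v.key]}")
        vcf_rows.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\t.\tPASS\t.\t"
            "GT:DP\t" + "\t".join(fields)
        )

    header = ["##fileformat=VCFv4.2"]
    for chrom in _chrom_names(cfg):
        header.append(f"##contig=<ID={chrom},length={cfg.chrom_len}>")
    header.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(lib_order)
    )
    vcf_text = "\n".join(header + vcf_rows) + "\n"

    meta = pd.DataFrame(
        [
            {
                "strain_id": s,
                "library_id": lib,
                "tissue": "shoot_root" if lib.endswith("_sr") else "spike",
                "row_type": two_row[s],
            }
            for s in strains
            for lib in libraries[s]
        ]
    )
    truth = SimTruth(
        config=cfg,
        variants=variants,
        strains=strains,
        libraries=libraries,
        library_calls=library_calls,
    )
    return vcf_text, meta, truth


def simulate_amplicon(
    cfg: SimConfig, truth: SimTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Amplicon panel over the planted clean markers, plus observed calls.

    Mean depths are drawn lognormally around ``amplicon_depth_mean`` with a
    fixed fraction of markers forced below the 100x gate.  Observed genotypes
    flip to the other homozygote with ``amplicon_error_rate`` and drop out
    with ``amplicon_missing_rate``.  Updates ``truth`` in place with the
    marker-id map and the amplicon truth/observations.
    """
    rng = _rng(cfg, 3)
    clean = truth.by_category(CLEAN)
    n = len(clean)
    depths = np.maximum(
        100.0,
        rng.lognormal(mean=math.log(cfg.amplicon_depth_mean), sigma=0.8, size=n),
    )
    n_low = int(round(cfg.amplicon_low_depth_fraction * n))
    if n_low:
        low_idx = rng.choice(n, size=n_low, replace=False)
        depths[low_idx] = rng.uniform(20.0, 99.0, size=n_low)

    panel_rows = []
    call_rows = []
    truth.marker_ids = {}
    truth.amplicon_truth = {}
    truth.amplicon_observed = {}
    for i, v in enumerate(clean):
        mid = f"M{i:04d}"
        truth.marker_ids[mid] = v.key
        panel_rows.append(
            {
                "marker_id": mid,
                "chrom": v.chrom,
                "pos": v.pos,
                "vtype": v.vtype,
                "mean_depth": round(float(depths[i]), 1),
            }
        )
        alleles = (v.ref,) + v.alts
        truth.amplicon_truth[mid] = dict(v.true_gt)
        observed: dict[str, str] = {}
        for s in truth.strains:
            if rng.random() < cfg.amplicon_missing_rate:
                continue
            gt = v.true_gt[s]
            if rng.random() < cfg.amplicon_error_rate:
                hom_ref = _gt_string(alleles, (0, 0))
                gt = _gt_string(alleles, (1, 1)) if gt == hom_ref else hom_ref
            observed[s] = gt
            call_rows.append(
                {
                    "marker_id": mid,
                    "strain_id": s,
                    "genotype": gt,
                    "depth": int(round(depths[i])),
                }
            )
        truth.amplicon_observed[mid] = observed
    panel = pd.DataFrame(panel_rows)
    calls = pd.DataFrame(call_rows, columns=["marker_id", "strain_id", "genotype", "depth"])
    return panel, calls


@dataclass
class SimBundle:
    """File paths of one generated fixture set."""

    out_dir: Path
    genome_fasta: Path
    chrom_sizes: Path
    gff3: Path
    vcf: Path
    metadata: Path
    panel: Path
    amplicon_calls: Path
    truth_json: Path
    truth: SimTruth


def simulate_all(cfg: SimConfig, out_dir: str | Path) -> SimBundle:
    """Generate and write the complete fixture bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(cfg)
    loci = simulate_annotation(cfg, genome)
    vcf_text, meta, truth = simulate_strain_vcf(cfg, loci, genome)
    panel, calls = simulate_amplicon(cfg, truth)

    genome_fasta = out / "genome.fa"
    with open(genome_fasta, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    chrom_sizes = out / "chrom.sizes"
    chrom_sizes.write_text(
        "".join(f"{name}\t{cfg.chrom_len}\n" for name in _chrom_names(cfg))
    )
    gff3 = out / "annotation.gff3"
    gff3.write_text(annotation_to_gff3(loci))
    vcf = out / "calls.vcf"
    vcf.write_text(vcf_text)
    metadata = out / "metadata.tsv"
    meta.to_csv(metadata, sep="\t", index=False)
    panel_path = out / "amplicon_panel.tsv"
    panel.to_csv(panel_path, sep="\t", index=False)
    calls_path = out / "amplicon_calls.tsv"
    calls.to_csv(calls_path, sep="\t", index=False)
    truth_json = out / "truth.json"
    truth.to_json(truth_json)
    return SimBundle(
        out_dir=out,
        genome_fasta=genome_fasta,
        chrom_sizes=chrom_sizes,
        gff3=gff3,
        vcf=vcf,
        metadata=metadata,
        panel=panel_path,
        amplicon_calls=calls_path,
        truth_json=truth_json,
        truth=truth,
    )
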