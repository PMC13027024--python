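"""Seed-deterministic fixture generators for every pipeline stage.

Generators emit machine-readable truth alongside the data so tests can
compare pipeline output against construction-time ground truth:

* per-site binomial edit counts at configured rates and depths,
* miniature reference + aligned reads (BAM) realizing chosen allele counts,
* expression matrices with features planted to depend monotonically on a
  per-sample editing score,
* VCFs planting germline A/G (T/C) polymorphisms at panel sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .counts import EditCounts, SampleSiteCounts
from .instability import HYPERMUTATOR_GENES, MMR_GENES, SIGNATURE_FEATURES
from .panel import EditingSite, Panel

__all__ = [
    "SimulationConfig",
    "AlignmentBundle",
    "simulate_site_counts",
    "simulate_alignments",
    "simulate_expression",
    "simulate_germline_vcf",
]

_READ_LEN = 100
_SITE_SPACING = 400
_FIRST_SITE_POS = 201  # 1-based toy coordinate of the first site on a contig


@dataclass
class SimulationConfig:
    """Knobs for all generators; a fixed seed makes outputs byte-identical."""

    seed: int = 0
    n_samples: int = 10
    editing_rate: float = 0.1          # scalar or overridden per site
    site_rates: dict[str, float] | None = None
    depth_mean: float = 50.0
    depth_dispersion: float | None = 10.0  # NB size parameter; None = fixed depth
    n_genes: int = 200
    n_planted_positive: int = 10
    n_planted_negative: int = 10
    effect_size: float = 1.0
    noise_sd: float = 0.3
    germline_fraction: float = 0.0
    n_low_mapq_reads: int = 0          # extra sub-threshold reads per site

    def __post_init__(self) -> None:
        rates = list((self.site_rates or {}).values()) + [self.editing_rate]
        if any(not (0.0 <= r <= 1.0) for r in rates):
            raise ValueError("editing rates must lie in [0, 1]")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be non-negative")

    def rate_for(self, site_id: str) -> float:
        if self.site_rates and site_id in self.site_rates:
            return self.site_rates[site_id]
        return self.editing_rate


def _draw_depths(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.depth_dispersion is None:
        return np.full(n, int(round(config.depth_mean)), dtype=int)
    k = config.depth_dispersion
    p = k / (k + config.depth_mean)
    return rng.negative_binomial(k, p, size=n)


def simulate_site_counts(
    config: SimulationConfig, panel: Panel
) -> tuple[list[SampleSiteCounts], pd.DataFrame]:
    """Binomial edit counts per site per sample, plus a truth table.

    Truth columns: sample_id, site_id, true_rate, depth, edit_count.
    """
    rng = np.random.default_rng(config.seed)
    samples: list[SampleSiteCounts] = []
    truth_rows = []
    for i in range(config.n_samples):
        sample_id = f"sample{i:03d}"
        depths = _draw_depths(config, len(panel), rng)
        counts: dict[str, EditCounts] = {}
        for site, depth in zip(panel, depths):
            rate = config.rate_for(site.site_id)
            edit = int(rng.binomial(depth, rate)) if depth > 0 else 0
            counts[site.site_id] = EditCounts(
                site_id=site.site_id, ref_count=int(depth) - edit, edit_count=edit
            )
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "site_id": site.site_id,
                    "true_rate": rate,
                    "depth": int(depth),
                    "edit_count": edit,
                }
            )
        samples.append(SampleSiteCounts(sample_id=sample_id, counts=counts))
    return samples, pd.DataFrame(truth_rows)


@dataclass
class AlignmentBundle:
    """Artifacts of :func:`simulate_alignments`."""

    fasta_path: Path
    bam_path: Path
    toy_panel: Panel
    sidecar_path: Path          # toy site_id <-> original site_id map
    truth: dict[str, tuple[int, int]] = field(default_factory=dict)  # site_id -> (ref, edit)


def _toy_layout(panel: Panel) -> tuple[dict[str, int], dict[str, int]]:
    """Place panel sites on short contigs; returns (contig lengths, toy pos per site)."""
    lengths: dict[str, int] = {}
    toy_pos: dict[str, int] = {}
    per_chrom: dict[str, int] = {}
    for site in panel:
        idx = per_chrom.get(site.chrom, 0)
        pos = _FIRST_SITE_POS + idx * _SITE_SPACING
        toy_pos[site.site_id] = pos
        per_chrom[site.chrom] = idx + 1
        lengths[site.chrom] = pos + _READ_LEN + 100
    return lengths, toy_pos


def simulate_alignments(
    panel: Panel,
    config: SimulationConfig,
    out_prefix: str | Path,
) -> AlignmentBundle:
    """Write a toy reference and a sorted, indexed BAM realizing edit counts.

    Panel loci are remapped onto short contigs (same chromosome names, new
    coordinates); the sidecar TSV maps toy coordinates back to the original
    ones. Reads are single-end, fully matching, MAPQ 60, base quality 40.
    With ``config.n_low_mapq_reads`` > 0, that many extra edited reads are
    planted per site at MAPQ 10 — below the default filter.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    lengths, toy_pos = _toy_layout(panel)
    contigs = {
        chrom: rng.choice(list("ACGT"), size=length)
        for chrom, length in lengths.items()
    }
    toy_sites: list[EditingSite] = []
    for site in panel:
        pos = toy_pos[site.site_id]
        contigs[site.chrom][pos - 1] = site.ref_base_plus
        toy_sites.append(
            EditingSite(
                gene_id=site.gene_id,
                chrom=site.chrom,
                pos=pos,
                ref_base_plus=site.ref_base_plus,
                substitution_label=site.substitution_label,
            )
        )
    toy_panel = Panel(sites=toy_sites, name=f"{panel.name}-toy")

    fasta_path = out_prefix.with_suffix(".fa")
    with fasta_path.open("w") as fh:
        for chrom, seq in contigs.items():
            fh.write(f">{chrom}\n{''.join(seq)}\n")

    sidecar_path = out_prefix.parent / (out_prefix.name + ".sitemap.tsv")
    with sidecar_path.open("w") as fh:
        fh.write("toy_site_id\toriginal_site_id\tgene\n")
        for toy, orig in zip(toy_panel, panel):
            fh.write(f"{toy.site_id}\t{orig.site_id}\t{orig.gene_id}\n")

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in lengths.items()],
    }
    truth: dict[str, tuple[int, int]] = {}
    unsorted_path = out_prefix.parent / (out_prefix.name + ".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted_path), "wb", header=header) as bam:
        read_no = 0
        for toy, orig in zip(toy_panel, panel):
            depth = _draw_depths(config, 1, rng)[0]
            rate = config.rate_for(orig.site_id)
            n_edit = int(rng.binomial(depth, rate)) if depth > 0 else 0
            truth[toy.site_id] = (int(depth) - n_edit, n_edit)
            alleles = [toy.edit_base_plus] * n_edit + [toy.ref_base_plus] * (int(depth) - n_edit)
            for allele in alleles:
                read_no += 1
                bam.write(_make_read(contigs, toy, allele, read_no, mapq=60))
            for _ in range(config.n_low_mapq_reads):
                read_no += 1
                bam.write(_make_read(contigs, toy, toy.edit_base_plus, read_no, mapq=10))

    bam_path = out_prefix.with_suffix(".bam")
    pysam.sort("-o", str(bam_path), str(unsorted_path))
    unsorted_path.unlink()
    pysam.index(str(bam_path))
    return AlignmentBundle(
        fasta_path=fasta_path,
        bam_path=bam_path,
        toy_panel=toy_panel,
        sidecar_path=sidecar_path,
        truth=truth,
    )


def _make_read(
    contigs: dict[str, np.ndarray],
    site: EditingSite,
    allele: str,
    read_no: int,
    mapq: int,
) -> pysam.AlignedSegment:
    start0 = site.pos - 1 - _READ_LEN // 2  # 0-based leftmost
    seq = contigs[site.chrom][start0 : start0 + _READ_LEN].copy()
    seq[site.pos - 1 - start0] = allele
    read = pysam.AlignedSegment()
    read.query_name = f"read{read_no:07d}"
    read.query_sequence = "".join(seq)
    read.flag = 0
    read.reference_id = list(contigs).index(site.chrom)
    read.reference_start = start0
    read.mapping_quality = mapq
    read.cigarstring = f"{_READ_LEN}M"
    read.query_qualities = pysam.qualitystring_to_array("I" * _READ_LEN)
    return read


def simulate_expression(
    config: SimulationConfig,
    editing_scores: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples) with planted monotone features.

    Planted features follow ``baseline * exp(+-effect_size * z(score) +
    noise)`` with log-normal noise; null features are independent of the
    score. Rows for the MMR genes, the hypermutator signature genes, and
    the retroelement signature features are appended (as nulls) so
    instability scoring is exercisable on the same matrix. Truth columns:
    feature_id, planted ("positive"/"negative"/"null").
    """
    rng = np.random.default_rng(config.seed)
    samples = list(editing_scores.index)
    n = len(samples)
    score = editing_scores.to_numpy(dtype=float)
    sd = score.std()
    z = (score - score.mean()) / (sd if sd > 0 else 1.0)

    special = list(MMR_GENES) + list(HYPERMUTATOR_GENES) + list(SIGNATURE_FEATURES)
    n_null = max(config.n_genes - config.n_planted_positive - config.n_planted_negative, 0)
    names = (
        [f"posgene{i:04d}" for i in range(config.n_planted_positive)]
        + [f"neggene{i:04d}" for i in range(config.n_planted_negative)]
        + [f"nullgene{i:04d}" for i in range(n_null)]
        + special
    )
    planted = (
        ["positive"] * config.n_planted_positive
        + ["negative"] * config.n_planted_negative
        + ["null"] * (n_null + len(special))
    )

    rows = []
    for name, kind in zip(names, planted):
        baseline = rng.lognormal(mean=3.0, sigma=0.5)
        noise = rng.normal(0.0, config.noise_sd, size=n)
        if kind == "positive":
            log_expr = config.effect_size * z + noise
        elif kind == "negative":
            log_expr = -config.effect_size * z + noise
        else:
            log_expr = rng.normal(0.0, config.noise_sd + config.effect_size / 4, size=n)
        rows.append(baseline * np.exp(log_expr))

    expr = pd.DataFrame(rows, index=names, columns=samples)
    truth = pd.DataFrame({"feature_id": names, "planted": planted})
    return expr, truth


def simulate_germline_vcf(
    panel: Panel,
    fraction: float,
    seed: int,
    path: str | Path,
) -> set[str]:
    """Write a VCF planting A/G (T/C) SNVs at a random fraction of panel sites.

    Returns the truth set of planted site_ids. ``fraction`` of the panel is
    rounded to the nearest whole number of sites.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_plant = int(round(fraction * len(panel)))
    chosen_idx = sorted(rng.choice(len(panel), size=n_plant, replace=False))
    chosen = [panel.sites[i] for i in chosen_idx]

    path = Path(path)
    chrom_order = list(dict.fromkeys(s.chrom for s in panel.sites))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chrom_order:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for site in sorted(chosen, key=lambda s: (chrom_order.index(s.chrom), s.pos)):
            alt = "G" if site.ref_base_plus == "A" else "C"
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref_base_plus}\t{alt}\t.\tPASS\t.\n"
            )
    return {s.site_id for s in chosen}
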