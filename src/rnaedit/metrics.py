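"""Sample-level editing indices over a hotspot panel.

Two indices are computed from oriented per-site counts:

* weighted index — pooled edited reads over pooled (ref + edited) reads
  across the panel, times 100. Sites with deeper coverage weigh more.
* mean index — arithmetic mean of per-site editing percentages over sites
  whose (ref + edited) coverage strictly exceeds a depth cutoff (default 5).

Panel sites where matched DNA sequencing shows an A/G (or T/C) polymorphism
are excluded from both indices so germline variants are not mistaken for
editing. Undefined values are reported as ``None`` (never 0 — a 0 index is a
meaningful measurement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

from .counts import EditCounts, SampleSiteCounts
from .panel import Panel

__all__ = [
    "SampleEditingResult",
    "GermlineEvidence",
    "site_rate",
    "weighted_editing",
    "mean_editing",
    "germline_exclusions",
    "score_sample",
    "write_results_table",
    "write_site_rates_table",
]

MEAN_MIN_TOTAL = 5  # sites must have ref+edit > this to enter the mean index


@dataclass
class GermlineEvidence:
    site_id: str
    variant_found: bool
    detail: str = ""


@dataclass
class SampleEditingResult:
    """Per-sample editing summary: per-site rates plus both indices."""

    sample_id: str
    site_rates: dict[str, float | None] = field(default_factory=dict)
    weighted_index: float | None = None
    mean_index: float | None = None
    n_sites_used_weighted: int = 0
    n_sites_used_mean: int = 0
    excluded_sites: set[str] = field(default_factory=set)


def site_rate(counts: EditCounts) -> float | None:
    """Editing percentage edit/(edit+ref)*100, or ``None`` at zero coverage."""
    total = counts.ref_count + counts.edit_count
    if total == 0:
        return None
    return 100.0 * counts.edit_count / total


def weighted_editing(
    counts: SampleSiteCounts,
    excluded: set[str] | None = None,
    min_total: int | None = None,
) -> tuple[float | None, int]:
    """Coverage-weighted pooled editing percentage and the number of sites used.

    ``min_total`` optionally applies the strict depth cutoff of the mean
    index to the weighted one as well; by default no per-site depth filter
    is applied.
    """
    excluded = excluded or set()
    num = 0
    den = 0
    n_used = 0
    for site_id, ec in counts.counts.items():
        if site_id in excluded:
            continue
        if min_total is not None and ec.total <= min_total:
            continue
        num += ec.edit_count
        den += ec.edit_count + ec.ref_count
        if ec.total > 0:
            n_used += 1
    if den == 0:
        return None, 0
    return 100.0 * num / den, n_used


def mean_editing(
    counts: SampleSiteCounts,
    excluded: set[str] | None = None,
    min_total: int = MEAN_MIN_TOTAL,
) -> tuple[float | None, int]:
    """Arithmetic mean of per-site rates over sufficiently covered sites.

    A site enters the mean only when its (ref + edit) coverage is strictly
    greater than ``min_total``. Returns ``(None, 0)`` when no site passes.
    """
    excluded = excluded or set()
    rates = []
    for site_id, ec in counts.counts.items():
        if site_id in excluded:
            continue
        if ec.total > min_total:
            rates.append(100.0 * ec.edit_count / ec.total)
    if not rates:
        return None, 0
    return math.fsum(rates) / len(rates), len(rates)


def _is_edit_pair(ref: str, alt: str) -> bool:
    pair = {ref.upper(), alt.upper()}
    return pair == {"A", "G"} or pair == {"T", "C"}


def germline_exclusions(
    variants: str | Path,
    panel: Panel,
    pass_only: bool = True,
) -> set[str]:
    """Panel sites overlapped by a germline A/G (T/C) SNV in a VCF.

    Only single-nucleotide records whose ref/alt pair is {A,G} or {T,C}
    (either orientation) trigger exclusion. A VCF whose contig naming
    cannot be reconciled with the panel raises rather than silently
    returning an empty set.
    """
    import pysam

    from .panel import normalize_chrom

    by_locus = {(s.chrom, s.pos): s for s in panel.sites}
    excluded: set[str] = set()
    n_records = 0
    vcf_contigs: set[str] = set()
    with pysam.VariantFile(str(variants)) as vcf:
        for rec in vcf:
            n_records += 1
            chrom = normalize_chrom(rec.chrom, "chr")
            vcf_contigs.add(chrom)
            site = by_locus.get((chrom, rec.pos))
            if site is None:
                continue
            if pass_only and rec.filter.keys() not in ([], ["PASS"]):
                continue
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if len(rec.ref) == 1 and len(alt) == 1 and _is_edit_pair(rec.ref, alt):
                    excluded.add(site.site_id)
                    break

    if n_records > 0 and vcf_contigs:
        panel_chroms = {s.chrom for s in panel.sites}
        if not vcf_contigs & panel_chroms:
            raise ValueError(
                "VCF and panel share no contig names after normalization: "
                f"VCF has {sorted(vcf_contigs)[:5]}, panel has {sorted(panel_chroms)[:5]}"
            )
    return excluded


def score_sample(
    counts: SampleSiteCounts,
    panel: Panel,
    variants: str | Path | None = None,
    excluded: set[str] | None = None,
    mean_min_total: int = MEAN_MIN_TOTAL,
    weighted_min_total: int | None = None,
) -> SampleEditingResult:
    """Compose germline exclusion, per-site rates, and both indices."""
    exclude = set(excluded or ())
    if variants is not None:
        exclude |= germline_exclusions(variants, panel)

    result = SampleEditingResult(sample_id=counts.sample_id, excluded_sites=exclude)
    for site_id, ec in counts.counts.items():
        result.site_rates[site_id] = None if site_id in exclude else site_rate(ec)

    result.weighted_index, result.n_sites_used_weighted = weighted_editing(
        counts, excluded=exclude, min_total=weighted_min_total
    )
    result.mean_index, result.n_sites_used_mean = mean_editing(
        counts, excluded=exclude, min_total=mean_min_total
    )
    return result


def _fmt(value: float | None) -> str:
    return "NA" if value is None else repr(value)


def _open_out(path):
    """Accept a filesystem path or an open file-like object."""
    import contextlib
    import io

    if hasattr(path, "write"):
        return contextlib.nullcontext(path)
    return io.open(Path(path), "w")


def write_results_table(results: list[SampleEditingResult], path) -> None:
    """Sample-level TSV: one row per sample with both indices."""
    with _open_out(path) as fh:
        fh.write(
            "sample_id\tweighted_index\tmean_index\t"
            "n_sites_used_weighted\tn_sites_used_mean\texcluded_sites\n"
        )
        for r in results:
            fh.write(
                f"{r.sample_id}\t{_fmt(r.weighted_index)}\t{_fmt(r.mean_index)}\t"
                f"{r.n_sites_used_weighted}\t{r.n_sites_used_mean}\t"
                f"{','.join(sorted(r.excluded_sites))}\n"
            )


def write_site_rates_table(results: list[SampleEditingResult], path) -> None:
    """Long-format per-site rate TSV (sample_id, site_id, rate_percent)."""
    with _open_out(path) as fh:
        fh.write("sample_id\tsite_id\trate_percent\n")
        for r in results:
            for site_id, rate in r.site_rates.items():
                fh.write(f"{r.sample_id}\t{site_id}\t{_fmt(rate)}\n")
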