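"""Per-site filtered base counting from alignment files and count tables.

Counting follows bam-readcount-style semantics: only primary, non-duplicate,
non-secondary, non-supplementary alignments with mapping quality >= 20
contribute, and only base calls with base quality >= 20 are counted
(both thresholds configurable). Deletions and reference skips spanning the
site are not counted. Overlapping mate pairs are counted once per fragment
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .panel import EditingSite, Panel, PanelError

__all__ = [
    "BaseCounts",
    "EditCounts",
    "SampleSiteCounts",
    "count_bases_at_site",
    "orient_counts",
    "pileup_sample",
    "read_counts_table",
    "write_counts_table",
]

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_BASEQ = 20

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class BaseCounts:
    """Plus-strand base counts observed at one site after filtering."""

    site_id: str
    n_A: int = 0
    n_C: int = 0
    n_G: int = 0
    n_T: int = 0
    n_other: int = 0

    def __post_init__(self) -> None:
        for name in ("n_A", "n_C", "n_G", "n_T", "n_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def depth(self) -> int:
        return self.n_A + self.n_C + self.n_G + self.n_T + self.n_other


@dataclass(frozen=True)
class EditCounts:
    """Reference-allele and edited-allele read counts in edit orientation."""

    site_id: str
    ref_count: int
    edit_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.edit_count < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_count + self.edit_count


@dataclass
class SampleSiteCounts:
    """Mapping site_id -> :class:`EditCounts` for one sample, keyed by a panel."""

    sample_id: str
    counts: dict[str, EditCounts] = field(default_factory=dict)

    def __getitem__(self, site_id: str) -> EditCounts:
        return self.counts[site_id]

    def __iter__(self):
        return iter(self.counts)

    @classmethod
    def zeros(cls, sample_id: str, panel: Panel) -> "SampleSiteCounts":
        return cls(
            sample_id=sample_id,
            counts={sid: EditCounts(sid, 0, 0) for sid in panel.site_ids},
        )


def _read_passes(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
        return False
    if read.is_qcfail:
        return False
    return read.mapping_quality >= min_mapq


def count_bases_at_site(
    alignments: str | Path | pysam.AlignmentFile,
    site: EditingSite,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    dedup_mate_overlap: bool = True,
) -> BaseCounts:
    """Count filtered plus-strand base calls covering ``site``.

    With ``dedup_mate_overlap`` (default), a fragment whose mates both cover
    the site contributes a single call: the one with the higher base quality
    wins; on a quality tie the first mate encountered is kept.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments), "rb")
        own = True
    try:
        if site.chrom not in alignments.references:
            raise PanelError(
                f"chromosome {site.chrom!r} absent from alignment header "
                f"(references: {alignments.references[:5]}...)"
            )
        target = site.pos - 1  # 0-based
        tallies = {b: 0 for b in _BASES}
        n_other = 0
        # fragment name -> (base, qual) kept so far, for mate-overlap dedup
        fragment_calls: dict[str, tuple[str, int]] = {}

        for read in alignments.fetch(site.chrom, target, target + 1):
            if not _read_passes(read, min_mapq):
                continue
            quals = read.query_qualities
            seq = read.query_sequence
            if seq is None:
                continue
            qpos = None
            for q, r in read.get_aligned_pairs(matches_only=True):
                if r == target:
                    qpos = q
                    break
            if qpos is None:  # deletion or refskip at the site
                continue
            baseq = quals[qpos] if quals is not None else 255
            if baseq < min_baseq:
                continue
            base = seq[qpos].upper()
            if dedup_mate_overlap and read.is_paired:
                prev = fragment_calls.get(read.query_name)
                if prev is None or baseq > prev[1]:
                    fragment_calls[read.query_name] = (base, baseq)
                continue
            if base in tallies:
                tallies[base] += 1
            else:
                n_other += 1

        for base, _q in fragment_calls.values():
            if base in tallies:
                tallies[base] += 1
            else:
                n_other += 1

        return BaseCounts(
            site_id=site.site_id,
            n_A=tallies["A"],
            n_C=tallies["C"],
            n_G=tallies["G"],
            n_T=tallies["T"],
            n_other=n_other,
        )
    finally:
        if own:
            alignments.close()


def orient_counts(base: BaseCounts, site: EditingSite) -> EditCounts:
    """Project raw base counts onto (ref, edit) in edit orientation.

    Ref ``A`` sites read editing as A>G on the plus strand; ref ``T`` sites
    (minus-strand genes) read it as T>C. All other observed bases are
    ignored.
    """
    if site.ref_base_plus == "A":
        return EditCounts(site_id=base.site_id, ref_count=base.n_A, edit_count=base.n_G)
    if site.ref_base_plus == "T":
        return EditCounts(site_id=base.site_id, ref_count=base.n_T, edit_count=base.n_C)
    raise PanelError(
        f"corrupted panel: ref_base_plus {site.ref_base_plus!r} at {site.site_id}"
    )


def pileup_sample(
    alignments: str | Path,
    panel: Panel,
    sample_id: str | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_baseq: int = DEFAULT_MIN_BASEQ,
    dedup_mate_overlap: bool = True,
) -> SampleSiteCounts:
    """Count every panel site in one alignment file.

    Sites on chromosomes absent from the alignment header raise with site
    context; sites with no coverage yield (0, 0).
    """
    path = Path(alignments)
    sample_id = sample_id or path.stem
    result = SampleSiteCounts(sample_id=sample_id)
    with pysam.AlignmentFile(str(path), "rb") as af:
        for site in panel:
            try:
                base = count_bases_at_site(
                    af, site, min_mapq=min_mapq, min_baseq=min_baseq,
                    dedup_mate_overlap=dedup_mate_overlap,
                )
            except PanelError as exc:
                raise PanelError(f"site {site.site_id} ({site.gene_id}): {exc}") from exc
            result.counts[site.site_id] = orient_counts(base, site)
    return result


def read_counts_table(path: str | Path, panel: Panel) -> list[SampleSiteCounts]:
    """Ingest a precomputed count table (TSV: sample_id, site_id, ref_count, edit_count).

    Rows are grouped by sample; panel sites absent for a sample are filled
    with zeros. Unknown site_ids and negative counts are errors.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "site_id": str})
    required = {"sample_id", "site_id", "ref_count", "edit_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(sorted(missing))}")

    panel_ids = set(panel.site_ids)
    unknown = set(df["site_id"]) - panel_ids
    if unknown:
        raise ValueError(f"{path}: site_id(s) not in panel: {sorted(unknown)[:5]}")
    if (df["ref_count"] < 0).any() or (df["edit_count"] < 0).any():
        raise ValueError(f"{path}: negative counts")

    out: list[SampleSiteCounts] = []
    for sample_id, group in df.groupby("sample_id", sort=False):
        ssc = SampleSiteCounts.zeros(str(sample_id), panel)
        for row in group.itertuples(index=False):
            ssc.counts[row.site_id] = EditCounts(
                site_id=row.site_id,
                ref_count=int(row.ref_count),
                edit_count=int(row.edit_count),
            )
        out.append(ssc)
    return out


def write_counts_table(samples: list[SampleSiteCounts], path: str | Path) -> None:
    """Write per-sample counts in the same schema accepted by :func:`read_counts_table`."""
    with Path(path).open("w") as fh:
        fh.write("sample_id\tsite_id\tref_count\tedit_count\n")
        for ssc in samples:
            for site_id, ec in ssc.counts.items():
                fh.write(f"{ssc.sample_id}\t{site_id}\t{ec.ref_count}\t{ec.edit_count}\n")
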