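"""Curated hotspot editing-site panel: parsing, validation, and export.

A panel is an ordered collection of exonic A-to-I editing sites. Each site
records the plus-strand reference base (``A`` or ``T``) so that downstream
pileup counting knows whether editing is observed as A>G or as T>C on the
plus strand.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "EditingSite",
    "Panel",
    "PanelError",
    "load_panel",
    "write_panel",
    "default_panel",
    "write_bed",
]

_REQUIRED_COLUMNS = ("gene", "chrom", "pos", "ref_base_plus", "label")

_VALID_REF_BASES = frozenset({"A", "T"})


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel definitions."""


def normalize_chrom(chrom: str, style: str = "chr") -> str:
    """Map between ``chr15`` and ``15`` chromosome-name dialects.

    Parameters
    ----------
    chrom
        Input chromosome name in either dialect.
    style
        ``"chr"`` for chr-prefixed output, ``"plain"`` for bare names.
    """
    bare = chrom[3:] if chrom.startswith("chr") else chrom
    if style == "chr":
        return f"chr{bare}"
    if style == "plain":
        return bare
    raise ValueError(f"unknown chromosome-name style: {style!r}")


@dataclass(frozen=True)
class EditingSite:
    """One curated hotspot editing locus (1-based, fully closed coordinate)."""

    gene_id: str
    chrom: str
    pos: int
    ref_base_plus: str
    substitution_label: str = ""

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise PanelError(f"site {self.gene_id}: pos must be positive, got {self.pos}")
        if self.ref_base_plus not in _VALID_REF_BASES:
            raise PanelError(
                f"site {self.gene_id} {self.chrom}:{self.pos}: ref_base_plus must be "
                f"'A' or 'T', got {self.ref_base_plus!r}"
            )

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def edit_base_plus(self) -> str:
        """Plus-strand base that an edited read carries (G for ref A, C for ref T)."""
        return "G" if self.ref_base_plus == "A" else "C"


@dataclass
class Panel:
    """Ordered, duplicate-free collection of :class:`EditingSite` records."""

    sites: list[EditingSite] = field(default_factory=list)
    name: str = "panel"
    genome_build: str = "hg38"

    def __post_init__(self) -> None:
        if not self.sites:
            raise PanelError("empty panel")
        seen: set[str] = set()
        for site in self.sites:
            if site.site_id in seen:
                raise PanelError(f"duplicate site_id {site.site_id}")
            seen.add(site.site_id)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[EditingSite]:
        return iter(self.sites)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Panel):
            return NotImplemented
        return self.sites == other.sites

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def gene_ids(self) -> list[str]:
        """Distinct gene symbols, in order of first appearance."""
        return list(dict.fromkeys(s.gene_id for s in self.sites))

    def get(self, site_id: str) -> EditingSite:
        for site in self.sites:
            if site.site_id == site_id:
                return site
        raise KeyError(site_id)


def load_panel(path: str | Path, name: str | None = None, chrom_style: str = "chr") -> Panel:
    """Parse a tab-separated panel file into a validated :class:`Panel`.

    The file must carry a header row with columns ``gene``, ``chrom``,
    ``pos``, ``ref_base_plus`` and ``label``; ``#``-prefixed lines are
    comments. Row order is preserved. Malformed rows raise
    :class:`PanelError` with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel file not found: {path}")

    header: list[str] | None = None
    sites: list[EditingSite] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in _REQUIRED_COLUMNS if c not in header]
                if missing:
                    raise PanelError(
                        f"{path}: missing required column(s): {', '.join(missing)}"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                pos = int(row["pos"].replace(",", ""))
            except (KeyError, ValueError):
                raise PanelError(
                    f"{path}:{lineno}: pos is not an integer: {row.get('pos')!r}"
                ) from None
            try:
                site = EditingSite(
                    gene_id=row["gene"].strip(),
                    chrom=normalize_chrom(row["chrom"].strip(), chrom_style),
                    pos=pos,
                    ref_base_plus=row["ref_base_plus"].strip().upper(),
                    substitution_label=row.get("label", "").strip(),
                )
            except PanelError as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from None
            sites.append(site)

    if header is None:
        raise PanelError(f"{path}: empty panel (no header row)")
    if not sites:
        raise PanelError(f"{path}: empty panel (header only)")
    try:
        return Panel(sites=sites, name=name or path.stem)
    except PanelError as exc:
        raise PanelError(f"{path}: {exc}") from None


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write ``panel`` as TSV such that :func:`load_panel` round-trips it."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_REQUIRED_COLUMNS) + "\n")
        for s in panel.sites:
            fh.write(
                f"{s.gene_id}\t{s.chrom}\t{s.pos}\t{s.ref_base_plus}\t{s.substitution_label}\n"
            )


def write_bed(panel: Panel, path: str | Path) -> None:
    """BED export (0-based half-open intervals) for interoperability."""
    path = Path(path)
    with path.open("w") as fh:
        for s in panel.sites:
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.gene_id}\n")


def default_panel() -> Panel:
    """The shipped curated 24-site hotspot panel (GRCh38)."""
    resource = importlib.resources.files("rnaedit.data").joinpath("hotspot_panel.tsv")
    with importlib.resources.as_file(resource) as path:
        return load_panel(path, name="hotspot24")


def validate_against_references(panel: Panel, references: Iterable[str]) -> None:
    """Check that each panel chromosome exists in a sequence dictionary."""
    known = set(references)
    for site in panel.sites:
        if site.chrom not in known:
            raise PanelError(
                f"panel chromosome {site.chrom!r} absent from alignment header"
            )
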