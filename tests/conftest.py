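from __future__ import annotations

import pytest

from rnaedit.counts import EditCounts, SampleSiteCounts
from rnaedit.panel import EditingSite, Panel, default_panel


@pytest.fixture(scope="session")
def panel() -> Panel:
    return default_panel()


@pytest.fixture
def tiny_panel() -> Panel:
    """Three-site panel mixing plus- and minus-strand orientations."""
    return Panel(
        sites=[
            EditingSite("GENEA", "chr1", 1000, "A", "nonsynonymous (K1R)"),
            EditingSite("GENEB", "chr1", 2000, "T", "synonymous (L2L)"),
            EditingSite("GENEC", "chr2", 500, "A", "nonsynonymous (Q3R)"),
        ],
        name="tiny",
    )


def make_counts(sample_id: str, pairs: dict[str, tuple[int, int]]) -> SampleSiteCounts:
    """Build SampleSiteCounts from {site_id: (ref, edit)}."""
    return SampleSiteCounts(
        sample_id=sample_id,
        counts={sid: EditCounts(sid, ref, edit) for sid, (ref, edit) in pairs.items()},
    )
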