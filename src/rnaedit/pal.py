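"""Pathway activation levels from case-to-normal expression ratios.

For each gene, the case-to-normal ratio (CNR) is its expression in a sample
divided by the geometric mean of that gene across the sample's group
(same tissue status within the same dataset). A pathway's activation level
is then

    PAL = 100 * sum_n(ARR_n * log10(CNR_n)) / sum_n(|ARR_n|)

where ARR encodes each member gene's role: +1 activator, -1 repressor,
0 ambiguous. Ambiguous genes contribute to neither sum. Pathways with more
than 10 member genes are retained for analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Pathway",
    "PALResult",
    "load_pathway_db",
    "write_pathway_db",
    "compute_cnr",
    "pal_score",
    "filter_pathways",
    "pal_matrix",
]

MIN_PATHWAY_GENES = 10  # strict: pathways must have MORE than this many genes

_VALID_ROLES = (-1, 0, 1)


@dataclass
class Pathway:
    """Pathway id plus member-gene -> activator/repressor role map."""

    pathway_id: str
    arr: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.arr:
            raise ValueError(f"pathway {self.pathway_id}: no member genes")
        bad = {g: r for g, r in self.arr.items() if r not in _VALID_ROLES}
        if bad:
            raise ValueError(
                f"pathway {self.pathway_id}: roles must be -1/0/+1, got {bad}"
            )

    def __len__(self) -> int:
        return len(self.arr)


@dataclass(frozen=True)
class PALResult:
    sample_id: str
    pathway_id: str
    pal: float
    n_genes_used: int


def load_pathway_db(path: str | Path) -> list[Pathway]:
    """Load a pathway database TSV with columns pathway_id, gene, arr."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"pathway_id": str, "gene": str})
    missing = {"pathway_id", "gene", "arr"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    pathways = []
    for pid, group in df.groupby("pathway_id", sort=False):
        arr = {row.gene: int(row.arr) for row in group.itertuples(index=False)}
        pathways.append(Pathway(pathway_id=str(pid), arr=arr))
    return pathways


def write_pathway_db(db: list[Pathway], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("pathway_id\tgene\tarr\n")
        for pw in db:
            for gene, role in pw.arr.items():
                fh.write(f"{pw.pathway_id}\t{gene}\t{role}\n")


def compute_cnr(
    expr: pd.DataFrame,
    group_samples: list[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Case-to-normal ratios for the samples of one normalization group.

    ``expr`` is genes x samples with non-negative values. Each gene's value
    (plus ``pseudocount``) is divided by the geometric mean of that gene
    (plus ``pseudocount``) across ``group_samples``. Entries are strictly
    positive when pseudocount > 0 or all group values are positive.
    """
    if not group_samples:
        raise ValueError("empty normalization group")
    missing = set(group_samples) - set(expr.columns)
    if missing:
        raise KeyError(f"group samples absent from matrix: {sorted(missing)[:5]}")
    sub = expr[group_samples].astype(float) + pseudocount
    if (sub <= 0).any().any():
        raise ValueError("non-positive expression after pseudocount; increase pseudocount")
    log_gm = np.log(sub).mean(axis=1)
    cnr = sub.div(np.exp(log_gm), axis=0)
    return cnr


def pal_score(
    cnr_sample: dict[str, float] | pd.Series,
    pathway: Pathway,
    log_base: float = 10.0,
) -> PALResult | None:
    """Activation level of one pathway in one sample, or ``None`` if undefined.

    Pathway genes absent from the expression data are dropped from both the
    numerator and the denominator. The result is undefined (``None``) when
    no present gene has a nonzero role.
    """
    if isinstance(cnr_sample, pd.Series):
        sample_id = str(cnr_sample.name) if cnr_sample.name is not None else ""
        cnr_sample = cnr_sample.to_dict()
    else:
        sample_id = ""
    num = 0.0
    den = 0.0
    n_used = 0
    for gene, role in pathway.arr.items():
        cnr = cnr_sample.get(gene)
        if cnr is None or not math.isfinite(cnr):
            continue
        if cnr <= 0:
            raise ValueError(f"non-positive CNR for gene {gene}: {cnr}")
        num += role * (math.log(cnr) / math.log(log_base))
        den += abs(role)
        n_used += 1
    if den == 0:
        return None
    return PALResult(
        sample_id=sample_id,
        pathway_id=pathway.pathway_id,
        pal=100.0 * num / den,
        n_genes_used=n_used,
    )


def filter_pathways(db: list[Pathway], min_genes: int = MIN_PATHWAY_GENES) -> list[Pathway]:
    """Keep pathways with strictly more than ``min_genes`` member genes."""
    return [pw for pw in db if len(pw) > min_genes]


def pal_matrix(
    expr: pd.DataFrame,
    db: list[Pathway],
    groups: dict[str, list[str]] | None = None,
    pseudocount: float = 1.0,
    log_base: float = 10.0,
    apply_size_filter: bool = True,
) -> pd.DataFrame:
    """PAL for every retained pathway x sample; pathways x samples frame.

    ``groups`` maps a group label to its member sample ids; each sample's
    CNR is computed against the geometric mean of its own group. With
    ``groups=None`` all samples form one group. Undefined PALs are NaN.
    """
    if groups is None:
        groups = {"all": list(expr.columns)}
    pathways = filter_pathways(db) if apply_size_filter else list(db)
    out = pd.DataFrame(
        np.nan,
        index=[pw.pathway_id for pw in pathways],
        columns=[s for members in groups.values() for s in members],
        dtype=float,
    )
    for _label, members in groups.items():
        cnr = compute_cnr(expr, members, pseudocount=pseudocount)
        for sample in members:
            col = cnr[sample]
            for pw in pathways:
                res = pal_score(col, pw, log_base=log_base)
                if res is not None:
                    out.at[pw.pathway_id, sample] = res.pal
    return out
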