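"""Association framework: correlation, multiplicity, intersections, permutations.

A per-sample editing score is correlated (Spearman) against each row of a
feature matrix; raw p-values are Benjamini–Hochberg adjusted; features are
split into positive/negative significant sets; sets from several groups are
intersected; and intersection sizes are tested against a size-preserving
uniform-resampling null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationRecord",
    "SignificantSets",
    "IntersectionResult",
    "correlate_profile",
    "bh_adjust",
    "significant_sets",
    "double_intersection",
    "permutation_intersection_test",
    "fisher_z_mean",
    "compare_groups",
]


@dataclass(frozen=True)
class AssociationRecord:
    feature_id: str
    rho: float  # NaN when undefined (constant input)
    p: float
    p_adj: float = float("nan")
    direction: str = "none"  # "positive" | "negative" | "none"


@dataclass
class SignificantSets:
    label: str
    positive: set[str] = field(default_factory=set)
    negative: set[str] = field(default_factory=set)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError("positive and negative sets overlap")


@dataclass(frozen=True)
class IntersectionResult:
    common_positive: frozenset[str]
    common_negative: frozenset[str]
    perm_p_positive: float
    perm_p_negative: float
    n_permutations: int
    seed: int


def correlate_profile(
    score: pd.Series,
    features: pd.DataFrame,
    min_overlap: int = 3,
) -> list[AssociationRecord]:
    """Spearman correlation of a per-sample score against each feature row.

    Samples are aligned by id; per feature, only samples where both values
    are defined are used. Features with fewer than ``min_overlap`` paired
    observations or a constant vector get ``rho = NaN`` and ``p = NaN``
    (reported but excluded from testing).
    """
    common = features.columns.intersection(score.index)
    if len(common) == 0:
        raise ValueError("no overlapping samples between score and feature matrix")
    score = score[common].astype(float)
    sub = features[common].astype(float)

    records: list[AssociationRecord] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        for feature_id, row in sub.iterrows():
            mask = row.notna() & score.notna()
            n = int(mask.sum())
            if n < min_overlap:
                records.append(AssociationRecord(str(feature_id), np.nan, np.nan))
                continue
            x = score[mask].to_numpy()
            y = row[mask].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                records.append(AssociationRecord(str(feature_id), np.nan, np.nan))
                continue
            rho, p = stats.spearmanr(x, y)
            records.append(AssociationRecord(str(feature_id), float(rho), float(p)))
    return records


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving.

    NaN entries are passed through unchanged and do not count toward the
    number of tests.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(m)
    result[order] = adj
    out[valid] = result
    return out


def adjust_records(records: list[AssociationRecord]) -> list[AssociationRecord]:
    """Attach BH-adjusted p-values to association records."""
    p_adj = bh_adjust([r.p for r in records])
    return [
        AssociationRecord(r.feature_id, r.rho, r.p, float(pa), r.direction)
        for r, pa in zip(records, p_adj)
    ]


def significant_sets(
    records: list[AssociationRecord],
    label: str = "",
    p_adj_threshold: float = 0.05,
    rho_threshold: float = 0.0,
) -> SignificantSets:
    """Split features into positively/negatively significant sets.

    Positive: rho > +rho_threshold and p_adj < p_adj_threshold; negative is
    symmetric. Features with undefined statistics go to neither set but stay
    in the universe.
    """
    out = SignificantSets(label=label)
    for r in records:
        out.universe.add(r.feature_id)
        if np.isnan(r.rho) or np.isnan(r.p_adj):
            continue
        if r.p_adj < p_adj_threshold:
            if r.rho > rho_threshold:
                out.positive.add(r.feature_id)
            elif r.rho < -rho_threshold:
                out.negative.add(r.feature_id)
    return out


def double_intersection(sets: list[SignificantSets]) -> tuple[set[str], set[str]]:
    """Intersect positive and negative sets across all groups."""
    if not sets:
        return set(), set()
    pos = set(sets[0].positive)
    neg = set(sets[0].negative)
    for s in sets[1:]:
        pos &= s.positive
        neg &= s.negative
    return pos, neg


def _permuted_intersection_sizes(
    sizes: list[int], universe_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Intersection sizes of size-preserving uniform random subsets."""
    common = np.ones((n_perm, universe_size), dtype=bool)
    for k in sizes:
        noise = rng.random((n_perm, universe_size))
        # indices of the k smallest values per row = uniform subset of size k
        if k == 0:
            common[:] = False
            continue
        kth = np.partition(noise, k - 1, axis=1)[:, k - 1 : k]
        common &= noise <= kth
    return common.sum(axis=1)


def permutation_intersection_test(
    sets: list[set[str]],
    universe: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical p-value for the observed multi-set intersection size.

    Null model: each group's set is redrawn uniformly at random from the
    universe at its observed size; p = (1 + #{permuted >= observed}) /
    (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for s in sets:
        if not s <= universe:
            raise ValueError("a set contains elements outside the universe")
    observed = len(set.intersection(*[set(s) for s in sets])) if sets else 0
    rng = np.random.default_rng(seed)
    sizes = _permuted_intersection_sizes(
        [len(s) for s in sets], len(universe), n_perm, rng
    )
    return float(1 + int((sizes >= observed).sum())) / (n_perm + 1)


def intersect_and_test(
    sets: list[SignificantSets],
    universe: set[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> IntersectionResult:
    """Intersections of positive/negative sets plus permutation p-values."""
    if universe is None:
        universe = set().union(*(s.universe for s in sets))
    pos, neg = double_intersection(sets)
    p_pos = permutation_intersection_test(
        [s.positive for s in sets], universe, n_perm=n_perm, seed=seed
    )
    p_neg = permutation_intersection_test(
        [s.negative for s in sets], universe, n_perm=n_perm, seed=seed + 1
    )
    return IntersectionResult(
        common_positive=frozenset(pos),
        common_negative=frozenset(neg),
        perm_p_positive=p_pos,
        perm_p_negative=p_neg,
        n_permutations=n_perm,
        seed=seed,
    )


def fisher_z_mean(rhos, clamp: float = 1.0 - 1e-12) -> float:
    """Average correlations on the Fisher-z (atanh) scale: tanh(mean(atanh(r))).

    Values at exactly +-1 are clamped just inside the open interval with a
    warning.
    """
    r = np.asarray(list(rhos), dtype=float)
    if r.size == 0:
        raise ValueError("no correlations to average")
    if (np.abs(r) > 1).any():
        raise ValueError("correlations must lie in [-1, 1]")
    if (np.abs(r) >= 1).any():
        warnings.warn("clamping |rho| = 1 before Fisher z-transform", stacklevel=2)
        r = np.clip(r, -clamp, clamp)
    return float(np.tanh(np.mean(np.arctanh(r))))


def compare_groups(
    values: pd.Series,
    labels: pd.Series,
    comparisons: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Two-sided Mann–Whitney U tests between labeled groups, BH-adjusted.

    ``comparisons`` lists (group_a, group_b) pairs; by default every
    unordered pair of observed labels is tested. Returns a frame with
    columns group_a, group_b, u_statistic, p, p_adj.
    """
    values, labels = values.align(labels, join="inner")
    observed = list(dict.fromkeys(labels.dropna()))
    if comparisons is None:
        comparisons = [
            (a, b) for i, a in enumerate(observed) for b in observed[i + 1 :]
        ]
    rows = []
    for a, b in comparisons:
        va = values[labels == a].dropna().to_numpy()
        vb = values[labels == b].dropna().to_numpy()
        if va.size == 0 or vb.size == 0:
            raise ValueError(f"empty group in comparison {a!r} vs {b!r}")
        u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "u_statistic": float(u), "p": float(p)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Association records as a tidy frame (feature, rho, p, p_adj, direction)."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "rho": [r.rho for r in records],
            "p": [r.p for r in records],
            "p_adj": [r.p_adj for r in records],
            "direction": [r.direction for r in records],
        }
    )
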