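"""Per-contig proportion-of-expression profiles, the constant-expression
null, upper-tail stage-enriched gene sets, and top-of-pool representation
lists.

The central statistic is simple: for each contig that passes the minimum
read filter, the fraction of its total depth-normalized expression observed
in each age group. Under constant expression each of the five libraries
would carry 20% of a transcript's reads — (40%, 20%, 40%) for the
{0+4, 8, 12+16} grouping — and stage-enriched transcripts are those in the
top quantile of the observed proportion for a group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix
from .stage_grouping import AgeGroupScheme

DEFAULT_TAIL_QUANTILE = 0.025
DEFAULT_SHARE_THRESHOLD = 0.001


def group_proportions(
    tpt: pd.DataFrame,
    scheme: AgeGroupScheme,
    filtered_ids=None,
) -> pd.DataFrame:
    """Proportion of each contig's expression falling in each age group.

    ``portion_g = sum(TPT over group g) / sum(TPT over all libraries)``;
    rows sum to 1. Contigs with zero total TPT are excluded with a warning.
    Restricting to ``filtered_ids`` applies the analysis filter.
    """
    df = tpt.loc[list(filtered_ids)] if filtered_ids is not None else tpt
    sums = pd.DataFrame(
        {name: df[list(libs)].sum(axis=1) for name, libs in zip(scheme.names, scheme.groups)}
    )
    total = sums.sum(axis=1)
    zero = total.index[total == 0]
    if len(zero):
        warnings.warn(f"excluding {len(zero)} contigs with zero total expression")
        sums = sums.loc[total > 0]
        total = total.loc[total > 0]
    return sums.div(total, axis=0)


def null_expectation(scheme: AgeGroupScheme) -> np.ndarray:
    """Constant-expression null: per group, libraries-in-group / libraries."""
    return scheme.null_proportions()


@dataclass
class TailSets:
    """Upper-tail (stage-enriched) contig sets per age group."""

    quantile: float
    sets: dict[str, list[str]]
    thresholds: dict[str, float]
    overlaps: dict[tuple[str, str], int]
    mean_portion: dict[str, float]

    def pairwise_disjoint(self) -> bool:
        return all(v == 0 for v in self.overlaps.values())


def tail_sets(
    profiles: pd.DataFrame,
    quantile: float = DEFAULT_TAIL_QUANTILE,
    totals: pd.Series | None = None,
) -> TailSets:
    """Select the top ``quantile`` of contigs for each group's proportion.

    Tail size is ``ceil(quantile * N)``. Ranking ties are broken
    deterministically: higher portion, then more total reads, then smaller
    contig id. Overlap counts between the per-group sets are reported, not
    resolved; use :func:`assign_argmax` to force disjointness.
    """
    if not 0 <= quantile <= 1:
        raise ValueError("quantile must be in [0, 1]")
    n = len(profiles)
    k = math.ceil(quantile * n)
    if totals is None:
        totals = pd.Series(0, index=profiles.index)
    sets: dict[str, list[str]] = {}
    thresholds: dict[str, float] = {}
    for g in profiles.columns:
        order = sorted(
            profiles.index,
            key=lambda c: (-profiles.at[c, g], -totals.at[c], str(c)),
        )
        chosen = order[:k]
        sets[g] = chosen
        thresholds[g] = float(profiles.loc[chosen, g].min()) if chosen else float("nan")
    overlaps = {
        (a, b): len(set(sets[a]) & set(sets[b]))
        for i, a in enumerate(profiles.columns)
        for b in profiles.columns[i + 1 :]
    }
    mean_portion = {g: float(profiles[g].mean()) for g in profiles.columns}
    return TailSets(quantile, sets, thresholds, overlaps, mean_portion)


def assign_argmax(tails: TailSets, profiles: pd.DataFrame) -> dict[str, list[str]]:
    """Resolve tail-set overlaps by assigning each contig to its max-portion group."""
    out: dict[str, list[str]] = {g: [] for g in tails.sets}
    for g, ids in tails.sets.items():
        for c in ids:
            if profiles.loc[c].idxmax() == g:
                out[g].append(c)
    return out


@dataclass
class TopRepresented:
    """Contigs holding more than a threshold share of each group's read pool."""

    share_threshold: float
    shares: pd.DataFrame  # contig x group share of pool
    lists: dict[str, list[str]]
    exclusive: dict[str, list[str]]
    common: list[str]


def top_represented(
    counts: CountMatrix,
    scheme: AgeGroupScheme,
    share_threshold: float = DEFAULT_SHARE_THRESHOLD,
) -> TopRepresented:
    """Most highly represented contigs per group (>0.1% of pool by default).

    A contig's share of a group is its reads there divided by the group's
    total reads; shares within a group sum to 1 over all contigs. The
    exclusive sublists contain contigs above threshold in exactly that one
    group.
    """
    sums = pd.DataFrame(
        {name: counts.df[list(libs)].sum(axis=1) for name, libs in zip(scheme.names, scheme.groups)}
    )
    pool = sums.sum(axis=0)
    zero = pool.index[pool == 0].tolist()
    if zero:
        raise ValueError(f"groups with zero total reads: {zero}")
    shares = sums.div(pool, axis=1)
    above = shares > share_threshold
    lists = {g: list(shares.index[above[g]]) for g in shares.columns}
    n_groups_above = above.sum(axis=1)
    exclusive = {
        g: list(shares.index[above[g] & (n_groups_above == 1)]) for g in shares.columns
    }
    common = list(shares.index[n_groups_above == len(shares.columns)])
    return TopRepresented(share_threshold, shares, lists, exclusive, common)
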