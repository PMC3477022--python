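"""K-means clustering of expression-shape profiles and GO category
enrichment with normalized frequencies, bootstrap SDs and hypergeometric
p-values.

Profiles are clustered on per-age portions (five non-negative values summing
to 1) so that shape, not magnitude, drives cluster membership. Lloyd's
algorithm is implemented directly — Euclidean distance, best of several
random restarts by inertia, empty clusters re-seeded from the farthest
point — so the iteration trace is available to callers.

GO enrichment follows the normalized-frequency convention: a gene set's
fraction annotated to a category divided by that category's genome-wide
fraction, with a bootstrap SD over resamples of the set and a hypergeometric
tail p-value (categories are multi-label; each is tested independently).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

DEFAULT_K = 10
DEFAULT_RESTARTS = 25
DEFAULT_N_BOOT = 100
CONVERGENCE_TOL = 1e-8
MAX_ITER = 300


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series  # contig -> cluster id in [0, k)
    centroids: pd.DataFrame  # k x ages
    inertia: float
    seed: int
    restarts: int
    inertia_history: list[float]  # per-iteration inertia of the winning restart


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator):
    n = X.shape[0]
    C = X[rng.choice(n, size=k, replace=False)].copy()
    history: list[float] = []
    labels = np.zeros(n, dtype=int)
    for _ in range(MAX_ITER):
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        history.append(float(d2[np.arange(n), labels].sum()))
        newC = C.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                newC[j] = X[members].mean(axis=0)
            else:  # re-seed an empty cluster from the farthest point
                far = int(d2[np.arange(n), labels].argmax())
                newC[j] = X[far]
        shift = float(np.sqrt(((newC - C) ** 2).sum(axis=1)).max())
        C = newC
        if shift < CONVERGENCE_TOL:
            break
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    history.append(inertia)
    return labels, C, inertia, history


def kmeans_profiles(
    profiles: pd.DataFrame,
    k: int = DEFAULT_K,
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
) -> ClusterResult:
    """Cluster per-age portion profiles with restarted Lloyd iterations."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(profiles):
        raise ValueError("k exceeds the number of profiles")
    X = profiles.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        labels, C, inertia, history = _lloyd(X, k, rng)
        if best is None or inertia < best[2]:
            best = (labels, C, inertia, history)
    labels, C, inertia, history = best
    return ClusterResult(
        k=k,
        labels=pd.Series(labels, index=profiles.index, name="cluster"),
        centroids=pd.DataFrame(C, columns=profiles.columns),
        inertia=inertia,
        seed=seed,
        restarts=restarts,
        inertia_history=history,
    )


def hypergeom_pvalue(
    overlap: int, set_size: int, category_size: int, genome_size: int
) -> dict[str, float]:
    """Hypergeometric tail probabilities for a set/category overlap.

    ``upper`` = P(X >= overlap) (enrichment), ``lower`` = P(X <= overlap)
    (depletion); the reported two-sided value is min(2 x directional tail, 1),
    the direction chosen by whether the observed fraction exceeds the genome
    fraction.
    """
    upper = float(hypergeom.sf(overlap - 1, genome_size, category_size, set_size))
    lower = float(hypergeom.cdf(overlap, genome_size, category_size, set_size))
    enriched = overlap / max(set_size, 1) >= category_size / genome_size
    tail = upper if enriched else lower
    return {"upper": upper, "lower": lower, "two_sided": min(2 * tail, 1.0)}


def go_enrichment(
    contig_set: Iterable[str],
    go_map: Mapping[str, set[str] | frozenset[str]],
    genome_frequencies: Mapping[str, float],
    genome_size: int = 27000,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """Normalized-frequency enrichment of a gene set over GO categories.

    ``genome_frequencies`` maps each category to its genome-wide fraction
    (multi-label, so fractions need not sum to 1). Genes absent from
    ``go_map`` contribute to the set size but to no category. A category
    annotated in the set but missing from the genome table is an error.
    Returns one row per genome category: observed count, set size,
    normalized frequency, bootstrap SD, and p-value.
    """
    genes = [str(g) for g in contig_set]
    if not genes:
        raise ValueError("empty contig set")
    set_cats = set().union(*(go_map.get(g, set()) for g in genes))
    missing = sorted(set_cats - set(genome_frequencies))
    if missing:
        raise ValueError(f"categories absent from genome_frequencies: {missing}")

    n = len(genes)
    cats = sorted(genome_frequencies)
    member = {c: np.array([c in go_map.get(g, set()) for g in genes]) for c in cats}
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n, size=(n_boot, n))

    rows = []
    for c in cats:
        gf = genome_frequencies[c]
        if gf <= 0:
            raise ValueError(f"non-positive genome frequency for category {c!r}")
        obs = int(member[c].sum())
        norm = (obs / n) / gf
        boot = member[c][boot_idx].mean(axis=1) / gf
        K = int(round(gf * genome_size))
        p = hypergeom_pvalue(obs, n, K, genome_size)
        rows.append(
            {
                "category": c,
                "observed": obs,
                "set_size": n,
                "set_fraction": obs / n,
                "genome_fraction": gf,
                "normalized_frequency": norm,
                "bootstrap_sd": float(boot.std(ddof=1)),
                "p_value": p["two_sided"],
                "p_upper": p["upper"],
                "p_lower": p["lower"],
            }
        )
    return pd.DataFrame(rows).set_index("category")


def enrichment_fold(set_fraction: float, reference_fraction: float) -> float:
    """Fold enrichment of a set fraction over its reference (genome) fraction."""
    if reference_fraction <= 0:
        raise ValueError("reference_fraction must be > 0")
    return set_fraction / reference_fraction
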