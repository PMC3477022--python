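"""Discover developmental stage groups from the library covariance structure.

A five-library experiment gives a five-point PCA: libraries are the
observations and (depth-normalized) contig abundances the variables.
Principal components come from the covariance matrix, and ages are merged
into contiguous groups by agglomeration in the PC1-PC2 plane — contiguity is
imposed because developmental stages are intervals of the age axis, and an
unconstrained clustering of five points would be fragile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, parse_age


@dataclass
class PcaResult:
    """Library scores and variance fractions of the covariance-matrix PCA."""

    scores: pd.DataFrame  # libraries x components
    variance_fraction: np.ndarray
    eigenvalues: np.ndarray
    ages: list[int]
    degenerate: bool = False


def pca_libraries(tpt: pd.DataFrame, restrict_to: pd.Index | list | None = None) -> PcaResult:
    """PCA of libraries over contig expression profiles.

    ``tpt`` is contig x library; ``restrict_to`` optionally limits the
    variables to the analysis set (e.g. contigs passing the minimum-read
    filter). Components are ordered by decreasing eigenvalue of the library
    covariance matrix, with the sign convention that each component's
    largest-magnitude library coordinate is positive. A matrix with no
    variance between libraries yields all-zero fractions and a warning.
    """
    if tpt.shape[1] < 2:
        raise ValueError("need at least 2 libraries")
    X = tpt.loc[restrict_to].to_numpy().T if restrict_to is not None else tpt.to_numpy().T
    n = X.shape[0]
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    if total <= 0 or not np.isfinite(total):
        warnings.warn("no variance between libraries; PCA is degenerate")
        k = min(n, X.shape[1])
        scores = pd.DataFrame(
            np.zeros((n, k)), index=tpt.columns, columns=[f"PC{i+1}" for i in range(k)]
        )
        return PcaResult(scores, np.zeros(k), np.zeros(k), [parse_age(c) for c in tpt.columns], True)
    scores = U * s
    # deterministic sign: largest-|coordinate| library positive per component
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=tpt.columns, columns=cols),
        variance_fraction=eig / total,
        eigenvalues=eig,
        ages=[parse_age(c) for c in tpt.columns],
    )


@dataclass(frozen=True)
class AgeGroupScheme:
    """Ordered partition of libraries into contiguous age groups.

    ``groups`` maps group name -> tuple of library labels; group names are
    the joined ages (e.g. ``"0+4"``). The null proportion of a group under
    constant expression is (libraries in group) / (total libraries).
    """

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self):
        ages = [parse_age(l) for g in self.groups for l in g]
        if any(b < a for a, b in zip(ages, ages[1:])):
            raise ValueError("groups must be contiguous, age-ordered, non-overlapping")
        if len(set(l for g in self.groups for l in g)) != len(ages):
            raise ValueError("a library appears in more than one group")

    @property
    def names(self) -> list[str]:
        out = []
        for g in self.groups:
            uniq = sorted({parse_age(l) for l in g})
            out.append("+".join(str(a) for a in uniq))
        return out

    @property
    def n_libraries(self) -> int:
        return sum(len(g) for g in self.groups)

    def null_proportions(self) -> np.ndarray:
        n = self.n_libraries
        return np.array([len(g) / n for g in self.groups])

    def group_ages(self) -> list[tuple[int, ...]]:
        return [tuple(sorted({parse_age(l) for l in g})) for g in self.groups]

    @staticmethod
    def from_ages(age_groups, libraries) -> "AgeGroupScheme":
        """Build a scheme from age tuples, e.g. ``[(0, 4), (8,), (12, 16)]``."""
        by_age: dict[int, list[str]] = {}
        for lab in libraries:
            by_age.setdefault(parse_age(lab), []).append(lab)
        groups = []
        for ag in age_groups:
            libs: list[str] = []
            for a in ag:
                libs.extend(by_age[a])
            groups.append(tuple(libs))
        return AgeGroupScheme(tuple(groups))


def group_ages(pca: PcaResult, n_groups: int = 3) -> AgeGroupScheme:
    """Merge age-adjacent libraries in the PC1-PC2 plane into ``n_groups``.

    Centroid-linkage agglomeration restricted to adjacent clusters: at each
    step the closest pair of neighbouring clusters (Euclidean distance
    between centroids in the first two components) is merged, so groups are
    contiguous along the age axis by construction. Ties merge the earliest
    pair.
    """
    labels = list(pca.scores.index)
    if n_groups < 1 or n_groups > len(labels):
        raise ValueError("n_groups must be in [1, number of libraries]")
    ncomp = min(2, pca.scores.shape[1])
    pts = pca.scores.iloc[:, :ncomp].to_numpy()
    clusters: list[list[int]] = [[i] for i in range(len(labels))]
    while len(clusters) > n_groups:
        cents = [pts[c].mean(axis=0) for c in clusters]
        dists = [np.linalg.norm(cents[i + 1] - cents[i]) for i in range(len(clusters) - 1)]
        i = int(np.argmin(dists))
        clusters[i : i + 2] = [clusters[i] + clusters[i + 1]]
    return AgeGroupScheme(tuple(tuple(labels[i] for i in c) for c in clusters))


def group_read_sums(counts: CountMatrix, scheme: AgeGroupScheme) -> pd.DataFrame:
    """Per-contig read sums within each age group (contig x group)."""
    cols = {}
    for name, libs in zip(scheme.names, scheme.groups):
        cols[name] = counts.df[list(libs)].sum(axis=1)
    return pd.DataFrame(cols)


def venn_partition(
    counts: CountMatrix, scheme: AgeGroupScheme, detect_min: int = 1
) -> dict[str, int]:
    """Counts of contigs detected in each nonempty combination of groups.

    A contig is "detected" in a group when its summed reads there reach
    ``detect_min``. Keys are "&"-joined group names; every contig detected
    anywhere lands in exactly one region, so region sizes sum to the number
    of detected contigs.
    """
    sums = group_read_sums(counts, scheme)
    detected = sums >= detect_min
    names = scheme.names
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(range(len(names)), r):
            mask = np.ones(len(sums), dtype=bool)
            for j in range(len(names)):
                mask &= detected.iloc[:, j].to_numpy() == (j in combo)
            regions["&".join(names[j] for j in combo)] = int(mask.sum())
    return regions
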