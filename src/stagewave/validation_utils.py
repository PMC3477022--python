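"""Validation computations: EST-count vs qPCR concordance and the
spectrophotometric total-chlorophyll closed form."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .abundance_filtering import tpt
from .io_formats import CountMatrix

#: Named coefficient sets for total chlorophyll (ug/ml) from absorbances in
#: N,N-dimethylformamide extracts: total = c647 * A647 + c665 * A665.
CHLOROPHYLL_COEFFICIENTS = {
    "dmf": {"c647": 17.67, "c665": 7.12},
}


def est_relative_expression(
    counts: CountMatrix,
    gene_ids: Iterable[str],
    baseline_age: int = 0,
    pseudo_reads: float = 0.5,
) -> pd.DataFrame:
    """Fold change of TPT at each age relative to the baseline age.

    Genes with zero reads at the baseline receive a pseudo-count of
    ``pseudo_reads`` in every library before normalization (for the fold
    computation only), recorded in the ``pseudo`` column. Ages with several
    libraries use the mean TPT within age. Emits one row per gene per
    non-baseline age.
    """
    ids = [str(g) for g in gene_ids]
    missing = [g for g in ids if g not in counts.df.index]
    if missing:
        raise KeyError(f"genes absent from count matrix: {missing}")
    tpt_all = tpt(counts)
    age_cols = counts.age_columns()
    if baseline_age not in age_cols:
        raise ValueError(f"baseline age {baseline_age} not among library ages {sorted(age_cols)}")

    depths = counts.depths
    rows = []
    for g in ids:
        by_age = {a: float(tpt_all.loc[g, libs].mean()) for a, libs in age_cols.items()}
        pseudo = by_age[baseline_age] == 0
        if pseudo:
            adj = (counts.df.loc[g] + pseudo_reads) * 1000.0 / depths
            by_age = {a: float(adj[libs].mean()) for a, libs in age_cols.items()}
        base = by_age[baseline_age]
        for a in sorted(age_cols):
            if a == baseline_age:
                continue
            fold = by_age[a] / base
            rows.append(
                {
                    "gene_id": g,
                    "age_dpp": a,
                    "fold": fold,
                    "log2_fold": np.log2(fold) if fold > 0 else -np.inf,
                    "pseudo": pseudo,
                }
            )
    return pd.DataFrame(rows)


def concordance(
    est_folds: Sequence[float] | pd.Series,
    qpcr_folds: Sequence[float] | pd.Series,
    scale: str = "log2",
) -> dict:
    """Pearson correlation between EST-derived and qPCR fold changes.

    Computed on log2 folds by default (multiplicative error is symmetric on
    that scale); ``scale="linear"`` uses raw folds. Returns pearson_r,
    r_squared and n; a zero-variance input yields NaNs with
    ``degenerate=True`` rather than an error.
    """
    if isinstance(est_folds, pd.Series) and isinstance(qpcr_folds, pd.Series):
        joined = pd.concat([est_folds, qpcr_folds], axis=1, join="inner").dropna()
        x, y = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    else:
        x = np.asarray(est_folds, dtype=float)
        y = np.asarray(qpcr_folds, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("fold vectors must be 1-D and aligned")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if scale == "log2":
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("folds must be positive on the log scale")
        x, y = np.log2(x), np.log2(y)
    elif scale != "linear":
        raise ValueError("scale must be 'log2' or 'linear'")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("zero variance in a fold vector; correlation undefined")
        return {"pearson_r": np.nan, "r_squared": np.nan, "n": len(x), "degenerate": True}
    r = float(pearsonr(x, y).statistic)
    return {"pearson_r": r, "r_squared": r * r, "n": len(x), "degenerate": False}


def chlorophyll_total(
    a665,
    a647,
    coefficients: str | Mapping[str, float] = "dmf",
    volume_ml: float = 1.0,
    mass_g: float = 1.0,
):
    """Total chlorophyll from absorbances at 665 and 647 nm.

    ``c647 * A647 + c665 * A665`` gives ug/ml of extract; scaling by
    ``volume_ml / mass_g`` converts to ug per g fresh weight. Coefficients
    are a named set (default the N,N-dimethylformamide method) or an
    explicit mapping. Negative inputs would produce a negative total, which
    is clipped to 0 with a warning. Accepts scalars or arrays.
    """
    if isinstance(coefficients, str):
        try:
            coefficients = CHLOROPHYLL_COEFFICIENTS[coefficients]
        except KeyError:
            raise KeyError(
                f"unknown coefficient set {coefficients!r}; "
                f"available: {sorted(CHLOROPHYLL_COEFFICIENTS)}"
            ) from None
    a665 = np.asarray(a665, dtype=float)
    a647 = np.asarray(a647, dtype=float)
    total = (coefficients["c647"] * a647 + coefficients["c665"] * a665) * volume_ml / mass_g
    if np.any(total < 0):
        warnings.warn("negative chlorophyll value clipped to 0")
        total = np.clip(total, 0.0, None)
    return total if total.ndim else float(total)
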