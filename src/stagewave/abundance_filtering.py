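"""Depth normalization (transcripts per thousand), the minimum-read analysis
filter, and the reads-per-contig saturation profile that motivates it."""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

#: Default reads-per-contig bin edges for the saturation profile
#: (bins are [2,5), [5,10), ..., [500, inf)).
DEFAULT_BIN_EDGES = (2, 5, 10, 20, 30, 50, 100, 500)

DEFAULT_MIN_READS = 30


def tpt(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts per thousand: ``count * 1000 / library total``.

    Computed over the full (unfiltered) matrix so each library column sums
    to 1000 exactly; the denominator is the total number of reads generated
    for that library.
    """
    depths = counts.depths
    zero = depths.index[depths == 0].tolist()
    if zero:
        raise ValueError(f"zero-depth libraries: {zero}")
    return counts.df * 1000.0 / depths


def filter_min_reads(
    counts: CountMatrix, min_total: int = DEFAULT_MIN_READS
) -> tuple[CountMatrix, CountMatrix]:
    """Partition into (retained, dropped) by total reads across libraries.

    Retention is inclusive: a contig with exactly ``min_total`` reads is kept.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    keep = counts.totals >= min_total
    return CountMatrix(counts.df.loc[keep]), CountMatrix(counts.df.loc[~keep])


def summary_stats(counts: CountMatrix, lengths: pd.Series | None = None) -> dict:
    """Assembly-level summaries: contig count, mean length, reads per contig."""
    totals = counts.totals
    if len(totals) == 0:
        raise ValueError("empty count matrix")
    out = {
        "n_contigs": int(len(totals)),
        "mean_reads_per_contig": float(totals.mean()),
        "median_reads_per_contig": float(totals.median()),
        "total_reads": int(totals.sum()),
    }
    if lengths is not None:
        out["mean_length"] = float(lengths.loc[counts.contig_ids].mean())
    return out


def saturation_profile(
    counts: CountMatrix,
    lengths: pd.Series,
    annotations: pd.DataFrame | Mapping,
    bin_edges: Iterable[float] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Profile contig length and Arabidopsis-homolog rate against reads/contig.

    Bins partition [first edge, inf): each row reports the number of contigs,
    mean assembled length, and the fraction with an Arabidopsis-tier homolog.
    Empty bins are emitted with count 0 and NaN means (flagged via ``empty``).
    The expected pattern — length and homolog rate rising steadily and
    leveling off near 30 reads/contig — is reported, not enforced.
    """
    edges = list(bin_edges) + [np.inf]
    totals = counts.totals
    ids = totals.index
    missing = [c for c in ids if c not in lengths.index]
    if missing:
        raise ValueError(f"lengths missing for contigs: {missing[:5]}...")
    if isinstance(annotations, pd.DataFrame):
        tier = annotations.set_index(annotations["contig_id"].astype(str))["tier"]
    else:
        tier = pd.Series({c: a.tier for c, a in annotations.items()})
    missing = [c for c in ids if c not in tier.index]
    if missing:
        raise ValueError(f"annotations missing for contigs: {missing[:5]}...")

    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (totals >= lo) & (totals < hi)
        n = int(in_bin.sum())
        sel = ids[in_bin]
        label = f"{int(lo)}-{int(hi) - 1}" if np.isfinite(hi) else f">={int(lo)}"
        rows.append(
            {
                "bin": label,
                "reads_lo": lo,
                "n_contigs": n,
                "mean_length": float(lengths.loc[sel].mean()) if n else np.nan,
                "arabidopsis_fraction": float((tier.loc[sel] == "arabidopsis").mean())
                if n
                else np.nan,
                "empty": n == 0,
            }
        )
    return pd.DataFrame(rows)
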