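"""Homology-tier classification of contigs and unknown-function flagging.

Each contig is placed in exactly one tier by a cascade over its best BLAST
hits: an Arabidopsis homolog wins outright; otherwise a passing hit in the
green-plant nr set outside the cucurbit genera gives ``other_plant``; hits
found only in cucurbit genera give ``cucurbit_only``; nothing passing gives
``no_hit``. A contig is "unknown function" when it has no hit at all or when
its best annotation is uninformative (contains "unknown" or "hypothetical",
or is the no-hit sentinel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import NO_HIT_SENTINEL, BlastHitRecord, best_hits_by_query

TIERS = ("arabidopsis", "other_plant", "cucurbit_only", "no_hit")

#: Genera counted as cucurbits for the cascade (configurable).
DEFAULT_CUCURBIT_TAXA = frozenset({"Cucumis", "Cucurbita", "Citrullus", "Momordica"})

DEFAULT_E_THRESHOLD = 1e-5


@dataclass(frozen=True)
class AnnotationRecord:
    contig_id: str
    tier: str
    best_hit_id: str | None
    best_hit_description: str | None
    e_value: float | None
    unknown_function: bool

    def __post_init__(self):
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == "no_hit" and not self.unknown_function:
            raise ValueError("no_hit implies unknown_function")


def _genus(taxon: str) -> str:
    return taxon.split()[0]


def _is_cucurbit(taxon: str, cucurbit_taxa: frozenset[str] | set[str]) -> bool:
    return taxon in cucurbit_taxa or _genus(taxon) in cucurbit_taxa


def flag_unknown(description: str | None, tier: str) -> bool:
    """True iff the annotation conveys no functional information.

    No-hit contigs are always unknown. Otherwise the description is unknown
    when it is the no-hit sentinel or contains "unknown" or "hypothetical"
    (case-insensitive); "hypothetical" counts because uncharacterized
    cross-species hits carry no more information than unknown proteins.
    """
    if tier == "no_hit":
        return True
    if description is None:
        return False
    d = description.strip()
    if d == NO_HIT_SENTINEL:
        return True
    low = d.lower()
    return "unknown" in low or "hypothetical" in low


def classify_tier(
    arabidopsis_hits: Iterable[BlastHitRecord] | Mapping[str, BlastHitRecord],
    nr_hits: Iterable[BlastHitRecord] | Mapping[str, BlastHitRecord],
    cucurbit_taxa: Iterable[str] = DEFAULT_CUCURBIT_TAXA,
    e_threshold: float = DEFAULT_E_THRESHOLD,
    contig_ids: Iterable[str] | None = None,
) -> dict[str, AnnotationRecord]:
    """Apply the homology cascade to best-hit lists.

    ``arabidopsis_hits`` and ``nr_hits`` are best-hit-per-query lists (or
    pre-indexed mappings). ``contig_ids`` optionally names the full universe
    of contigs so that queries with no hit anywhere still receive a
    ``no_hit`` record. nr hits that pass the E-value threshold must carry a
    ``subject_taxon``; the cascade cannot run without one.
    """
    cuc = frozenset(cucurbit_taxa)
    if not cuc:
        raise ValueError("cucurbit_taxa must be nonempty")
    at = arabidopsis_hits if isinstance(arabidopsis_hits, Mapping) else best_hits_by_query(arabidopsis_hits)
    nr = nr_hits if isinstance(nr_hits, Mapping) else best_hits_by_query(nr_hits)

    universe = set(at) | set(nr)
    if contig_ids is not None:
        universe |= {str(c) for c in contig_ids}

    out: dict[str, AnnotationRecord] = {}
    for cid in sorted(universe):
        a = at.get(cid)
        n = nr.get(cid)
        if a is not None and a.e_value <= e_threshold:
            tier, hit = "arabidopsis", a
        elif n is not None and n.e_value <= e_threshold:
            if n.subject_taxon is None:
                raise ValueError(
                    f"contig {cid!r}: nr hit {n.subject_id!r} lacks a subject taxon, "
                    "required to separate cucurbit-only from other-plant homologs"
                )
            tier = "cucurbit_only" if _is_cucurbit(n.subject_taxon, cuc) else "other_plant"
            hit = n
        else:
            tier, hit = "no_hit", None
        desc = hit.subject_description if hit else None
        out[cid] = AnnotationRecord(
            contig_id=cid,
            tier=tier,
            best_hit_id=hit.subject_id if hit else None,
            best_hit_description=desc,
            e_value=hit.e_value if hit else None,
            unknown_function=flag_unknown(desc, tier),
        )
    return out


def tier_composition(
    contig_set: Iterable[str],
    annotations: Mapping[str, AnnotationRecord] | pd.DataFrame,
) -> dict[str, float]:
    """Tier fractions and the unknown-function fraction of a contig set.

    Returns ``{tier: fraction, ..., "unknown": fraction}``; tier fractions
    sum to 1 over the set. Raises if any contig is unannotated.
    """
    ids = [str(c) for c in contig_set]
    if not ids:
        raise ValueError("empty contig set")
    if isinstance(annotations, pd.DataFrame):
        ann = annotations.set_index(annotations["contig_id"].astype(str))
        missing = [c for c in ids if c not in ann.index]
        if missing:
            raise ValueError(f"unannotated contigs: {missing}")
        tiers = ann.loc[ids, "tier"]
        unknown = ann.loc[ids, "unknown_function"].astype(bool)
    else:
        missing = [c for c in ids if c not in annotations]
        if missing:
            raise ValueError(f"unannotated contigs: {missing}")
        tiers = pd.Series([annotations[c].tier for c in ids], index=ids)
        unknown = pd.Series([annotations[c].unknown_function for c in ids], index=ids)
    n = len(ids)
    comp = {t: float((tiers == t).sum()) / n for t in TIERS}
    comp["unknown"] = float(unknown.sum()) / n
    return comp


def fixture_unknown_flags(table: pd.DataFrame) -> pd.Series:
    """Unknown-function flags for a packaged worked-example table.

    Rows whose Arabidopsis hit field is the no-hit sentinel are treated as
    tier ``no_hit``; otherwise the (primary + secondary) description is
    screened by :func:`flag_unknown`.
    """
    sec = table.get("secondary_description")
    flags = []
    for i, row in table.iterrows():
        hit = str(row.get("arabidopsis_hit", row.get("hit_id", ""))).strip()
        tier = "no_hit" if hit == NO_HIT_SENTINEL else "arabidopsis"
        desc = str(row.get("description", "") or "")
        if sec is not None and str(row["secondary_description"]).strip():
            desc = (desc + " " + str(row["secondary_description"])).strip()
        flags.append(flag_unknown(desc, tier))
    return pd.Series(flags, index=table.index, name="unknown_function")
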