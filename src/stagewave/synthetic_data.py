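"""Synthetic 454-style EST count data with known stage structure.

The generator emulates the statistical shape of a five-library early-fruit
sequencing experiment (libraries at 0, 4, 8, 12 and 16 days post
pollination): contigs are drawn from latent stage programs — cell division
peaking at 0-4 dpp, photosynthesis at 4, cell expansion at 8, surface/phloem
at 8-16, stress at 12-16, and flat housekeeping — with heavy-tailed
(lognormal) base abundances, and reads are allocated multinomially within
each library conditional on its fixed depth, mirroring fixed sequencing
throughput per plate. Contig lengths follow a saturating curve that levels
off near 1400 bp above ~30 reads/contig, and annotation tiers (Arabidopsis
homolog / other plant / cucurbit-only / no hit) are drawn per program, with
a read-depth detection censor so that the observed homolog rate rises with
reads/contig the way assembly quality does.

Ground truth (program, true age proportions, true tier, unknown flag) is
returned for every contig so recovery tests can score the analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import NO_HIT_SENTINEL, CountMatrix

AGES = (0, 4, 8, 12, 16)
LIBRARY_LABELS = tuple(f"{a}dpp" for a in AGES)

TIER_NAMES = ("arabidopsis", "other_plant", "cucurbit_only", "no_hit")


@dataclass(frozen=True)
class StageProgram:
    """A latent expression program: relative expression per age plus the
    homology-tier mix of its contigs."""

    name: str
    age_weights: tuple[float, float, float, float, float]
    tier_probs: tuple[float, float, float, float]
    unknown_prob: float = 0.1

    def __post_init__(self):
        w = np.asarray(self.age_weights, dtype=float)
        if w.min() < 0 or w.sum() <= 0:
            raise ValueError(f"program {self.name!r}: age_weights must be >=0, not all zero")
        p = np.asarray(self.tier_probs, dtype=float)
        if p.min() < 0 or abs(p.sum() - 1) > 1e-9:
            raise ValueError(f"program {self.name!r}: tier_probs must sum to 1")
        if not 0 <= self.unknown_prob <= 1:
            raise ValueError(f"program {self.name!r}: unknown_prob must be in [0,1]")

    def age_proportions(self) -> np.ndarray:
        w = np.asarray(self.age_weights, dtype=float)
        return w / w.sum()

    def group_proportion(self, ages: Sequence[int]) -> float:
        """Analytic proportion of expression falling in the given ages
        (equal library depths)."""
        p = self.age_proportions()
        return float(sum(p[AGES.index(a)] for a in ages))


#: Default stage programs. The cell-division program is deliberately extreme
#: (>96% of its expression at 0-4 dpp) and rare, providing a planted class of
#: strongly stage-specific transcripts; expansion/surface programs carry an
#: elevated cucurbit-only tier probability, matching the observation that
#: cucurbit-specific transcripts concentrate in the growth phase.
DEFAULT_PROGRAMS = (
    StageProgram("division", (1.0, 1.0, 0.05, 0.01, 0.01), (0.85, 0.10, 0.01, 0.04), 0.05),
    StageProgram("photosynthesis", (0.5, 1.0, 0.3, 0.05, 0.05), (0.90, 0.07, 0.01, 0.02), 0.03),
    StageProgram("expansion", (0.02, 0.1, 1.0, 0.3, 0.1), (0.60, 0.15, 0.12, 0.13), 0.25),
    StageProgram("surface_phloem", (0.01, 0.05, 1.0, 0.8, 0.6), (0.55, 0.15, 0.18, 0.12), 0.20),
    StageProgram("stress", (0.02, 0.05, 0.2, 1.0, 1.0), (0.70, 0.15, 0.06, 0.09), 0.12),
    StageProgram("housekeeping", (1.0, 1.0, 1.0, 1.0, 1.0), (0.92, 0.05, 0.01, 0.02), 0.05),
)

DEFAULT_PROGRAM_MIX = (0.015, 0.15, 0.22, 0.15, 0.18, 0.285)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults describe the emulated study design
    (five libraries totalling ~1.13M reads)."""

    n_contigs: int = 5000
    library_depths: tuple[int, ...] = (226_000,) * 5
    program_mix: tuple[float, ...] | None = None  # None -> DEFAULT_PROGRAM_MIX
    abundance_shape: float = 1.5  # lognormal sigma of base abundance
    seed: int = 0
    qpcr_noise_sd: float = 0.25  # log2-scale SD of qPCR noise
    allocation: str = "multinomial"  # or "poisson"
    detect_tau: float = 6.0  # read scale of homolog-detection censoring
    length_plateau: float = 1400.0
    length_min: float = 100.0
    length_tau: float = 8.0
    length_noise_sd: float = 120.0

    def __post_init__(self):
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if any(d <= 0 for d in self.library_depths):
            raise ValueError("library depths must be positive")
        if len(self.library_depths) != len(AGES):
            raise ValueError(f"expected {len(AGES)} library depths")
        if self.program_mix is not None:
            m = np.asarray(self.program_mix, dtype=float)
            if m.min() < 0 or abs(m.sum() - 1) > 1e-9:
                raise ValueError("program_mix must be a probability vector")
        if self.allocation not in ("multinomial", "poisson"):
            raise ValueError("allocation must be 'multinomial' or 'poisson'")


@dataclass
class SyntheticTruth:
    """Per-contig ground truth: program, true tier/unknown flag, and the
    analytic age proportions (which sum to 1 per contig)."""

    table: pd.DataFrame


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def generate_counts(
    config: SimulationConfig,
    programs: Sequence[StageProgram] = DEFAULT_PROGRAMS,
) -> tuple[CountMatrix, pd.Series, pd.DataFrame, SyntheticTruth]:
    """Simulate the full input bundle: counts, lengths, annotations, truth.

    Each library's reads are allocated over contigs with probabilities
    proportional to (base abundance x program age weight); column sums equal
    the configured depths exactly in multinomial mode. The expected
    cross-library profile of every contig is its program's age-weight
    profile scaled by base abundance.
    """
    if not programs:
        raise ValueError("need at least one program")
    mix = np.asarray(
        config.program_mix if config.program_mix is not None else DEFAULT_PROGRAM_MIX[: len(programs)],
        dtype=float,
    )
    if len(mix) != len(programs):
        raise ValueError("program_mix length must match number of programs")
    mix = mix / mix.sum()

    n = config.n_contigs
    rng = _rng(config.seed, 0)
    prog_idx = rng.choice(len(programs), size=n, p=mix)
    base = rng.lognormal(mean=0.0, sigma=config.abundance_shape, size=n)
    weights = np.array([programs[i].age_weights for i in prog_idx], dtype=float)
    expected = base[:, None] * weights  # n x 5

    contig_ids = [f"c{i:05d}" for i in range(n)]
    cols = {}
    for j, (lab, depth) in enumerate(zip(LIBRARY_LABELS, config.library_depths)):
        w = expected[:, j]
        tot = w.sum()
        if tot <= 0:
            raise ValueError(f"library {lab}: zero total expected weight")
        if config.allocation == "multinomial":
            cols[lab] = rng.multinomial(int(depth), w / tot)
        else:
            cols[lab] = rng.poisson(w / tot * depth)
    counts = CountMatrix(pd.DataFrame(cols, index=contig_ids))

    lengths = generate_lengths(counts, seed=config.seed, plateau=config.length_plateau,
                               min_length=config.length_min, tau=config.length_tau,
                               noise_sd=config.length_noise_sd)
    annotations, truth_tier, truth_unknown = _annotate(config, programs, prog_idx, counts)

    props = np.array([programs[i].age_proportions() for i in prog_idx])
    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "contig_id": contig_ids,
                "program": [programs[i].name for i in prog_idx],
                "tier": truth_tier,
                "unknown_function": truth_unknown,
                **{f"p{a}": props[:, k] for k, a in enumerate(AGES)},
            }
        )
    )
    return counts, lengths, annotations, truth


def generate_lengths(
    counts: CountMatrix,
    seed: int = 0,
    plateau: float = 1400.0,
    min_length: float = 100.0,
    tau: float = 8.0,
    noise_sd: float = 120.0,
) -> pd.Series:
    """Contig lengths saturating with reads/contig.

    Expected length is ``min + (plateau - min) * (1 - exp(-reads/tau))`` —
    rising steadily up to roughly 30 reads/contig and levelling off at the
    plateau — plus Gaussian noise, clipped to stay positive. With
    ``noise_sd=0`` lengths equal the curve exactly.
    """
    if len(counts.contig_ids) == 0:
        raise ValueError("empty count matrix")
    r = counts.totals.to_numpy(dtype=float)
    mean = min_length + (plateau - min_length) * (1.0 - np.exp(-r / tau))
    if noise_sd > 0:
        rng = _rng(seed, 1)
        mean = mean + rng.normal(0.0, noise_sd, size=len(mean))
    lengths = np.maximum(mean, 40.0)
    return pd.Series(lengths, index=counts.contig_ids, name="length_bp")


_INFORMATIVE_DESCRIPTIONS = (
    "60S ribosomal protein",
    "histone family protein",
    "cyclin-dependent kinase",
    "chlorophyll a/b binding protein",
    "expansin family protein",
    "tubulin chain",
    "GDSL-motif lipase/hydrolase family protein",
    "lipid transfer protein",
    "heat shock protein",
    "WRKY family transcription factor",
    "aquaporin",
    "pectate lyase family protein",
)

_CUCURBIT_DESCRIPTIONS = (
    "26 kDa phloem protein [Cucumis sativus]",
    "phloem filament protein PP1 [Cucurbita maxima]",
    "17 kDa phloem lectin [Cucumis sativus]",
    "pathogen-induced protein [Cucumis sativus]",
    "expressed protein [Cucumis melo]",
)


def _annotate(config, programs, prog_idx, counts):
    """Draw true tiers from each program's tier mix, then censor detection
    by read depth so low-read contigs lose their homolog call."""
    rng = _rng(config.seed, 2)
    n = len(prog_idx)
    tier_probs = np.array([programs[i].tier_probs for i in prog_idx])
    u = rng.random(n)
    cum = tier_probs.cumsum(axis=1)
    true_tier_idx = (u[:, None] > cum).sum(axis=1)
    true_tier = [TIER_NAMES[i] for i in true_tier_idx]

    unk_prob = np.array([programs[i].unknown_prob for i in prog_idx])
    draw_unknown = rng.random(n) < unk_prob
    true_unknown = []
    for t, du in zip(true_tier, draw_unknown):
        if t == "no_hit":
            true_unknown.append(True)
        elif t in ("arabidopsis", "other_plant"):
            true_unknown.append(bool(du))
        else:  # cucurbit-only hits in the tables carry informative descriptions
            true_unknown.append(False)

    reads = counts.totals.to_numpy(dtype=float)
    p_detect = 1.0 - np.exp(-reads / config.detect_tau)
    detected = rng.random(n) < p_detect

    rows = []
    for i, cid in enumerate(counts.contig_ids):
        tier = true_tier[i] if detected[i] else "no_hit"
        unknown = true_unknown[i] if detected[i] else True
        if tier == "no_hit":
            hit_id, desc, ev = None, NO_HIT_SENTINEL, np.nan
        else:
            if tier == "arabidopsis":
                hit_id = f"AT{rng.integers(1, 6)}G{rng.integers(1000, 80000):05d}"
            else:
                hit_id = f"gi|{rng.integers(10**6, 10**9)}"
            if unknown:
                desc = "unknown protein"
            elif tier == "cucurbit_only":
                desc = _CUCURBIT_DESCRIPTIONS[rng.integers(len(_CUCURBIT_DESCRIPTIONS))]
            else:
                desc = _INFORMATIVE_DESCRIPTIONS[rng.integers(len(_INFORMATIVE_DESCRIPTIONS))]
            ev = 10.0 ** (-rng.uniform(6, 150))
        rows.append(
            {
                "contig_id": cid,
                "tier": tier,
                "best_hit_id": hit_id,
                "best_hit_description": desc,
                "e_value": ev,
                "unknown_function": unknown,
            }
        )
    return pd.DataFrame(rows), true_tier, true_unknown


def generate_qpcr(
    counts: CountMatrix,
    gene_ids: Sequence[str],
    noise_sd: float = 0.25,
    seed: int = 0,
    baseline_age: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Pseudo-qPCR relative quantities: TPT ratio x lognormal noise.

    Per gene and non-baseline age, the reported relative quantity is
    (TPT at age / TPT at baseline) x 2**N(0, noise_sd). Genes with zero
    baseline TPT are skipped and returned in the second element with a
    warning. ``noise_sd=0`` reproduces the TPT ratios exactly.
    """
    from .abundance_filtering import tpt as _tpt

    rng = _rng(seed, 3)
    tpt_all = _tpt(counts)
    age_cols = counts.age_columns()
    rows, skipped = [], []
    for g in (str(x) for x in gene_ids):
        if g not in counts.df.index:
            raise KeyError(f"gene {g!r} absent from count matrix")
        by_age = {a: float(tpt_all.loc[g, libs].mean()) for a, libs in age_cols.items()}
        if by_age[baseline_age] == 0:
            skipped.append(g)
            continue
        base = by_age[baseline_age]
        for a in sorted(age_cols):
            if a == baseline_age:
                continue
            noise = 2.0 ** rng.normal(0.0, noise_sd) if noise_sd > 0 else 1.0
            rows.append(
                {
                    "gene_id": g,
                    "age_dpp": a,
                    "relative_quantity": by_age[a] / base * noise,
                    "replicate": 1,
                }
            )
    if skipped:
        warnings.warn(f"skipped genes with zero baseline expression: {skipped}")
    return pd.DataFrame(rows), skipped


def generate_go_map(
    annotations: pd.DataFrame,
    truth: SyntheticTruth,
    seed: int = 0,
) -> tuple[dict[str, set[str]], dict[str, float]]:
    """Assign SuperViewer-style GO classes to Arabidopsis-tier contigs.

    Categories are drawn with a program-dependent tilt (division contigs
    toward cell organization and DNA/RNA metabolism, stress contigs toward
    the stress categories, and so on) over a fixed genome-frequency table,
    so stage-enriched gene sets show the expected category enrichment.
    Returns (contig -> categories, category -> genome fraction).
    """
    genome_freq = {
        "cell organization and biogenesis": 0.06,
        "DNA or RNA metabolism": 0.03,
        "photosynthesis": 0.02,
        "cell wall and cytoskeleton": 0.04,
        "transport": 0.08,
        "response to stress": 0.07,
        "response to abiotic or biotic stimulus": 0.07,
        "transcription factor activity": 0.0645,
        "other metabolic processes": 0.25,
        "unknown biological processes": 0.30,
    }
    tilts = {
        "division": {"cell organization and biogenesis": 6, "DNA or RNA metabolism": 6},
        "photosynthesis": {"photosynthesis": 10},
        "expansion": {"cell wall and cytoskeleton": 6, "transport": 3},
        "surface_phloem": {"cell wall and cytoskeleton": 3, "transport": 3},
        "stress": {
            "response to stress": 4,
            "response to abiotic or biotic stimulus": 4,
            "transcription factor activity": 3,
        },
        "housekeeping": {"other metabolic processes": 2},
    }
    rng = _rng(seed, 4)
    cats = list(genome_freq)
    base_p = np.array([genome_freq[c] for c in cats])
    program = truth.table.set_index("contig_id")["program"]
    go_map: dict[str, set[str]] = {}
    ann = annotations.set_index("contig_id")
    for cid, rec in ann.iterrows():
        if rec["tier"] != "arabidopsis" or rec["unknown_function"]:
            continue
        p = base_p.copy()
        for cat, mult in tilts.get(program.get(cid, ""), {}).items():
            p[cats.index(cat)] *= mult
        p = p / p.sum()
        k = 2 if rng.random() < 0.25 else 1  # some genes are multi-label
        chosen = rng.choice(len(cats), size=k, replace=False, p=p)
        go_map[cid] = {cats[i] for i in chosen}
    return go_map, genome_freq
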