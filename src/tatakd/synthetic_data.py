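"""Synthetic promoter cohorts with planted TATA-like sites.

Real study cohorts are proprietary database retrievals; this module
generates cohorts with the same statistical structure instead: two
groups (food / non-food) of 90 bp sequences, each carrying one planted
TATA-like element whose recognition strength is drawn from a truncated
normal distribution, with a controllable shift in mean strength between
the groups.  Because food plants show weaker TBP affinity in this
analysis, the default plants weaker sites (lower strength, higher KD)
in the food group.

The background is i.i.d. with a GC-content knob — sufficient for the
best-window statistic the affinity model uses, though it reproduces
neither dinucleotide structure nor phylogenetic correlation of real
promoters.  The planted site's span is restricted to positions 21..70
of the 90-mer, i.e. site centres between -70 and -20 relative to the
transcription start site at the downstream end, where functional TATA
boxes concentrate.  One site is planted per promoter: the affinity
model only uses the best window, so additional sites add nothing
testable.

Generation is driven by ``numpy.random.default_rng`` (PCG64) from an
integer seed recorded in the cohort provenance; identical spec + seed
reproduce the cohort byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .promoter_io import (
    PROMOTER_LENGTH,
    Cohort,
    GeneFamily,
    PlantGroup,
    PromoterRecord,
)
from .tbp_affinity import BASES, TataMatrix, encode

# planted site must lie within forward positions 21..70 (1-based)
SITE_REGION = (21, 70)


class SpecError(ValueError):
    """The cohort spec is internally inconsistent."""


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs for one synthetic cohort.

    Defaults describe the simulation conditions used throughout the
    package's validation studies: 50 promoters per group spread over
    10 species each, one gene family, 40 % GC background, planted-site
    strengths 0.4 (food) vs 0.8 (non-food) with SD 0.1 — the food group
    weaker, hence larger KD, matching the direction of the published
    food vs non-food difference.
    """

    n_food: int = 50
    n_nonfood: int = 50
    species_per_group: int = 10
    families: tuple[GeneFamily, ...] = (GeneFamily.GLOBULIN,)
    gc_background: float = 0.40
    strength_mean_food: float = 0.4
    strength_mean_nonfood: float = 0.8
    strength_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_food < 1 or self.n_nonfood < 1 or self.species_per_group < 1:
            raise SpecError("counts must be positive")
        if not 0 < self.gc_background < 1:
            raise SpecError("gc_background must be in (0, 1)")
        for m in (self.strength_mean_food, self.strength_mean_nonfood):
            if not 0.0 <= m <= 1.0:
                raise SpecError("strength means must be in [0, 1]")
        if self.strength_sd < 0:
            raise SpecError("strength_sd must be nonnegative")
        if not self.families:
            raise SpecError("at least one gene family required")
        object.__setattr__(
            self, "families",
            tuple(GeneFamily(f) for f in self.families),
        )


def _truncated_normal(mean: float, sd: float, size: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated to [0, 1]."""
    if sd == 0:
        return np.full(size, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _background(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def degrade_to_score(
    consensus_window: str,
    target_score: float,
    matrix: TataMatrix,
    rng: np.random.Generator,
) -> str:
    """Degrade a consensus window towards a target normalised score.

    Greedy single-base substitution: at each step the (position, base)
    substitution whose resulting score lies closest to the target is
    applied; the walk stops once the score is at or below the target.
    Scores live on a discrete lattice, so the achieved score is within
    one substitution step of the target rather than exact.  Ties among
    equally good substitutions are broken uniformly at random.
    """
    if not 0.0 <= target_score <= 1.0:
        raise ValueError("target_score must be in [0, 1]")
    lo = matrix.log_odds
    s_max = matrix.max_score
    idx = encode(consensus_window)
    raw = float(lo[np.arange(matrix.width), idx].sum()) / s_max
    score = max(0.0, raw)
    while score > target_score:
        # each substitution changes the raw score by a per-cell delta;
        # evaluate all (position, base) moves in O(width)
        candidates: list[tuple[float, int, int]] = []
        best_gap = np.inf
        for pos in range(matrix.width):
            cur = idx[pos]
            for b in range(4):
                if b == cur:
                    continue
                new_raw = raw + (lo[pos, b] - lo[pos, cur]) / s_max
                s = max(0.0, new_raw)
                if s >= score - 1e-12:  # must strictly reduce
                    continue
                gap = abs(s - target_score)
                if gap < best_gap - 1e-12:
                    best_gap, candidates = gap, [(new_raw, pos, b)]
                elif gap <= best_gap + 1e-12:
                    candidates.append((new_raw, pos, b))
        if not candidates:
            break  # floor of the score lattice reached
        new_raw, pos, b = candidates[rng.integers(len(candidates))]
        idx[pos] = b
        raw = new_raw
        score = max(0.0, raw)
    return "".join(BASES[i] for i in idx)


def _consensus_with_flanks(matrix: TataMatrix, gc: float,
                           rng: np.random.Generator) -> str:
    """Consensus window, with uniform-column positions drawn from background.

    Columns that carry no information (uniform probabilities) have no
    single modal base; filling them from the background composition
    keeps planted sites sequence-diverse without changing their score.
    """
    probs = matrix.probs
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    for j in range(matrix.width):
        col = probs[j]
        if np.allclose(col, col[0]):
            out.append(BASES[rng.choice(4, p=p_bg)])
        else:
            out.append(BASES[int(np.argmax(col))])
    return "".join(out)


def _round_robin(labels: Sequence[str], n: int) -> list[str]:
    return [labels[i % len(labels)] for i in range(n)]


def generate_cohort(spec: CohortSpec, matrix: TataMatrix) -> Cohort:
    """Generate one two-group cohort of 90 bp promoters.

    Each record is an i.i.d. background sequence at ``gc_background``
    with a single planted site whose normalised score is drawn from a
    truncated normal on [0, 1] (group-specific mean), realised by
    greedy degradation of the consensus window, placed uniformly so the
    site span stays within positions 21..70.  Species and family labels
    are assigned round-robin.  Deterministic given spec + seed.
    """
    width = matrix.width
    lo, hi = SITE_REGION
    max_start = hi - width + 1
    if max_start < lo:
        raise SpecError(
            f"matrix width {width} does not fit in site region {lo}..{hi}"
        )
    rng = np.random.default_rng(spec.seed)
    records: list[PromoterRecord] = []
    for group, n, mean in (
        (PlantGroup.FOOD, spec.n_food, spec.strength_mean_food),
        (PlantGroup.NON_FOOD, spec.n_nonfood, spec.strength_mean_nonfood),
    ):
        targets = _truncated_normal(mean, spec.strength_sd, n, rng)
        species = _round_robin(
            [f"{group.value}_species_{k + 1:02d}"
             for k in range(spec.species_per_group)], n,
        )
        families = _round_robin(list(spec.families), n)
        for i in range(n):
            seq = list(_background(PROMOTER_LENGTH, spec.gc_background, rng))
            site = degrade_to_score(
                _consensus_with_flanks(matrix, spec.gc_background, rng),
                float(targets[i]), matrix, rng,
            )
            start = int(rng.integers(lo, max_start + 1))  # 1-based
            seq[start - 1 : start - 1 + width] = site
            records.append(
                PromoterRecord(
                    record_id=f"{group.value}_{i + 1:04d}",
                    species=species[i],
                    gene_family=families[i],
                    group=group,
                    sequence="".join(seq),
                )
            )
    return Cohort(
        records=records,
        provenance=f"synthetic:pcg64:seed={spec.seed}",
    )
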