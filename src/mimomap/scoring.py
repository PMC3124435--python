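"""Score calibration and patch ranking.

Raw alignment scores are not comparable across graphs or query lengths, so
each (patch graph, query length) pair gets its own null model: random
peptides of that length are drawn with NNK amino-acid frequencies, aligned to
the graph, and a Gumbel (Type-I extreme-value) distribution is fitted to the
resulting score sample by the method of moments,

    scale β = s √6 / π,    location μ = mean − γ β   (γ Euler–Mascheroni),

giving P(score ≥ x) = 1 − exp(−exp(−(x − μ)/β)).  A patch's score aggregates
its mimotope alignments as Σ −log10(P); the highest-scoring patch is the
epitope candidate.  Maximum-likelihood fitting is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import (
    Mimotope,
    PathAlignment,
    SubstitutionModel,
    batch_best_scores,
    nnk_frequencies,
)
from .patches import Patch, PatchGraph

__all__ = [
    "EvdModel",
    "PatchScore",
    "fit_evd",
    "fit_gumbel_moments",
    "p_value",
    "score_patch",
    "score_patch_from_scores",
    "rank_patches",
    "sample_random_peptides",
    "DEFAULT_EVD_SAMPLES",
    "DEFAULT_EVD_SEED",
]

EULER_GAMMA = float(np.euler_gamma)
DEFAULT_EVD_SAMPLES = 1000
DEFAULT_EVD_SEED = 42
SCALE_FLOOR = 1e-9


@dataclass
class EvdModel:
    query_length: int
    location: float     # Gumbel μ
    scale: float        # Gumbel β > 0
    n_samples: int
    seed: int
    degenerate: bool = False  # zero-variance score sample; scale floored

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("Gumbel scale must be positive")


@dataclass
class PatchScore:
    """One patch's evidence: per-mimotope (raw score, P-value) and Σ −log10 P.

    ``alignments`` (explicit best paths) are attached only where reported —
    ranking needs scores, not paths.
    """

    patch: Patch
    graph: PatchGraph
    per_mimotope: list[tuple[Mimotope, float, float]]  # (query, raw score, P)
    alignments: list[PathAlignment] | None = None
    aggregate: float = field(init=False)

    def __post_init__(self):
        self.aggregate = float(
            sum(-np.log10(p) for _, _, p in self.per_mimotope)
        )

    @property
    def predicted_residues(self):
        return set(self.patch.members)


def fit_gumbel_moments(scores: np.ndarray) -> tuple[float, float, bool]:
    """(location, scale, degenerate) by the method of moments."""
    scores = np.asarray(scores, float)
    mean = float(scores.mean())
    sd = float(scores.std(ddof=0))
    scale = sd * np.sqrt(6.0) / np.pi
    degenerate = scale < SCALE_FLOOR
    if degenerate:
        scale = SCALE_FLOOR
    location = mean - EULER_GAMMA * scale
    return location, scale, degenerate


def sample_random_peptides(
    length: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, length) amino-acid index array drawn with NNK frequencies."""
    freqs = nnk_frequencies()
    return rng.choice(20, size=(n, length), p=freqs)


def fit_evd(
    graph: PatchGraph,
    query_length: int,
    model: SubstitutionModel,
    n_samples: int = DEFAULT_EVD_SAMPLES,
    seed: int = DEFAULT_EVD_SEED,
    method: str = "moments",
) -> EvdModel:
    """Calibrate a Gumbel null for one graph and one query length.

    Draws ``n_samples`` random NNK peptides, aligns each to the graph (exact
    batch DP), and fits the score distribution.  ``method='ml'`` uses
    maximum likelihood via scipy instead of the default method of moments.
    """
    if n_samples < 200:
        raise ValueError("need at least 200 calibration samples")
    rng = np.random.default_rng(seed)
    peptides = sample_random_peptides(query_length, n_samples, rng)
    scores = batch_best_scores(graph, peptides, model)
    if method == "moments":
        location, scale, degenerate = fit_gumbel_moments(scores)
    elif method == "ml":
        from scipy.stats import gumbel_r

        location, scale = gumbel_r.fit(scores)
        degenerate = scale < SCALE_FLOOR
        if degenerate:
            scale = SCALE_FLOOR
    else:
        raise ValueError("method must be 'moments' or 'ml'")
    return EvdModel(
        query_length=query_length,
        location=float(location),
        scale=float(scale),
        n_samples=n_samples,
        seed=seed,
        degenerate=degenerate,
    )


def p_value(raw_score: float, evd: EvdModel) -> float:
    """Gumbel upper-tail probability of a raw score; in (0, 1), decreasing."""
    z = (raw_score - evd.location) / evd.scale
    p = -np.expm1(-np.exp(-z))
    tiny = np.finfo(float).tiny
    return float(min(max(p, tiny), 1.0 - 1e-16))


def score_patch(
    patch: Patch,
    graph: PatchGraph,
    alignments: list[PathAlignment],
    evds: dict[int, EvdModel],
) -> PatchScore:
    """Aggregate a patch's mimotope alignments into Σ −log10(P)."""
    per = []
    for aln in alignments:
        length = len(aln.query)
        if length not in evds:
            raise KeyError(f"no EVD calibrated for query length {length}")
        per.append((aln.query, aln.raw_score, p_value(aln.raw_score, evds[length])))
    return PatchScore(patch=patch, graph=graph, per_mimotope=per, alignments=alignments)


def score_patch_from_scores(
    patch: Patch,
    graph: PatchGraph,
    mimotopes: list[Mimotope],
    raw_scores: Sequence[float],
    evds: dict[int, EvdModel],
) -> PatchScore:
    """As :func:`score_patch`, from precomputed raw scores (no explicit paths)."""
    if len(mimotopes) != len(raw_scores):
        raise ValueError("one raw score per mimotope required")
    per = []
    for mim, raw in zip(mimotopes, raw_scores):
        if len(mim) not in evds:
            raise KeyError(f"no EVD calibrated for query length {len(mim)}")
        per.append((mim, float(raw), p_value(float(raw), evds[len(mim)])))
    return PatchScore(patch=patch, graph=graph, per_mimotope=per)


def rank_patches(scores: list[PatchScore], top_n: int | None = None) -> list[PatchScore]:
    """Descending by aggregate; ties by smaller patch, then center residue."""
    if not scores:
        raise ValueError("no patch scores to rank")
    ranked = sorted(
        scores,
        key=lambda s: (-s.aggregate, s.patch.size, s.patch.center[1], s.patch.center[2]),
    )
    return ranked if top_n is None else ranked[:top_n]
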