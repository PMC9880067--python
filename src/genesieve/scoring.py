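"""Per-gene two-class filter scores.

Implements every filter criterion of the extraction path: the
Bhattacharyya distance between the two class-conditional Gaussians of a
gene, a Gini impurity over min–max discretized expression levels, and the
classical mean-difference filters (feature score criterion, Fisher ratio,
signal-to-noise ratio, Welch t-statistic).

The mean-difference filters are published in a form whose denominator is a
*difference* of standard deviations (or variances) — singular whenever the
two classes have equal spread and sign-unstable nearby.  Both that literal
``as_printed`` form and the classical ``standard_sum`` form (sum in the
denominator) are provided; the pipeline defaults to ``standard_sum``.

Degenerate genes (zero class variance, zero range) get a NaN score and a
degenerate flag instead of raising: real matrices contain constant probes
and a whole run should not die on one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import ClassLabels, ExpressionMatrix

logger = logging.getLogger(__name__)

#: number of discretization levels is LEVELS + 1 (integer levels 0..LEVELS)
LEVELS = 20

HIGHER = "higher_is_informative"
LOWER = "lower_is_informative"


@dataclass(frozen=True)
class ClassStats:
    """Per-gene means, standard deviations, variances and counts by class.

    Standard deviations use the sample (n−1) denominator.  ``pos`` refers to
    the labels' positive class, ``neg`` to the other.
    """

    gene_ids: tuple[str, ...]
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    sd_pos: np.ndarray
    sd_neg: np.ndarray
    n_pos: int
    n_neg: int

    @property
    def var_pos(self) -> np.ndarray:
        return self.sd_pos ** 2

    @property
    def var_neg(self) -> np.ndarray:
        return self.sd_neg ** 2


@dataclass(frozen=True)
class GeneScoreTable:
    """Scores for one criterion over a set of genes.

    ``scores`` holds NaN for degenerate genes (also flagged in
    ``degenerate``).  ``direction`` states which end of the scale is
    informative; when ``rank_by_magnitude`` is set, ranking uses |score|
    (the signed filters separate classes in either direction).
    """

    gene_ids: tuple[str, ...]
    criterion: str
    scores: np.ndarray
    direction: str
    rank_by_magnitude: bool = False

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("one score per gene required")
        if self.direction not in (HIGHER, LOWER):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def degenerate(self) -> np.ndarray:
        return ~np.isfinite(self.scores)

    def ranking_values(self) -> np.ndarray:
        return np.abs(self.scores) if self.rank_by_magnitude else self.scores

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tcriterion\tscore\tdegenerate\n")
            for gid, s, d in zip(self.gene_ids, self.scores, self.degenerate):
                fh.write(f"{gid}\t{self.criterion}\t{s:.12g}\t{int(d)}\n")


@dataclass(frozen=True)
class DiscretizedGene:
    """A gene's expression mapped to integer levels 0..20 by min–max scaling."""

    levels: np.ndarray  # int, one per sample; empty if degenerate
    degenerate: bool = False


# ---------------------------------------------------------------------------
# class statistics
# ---------------------------------------------------------------------------

def class_stats(matrix: ExpressionMatrix, labels: ClassLabels) -> ClassStats:
    """Per-gene per-class mean and sample standard deviation (ddof=1)."""
    pos, neg = labels.mask_for(matrix)
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("each class needs at least 2 samples for a variance")
    xp = matrix.values[:, pos]
    xn = matrix.values[:, neg]
    return ClassStats(
        gene_ids=matrix.gene_ids,
        mean_pos=xp.mean(axis=1),
        mean_neg=xn.mean(axis=1),
        sd_pos=xp.std(axis=1, ddof=1),
        sd_neg=xn.std(axis=1, ddof=1),
        n_pos=int(pos.sum()),
        n_neg=int(neg.sum()),
    )


def _warn_degenerate(criterion: str, gene_ids, mask: np.ndarray) -> None:
    k = int(mask.sum())
    if k:
        sample = [gene_ids[i] for i in np.flatnonzero(mask)[:5]]
        logger.warning("%s: %d degenerate gene(s) excluded from ranking (e.g. %s)",
                       criterion, k, ", ".join(sample))


# ---------------------------------------------------------------------------
# Bhattacharyya distance
# ---------------------------------------------------------------------------

def bhattacharyya_score(stats: ClassStats) -> GeneScoreTable:
    """Bhattacharyya distance between the two class-conditional Gaussians.

    Bd = (1/8)·(η₁−η₂)²/(ω₁²+ω₂²) + (1/2)·ln((ω₁²+ω₂²)/(2ω₁ω₂))

    with η the class means and ω the class standard deviations.  Zero at
    identical class distributions; grows with mean separation and with
    variance disparity.  Larger is more informative.  Genes with a zero
    class variance are flagged degenerate.
    """
    v1, v2 = stats.var_pos, stats.var_neg
    bad = (v1 <= 0) | (v2 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dmu2 = (stats.mean_pos - stats.mean_neg) ** 2
        bd = dmu2 / (8.0 * (v1 + v2)) + 0.5 * np.log(
            (v1 + v2) / (2.0 * stats.sd_pos * stats.sd_neg)
        )
    bd = np.where(bad, np.nan, bd)
    _warn_degenerate("bhattacharyya", stats.gene_ids, bad)
    return GeneScoreTable(stats.gene_ids, "bhattacharyya", bd, HIGHER)


# ---------------------------------------------------------------------------
# discretization + Gini impurity
# ---------------------------------------------------------------------------

def discretize_gene(values: np.ndarray) -> DiscretizedGene:
    """Map a gene's values onto integer levels 0..20.

    S = Int(20·(x − min)/(max − min) + 0.5) where Int truncates toward zero
    — round-half-up on the nonnegative argument, so the minimum maps to
    level 0 and the maximum to level 20 exactly.  Constant genes have no
    range and come back flagged degenerate.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return DiscretizedGene(np.empty(0, dtype=int), degenerate=True)
    levels = np.trunc(LEVELS * (values - lo) / (hi - lo) + 0.5).astype(int)
    return DiscretizedGene(levels)


def gini_level(level_counts: np.ndarray) -> float:
    """Gini impurity 1 − Σ p² of a within-class level histogram."""
    level_counts = np.asarray(level_counts, dtype=float)
    total = level_counts.sum()
    if total < 1:
        raise ValueError("empty class: no samples to compute impurity over")
    p = level_counts / total
    return float(1.0 - np.sum(p ** 2))


def gini_score(matrix: ExpressionMatrix, labels: ClassLabels) -> GeneScoreTable:
    """Class-size-weighted Gini impurity of each gene's discretized levels.

    Gini(g) = Σ_k (n_k/n)·Gini_k over the two classes, where Gini_k is the
    impurity of the level histogram within class k.  A gene whose levels are
    pure within each class scores 0; smaller is more informative.
    """
    pos, neg = labels.mask_for(matrix)
    n = matrix.n_samples
    w = np.array([pos.sum() / n, neg.sum() / n])
    scores = np.full(matrix.n_genes, np.nan)
    for i in range(matrix.n_genes):
        disc = discretize_gene(matrix.values[i])
        if disc.degenerate:
            continue
        g = 0.0
        for weight, mask in zip(w, (pos, neg)):
            counts = np.bincount(disc.levels[mask], minlength=LEVELS + 1)
            g += weight * gini_level(counts)
        scores[i] = g
    _warn_degenerate("gini", matrix.gene_ids, ~np.isfinite(scores))
    return GeneScoreTable(matrix.gene_ids, "gini", scores, LOWER)


# ---------------------------------------------------------------------------
# mean-difference filters
# ---------------------------------------------------------------------------

def _check_variant(variant: str) -> None:
    if variant not in ("as_printed", "standard_sum"):
        raise ValueError(f"unknown variant {variant!r}")


def _mean_over_sd(stats: ClassStats, variant: str, criterion: str) -> GeneScoreTable:
    # shared form of the FSC and signal-to-noise filters:
    # (η+ − η−) over a difference (as_printed) or sum (standard_sum) of sds
    _check_variant(variant)
    num = stats.mean_pos - stats.mean_neg
    if variant == "as_printed":
        den = stats.sd_pos - stats.sd_neg
    else:
        den = stats.sd_pos + stats.sd_neg
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(den == 0, np.nan, num / den)
    _warn_degenerate(criterion, stats.gene_ids, ~np.isfinite(score))
    return GeneScoreTable(stats.gene_ids, criterion, score, HIGHER,
                          rank_by_magnitude=True)


def snr_score(stats: ClassStats, variant: str = "standard_sum") -> GeneScoreTable:
    """Signal-to-noise ratio (η+ − η−)/(ω+ ± ω−); ranked by magnitude."""
    return _mean_over_sd(stats, variant, "snr")


def fsc_score(stats: ClassStats, variant: str = "standard_sum") -> GeneScoreTable:
    """Feature score criterion — same functional form as the SNR filter."""
    return _mean_over_sd(stats, variant, "fsc")


def fisher_score(stats: ClassStats, variant: str = "standard_sum") -> GeneScoreTable:
    """Fisher discriminant ratio (η+ − η−)² over a combination of variances.

    ``standard_sum`` divides by ω+² + ω−² (the classical ratio);
    ``as_printed`` divides by ω+² − ω−², degenerate at equal variances.
    """
    _check_variant(variant)
    num = (stats.mean_pos - stats.mean_neg) ** 2
    if variant == "as_printed":
        den = stats.var_pos - stats.var_neg
    else:
        den = stats.var_pos + stats.var_neg
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(den == 0, np.nan, num / den)
    _warn_degenerate("fisher", stats.gene_ids, ~np.isfinite(score))
    return GeneScoreTable(stats.gene_ids, "fisher", score, HIGHER,
                          rank_by_magnitude=True)


def t_statistic_score(matrix: ExpressionMatrix, labels: ClassLabels) -> GeneScoreTable:
    """Welch t-statistic (x̄ − ȳ)/√(s₁²/n₁ + s₂²/n₂); ranked by |t|.

    Genes with both variances zero score 0 when the means agree and are
    flagged degenerate when they do not (infinite evidence from a constant
    gene is an artifact, not information).
    """
    stats = class_stats(matrix, labels)
    se2 = stats.var_pos / stats.n_pos + stats.var_neg / stats.n_neg
    num = stats.mean_pos - stats.mean_neg
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 == 0, np.where(num == 0, 0.0, np.nan), num / np.sqrt(se2))
    _warn_degenerate("t_statistic", stats.gene_ids, ~np.isfinite(t))
    return GeneScoreTable(stats.gene_ids, "t_statistic", t, HIGHER,
                          rank_by_magnitude=True)
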