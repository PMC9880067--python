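"""Ranking, top-k selection and the common-gene intersection.

The hybrid filter ranks all genes under the Bhattacharyya criterion and
under the Gini criterion, keeps the top-k most informative genes under
each, and intersects the two keep-lists; only the common genes go forward
to PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .scoring import GeneScoreTable, HIGHER

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedList:
    """Genes ordered from most to least informative under one criterion.

    Degenerate genes are absent.  Ties are broken lexicographically by
    gene id, so the order is a deterministic total order.
    """

    criterion: str
    gene_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class SelectionResult:
    """Top-k sets under both criteria and their intersection."""

    selected_bhattacharyya: frozenset[str]
    selected_gini: frozenset[str]

    @property
    def common(self) -> frozenset[str]:
        return self.selected_bhattacharyya & self.selected_gini


def rank_genes(scores: GeneScoreTable, literal_bottom: bool = False) -> RankedList:
    """Deterministic total order, most informative gene first.

    ``literal_bottom`` reverses the order — it reproduces a literal
    "sort ascending, keep the bottom" reading, which keeps the *least*
    informative genes; the default keeps the most informative.
    """
    vals = scores.ranking_values()
    keep = np.isfinite(vals)
    if not keep.any():
        raise ValueError(f"{scores.criterion}: every gene is degenerate")
    ids = np.array(scores.gene_ids, dtype=object)[keep]
    v = vals[keep]
    ascending = scores.direction != HIGHER
    if literal_bottom:
        ascending = not ascending
    # lexsort: last key is primary; gene id breaks ties deterministically
    order = np.lexsort((ids, v if ascending else -v))
    return RankedList(scores.criterion, tuple(ids[order]))


def select_top_k(ranked: RankedList, k: int) -> tuple[frozenset[str], int]:
    """First min(k, n) genes of the ranking and the eliminated count."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    n = len(ranked)
    if k > n:
        logger.warning("%s: requested top %d of only %d genes; keeping all",
                       ranked.criterion, k, n)
    chosen = frozenset(ranked.gene_ids[:k])
    eliminated = n - len(chosen)
    logger.info("%s: selected %d genes, eliminated %d", ranked.criterion,
                len(chosen), eliminated)
    return chosen, eliminated


def intersect_selections(a: frozenset[str], b: frozenset[str]) -> frozenset[str]:
    """Common genes of two keep-sets; warns when too small for PCA."""
    common = frozenset(a) & frozenset(b)
    logger.info("intersection: |a|=%d, |b|=%d, common=%d", len(a), len(b), len(common))
    if len(common) < 2:
        logger.warning("common-gene set has %d gene(s); PCA needs at least 2 "
                       "(consider a larger top-k)", len(common))
    return common


def write_selection_report(path, gene_ids, result: SelectionResult) -> None:
    common = result.common
    with open(path, "w") as fh:
        fh.write("gene_id\tin_bhattacharyya\tin_gini\tin_common\n")
        for gid in gene_ids:
            fh.write(f"{gid}\t{int(gid in result.selected_bhattacharyya)}"
                     f"\t{int(gid in result.selected_gini)}\t{int(gid in common)}\n")
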