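"""PCA over the common genes and contribution-rate feature-gene choice.

Samples are the observations and the common genes the variables: the
correlation matrix is gene × gene, computed across samples.  Components
are retained by an eigenvalue threshold (default γ > 2) or a cumulative
contribution threshold, and each gene is scored by its normalized share
of absolute loadings over the retained components — the gene contribution
rate

    g_j = Σ_{i≤t} d_ij / Σ_{i≤t} Σ_k d_ik,   d_ij = |e_ji|

which sums to 1 over genes by construction.  The final feature genes are
the largest-g_j genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix


@dataclass(frozen=True)
class StandardizedMatrix:
    """Samples × genes matrix with zero-mean, unit-sd (ddof=1) columns."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_samples, n_genes)


@dataclass(frozen=True)
class EigenSystem:
    """Descending eigenvalues and matched orthonormal eigenvectors.

    ``eigenvectors[:, i]`` is the loading vector of component i over the
    genes; each vector's largest-magnitude entry is nonnegative so the
    decomposition is deterministic across backends.
    """

    gene_ids: tuple[str, ...]
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def m(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class ContributionTable:
    """Per-component contribution rates λ_i = γ_i/Σγ and their running sum."""

    rates: np.ndarray
    cumulative: np.ndarray


@dataclass(frozen=True)
class GeneContribution:
    """Per-gene contribution rates over the retained components (sum = 1)."""

    gene_ids: tuple[str, ...]
    contributions: np.ndarray
    t: int


def standardize(matrix: ExpressionMatrix) -> StandardizedMatrix:
    """Transpose to samples × genes and scale each gene to mean 0, sd 1.

    Uses the sample (n−1) standard deviation.  A constant gene has no
    scale and is an error — it should have been filtered out upstream.
    """
    if matrix.n_samples < 3:
        raise ValueError("standardization for PCA needs at least 3 samples")
    x = matrix.values.T.astype(float)  # samples × genes
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"constant gene cannot be standardized: "
                         f"{matrix.gene_ids[flat[0]]!r}")
    return StandardizedMatrix(matrix.gene_ids, matrix.sample_ids, (x - mu) / sd)


def correlation_matrix(std: StandardizedMatrix) -> np.ndarray:
    """Gene × gene Pearson correlation matrix of the standardized data."""
    n = std.values.shape[0]
    corr = std.values.T @ std.values / (n - 1)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def eigendecompose(corr: np.ndarray, gene_ids) -> EigenSystem:
    """Symmetric eigendecomposition, descending, with a fixed sign gauge.

    Eigenvalues within −1e-10 of zero are floored at 0; each eigenvector is
    flipped so its largest-magnitude entry is nonnegative.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError(f"correlation matrix must be square, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals = np.where((vals < 0) & (vals > -1e-10), 0.0, vals)
    for i in range(vecs.shape[1]):
        j = np.argmax(np.abs(vecs[:, i]))
        if vecs[j, i] < 0:
            vecs[:, i] = -vecs[:, i]
    return EigenSystem(tuple(gene_ids), vals, vecs)


def contribution_rates(eig: EigenSystem) -> ContributionTable:
    """λ_i = γ_i/Σγ_k and the nondecreasing cumulative contribution."""
    total = eig.eigenvalues.sum()
    rates = eig.eigenvalues / total
    return ContributionTable(rates, np.cumsum(rates))


def retain_components(table: ContributionTable, eig: EigenSystem,
                      rule: str = "eigenvalue_threshold",
                      threshold: float = 2.0) -> int:
    """Number of components to keep, forced to at least 1.

    ``eigenvalue_threshold`` keeps components with γ_i > threshold
    (default 2.0; threshold 1.0 is the Kaiser rule);
    ``cumulative_threshold`` keeps the smallest t whose cumulative
    contribution reaches the threshold.
    """
    if rule == "eigenvalue_threshold":
        t = int(np.sum(eig.eigenvalues > threshold))
    elif rule == "cumulative_threshold":
        t = int(np.searchsorted(table.cumulative, threshold) + 1)
        t = min(t, eig.m)
    else:
        raise ValueError(f"unknown retention rule {rule!r}")
    return max(t, 1)


def gene_contribution(eig: EigenSystem, t: int,
                      loading: str = "weighted_squared") -> GeneContribution:
    """Gene contribution rates g_j = Σ_{i≤t} d_ij / Σ_{i≤t} Σ_k d_ik.

    ``loading`` picks the per-component gene weight d_ij:

    - ``weighted_squared`` (default): d_ij = γ_i·e_ji², the standard
      variable-contribution measure of PCA practice (each component's
      squared loadings weighted by its eigenvalue).  A component then
      contributes in proportion to the variance it explains, so
      low-eigenvalue noise components cannot drown out the leading ones.
    - ``absolute``: d_ij = |e_ji|, an unweighted share of absolute
      loadings.  Every retained component counts equally, which makes the
      score sensitive to how many marginal components clear the retention
      threshold.
    - ``squared``: d_ij = e_ji², unweighted.

    All variants are self-normalizing: Σ_j g_j = 1.
    """
    if not 1 <= t <= eig.m:
        raise ValueError(f"t={t} outside 1..{eig.m}")
    if loading == "weighted_squared":
        d = eig.eigenvalues[:t] * eig.eigenvectors[:, :t] ** 2
    elif loading == "absolute":
        d = np.abs(eig.eigenvectors[:, :t])
    elif loading == "squared":
        d = eig.eigenvectors[:, :t] ** 2
    else:
        raise ValueError(f"unknown loading variant {loading!r}")
    g = d.sum(axis=1) / d.sum()
    return GeneContribution(eig.gene_ids, g, t)


def select_feature_genes(g: GeneContribution, n_features: int) -> list[tuple[str, float]]:
    """The n_features genes with the largest contribution rate.

    Ties broken lexicographically by gene id; returns (gene_id, g_j) pairs
    in descending contribution order.
    """
    if not 1 <= n_features <= len(g.gene_ids):
        raise ValueError(f"n_features={n_features} outside 1..{len(g.gene_ids)}")
    ids = np.array(g.gene_ids, dtype=object)
    order = np.lexsort((ids, -g.contributions))
    return [(str(ids[i]), float(g.contributions[i])) for i in order[:n_features]]


def write_pca_report(path_components, path_genes, eig: EigenSystem,
                     table: ContributionTable, g: GeneContribution) -> None:
    with open(path_components, "w") as fh:
        fh.write("component\teigenvalue\tcontribution_rate\tcumulative\tretained\n")
        for i, (ev, r, c) in enumerate(zip(eig.eigenvalues, table.rates,
                                           table.cumulative), start=1):
            fh.write(f"PC{i}\t{ev:.12g}\t{r:.12g}\t{c:.12g}\t{int(i <= g.t)}\n")
    with open(path_genes, "w") as fh:
        fh.write("gene_id\tcontribution_rate\n")
        for gid, gj in zip(g.gene_ids, g.contributions):
            fh.write(f"{gid}\t{gj:.12g}\n")
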