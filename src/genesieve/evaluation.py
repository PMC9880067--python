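"""SVM verification of the selected feature genes.

A radial-basis-kernel support vector machine is trained on the training
split restricted to the candidate gene subset and scored on the held-out
test split.  The classifier is a verification stage, not part of the
selection method itself, so a standard implementation (scikit-learn's SVC)
is used with fixed, recorded hyperparameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from sklearn.svm import SVC

from .data_io import ClassLabels, ExpressionMatrix, SplitSpec
from .pca_extraction import GeneContribution, select_feature_genes


@dataclass(frozen=True)
class ClassificationReport:
    """Test-set accuracy (%), misjudged-sample count and predictions."""

    n_features: int
    accuracy: float
    misjudgments: int
    predictions: dict[str, str] = field(default_factory=dict)

    @property
    def n_test(self) -> int:
        return len(self.predictions)


@dataclass(frozen=True)
class RemovalReport:
    """Share of the input genes eliminated by the extraction path."""

    total_genes: int
    kept_genes: int
    removal_rate: float  # percent, exact rational before formatting


def evaluate_classifier(matrix: ExpressionMatrix, labels: ClassLabels,
                        split: SplitSpec, genes, C: float = 1.0,
                        gamma: str | float = "scale",
                        seed: int = 0) -> ClassificationReport:
    """Train an RBF SVM on the gene subset and score the test samples.

    ``gamma="scale"`` is 1/(n_features · Var(X_train)).  The fit is
    deterministic for a given split and parameter set; ``seed`` feeds the
    underlying solver's tie-breaking state for full reproducibility.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list: nothing to classify with")
    sub = matrix.subset_genes(genes)
    train_ids = [s for s in sub.sample_ids if s in split.train_ids]
    test_ids = [s for s in sub.sample_ids if s in split.test_ids]
    x_train = sub.subset_samples(train_ids).values.T
    x_test = sub.subset_samples(test_ids).values.T
    y_train = [labels.assignments[s] for s in train_ids]
    y_test = [labels.assignments[s] for s in test_ids]
    if len(set(y_train)) < 2:
        raise ValueError("training split contains a single class")
    clf = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
    clf.fit(x_train, y_train)
    pred = clf.predict(x_test)
    wrong = sum(p != y for p, y in zip(pred, y_test))
    accuracy = 100.0 * (len(y_test) - wrong) / len(y_test)
    return ClassificationReport(
        n_features=len(genes),
        accuracy=accuracy,
        misjudgments=wrong,
        predictions=dict(zip(test_ids, pred)),
    )


def sweep_feature_counts(matrix: ExpressionMatrix, labels: ClassLabels,
                         split: SplitSpec, contributions: GeneContribution,
                         counts, C: float = 1.0,
                         gamma: str | float = "scale",
                         seed: int = 0) -> list[ClassificationReport]:
    """One classification report per candidate feature-gene count.

    For each count the top-count genes by contribution rate form the
    subset; the output rows mirror an accuracy-vs-gene-count table.
    """
    reports = []
    for k in counts:
        genes = [gid for gid, _ in select_feature_genes(contributions, k)]
        reports.append(evaluate_classifier(matrix, labels, split, genes,
                                           C=C, gamma=gamma, seed=seed))
    return reports


def removal_rate(total: int, kept: int) -> RemovalReport:
    """Exact redundant-gene removal percentage 100·(total − kept)/total."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= kept <= total:
        raise ValueError(f"kept={kept} outside 0..{total}")
    rate = Fraction(100) * Fraction(total - kept, total)
    return RemovalReport(total, kept, float(rate))


def write_evaluation_report(path, reports: list[ClassificationReport]) -> None:
    with open(path, "w") as fh:
        fh.write("n_genes\taccuracy_pct\tmisjudgments\n")
        for r in reports:
            fh.write(f"{r.n_features}\t{r.accuracy:.2f}\t{r.misjudgments}\n")
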