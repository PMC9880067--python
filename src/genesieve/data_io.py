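"""Expression-matrix data model and tabular I/O.

The pipeline works on a genes × samples matrix of real-valued intensities
with unique string identifiers on both axes, paired with a two-class label
assignment over the samples.  On disk the matrix is a TSV (CSV accepted via
delimiter sniffing) with genes in rows, a header row of sample ids and the
gene ids in the first column; labels are a two-column table
``sample_id<TAB>class``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Structural problem in an on-disk table (duplicates, bad shape)."""


class ParseError(ValueError):
    """A cell that should be numeric is not."""


class ValidationError(ValueError):
    """A loaded object violates a data-model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples real-valued intensity matrix.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    sample_ids
        Unique sample identifiers, one per column.
    values
        Array of shape ``(n_genes, n_samples)``; every entry finite.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if values.ndim != 2 or values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 2 or len(self.sample_ids) < 2:
            raise ValidationError("matrix needs at least 2 genes and 2 samples")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to the given genes, preserving this matrix's row order."""
        wanted = set(genes)
        missing = wanted - set(self.gene_ids)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)}")
        idx = [i for i, g in enumerate(self.gene_ids) if g in wanted]
        return ExpressionMatrix(
            tuple(self.gene_ids[i] for i in idx), self.sample_ids, self.values[idx]
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        """Restrict to the given samples, preserving this matrix's column order."""
        wanted = set(samples)
        missing = wanted - set(self.sample_ids)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)}")
        idx = [j for j, s in enumerate(self.sample_ids) if s in wanted]
        return ExpressionMatrix(
            self.gene_ids, tuple(self.sample_ids[j] for j in idx), self.values[:, idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class ClassLabels:
    """Two-class sample labelling.

    ``assignments`` maps each sample id to one of exactly two class tags.
    The *positive* class ("+" in the two-class score formulas) defaults to
    the tag of the first sample in insertion/file order; pass
    ``positive_class`` to override.
    """

    assignments: dict[str, str]
    positive_class: str | None = None

    def __post_init__(self) -> None:
        tags = list(dict.fromkeys(self.assignments.values()))  # insertion order
        if len(tags) != 2:
            raise ValidationError(f"expected exactly 2 class tags, found {len(tags)}: {tags}")
        pos = self.positive_class if self.positive_class is not None else tags[0]
        if pos not in tags:
            raise ValidationError(f"positive class {pos!r} not among tags {tags}")
        object.__setattr__(self, "positive_class", pos)
        counts = self.class_counts()
        for tag, n in counts.items():
            if n < 2:
                raise ValidationError(
                    f"class {tag!r} has {n} sample(s); need >= 2 for variance"
                )

    @property
    def negative_class(self) -> str:
        return next(t for t in dict.fromkeys(self.assignments.values())
                    if t != self.positive_class)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.assignments)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for tag in self.assignments.values():
            counts[tag] = counts.get(tag, 0) + 1
        return counts

    def mask_for(self, matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (positive, negative) masks over the matrix's sample axis."""
        missing = [s for s in matrix.sample_ids if s not in self.assignments]
        if missing:
            raise ValidationError(f"samples without labels: {missing}")
        tags = np.array([self.assignments[s] for s in matrix.sample_ids])
        return tags == self.positive_class, tags == self.negative_class


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/test partition of the sample ids."""

    train_ids: frozenset[str]
    test_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_ids", frozenset(self.train_ids))
        object.__setattr__(self, "test_ids", frozenset(self.test_ids))
        if self.train_ids & self.test_ids:
            raise ValidationError("train and test sets overlap")
        if not self.train_ids or not self.test_ids:
            raise ValidationError("train and test sets must both be non-empty")


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {kind} id {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_expression(path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read an expression table into genes × samples orientation.

    ``orientation`` states how the file is laid out; the returned matrix is
    always genes in rows.  Errors name the offending identifier or cell.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate row id {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate column id {dup!r} in {path}")
    try:
        values = df.astype(float)
    except ValueError:
        for i, row in enumerate(df.itertuples(index=True)):
            for j, cell in enumerate(row[1:]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric cell {cell!r} at row {row[0]!r} "
                        f"(row {i + 2}), column {df.columns[j]!r} in {path}"
                    ) from None
        raise
    arr = values.to_numpy()
    if not np.all(np.isfinite(arr)):
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise ValidationError(
            f"NaN/Inf at row {values.index[i]!r}, column {values.columns[j]!r} in {path}"
        )
    if orientation == "samples_in_rows":
        values = values.T
    return ExpressionMatrix(tuple(values.index), tuple(values.columns),
                            values.to_numpy())


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write genes-in-rows TSV at 12 significant digits (round-trip stable)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_labels(path, positive_class: str | None = None) -> ClassLabels:
    """Read a two-column (sample_id, class) table; exactly two classes."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    sep = _sniff_sep(path)
    assignments: dict[str, str] = {}
    with open(path, newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sid, tag = (p.strip() for p in parts)
            if lineno == 1 and sid.lower() in ("sample_id", "sample", "id"):
                continue
            if sid in assignments:
                raise FormatError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            assignments[sid] = tag
    return ClassLabels(assignments, positive_class=positive_class)


def write_labels(labels: ClassLabels, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("sample_id\tclass\n")
        for sid, tag in labels.assignments.items():
            fh.write(f"{sid}\t{tag}\n")


def pair(matrix: ExpressionMatrix, labels: ClassLabels) -> None:
    """Validate that labels cover the matrix's samples exactly once each."""
    missing = [s for s in matrix.sample_ids if s not in labels.assignments]
    if missing:
        raise ValidationError(f"samples without labels: {missing}")
    extra = [s for s in labels.assignments if s not in matrix.sample_ids]
    if extra:
        raise ValidationError(f"labelled samples absent from matrix: {extra}")


# ---------------------------------------------------------------------------
# train/test splitting
# ---------------------------------------------------------------------------

def split_train_test(labels: ClassLabels, train_counts: dict[str, int],
                     seed: int) -> SplitSpec:
    """Seeded per-class train/test split with exact training counts.

    ``train_counts`` maps each class tag to the number of its samples to put
    in the training set; the remainder forms the test set.  Both sides must
    end up containing both classes.
    """
    counts = labels.class_counts()
    if set(train_counts) != set(counts):
        raise ValueError(
            f"train_counts classes {sorted(train_counts)} do not match "
            f"label classes {sorted(counts)}"
        )
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for tag in counts:
        members = [s for s, t in labels.assignments.items() if t == tag]
        k = train_counts[tag]
        if not 0 < k <= len(members):
            raise ValueError(
                f"train count {k} for class {tag!r} out of range 1..{len(members)}"
            )
        if k == len(members):
            raise ValueError(
                f"class {tag!r}: all {k} samples requested for training, "
                "leaving none for test"
            )
        chosen = rng.permutation(len(members))[:k]
        mask = np.zeros(len(members), dtype=bool)
        mask[chosen] = True
        train.extend(m for m, pick in zip(members, mask) if pick)
        test.extend(m for m, pick in zip(members, mask) if not pick)
    return SplitSpec(frozenset(train), frozenset(test))


def write_split(split: SplitSpec, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("sample_id\tpartition\n")
        for sid in sorted(split.train_ids):
            fh.write(f"{sid}\ttrain\n")
        for sid in sorted(split.test_ids):
            fh.write(f"{sid}\ttest\n")
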