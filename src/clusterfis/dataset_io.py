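"""Reading, cleaning and remapping ordinal classification tables.

The canonical input dialect is the Wisconsin Breast Cancer "original" CSV
layout: a record id, nine cytology features scored 1-10 (with ``?`` marking a
missing score), and a class code (2 = benign, 4 = malignant).  Preprocessing
replaces every missing cell with 0 ("score absent") and remaps the class codes
to 1 (benign) / 2 (malignant) so that the midpoint of the output domain is an
unambiguous decision boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Column names of the WBCD "original" dialect, in file order (id and class
#: columns excluded).
WBCD_FEATURE_NAMES = [
    "Clump Thickness",
    "Uniformity of Cell Size",
    "Uniformity of Cell Shape",
    "Marginal Adhesion",
    "Single Epithelial Cell Size",
    "Bare Nuclei",
    "Bland Chromatin",
    "Normal Nucleoli",
    "Mitoses",
]

MISSING = "?"


class ParseError(ValueError):
    """Raised when an input file does not match the expected dialect."""


class ValidationError(ValueError):
    """Raised when table contents violate a contract (e.g. unknown class code)."""


@dataclass
class RecordTable:
    """Crisp inputs and outputs: integer feature matrix plus class labels.

    Attributes
    ----------
    feature_names : list of str
        One short name per feature column.
    features : (n, F) int ndarray
        Feature values; within ``[0, 10]`` once imputed (WBCD dialect).
    labels : (n,) int ndarray
        Class codes.  Raw WBCD codes are {2, 4}; after :func:`remap_labels`
        they are {1, 2} (1 = benign, 2 = malignant).
    ids : (n,) ndarray or None
        Record identifiers, carried through but never used in modelling.
    missing_mask : (n, F) bool ndarray or None
        True where the source cell was the missing marker; cleared by
        :func:`impute_missing`.
    remapped : bool
        Whether labels have been remapped to {1, 2}.
    domain : (lo, hi)
        Closed feature domain shared by every column (WBCD: ``(0, 10)``).
    """

    feature_names: list[str]
    features: np.ndarray
    labels: np.ndarray
    ids: np.ndarray | None = None
    missing_mask: np.ndarray | None = None
    remapped: bool = False
    domain: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        n, f = self.features.shape
        if len(self.feature_names) != f:
            raise ValidationError(
                f"{len(self.feature_names)} feature names for {f} columns"
            )
        if self.labels.shape != (n,):
            raise ValidationError("label count does not match record count")
        if self.ids is not None and len(self.ids) != n:
            raise ValidationError("id count does not match record count")
        if self.missing_mask is not None and self.missing_mask.shape != (n, f):
            raise ValidationError("missing mask shape does not match features")

    @property
    def n_records(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.features[:, self.feature_names.index(name)]


@dataclass(frozen=True)
class ClassCounts:
    n_benign: int
    n_malign: int

    @property
    def total(self) -> int:
        return self.n_benign + self.n_malign


def read_records(path, dialect: str = "wbcd") -> RecordTable:
    """Read a CSV classification table in the WBCD or generic dialect.

    Every row must be ``id, f_1, ..., f_F, class``.  Feature cells are
    integers or the missing marker ``?``; the class cell must be an integer.
    A single header line is tolerated and skipped.  The returned table is
    *raw*: missing cells are flagged (value 0 placeholder) and class codes
    are kept as found — call :func:`impute_missing` and :func:`remap_labels`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    rows = [(i + 1, ln) for i, ln in enumerate(lines) if ln]
    if not rows:
        raise ParseError(f"{path}: empty file, zero-record input rejected")

    # Header detection: a non-numeric, non-"?" cell in the first line.
    first_cells = rows[0][1].split(",")
    if any(not _is_int(c) and c.strip() != MISSING for c in first_cells):
        rows = rows[1:]
        if not rows:
            raise ParseError(f"{path}: header only, zero-record input rejected")

    width = len(rows[0][1].split(","))
    if width < 3:
        raise ParseError(f"{path}: line {rows[0][0]}: need id, features and class")
    n_feat = width - 2

    ids, feats, labels, mask = [], [], [], []
    for lineno, ln in rows:
        cells = [c.strip() for c in ln.split(",")]
        if len(cells) != width:
            raise ParseError(
                f"{path}: line {lineno}: expected {width} columns, got {len(cells)}"
            )
        if not _is_int(cells[0]):
            raise ParseError(f"{path}: line {lineno}: non-integer id {cells[0]!r}")
        if not _is_int(cells[-1]):
            raise ParseError(
                f"{path}: line {lineno}: non-integer class code {cells[-1]!r}"
            )
        row_vals, row_mask = [], []
        for j, c in enumerate(cells[1:-1]):
            if c == MISSING:
                row_vals.append(0)
                row_mask.append(True)
            elif _is_int(c):
                row_vals.append(int(c))
                row_mask.append(False)
            else:
                raise ParseError(
                    f"{path}: line {lineno}: cell {c!r} in feature column "
                    f"{j + 1} is neither an integer nor '{MISSING}'"
                )
        ids.append(int(cells[0]))
        feats.append(row_vals)
        labels.append(int(cells[-1]))
        mask.append(row_mask)

    features = np.array(feats, dtype=int)
    if dialect == "wbcd":
        if n_feat != len(WBCD_FEATURE_NAMES):
            raise ParseError(
                f"{path}: wbcd dialect needs {len(WBCD_FEATURE_NAMES)} feature "
                f"columns, found {n_feat}"
            )
        names = list(WBCD_FEATURE_NAMES)
        domain = (0.0, 10.0)
    elif dialect == "generic":
        names = [f"F{j + 1}" for j in range(n_feat)]
        domain = (float(features.min()), float(features.max()))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    return RecordTable(
        feature_names=names,
        features=features,
        labels=np.array(labels, dtype=int),
        ids=np.array(ids, dtype=int),
        missing_mask=np.array(mask, dtype=bool),
        remapped=False,
        domain=domain,
    )


def write_records(table: RecordTable, path, wbcd_codes: bool = False) -> None:
    """Write a table back to the CSV dialect (no header).

    Missing-flagged cells are written as ``?``.  With ``wbcd_codes`` a
    remapped table's labels {1, 2} are written as the raw codes {2, 4}.
    """
    labels = table.labels
    if wbcd_codes and table.remapped:
        labels = np.where(labels == 1, 2, 4)
    ids = table.ids if table.ids is not None else np.arange(1, table.n_records + 1)
    mask = table.missing_mask
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(table.n_records):
            cells = [str(int(ids[i]))]
            for j in range(table.n_features):
                if mask is not None and mask[i, j]:
                    cells.append(MISSING)
                else:
                    cells.append(str(int(table.features[i, j])))
            cells.append(str(int(labels[i])))
            fh.write(",".join(cells) + "\n")


def impute_missing(table: RecordTable) -> RecordTable:
    """Replace every missing feature cell with 0; all other cells unchanged.

    0 encodes "score absent" — the feature scale itself starts at 1, so the
    imputed value is outside the observed range and cannot be confused with a
    real score.  Deterministic; no statistical imputation is performed.
    """
    features = table.features.copy()
    if table.missing_mask is not None:
        n_missing = int(table.missing_mask.sum())
        features[table.missing_mask] = 0
        if n_missing:
            logger.info("imputed %d missing cells to 0", n_missing)
    return replace(table, features=features, missing_mask=None)


def remap_labels(table: RecordTable) -> RecordTable:
    """Remap class codes 2 -> 1 (benign) and 4 -> 2 (malignant).

    Any other code — including an already-remapped 1 — is an error, so that
    accidental double-processing is caught rather than silently absorbed.
    """
    codes = np.unique(table.labels)
    bad = [int(c) for c in codes if c not in (2, 4)]
    if bad:
        raise ValidationError(
            f"unknown class code(s) {bad}; expected raw codes {{2, 4}}"
        )
    labels = np.where(table.labels == 2, 1, 2)
    return replace(table, labels=labels, remapped=True)


def class_counts(table: RecordTable) -> ClassCounts:
    """Tally benign (label 1) and malignant (label 2) records."""
    if not table.remapped:
        raise ValidationError("labels must be remapped before counting classes")
    return ClassCounts(
        n_benign=int(np.sum(table.labels == 1)),
        n_malign=int(np.sum(table.labels == 2)),
    )


def _is_int(cell: str) -> bool:
    try:
        int(cell.strip())
        return True
    except ValueError:
        return False
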