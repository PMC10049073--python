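"""Fuzzy rule induction by deduplicating per-record cluster-label tuples.

Every training record is labelled with the argmax-membership cluster index of
each selected input variable and of the output variable; identical
(antecedent, consequent) tuples collapse into one candidate rule carrying a
support count.  Antecedents that appear with more than one consequent are
resolved to the majority consequent (ties: larger summed membership strength
of the matching records, then the lower class index), so the final rule base
has unique antecedents.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .dataset_io import RecordTable
from .fuzzification import FuzzyVariable

logger = logging.getLogger(__name__)


@dataclass
class LabelTable:
    """Per-record cluster labels for the selected features and the output.

    ``rows[i]`` is a tuple of input labels; ``outputs[i]`` is the output
    label.  ``strengths``, when present, holds each record's own firing
    strength (min over its per-variable max memberships) and is used only to
    break conflict-resolution ties.
    """

    feature_names: list[str]
    output_name: str
    rows: list[tuple[int, ...]]
    outputs: list[int]
    strengths: list[float] | None = None

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class FuzzyRule:
    """IF <feature_j is MF a_j for all j> THEN <output is MF c>."""

    antecedent: tuple[tuple[str, int], ...]
    consequent: int
    support: int = 1

    def text(self) -> str:
        clauses = " AND ".join(f"{f} is MF{i + 1}" for f, i in self.antecedent)
        return f"IF {clauses} THEN output is MF{self.consequent + 1}"


@dataclass
class RuleBase:
    rules: list[FuzzyRule]
    features: list[str]

    def __len__(self) -> int:
        return len(self.rules)

    def to_dict(self) -> dict:
        return {
            "features": self.features,
            "rules": [
                {
                    "if": {f: i for f, i in r.antecedent},
                    "then": r.consequent,
                    "support": r.support,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RuleBase":
        features = list(d["features"])
        rules = [
            FuzzyRule(
                antecedent=tuple((f, int(r["if"][f])) for f in features),
                consequent=int(r["then"]),
                support=int(r.get("support", 1)),
            )
            for r in d["rules"]
        ]
        return cls(rules=rules, features=features)

    def text(self) -> str:
        return "\n".join(r.text() for r in self.rules)


def assign_cluster_labels(
    table: RecordTable,
    variables: dict[str, FuzzyVariable],
    output_var: FuzzyVariable,
    features: list[str],
    indices: np.ndarray | None = None,
) -> LabelTable:
    """Label each record with its argmax-membership cluster per variable.

    ``indices`` restricts labelling to a subset of records (e.g. a training
    split).  Argmax ties break toward the lower membership-function index.
    For the binary output variable with apexes at the two class codes, the
    output label equals ``class - 1``.
    """
    missing = [f for f in features if f not in variables]
    if missing:
        raise KeyError(f"no fitted FuzzyVariable for feature(s) {missing}")
    if indices is None:
        indices = np.arange(table.n_records)
    rows: list[tuple[int, ...]] = []
    outputs: list[int] = []
    strengths: list[float] = []

    # Degree matrix per variable: (n_sel, k_f)
    deg = {}
    for f in features:
        var = variables[f]
        col = np.clip(table.column(f)[indices], *var.domain).astype(float)
        deg[f] = np.stack([m.degree(col) for m in var.mfs], axis=1)
    out_vals = np.clip(table.labels[indices], *output_var.domain).astype(float)
    out_deg = np.stack([m.degree(out_vals) for m in output_var.mfs], axis=1)

    for i in range(len(indices)):
        labels = tuple(int(np.argmax(deg[f][i])) for f in features)
        rows.append(labels)
        outputs.append(int(np.argmax(out_deg[i])))
        strengths.append(float(min(deg[f][i].max() for f in features)))
    return LabelTable(
        feature_names=list(features),
        output_name=output_var.name,
        rows=rows,
        outputs=outputs,
        strengths=strengths,
    )


def induce_rules(labels: LabelTable) -> RuleBase:
    """Deduplicate label tuples into a conflict-free rule base.

    Distinct (antecedent, consequent) pairs become candidate rules with
    support = number of matching records; an antecedent seen with several
    consequents keeps the one with the largest support (ties: largest summed
    record strength, then lowest consequent index).  The result has unique
    antecedents, and its size is bounded by both the number of distinct
    antecedent tuples and the number of records.
    """
    if len(labels) == 0:
        raise ValueError("cannot induce rules from an empty label table")
    support: dict[tuple, dict[int, int]] = defaultdict(lambda: defaultdict(int))
    strength: dict[tuple, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for i, (ant, cons) in enumerate(zip(labels.rows, labels.outputs)):
        support[ant][cons] += 1
        if labels.strengths is not None:
            strength[ant][cons] += labels.strengths[i]

    rules = []
    for ant in sorted(support):
        by_cons = support[ant]
        if len(by_cons) > 1:
            logger.info(
                "conflicting consequents for antecedent %s: %s",
                ant,
                dict(by_cons),
            )
        best = min(
            by_cons,
            key=lambda c: (-by_cons[c], -strength[ant].get(c, 0.0), c),
        )
        rules.append(
            FuzzyRule(
                antecedent=tuple(zip(labels.feature_names, ant)),
                consequent=best,
                support=by_cons[best],
            )
        )
    return RuleBase(rules=rules, features=list(labels.feature_names))
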