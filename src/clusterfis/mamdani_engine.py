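"""Mamdani inference: fuzzify, fire rules, aggregate, defuzzify, classify.

The operator set is the canonical Mamdani configuration — min for antecedent
conjunction, min (clipping) for implication, max for aggregation — followed
by defuzzification of the aggregated output set.  The default defuzzifier is
the center of gravity

    Z = sum_i mu_c(z_i) z_i / sum_i mu_c(z_i)

evaluated on a uniform grid over the output domain (1001 points by default);
``som`` / ``mom`` / ``lom`` take the smallest / mean / largest grid point
attaining the maximum degree.  For the binary classification problem the
output domain is [1, 2] with one membership function per class, and the
crisp Z is thresholded at the midpoint of the two output apexes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .fuzzification import FuzzyVariable
from .rule_induction import RuleBase

logger = logging.getLogger(__name__)

DEFUZZ_METHODS = ("centroid", "som", "mom", "lom")


class AssemblyError(ValueError):
    """Raised when FIS components are mutually inconsistent."""


@dataclass
class FIS:
    """An assembled Mamdani fuzzy inference system."""

    input_vars: dict[str, FuzzyVariable]
    output_var: FuzzyVariable
    rule_base: RuleBase
    and_op: str = "min"
    implication: str = "min"
    aggregation: str = "max"
    defuzz: str = "centroid"
    grid_points: int = 1001
    majority_class: int = 1

    def __post_init__(self):
        self._grid = None
        self._out_curves = None

    @property
    def features(self) -> list[str]:
        return self.rule_base.features

    @property
    def threshold(self) -> float:
        """Class decision boundary: midpoint of the extreme output apexes."""
        return (self.output_var.mfs[0].apex + self.output_var.mfs[-1].apex) / 2.0

    def grid(self) -> np.ndarray:
        if self._grid is None or len(self._grid) != self.grid_points:
            self._grid = np.linspace(*self.output_var.domain, self.grid_points)
            self._out_curves = None
        return self._grid

    def output_curves(self) -> np.ndarray:
        """Output membership functions sampled on the grid, shape (k, G)."""
        grid = self.grid()
        if self._out_curves is None:
            self._out_curves = np.stack(
                [m.degree(grid) for m in self.output_var.mfs]
            )
        return self._out_curves

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "input_vars": {f: v.to_dict() for f, v in self.input_vars.items()},
            "output_var": self.output_var.to_dict(),
            "rule_base": self.rule_base.to_dict(),
            "settings": {
                "and_op": self.and_op,
                "implication": self.implication,
                "aggregation": self.aggregation,
                "defuzz": self.defuzz,
                "grid_points": self.grid_points,
                "majority_class": self.majority_class,
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "FIS":
        settings = d.get("settings", {})
        return assemble_fis(
            {f: FuzzyVariable.from_dict(v) for f, v in d["input_vars"].items()},
            FuzzyVariable.from_dict(d["output_var"]),
            RuleBase.from_dict(d["rule_base"]),
            settings,
        )

    @classmethod
    def from_json(cls, path) -> "FIS":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class AggregatedFuzzySet:
    """The composed output set mu_c sampled on the output grid."""

    grid: np.ndarray
    degrees: np.ndarray


@dataclass
class CrispOutput:
    z: float
    predicted_class: int
    fired_rules: int
    no_rule_fired: bool = False


def assemble_fis(
    input_vars: dict[str, FuzzyVariable],
    output_var: FuzzyVariable,
    rule_base: RuleBase,
    settings: dict | None = None,
) -> FIS:
    """Validate components against each other and assemble the system."""
    settings = dict(settings or {})
    problems = []
    for r in rule_base.rules:
        for feat, idx in r.antecedent:
            if feat not in input_vars:
                problems.append(f"rule references unknown feature {feat!r}")
            elif not 0 <= idx < input_vars[feat].k:
                problems.append(
                    f"rule clause '{feat} is MF{idx + 1}' exceeds the "
                    f"{input_vars[feat].k} mfs of {feat!r}"
                )
            seen = [f for f, _ in r.antecedent]
            if len(seen) != len(set(seen)):
                problems.append(f"duplicate feature in antecedent {r.antecedent}")
        if not 0 <= r.consequent < output_var.k:
            problems.append(f"consequent MF{r.consequent + 1} out of range")
    if problems:
        raise AssemblyError("; ".join(sorted(set(problems))))
    defuzz = settings.get("defuzz", "centroid")
    if defuzz not in DEFUZZ_METHODS:
        raise AssemblyError(f"unknown defuzzification method {defuzz!r}")
    return FIS(
        input_vars=input_vars,
        output_var=output_var,
        rule_base=rule_base,
        and_op=settings.get("and_op", "min"),
        implication=settings.get("implication", "min"),
        aggregation=settings.get("aggregation", "max"),
        defuzz=defuzz,
        grid_points=int(settings.get("grid_points", 1001)),
        majority_class=int(settings.get("majority_class", 1)),
    )


def rule_activation(fis: FIS, record: dict[str, float]) -> np.ndarray:
    """Firing strength of every rule: min over antecedent clause degrees."""
    missing = [f for f in fis.features if f not in record]
    if missing:
        raise KeyError(f"record missing feature value(s) {missing}")
    degrees = {}
    for f in fis.features:
        var = fis.input_vars[f]
        x = min(max(float(record[f]), var.domain[0]), var.domain[1])
        degrees[f] = np.array([m.degree(x) for m in var.mfs], dtype=float)
    return np.array(
        [
            min(degrees[f][i] for f, i in r.antecedent)
            for r in fis.rule_base.rules
        ],
        dtype=float,
    )


def aggregate(fis: FIS, strengths: np.ndarray) -> AggregatedFuzzySet:
    """Clip each rule's consequent at its strength; point-wise max over rules."""
    grid = fis.grid()
    curves = fis.output_curves()
    if len(strengths) == 0:
        return AggregatedFuzzySet(grid=grid, degrees=np.zeros_like(grid))
    cons = np.array([r.consequent for r in fis.rule_base.rules])
    clipped = np.minimum(curves[cons], np.asarray(strengths)[:, None])
    return AggregatedFuzzySet(grid=grid, degrees=clipped.max(axis=0))


def defuzzify(agg: AggregatedFuzzySet, method: str = "centroid"):
    """Collapse the aggregated set to a crisp Z.

    centroid: grid-sum center of gravity.  som/mom/lom: smallest / mean /
    largest grid point attaining the maximum degree.  An all-zero set yields
    the domain midpoint with ``fired=False`` (flagged, not raised).

    Returns ``(z, fired)``.
    """
    mu = agg.degrees
    total = mu.sum()
    if total <= 0.0:
        z = float((agg.grid[0] + agg.grid[-1]) / 2.0)
        logger.debug("no rule fired; defuzzify falls back to domain midpoint")
        return z, False
    if method == "centroid":
        return float((mu * agg.grid).sum() / total), True
    peak = mu.max()
    at_max = agg.grid[mu >= peak - 1e-12]
    if method == "som":
        return float(at_max[0]), True
    if method == "mom":
        return float(at_max.mean()), True
    if method == "lom":
        return float(at_max[-1]), True
    raise ValueError(f"unknown defuzzification method {method!r}")


def classify(fis: FIS, record: dict[str, float]) -> CrispOutput:
    """Run the full chain on one record and emit a crisp class in {1, 2}.

    Z strictly below the apex midpoint -> class 1; at or above -> class 2
    (the exact-midpoint case is logged).  When no rule fires, the prediction
    falls back to the system's majority class.
    """
    strengths = rule_activation(fis, record)
    agg = aggregate(fis, strengths)
    z, fired = defuzzify(agg, fis.defuzz)
    fired_rules = int(np.sum(strengths > 0))
    if not fired:
        return CrispOutput(
            z=z,
            predicted_class=fis.majority_class,
            fired_rules=0,
            no_rule_fired=True,
        )
    if z == fis.threshold:
        logger.debug("Z exactly at threshold %.6g; assigning class 2", z)
    predicted = 1 if z < fis.threshold else 2
    return CrispOutput(z=z, predicted_class=predicted, fired_rules=fired_rules)


def classify_batch(fis: FIS, features: np.ndarray, feature_names: list[str]):
    """Vectorized :func:`classify` over a feature matrix.

    Returns ``(z, predicted_class)`` arrays.  Identical in semantics to the
    per-record path; used by the evaluation loops.
    """
    cols = {f: feature_names.index(f) for f in fis.features}
    n = features.shape[0]
    deg = {}
    for f in fis.features:
        var = fis.input_vars[f]
        x = np.clip(features[:, cols[f]].astype(float), *var.domain)
        deg[f] = np.stack([m.degree(x) for m in var.mfs], axis=1)  # (n, k_f)

    rules = fis.rule_base.rules
    strengths = np.ones((n, len(rules)))
    for r_idx, r in enumerate(rules):
        for f, i in r.antecedent:
            strengths[:, r_idx] = np.minimum(strengths[:, r_idx], deg[f][:, i])

    grid = fis.grid()
    curves = fis.output_curves()
    cons = np.array([r.consequent for r in rules])
    # (n, R, G) would be large; reduce per consequent first: the max of
    # clipped curves sharing one consequent equals that curve clipped at the
    # max strength among its rules.
    k = fis.output_var.k
    s_by_cons = np.zeros((n, k))
    for c in range(k):
        sel = cons == c
        if sel.any():
            s_by_cons[:, c] = strengths[:, sel].max(axis=1)
    clipped = np.minimum(curves[None, :, :], s_by_cons[:, :, None])
    mu = clipped.max(axis=1)  # (n, G)

    total = mu.sum(axis=1)
    fired = total > 0
    z = np.full(n, (grid[0] + grid[-1]) / 2.0)
    if fis.defuzz == "centroid":
        z[fired] = (mu[fired] * grid).sum(axis=1) / total[fired]
    else:
        for i in np.nonzero(fired)[0]:
            z[i], _ = defuzzify(AggregatedFuzzySet(grid, mu[i]), fis.defuzz)
    predicted = np.where(z < fis.threshold, 1, 2)
    predicted[~fired] = fis.majority_class
    return z, predicted
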