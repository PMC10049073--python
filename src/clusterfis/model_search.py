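"""Candidate enumeration and selection: one FIS per (feature subset, method).

For each candidate, the selected variables are clustered on the full value
column (cluster count = number of distinct observed values, capped), rules
are induced on the training portion of every partition iteration or fold,
and the assembled system is scored on the corresponding validation portion.
Candidates are ranked by pooled validation accuracy (ties: fewer rules, then
enumeration order), and the winner is refit on the full table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset_io import RecordTable
from .evaluation import (
    ConfusionMatrix,
    MetricSet,
    PartitionPlan,
    compute_metrics,
    confusion_matrix,
    kfold_partition,
    random_partition,
)
from .fuzzification import (
    ClusterModel,
    FuzzyVariable,
    build_fuzzy_variable,
    fit_fcm,
    fit_kmeans,
    fit_ward,
)
from .mamdani_engine import FIS, assemble_fis, classify_batch
from .rule_induction import assign_cluster_labels, induce_rules

logger = logging.getLogger(__name__)

METHODS = ("kmeans", "ward", "fcm")


@dataclass
class SearchConfig:
    """Settings for the model search.

    ``subsets`` (explicit feature-name lists) takes precedence over
    ``subset_sizes`` (enumerate all combinations of each size).  Per-variable
    cluster counts default to the distinct-value count, clipped to
    ``cluster_range``; the output always uses ``output_clusters`` clusters.
    """

    methods: tuple[str, ...] = ("kmeans", "ward", "fcm")
    cluster_range: tuple[int, int] = (2, 10)
    output_clusters: int = 2
    subsets: list[list[str]] | None = None
    subset_sizes: tuple[int, ...] | None = None
    plan: PartitionPlan = field(default_factory=PartitionPlan)
    seed: int = 0
    max_candidates: int = 10_000
    fcm_fuzzifier: float = 50.0

    def __post_init__(self):
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown clustering method(s) {sorted(unknown)}")
        lo, hi = self.cluster_range
        if lo < 2 or hi < lo:
            raise ValueError(f"cluster_range must satisfy 2 <= lo <= hi: {lo}, {hi}")
        if self.max_candidates <= 0:
            raise ValueError("candidate budget must be positive")


@dataclass
class CandidateResult:
    features: list[str]
    method: str
    k_per_variable: dict[str, int]
    rule_count: int
    metrics: MetricSet
    confusion: ConfusionMatrix


@dataclass
class SearchReport:
    candidates: list[CandidateResult]
    best: CandidateResult | None
    best_fis: FIS | None
    complete: bool
    seed: int


def optimal_cluster_count(
    table: RecordTable, cap: int = 10
) -> dict[str, int]:
    """Distinct observed values per variable, capped at ``cap``.

    A constant column yields 1 and a warning — it cannot support membership
    functions and should be excluded from subsets.
    """
    counts = {}
    for j, name in enumerate(table.feature_names):
        distinct = len(np.unique(table.features[:, j]))
        if distinct == 1:
            logger.warning("%s: constant column, excluded from clustering", name)
        if distinct > cap:
            logger.info("%s: %d distinct values capped at %d", name, distinct, cap)
        counts[name] = min(distinct, cap)
    return counts


def enumerate_subsets(features: list[str], sizes) -> list[list[str]]:
    """All size-s combinations of the features, deterministic order."""
    sizes = sorted(set(int(s) for s in np.atleast_1d(sizes)))
    if not sizes:
        raise ValueError("at least one subset size is required")
    bad = [s for s in sizes if s < 1 or s > len(features)]
    if bad:
        raise ValueError(f"subset size(s) {bad} outside 1..{len(features)}")
    out = []
    for s in sizes:
        out.extend([list(c) for c in itertools.combinations(features, s)])
    return out


def _fit_variable(
    values, method: str, k: int, seed: int, name: str, domain, fuzzifier: float
) -> FuzzyVariable:
    if method == "kmeans":
        model = fit_kmeans(values, k, seed=seed, name=name)
    elif method == "ward":
        model = fit_ward(values, k, name=name)
    elif method == "fcm":
        model = fit_fcm(values, k, fuzzifier=fuzzifier, seed=seed, name=name)
    else:
        raise ValueError(f"unknown method {method!r}")
    return build_fuzzy_variable(model, domain, name)


def _output_variable(labels: np.ndarray, method: str, k: int, seed: int,
                     fuzzifier: float) -> FuzzyVariable:
    lo, hi = float(labels.min()), float(labels.max())
    return _fit_variable(
        labels.astype(float), method, k, seed, "class", (lo, hi), fuzzifier
    )


def run_search(table: RecordTable, config: SearchConfig) -> SearchReport:
    """Evaluate every (subset, method) candidate and pick the best.

    Fully reproducible given ``config.seed``: partition draws and cluster
    initializations are derived from it.  If the candidate budget runs out
    the partial report is returned with ``complete=False``.
    """
    if config.subsets is not None:
        subsets = [list(s) for s in config.subsets]
    elif config.subset_sizes is not None:
        subsets = enumerate_subsets(table.feature_names, config.subset_sizes)
    else:
        subsets = [list(table.feature_names)]

    k_opt = optimal_cluster_count(table, cap=config.cluster_range[1])
    lo_k = config.cluster_range[0]

    # Cluster each (feature, method) once; subsets share the fits.
    var_cache: dict[tuple[str, str], FuzzyVariable] = {}

    def variable_for(feat: str, method: str) -> FuzzyVariable:
        key = (feat, method)
        if key not in var_cache:
            k = max(k_opt[feat], lo_k)
            var_cache[key] = _fit_variable(
                table.column(feat).astype(float),
                method,
                k,
                seed=config.seed,
                name=feat,
                domain=table.domain,
                fuzzifier=config.fcm_fuzzifier,
            )
        return var_cache[key]

    candidates: list[CandidateResult] = []
    complete = True
    plan = config.plan
    n = table.n_records

    for method in config.methods:
        output_var = _output_variable(
            table.labels, method, config.output_clusters, config.seed,
            config.fcm_fuzzifier,
        )
        for subset in subsets:
            if len(candidates) >= config.max_candidates:
                logger.warning("candidate budget exhausted; partial report")
                complete = False
                break
            skip = [f for f in subset if k_opt[f] < 2]
            if skip:
                logger.warning("skipping subset %s: constant column(s) %s",
                               subset, skip)
                continue
            variables = {f: variable_for(f, method) for f in subset}

            if plan.scheme == "random_sampling":
                splits = [
                    random_partition(n, plan, seed=(plan.seed + 7919 * i) % (2**31))
                    [:2]
                    for i in range(plan.iterations)
                ]
            else:
                splits = kfold_partition(n, plan.k, plan.seed)

            pooled = ConfusionMatrix(0, 0, 0, 0)
            for train_idx, val_idx in splits:
                fis = _fit_candidate(
                    table, variables, output_var, subset, train_idx
                )
                _, pred = classify_batch(
                    fis, table.features[val_idx], table.feature_names
                )
                pooled = pooled + confusion_matrix(table.labels[val_idx], pred)

            full_fis = _fit_candidate(
                table, variables, output_var, subset,
                np.arange(n),
            )
            candidates.append(
                CandidateResult(
                    features=list(subset),
                    method=method,
                    k_per_variable={f: variables[f].k for f in subset},
                    rule_count=len(full_fis.rule_base),
                    metrics=compute_metrics(pooled),
                    confusion=pooled,
                )
            )
        if not complete:
            break

    if not candidates:
        return SearchReport([], None, None, complete, config.seed)

    best_idx = min(
        range(len(candidates)),
        key=lambda i: (-candidates[i].metrics.accuracy, candidates[i].rule_count, i),
    )
    best = candidates[best_idx]
    output_var = _output_variable(
        table.labels, best.method, config.output_clusters, config.seed,
        config.fcm_fuzzifier,
    )
    best_fis = _fit_candidate(
        table,
        {f: variable_for(f, best.method) for f in best.features},
        output_var,
        best.features,
        np.arange(n),
    )
    return SearchReport(
        candidates=candidates,
        best=best,
        best_fis=best_fis,
        complete=complete,
        seed=config.seed,
    )


def _fit_candidate(table, variables, output_var, subset, train_idx) -> FIS:
    labels = assign_cluster_labels(
        table, variables, output_var, subset, indices=train_idx
    )
    rule_base = induce_rules(labels)
    y_train = table.labels[train_idx]
    majority = 1 if np.sum(y_train == 1) >= np.sum(y_train == 2) else 2
    return assemble_fis(
        variables, output_var, rule_base, {"majority_class": majority}
    )
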