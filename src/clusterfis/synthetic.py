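"""Synthetic datasets with a known generating fuzzy system.

Emulates the shape of the breast-cancer case study — integer cytology-style
features on 0..10, a binary benign/malignant label with roughly 2:1 class
imbalance, and per-class cluster structure — so that every pipeline stage
(reading, imputation, fuzzification, rule induction, inference, evaluation,
search) can be exercised end to end with ground truth in hand.  Features are
sampled independently within each class; real cytology features are
correlated, which this generator deliberately does not model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset_io import RecordTable
from .fuzzification import FuzzyVariable, MembershipFunction
from .mamdani_engine import FIS, assemble_fis
from .rule_induction import FuzzyRule, RuleBase

logger = logging.getLogger(__name__)

#: Benign fraction of the case-study dataset (458 of 699 records).
DEFAULT_BALANCE = 458 / 699

VALUES = np.arange(11)  # feature support 0..10


@dataclass
class GroundTruth:
    """A generating FIS plus the per-class sampling distributions.

    ``class_mixture[c, j]`` is the value distribution (length 11, sums to 1)
    of feature j in class c (0 = benign, 1 = malignant).  Benign mass sits on
    low scores, malignant on high scores, mirroring the ordinal 1-10 cytology
    scales.  ``noise_rate`` is the label-flip probability applied at sampling
    time.
    """

    fis: FIS
    class_mixture: np.ndarray  # (2, n_features, 11)
    feature_names: list[str]
    informative: list[str]
    noise_rate: float = 0.0
    seed: int = 0

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def make_ground_truth(
    n_features: int = 9,
    seed: int = 0,
    n_informative: int | None = None,
    noise_rate: float = 0.0,
) -> GroundTruth:
    """Construct separable per-class distributions and their generating FIS.

    Informative features put benign mass on scores 1-4 and malignant mass on
    7-10 (non-overlapping supports, so the generating system classifies its
    own noiseless samples perfectly); the remaining features are uniform on
    1-10 in both classes and carry no signal.  The generating FIS has one
    two-cluster variable per informative feature and two rules: all-low ->
    benign, all-high -> malignant.
    """
    if n_features < 2:
        raise ValueError("need at least 2 features")
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must lie in [0, 0.5)")
    if n_informative is None:
        n_informative = n_features
    if not 2 <= n_informative <= n_features:
        raise ValueError("n_informative must lie in 2..n_features")
    rng = np.random.default_rng(seed)
    names = [f"F{j + 1}" for j in range(n_features)]
    informative = names[:n_informative]

    mixture = np.zeros((2, n_features, 11))
    for j in range(n_features):
        if j < n_informative:
            # Ordinal cytology-style scores are heavily skewed: benign mass
            # decays away from 1, malignant away from 10.
            r_b = rng.uniform(0.2, 0.4)
            r_m = rng.uniform(0.2, 0.4)
            benign_w = r_b ** np.arange(4)
            malign_w = r_m ** np.arange(4)[::-1]
            mixture[0, j, 1:5] = benign_w / benign_w.sum()
            mixture[1, j, 7:11] = malign_w / malign_w.sum()
        else:
            mixture[:, j, 1:11] = 1.0 / 10.0

    input_vars = {}
    for j, name in enumerate(informative):
        lo_mean = float((VALUES * mixture[0, j]).sum())
        hi_mean = float((VALUES * mixture[1, j]).sum())
        input_vars[name] = FuzzyVariable(
            name=name,
            domain=(0.0, 10.0),
            mfs=[
                MembershipFunction("left_shoulder", lo_mean, 0.0, hi_mean),
                MembershipFunction("right_shoulder", hi_mean, lo_mean, 10.0),
            ],
        )
    output_var = FuzzyVariable(
        name="class",
        domain=(1.0, 2.0),
        mfs=[
            MembershipFunction("left_shoulder", 1.0, 1.0, 2.0),
            MembershipFunction("right_shoulder", 2.0, 1.0, 2.0),
        ],
    )
    rules = [
        FuzzyRule(tuple((f, 0) for f in informative), consequent=0),
        FuzzyRule(tuple((f, 1) for f in informative), consequent=1),
    ]
    fis = assemble_fis(
        input_vars, output_var, RuleBase(rules=rules, features=informative)
    )
    return GroundTruth(
        fis=fis,
        class_mixture=mixture,
        feature_names=names,
        informative=informative,
        noise_rate=noise_rate,
        seed=seed,
    )


def sample_records(
    gt: GroundTruth,
    n: int,
    class_balance: float = DEFAULT_BALANCE,
    seed: int = 0,
) -> RecordTable:
    """Draw n records from the ground truth.

    Each record's class is Bernoulli(class_balance) benign; features are
    sampled from the class's per-feature distributions; the recorded label
    is flipped with probability ``gt.noise_rate`` (features keep their
    original class's distribution, making flipped records genuinely
    mislabelled).  Labels are already in {1, 2}.
    """
    if n < 2:
        raise ValueError("need at least 2 records")
    if not 0.0 < class_balance < 1.0:
        raise ValueError("class_balance must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    true_class = (rng.random(n) >= class_balance).astype(int)  # 0 benign, 1 malign
    features = np.empty((n, gt.n_features), dtype=int)
    for j in range(gt.n_features):
        for c in (0, 1):
            rows = true_class == c
            features[rows, j] = rng.choice(
                VALUES, size=int(rows.sum()), p=gt.class_mixture[c, j]
            )
    labels = true_class + 1
    if gt.noise_rate > 0:
        flip = rng.random(n) < gt.noise_rate
        labels = np.where(flip, 3 - labels, labels)
        logger.info("flipped %d of %d labels", int(flip.sum()), n)
    return RecordTable(
        feature_names=list(gt.feature_names),
        features=features,
        labels=labels,
        ids=np.arange(1, n + 1),
        remapped=True,
        domain=(0.0, 10.0),
    )


def inject_missing(table: RecordTable, rate: float, seed: int = 0) -> RecordTable:
    """Flag a random fraction of feature cells as missing (for "?" round-trips)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(table.features.shape) < rate
    from dataclasses import replace

    return replace(table, missing_mask=mask)
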