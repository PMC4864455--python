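"""Reference-set contamination simulation and Bayesian posterior conversion.

Curated disease-mutation databases carry annotation errors: a fraction of
"pathogenic" entries are in fact benign.  :func:`simulate_contaminated`
quantifies what such contamination does to a performance estimate by
repeatedly rebuilding the positive class as a 73/27 mixture (by default) of
stringent positives and relabeled negatives and recomputing AUPRC_norm
(AUPRC over the positive-class prior, which is invariant to the prior shift
a contamination step induces).

For clinical use, an assay's confusion counts convert to likelihood ratios
(LR+ = sens/(1-spec), LR- = (1-sens)/spec) which update a disease prior
through the odds form of Bayes' Rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .benchmark import ConfusionCounts, auprc_norm
from .errors import ConfigurationError, DegenerateSetError, InputError


@dataclass
class ContaminationConfig:
    """contamination: fraction of the positive set replaced by relabeled
    negatives (set size is held fixed); n_sims Monte-Carlo rebuilds."""

    contamination: float = 0.27
    n_sims: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.contamination < 1:
            raise ConfigurationError("contamination must be in [0, 1)")
        if self.n_sims < 1:
            raise ConfigurationError("n_sims must be >= 1")


@dataclass
class ContaminationResult:
    values: np.ndarray
    clean_value: float
    median: float


@dataclass
class BayesResult:
    prior: float
    lr_positive: float
    lr_negative: float
    posterior_given_deleterious: float
    posterior_given_neutral: float


def simulate_contaminated(
    pos_scores, neg_scores, config: ContaminationConfig
) -> ContaminationResult:
    """Distribution of AUPRC_norm under positive-set contamination.

    Each simulation keeps the positive-set size fixed: ceil(contamination*n)
    stringent positives are replaced by negatives sampled without
    replacement, and those negatives are removed from the negative class so
    no variant scores on both sides.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DegenerateSetError("need non-empty positive and negative score sets")
    n_pos = pos.size
    k = math.ceil(config.contamination * n_pos)
    if k >= neg.size:
        raise DegenerateSetError(
            f"need more than {k} negatives to contaminate and still score against"
        )
    labels_clean = np.r_[np.ones(n_pos), np.zeros(neg.size)]
    clean = auprc_norm(np.r_[pos, neg], labels_clean)
    if k == 0:
        values = np.full(config.n_sims, clean)
        return ContaminationResult(values=values, clean_value=clean, median=clean)
    rng = np.random.default_rng(config.seed)
    values = np.empty(config.n_sims)
    for i in range(config.n_sims):
        drop_pos = rng.choice(n_pos, size=k, replace=False)
        take_neg = rng.choice(neg.size, size=k, replace=False)
        kept_pos = np.delete(pos, drop_pos)
        new_pos = np.r_[kept_pos, neg[take_neg]]
        new_neg = np.delete(neg, take_neg)
        scores = np.r_[new_pos, new_neg]
        labels = np.r_[np.ones(new_pos.size), np.zeros(new_neg.size)]
        values[i] = auprc_norm(scores, labels)
    return ContaminationResult(values=values, clean_value=clean, median=float(np.median(values)))


def likelihood_ratios(counts: ConfusionCounts) -> tuple[float, float]:
    """(LR+, LR-) of a binary assay from its confusion counts."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise InputError("likelihood_ratios: both class margins must be positive")
    sens = counts.sensitivity
    spec = counts.specificity
    if spec == 0:
        raise InputError("specificity = 0: LR- undefined")
    lr_pos = math.inf if spec == 1 else sens / (1.0 - spec)
    lr_neg = (1.0 - sens) / spec
    return lr_pos, lr_neg


def posterior(prior: float, lr: float) -> float:
    """Posterior probability via the odds form of Bayes' Rule."""
    if not 0 < prior < 1:
        raise InputError("prior must lie strictly inside (0, 1)")
    if lr < 0:
        raise InputError("likelihood ratio must be >= 0")
    if math.isinf(lr):
        return 1.0
    odds = prior / (1.0 - prior) * lr
    return odds / (1.0 + odds)


def bayes_result(prior: float, counts: ConfusionCounts) -> BayesResult:
    """Posterior pathogenicity after a deleterious or a neutral assay call."""
    lr_pos, lr_neg = likelihood_ratios(counts)
    return BayesResult(
        prior=prior,
        lr_positive=lr_pos,
        lr_negative=lr_neg,
        posterior_given_deleterious=posterior(prior, lr_pos),
        posterior_given_neutral=posterior(prior, lr_neg),
    )
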