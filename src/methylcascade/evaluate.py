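"""Evaluation of cascade predictions and the eigenvector + t-SNE embedding.

The scoring convention follows how a rejection-option classifier is judged:
a positive-class sample is correct when it gets its true label, a mimicker
sample is correct when it lands in ``NoMatch`` (configurable via
``mimicker_policy``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .cascade import NO_MATCH, POSITIVE_CLASSES


@dataclass
class EvaluationResult:
    """Confusion matrix (rows = truth, columns = predicted), overall
    accuracy, per-class sensitivity and anomaly pass-rates by truth class."""

    confusion: pd.DataFrame
    accuracy: float
    per_class_sensitivity: dict
    anomaly_pass_rate: dict

    def check(self, truth_counts: pd.Series) -> None:
        row_sums = self.confusion.sum(axis=1)
        for cls, n in truth_counts.items():
            if row_sums.get(cls, 0) != n:
                raise AssertionError(f"confusion row for {cls} does not sum to {n}")


def evaluate_predictions(
    records: pd.DataFrame,
    truth_labels,
    mimicker_policy: str = "nomatch",
    positive_classes=POSITIVE_CLASSES,
) -> EvaluationResult:
    """Score prediction records against truth labels.

    ``records`` needs columns ``label`` and (optionally) ``anomaly_pass``.
    Truth labels outside ``positive_classes`` are mimickers; under the
    default policy they are counted correct when predicted ``NoMatch``.
    """
    truth = np.asarray(truth_labels).astype(str)
    if len(truth) != len(records):
        raise ValueError("one truth label per record required")
    pred = records["label"].astype(str).to_numpy()
    pred_space = list(positive_classes) + [NO_MATCH]
    bad = set(pred) - set(pred_space)
    if bad:
        raise ValueError(f"unknown predicted labels: {sorted(bad)}")

    truth_classes = list(dict.fromkeys(truth))
    confusion = pd.DataFrame(0, index=truth_classes, columns=pred_space, dtype=int)
    for t, p in zip(truth, pred):
        confusion.loc[t, p] += 1

    is_pos = np.isin(truth, positive_classes)
    if mimicker_policy == "nomatch":
        correct = np.where(is_pos, pred == truth, pred == NO_MATCH)
    elif mimicker_policy == "ignore":
        correct = (pred == truth)[is_pos]
    else:
        raise ValueError(f"unknown mimicker_policy {mimicker_policy!r}")
    accuracy = float(np.mean(correct))

    sens = {}
    for cls in truth_classes:
        m = truth == cls
        target = cls if cls in positive_classes else NO_MATCH
        sens[cls] = float((pred[m] == target).mean())

    pass_rate = {}
    if "anomaly_pass" in records.columns:
        ap = records["anomaly_pass"].to_numpy(dtype=bool)
        for cls in truth_classes:
            pass_rate[cls] = float(ap[truth == cls].mean())

    result = EvaluationResult(confusion, accuracy, sens, pass_rate)
    result.check(pd.Series(truth).value_counts())
    return result


@dataclass
class TsneParams:
    """Eigenvector-then-t-SNE convention: reduce to ``k`` leading principal
    components, then embed with the given perplexity."""

    k: int = 30
    perplexity: float = 15.0
    iterations: int = 5000
    seed: int = 0

    def validate(self, n_samples: int) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.perplexity >= (n_samples - 1) / 3:
            raise ValueError(
                f"perplexity {self.perplexity} too large: must be < (n-1)/3 "
                f"= {(n_samples - 1) / 3:.1f} for n={n_samples}"
            )


def tsne_embed(X, params: TsneParams | None = None) -> np.ndarray:
    """Embed samples (rows) to 2-D: PCA to ``params.k`` eigenvectors, then
    t-SNE. Deterministic for a fixed seed."""
    params = params or TsneParams()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    params.validate(n)
    k = min(params.k, n - 1, X.shape[1])
    comp = PCA(n_components=k, random_state=params.seed).fit_transform(X)
    ts = TSNE(
        n_components=2,
        perplexity=params.perplexity,
        max_iter=max(params.iterations, 250),
        random_state=params.seed,
        init="pca",
    )
    return ts.fit_transform(comp)
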