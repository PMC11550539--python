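"""The three-layer cascade classifier.

Layer 1 — anomaly detection: an ensemble of four sigmoid networks trained
with fourfold cross-validation to separate the reference classes (PAAD,
iCCA, normal bile duct) from mimicker carcinomas; a sample passes if the
mean ensemble output reaches the anomaly threshold.

Layer 2 — classification: a softmax network over the three positive
classes, trained on the reference samples only.

Layer 3 — thresholds: the argmax class is called only if its probability
reaches the per-class threshold (0.8 for PAAD and iCCA, 0.5 for normal
bile); otherwise, and for samples rejected by layer 1, the result is
``NoMatch``.

Features are the top-k CpGs by standard deviation among the reference
samples (k = 2048 by default), optionally batch-corrected with a frozen
:class:`~methylcascade.recombat.ReCombat` model between feature extraction
and the networks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .nn import MlpNet
from .recombat import ReCombat

POSITIVE_CLASSES = ("PAAD", "iCCA", "NormalBile")
NO_MATCH = "NoMatch"

#: Published training recipe for the anomaly-ensemble networks:
#: 5 hidden layers of 2048 neurons, lr 0.0088, dropout 0.2, L1 0.00067,
#: 228 epochs.
ANOMALY_SPEC_DEFAULT = dict(
    hidden_widths=[2048] * 5, learning_rate=0.0088, dropout=0.2, l1=0.00067, epochs=228
)

#: Published classifier recipe: 8 hidden layers from 256 down to 16 neurons
#: (rounded geometric grid), lr 0.00895, dropout 0, L1 0.00441, 191 epochs.
CLASSIFIER_WIDTHS_DEFAULT = [256, 172, 116, 78, 52, 35, 24, 16]
CLASSIFIER_SPEC_DEFAULT = dict(
    hidden_widths=CLASSIFIER_WIDTHS_DEFAULT,
    learning_rate=0.00895, dropout=0.0, l1=0.00441, epochs=191,
)


@dataclass
class MlpSpec:
    """Training recipe for one network (architecture + optimizer settings)."""

    hidden_widths: list[int]
    learning_rate: float = 1e-3
    epochs: int = 100
    dropout: float = 0.0
    l1: float = 0.0
    batch_size: int | None = 64
    activation: str = "relu"
    output: str = "softmax"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def build(self, out_dim: int, seed: int) -> MlpNet:
        return MlpNet(
            hidden_widths=self.hidden_widths,
            out_dim=out_dim,
            output=self.output,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            dropout=self.dropout,
            l1=self.l1,
            batch_size=self.batch_size,
            seed=seed,
        )


@dataclass
class ThresholdPolicy:
    """Per-class probability thresholds plus the anomaly-layer threshold."""

    class_thresholds: dict = field(
        default_factory=lambda: {"PAAD": 0.8, "iCCA": 0.8, "NormalBile": 0.5}
    )
    anomaly_threshold: float = 0.5

    def __post_init__(self) -> None:
        for c, t in self.class_thresholds.items():
            if not (0 < t <= 1):
                raise ValueError(f"threshold for {c} must be in (0, 1]")
        if not (0 < self.anomaly_threshold <= 1):
            raise ValueError("anomaly_threshold must be in (0, 1]")


# ---------------------------------------------------------------------------
# feature selection


def select_features(reference_beta: pd.DataFrame, k: int = 2048) -> pd.Series:
    """Top-k probes by standard deviation among the reference samples.

    ``reference_beta`` is probes x samples. SD uses denominator n-1; ties
    are broken by probe id ascending. Returns a Series (index = probe id,
    values = SD) in rank order.
    """
    if reference_beta.shape[1] < 2:
        raise ValueError("need at least 2 reference samples")
    if k > reference_beta.shape[0]:
        raise ValueError(f"k={k} exceeds probe count {reference_beta.shape[0]}")
    sd = reference_beta.std(axis=1, ddof=1)
    ranked = sd.sort_index().sort_values(ascending=False, kind="stable")
    return ranked.iloc[:k]


class StdFeatureSelector(BaseEstimator):
    """Transformer selecting the k highest-SD features.

    sklearn orientation: ``X`` is (n_samples, n_features); feature names are
    taken from DataFrame columns when available (tie-break is lexicographic
    on the name, otherwise on column position).
    """

    def __init__(self, k: int = 2048):
        self.k = k

    def fit(self, X, y=None) -> "StdFeatureSelector":
        if isinstance(X, pd.DataFrame):
            names = X.columns.astype(str)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            names = pd.Index([f"f{i:06d}" for i in range(values.shape[1])])
        ranked = select_features(pd.DataFrame(values.T, index=names), k=self.k)
        self.feature_names_ = list(ranked.index)
        self.feature_sds_ = ranked.to_numpy()
        name_pos = {n: i for i, n in enumerate(names)}
        self.feature_indices_ = np.array([name_pos[n] for n in self.feature_names_])
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.feature_names_].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)[:, self.feature_indices_]

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


# ---------------------------------------------------------------------------
# anomaly ensemble


class AnomalyEnsemble(BaseEstimator):
    """Four-network anomaly detector trained with fourfold cross-validation.

    Network i is trained on the three folds other than i; fold i provides
    its validation metric. The anomaly score of a sample is the arithmetic
    mean of the four sigmoid outputs.
    """

    def __init__(self, spec: MlpSpec | None = None, n_folds: int = 4, seed: int = 0):
        self.spec = spec
        self.n_folds = n_folds
        self.seed = seed

    def fit(self, X, y) -> "AnomalyEnsemble":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("anomaly ensemble needs exactly two classes (0/1)")
        spec = self.spec or MlpSpec(output="sigmoid", **ANOMALY_SPEC_DEFAULT)
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        self.networks_ = []
        self.fold_metrics_ = []
        for i, (train_idx, val_idx) in enumerate(skf.split(X, y)):
            if len(np.unique(y[val_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
                raise ValueError("stratification failed: a fold is missing a class")
            net = spec.build(out_dim=1, seed=self.seed * 1000 + i)
            net.fit(X[train_idx], y[train_idx])
            val_p = net.predict_proba(X[val_idx])[:, 0]
            acc = float(((val_p >= 0.5).astype(int) == y[val_idx]).mean())
            self.networks_.append(net)
            self.fold_metrics_.append({"fold": i, "val_accuracy": acc, "n_val": len(val_idx)})
        return self

    def member_scores(self, X) -> np.ndarray:
        """Per-network sigmoid outputs, shape (n_samples, n_networks)."""
        return np.column_stack([net.predict_proba(X)[:, 0] for net in self.networks_])

    def score_samples(self, X) -> np.ndarray:
        """Mean of the member outputs — the anomaly score in [0, 1]."""
        return self.member_scores(X).mean(axis=1)


def anomaly_score(ensemble: AnomalyEnsemble, feature_vector) -> float:
    """Score a single feature vector with a fitted ensemble."""
    v = np.asarray(feature_vector, dtype=float).reshape(1, -1)
    return float(ensemble.score_samples(v)[0])


# ---------------------------------------------------------------------------
# threshold layer


def apply_thresholds(
    class_probs,
    anomaly_pass: bool,
    policy: ThresholdPolicy,
    class_names: Sequence[str] = POSITIVE_CLASSES,
) -> tuple[str, str]:
    """Final decision for one sample.

    Returns (label, reason): ``(NoMatch, "anomaly_reject")`` if the anomaly
    layer rejected the sample; otherwise the argmax class if its probability
    reaches (>=) the class threshold, else ``(NoMatch, "below_threshold")``.
    Argmax ties resolve to the first class in ``class_names`` order.
    """
    p = np.asarray(class_probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("class_probs must lie on the simplex")
    if not anomaly_pass:
        return NO_MATCH, "anomaly_reject"
    c = int(np.argmax(p))
    name = class_names[c]
    if p[c] >= policy.class_thresholds[name]:
        return name, "passed"
    return NO_MATCH, "below_threshold"


# ---------------------------------------------------------------------------
# the full cascade


class CascadeClassifier(BaseEstimator, ClassifierMixin):
    """Deployable three-layer cascade.

    ``fit(X, y)`` takes ``X`` as (n_samples, n_probes) — a DataFrame with
    probe-id columns, or an array — and string labels ``y``. Samples whose
    label is one of ``positive_classes`` are the reference set; all other
    labels are treated as mimickers (the anomaly-negative class).

    Pipeline at fit time: select the top-k SD features on the reference
    samples, record per-feature imputation means, optionally fit a frozen
    batch-correction model (pass ``batch=`` labels), train the anomaly
    ensemble on reference-vs-mimicker, train the softmax classifier on the
    reference samples. At predict time every step is replayed per sample.

    Fitted attributes use sklearn's trailing-underscore convention; the
    bundle round-trips through :meth:`save`/:meth:`load` to identical
    predictions.
    """

    def __init__(
        self,
        k: int = 2048,
        anomaly_spec: MlpSpec | None = None,
        classifier_spec: MlpSpec | None = None,
        policy: ThresholdPolicy | None = None,
        positive_classes: tuple[str, ...] = POSITIVE_CLASSES,
        recombat_lam: float = 1e-3,
        min_feature_fraction: float = 0.9,
        n_folds: int = 4,
        seed: int = 0,
    ):
        self.k = k
        self.anomaly_spec = anomaly_spec
        self.classifier_spec = classifier_spec
        self.policy = policy
        self.positive_classes = positive_classes
        self.recombat_lam = recombat_lam
        self.min_feature_fraction = min_feature_fraction
        self.n_folds = n_folds
        self.seed = seed

    # -- helpers ---------------------------------------------------------

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"f{i:06d}" for i in range(X.shape[1])])

    def _extract_features(self, Xf: pd.DataFrame) -> np.ndarray:
        present = [f for f in self.feature_names_ if f in Xf.columns]
        frac = len(present) / len(self.feature_names_)
        if frac < self.min_feature_fraction:
            missing = len(self.feature_names_) - len(present)
            raise ValueError(
                f"{missing} of {len(self.feature_names_)} cascade features missing "
                f"(fraction present {frac:.2f} < {self.min_feature_fraction})"
            )
        F = Xf.reindex(columns=self.feature_names_).to_numpy(dtype=float)
        nan_mask = np.isnan(F)
        if nan_mask.any():
            F[nan_mask] = np.take(self.imputation_means_, np.nonzero(nan_mask)[1])
        return F

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y, batch=None) -> "CascadeClassifier":
        Xf = self._as_frame(X)
        y = np.asarray(y).astype(str)
        if len(y) != len(Xf):
            raise ValueError("X and y length mismatch")
        pos_mask = np.isin(y, self.positive_classes)
        present_pos = [c for c in self.positive_classes if c in set(y)]
        if len(present_pos) != len(self.positive_classes):
            missing = sorted(set(self.positive_classes) - set(y))
            raise ValueError(f"positive classes absent from y: {missing}")

        ref = Xf.loc[pos_mask]
        ranked = select_features(ref.T, k=self.k)
        self.feature_names_ = list(ranked.index)
        self.feature_sds_ = ranked.to_numpy()
        F_ref_raw = Xf.loc[pos_mask, self.feature_names_].to_numpy(dtype=float)
        self.imputation_means_ = np.nanmean(F_ref_raw, axis=0)

        F_all = self._extract_features(Xf)
        if batch is not None:
            batch = np.asarray(batch).astype(str)
            self.recombat_ = ReCombat(lam=self.recombat_lam).fit(
                F_all, batch, covariates=y
            )
            F_all = self.recombat_.transform(F_all, batch)
        else:
            self.recombat_ = None

        policy = self.policy or ThresholdPolicy()
        self.policy_ = policy
        self.classes_ = np.array(list(self.positive_classes) + [NO_MATCH])

        spec_a = self.anomaly_spec or MlpSpec(output="sigmoid", **ANOMALY_SPEC_DEFAULT)
        spec_c = self.classifier_spec or MlpSpec(output="softmax", **CLASSIFIER_SPEC_DEFAULT)
        self.anomaly_ = AnomalyEnsemble(spec=spec_a, n_folds=self.n_folds, seed=self.seed)
        self.anomaly_.fit(F_all, pos_mask.astype(int))

        y_pos = y[pos_mask]
        class_index = {c: i for i, c in enumerate(self.positive_classes)}
        self.classifier_ = spec_c.build(out_dim=len(self.positive_classes),
                                        seed=self.seed + 7919)
        self.classifier_.fit(F_all[pos_mask], np.array([class_index[c] for c in y_pos]))

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(F_all).tobytes())
        h.update(",".join(y).encode())
        self.training_metadata_ = {
            "seed": self.seed,
            "n_samples": int(len(y)),
            "n_reference": int(pos_mask.sum()),
            "n_negative": int((~pos_mask).sum()),
            "data_hash": h.hexdigest()[:16],
        }
        return self

    # -- prediction ------------------------------------------------------

    def predict_records(self, X, batch=None) -> pd.DataFrame:
        """Full per-sample prediction records.

        Columns: sample_id, anomaly_score, anomaly_pass, p_<class> for each
        positive class, label, reason.
        """
        if not hasattr(self, "feature_names_"):
            raise RuntimeError("CascadeClassifier is not fitted")
        Xf = self._as_frame(X)
        F = self._extract_features(Xf)
        if np.isnan(F).any():
            raise ValueError("NaN features remain after imputation")
        if self.recombat_ is not None:
            if batch is None:
                raise ValueError("model was fitted with batch correction; pass batch labels")
            F = self.recombat_.transform(F, np.asarray(batch).astype(str))
        scores = self.anomaly_.score_samples(F)
        probs = self.classifier_.predict_proba(F)
        rows = []
        ids = Xf.index if isinstance(X, pd.DataFrame) else range(len(F))
        for sid, s, p in zip(ids, scores, probs):
            a_pass = bool(s >= self.policy_.anomaly_threshold)
            label, reason = apply_thresholds(p, a_pass, self.policy_,
                                             class_names=self.positive_classes)
            row = {"sample_id": sid, "anomaly_score": float(s), "anomaly_pass": a_pass}
            for c, pc in zip(self.positive_classes, p):
                row[f"p_{c}"] = float(pc)
            row["label"] = label
            row["reason"] = reason
            rows.append(row)
        return pd.DataFrame(rows)

    def predict(self, X, batch=None) -> np.ndarray:
        return self.predict_records(X, batch=batch)["label"].to_numpy()

    def predict_proba(self, X, batch=None) -> np.ndarray:
        """Softmax probabilities over the positive classes (layer 2 only)."""
        Xf = self._as_frame(X)
        F = self._extract_features(Xf)
        if self.recombat_ is not None:
            if batch is None:
                raise ValueError("model was fitted with batch correction; pass batch labels")
            F = self.recombat_.transform(F, np.asarray(batch).astype(str))
        return self.classifier_.predict_proba(F)

    # -- serialization ---------------------------------------------------

    def save(self, outdir) -> None:
        """Write the bundle: model.json + one array container."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        spec_c = self.classifier_.spec_dict()
        meta = {
            "format_version": 1,
            "k": self.k,
            "positive_classes": list(self.positive_classes),
            "policy": {
                "class_thresholds": self.policy_.class_thresholds,
                "anomaly_threshold": self.policy_.anomaly_threshold,
            },
            "feature_names": self.feature_names_,
            "n_anomaly_networks": len(self.anomaly_.networks_),
            "anomaly_net_specs": [n.spec_dict() for n in self.anomaly_.networks_],
            "classifier_spec": spec_c,
            "min_feature_fraction": self.min_feature_fraction,
            "recombat": self.recombat_ is not None,
            "training_metadata": self.training_metadata_,
            "fold_metrics": self.anomaly_.fold_metrics_,
            "seed": self.seed,
        }
        (out / "model.json").write_text(json.dumps(meta, indent=2))
        arrays = {
            "feature_sds": self.feature_sds_,
            "imputation_means": self.imputation_means_,
        }
        for i, net in enumerate(self.anomaly_.networks_):
            arrays.update(net.weight_arrays(f"anom{i}_"))
        arrays.update(self.classifier_.weight_arrays("clf_"))
        np.savez(out / "weights.npz", **arrays)
        if self.recombat_ is not None:
            self.recombat_.save(out)

    @classmethod
    def load(cls, indir) -> "CascadeClassifier":
        indir = Path(indir)
        meta = json.loads((indir / "model.json").read_text())
        model = cls(
            k=meta["k"],
            positive_classes=tuple(meta["positive_classes"]),
            min_feature_fraction=meta["min_feature_fraction"],
            seed=meta["seed"],
        )
        model.policy_ = ThresholdPolicy(
            class_thresholds=meta["policy"]["class_thresholds"],
            anomaly_threshold=meta["policy"]["anomaly_threshold"],
        )
        model.feature_names_ = meta["feature_names"]
        arrays = np.load(indir / "weights.npz")
        model.feature_sds_ = arrays["feature_sds"]
        model.imputation_means_ = arrays["imputation_means"]
        ens = AnomalyEnsemble(seed=meta["seed"])
        ens.networks_ = [
            MlpNet.from_arrays(spec, arrays, f"anom{i}_")
            for i, spec in enumerate(meta["anomaly_net_specs"])
        ]
        ens.fold_metrics_ = meta.get("fold_metrics", [])
        model.anomaly_ = ens
        model.classifier_ = MlpNet.from_arrays(meta["classifier_spec"], arrays, "clf_")
        model.recombat_ = ReCombat.load(indir) if meta["recombat"] else None
        model.classes_ = np.array(meta["positive_classes"] + [NO_MATCH])
        model.training_metadata_ = meta["training_metadata"]
        return model
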