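"""Regularized empirical-Bayes batch correction (reComBat-style ComBat).

Standard parametric ComBat with an L2 (ridge) penalty on the
standardization regression:

1. regress the data on batch indicators plus optional covariates to
   preserve (ridge-penalized with strength ``lam``), pool residual
   variances, and standardize;
2. estimate per-batch location (gamma) and scale (delta^2) on the
   standardized data; shrink them with parametric empirical-Bayes priors
   (normal on gamma, inverse-gamma on delta^2) fitted per batch by the
   method of moments, solved by the usual fixed-point iteration;
3. remove the shrunken batch effects and restore the pooled scale and the
   covariate-preserving standardized mean.

The fitted model is a per-probe, per-batch affine transform and can be
frozen and applied to single new samples.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _it_sol(z_batch, g_hat, d_hat, g_bar, t2, a_prior, b_prior, conv=1e-4, max_iter=500):
    """ComBat fixed-point iteration for the EB posterior estimates."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        if t2 > 0:
            g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        else:
            g_new = np.full_like(g_hat, g_bar)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2.0 + a_prior - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / max(np.abs(g_old).max(), 1e-12),
            np.abs(d_new - d_old).max() / max(np.abs(d_old).max(), 1e-12),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


class ReCombat:
    """sklearn-style batch-correction transformer.

    Parameters
    ----------
    lam : float
        Ridge strength on the standardization regression (0 = classic
        ComBat).
    on_unseen_batch : {"identity", "error"}
        Policy when ``transform`` meets a batch label absent at fit time.

    ``fit``/``transform`` take ``X`` of shape (n_samples, n_features),
    per-sample ``batches`` and optional categorical ``covariates`` whose
    effect should be preserved (e.g. the class label during training).
    """

    def __init__(self, lam: float = 1e-3, on_unseen_batch: str = "identity"):
        self.lam = lam
        self.on_unseen_batch = on_unseen_batch

    def get_params(self, deep: bool = True) -> dict:
        return {"lam": self.lam, "on_unseen_batch": self.on_unseen_batch}

    def set_params(self, **params) -> "ReCombat":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # -- fitting ---------------------------------------------------------

    def fit(self, X, batches, covariates=None) -> "ReCombat":
        X = np.asarray(X, dtype=float)
        batches = np.asarray(batches)
        if X.shape[0] != len(batches):
            raise ValueError("batches must have one label per sample")
        self.batch_levels_ = [str(b) for b in pd.unique(batches)]
        counts = pd.Series(batches.astype(str)).value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"batches with fewer than 2 samples: {list(small.index)}")

        Y = X.T  # features x samples
        n_feat, n = Y.shape
        B = pd.get_dummies(pd.Categorical(batches.astype(str), categories=self.batch_levels_))
        B = B.to_numpy(dtype=float)  # n x K
        K = B.shape[1]
        if covariates is not None:
            C = pd.get_dummies(pd.Series(np.asarray(covariates).astype(str)), drop_first=True)
            self.covariate_levels_ = list(C.columns)
            C = C.to_numpy(dtype=float)
            D = np.hstack([B, C])
        else:
            self.covariate_levels_ = []
            D = B
        p = D.shape[1]

        # Ridge-penalized standardization regression (batch means + covariate
        # coefficients). The penalty is the reComBat ridge term.
        XtX = D.T @ D + self.lam * np.eye(p)
        theta = np.linalg.solve(XtX, D.T @ Y.T)  # p x features
        batch_frac = B.sum(axis=0) / n
        self.grand_mean_ = batch_frac @ theta[:K]          # per-feature alpha
        self.covariate_coef_ = theta[K:]                   # (p-K) x features

        resid = Y - (D @ theta).T
        var_pooled = (resid ** 2).mean(axis=1)             # ddof 0, as usual
        self.zero_var_mask_ = var_pooled <= 1e-12
        if self.zero_var_mask_.any():
            warnings.warn(
                f"{int(self.zero_var_mask_.sum())} zero-variance probes left uncorrected",
                RuntimeWarning,
            )
        self.var_pooled_ = np.where(self.zero_var_mask_, 1.0, var_pooled)

        stand_mean = self.grand_mean_[:, None] + (self.covariate_coef_.T @ C.T if covariates is not None else 0.0)
        Z = (Y - stand_mean) / np.sqrt(self.var_pooled_)[:, None]

        self.gamma_star_ = np.zeros((K, n_feat))
        self.delta_star_ = np.ones((K, n_feat))
        if K > 1:
            for k, level in enumerate(self.batch_levels_):
                idx = B[:, k] == 1
                zb = Z[:, idx]
                g_hat = zb.mean(axis=1)
                d_hat = zb.var(axis=1, ddof=1)
                g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
                m, s2 = float(d_hat.mean()), float(d_hat.var(ddof=1))
                if s2 > 1e-12:
                    a_prior = (2 * s2 + m ** 2) / s2
                    b_prior = (m * s2 + m ** 3) / s2
                    g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a_prior, b_prior)
                else:
                    g_star, d_star = g_hat, d_hat
                self.gamma_star_[k] = g_star
                self.delta_star_[k] = np.maximum(d_star, 1e-12)
        # Single batch: gamma*=0, delta*=1 — the transform is the identity.
        self.gamma_star_[:, self.zero_var_mask_] = 0.0
        self.delta_star_[:, self.zero_var_mask_] = 1.0
        self.n_features_in_ = n_feat
        return self

    # -- application -----------------------------------------------------

    def transform(self, X, batches, covariates=None) -> np.ndarray:
        if not hasattr(self, "gamma_star_"):
            raise RuntimeError("ReCombat is not fitted")
        X = np.asarray(X, dtype=float)
        batches = np.asarray(batches).astype(str)
        Y = X.T
        sd = np.sqrt(self.var_pooled_)[:, None]
        if covariates is not None:
            C = pd.get_dummies(pd.Series(np.asarray(covariates).astype(str)))
            C = C.reindex(columns=self.covariate_levels_, fill_value=0).to_numpy(dtype=float)
            stand_mean = self.grand_mean_[:, None] + self.covariate_coef_.T @ C.T
        else:
            stand_mean = np.broadcast_to(self.grand_mean_[:, None], Y.shape).copy()
        Z = (Y - stand_mean) / sd

        out = np.empty_like(Z)
        level_index = {b: k for k, b in enumerate(self.batch_levels_)}
        for j, b in enumerate(batches):
            k = level_index.get(b)
            if k is None:
                if self.on_unseen_batch == "error":
                    raise ValueError(f"unseen batch label {b!r}")
                warnings.warn(
                    f"unseen batch label {b!r}: applying identity transform", RuntimeWarning
                )
                out[:, j] = Z[:, j]
            else:
                out[:, j] = (Z[:, j] - self.gamma_star_[k]) / np.sqrt(self.delta_star_[k])
        corrected = out * sd + stand_mean
        corrected[self.zero_var_mask_, :] = Y[self.zero_var_mask_, :]
        return corrected.T

    def fit_transform(self, X, batches, covariates=None) -> np.ndarray:
        return self.fit(X, batches, covariates).transform(X, batches, covariates)

    # -- serialization ---------------------------------------------------

    def to_arrays(self) -> dict:
        return {
            "grand_mean": self.grand_mean_,
            "covariate_coef": self.covariate_coef_,
            "var_pooled": self.var_pooled_,
            "gamma_star": self.gamma_star_,
            "delta_star": self.delta_star_,
            "zero_var_mask": self.zero_var_mask_,
        }

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {
            "lam": self.lam,
            "on_unseen_batch": self.on_unseen_batch,
            "batch_levels": self.batch_levels_,
            "covariate_levels": self.covariate_levels_,
        }
        (out / "recombat.json").write_text(json.dumps(meta, indent=2))
        np.savez(out / "recombat_arrays.npz", **self.to_arrays())

    @classmethod
    def load(cls, indir) -> "ReCombat":
        indir = Path(indir)
        meta = json.loads((indir / "recombat.json").read_text())
        model = cls(lam=meta["lam"], on_unseen_batch=meta["on_unseen_batch"])
        model.batch_levels_ = meta["batch_levels"]
        model.covariate_levels_ = meta["covariate_levels"]
        arrays = np.load(indir / "recombat_arrays.npz")
        model.grand_mean_ = arrays["grand_mean"]
        model.covariate_coef_ = arrays["covariate_coef"]
        model.var_pooled_ = arrays["var_pooled"]
        model.gamma_star_ = arrays["gamma_star"]
        model.delta_star_ = arrays["delta_star"]
        model.zero_var_mask_ = arrays["zero_var_mask"]
        model.n_features_in_ = len(model.grand_mean_)
        return model


def fit_recombat(matrix, batch_design, lam: float = 1e-3, covariates=None) -> ReCombat:
    """Functional wrapper: fit on ``matrix`` (samples x features)."""
    return ReCombat(lam=lam).fit(matrix, batch_design, covariates=covariates)


def apply_recombat(model: ReCombat, matrix, batch_labels, covariates=None) -> np.ndarray:
    """Apply a frozen correction model to new samples."""
    return model.transform(matrix, batch_labels, covariates=covariates)
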