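"""Beta-mixture quantile (BMIQ) normalization of type-II probes.

Infinium type-II probes have compressed beta distributions relative to
type-I probes measured in the same sample. BMIQ fits a three-state
(unmethylated / hemimethylated / methylated) beta mixture separately to the
type-I and type-II probes of one sample, quantile-maps the type-II U and M
states onto the corresponding type-I state distributions, and rescales the
hemimethylated state by an affine dilation anchored at the mapped state
boundaries. Type-I values are returned unchanged. The procedure is strictly
per-sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

EPS = 1e-6
MIN_PROBES_PER_TYPE = 50


@dataclass
class BetaMixture3:
    """Three-component beta mixture, components ordered by increasing mean."""

    weights: np.ndarray  # (3,)
    a: np.ndarray        # (3,) shape parameters
    b: np.ndarray        # (3,)

    def means(self) -> np.ndarray:
        return self.a / (self.a + self.b)


def _moment_ab(mean: float, var: float) -> tuple[float, float]:
    # Method-of-moments beta parameters, floored for stability.
    mean = min(max(mean, 1e-4), 1 - 1e-4)
    var = max(var, 1e-6)
    common = mean * (1 - mean) / var - 1.0
    common = max(common, 1e-2)
    return max(mean * common, 1e-2), max((1 - mean) * common, 1e-2)


def fit_beta_mixture3(
    x: np.ndarray, max_iter: int = 100, tol: float = 1e-5
) -> BetaMixture3:
    """EM fit of a 3-state beta mixture with moment-matching M-steps.

    Initialization is deterministic: hard assignment at the empirical
    tertiles of the sample, so the three components start distinct even
    when the distribution is compressed.
    """
    x = np.clip(np.asarray(x, dtype=float), EPS, 1 - EPS)
    n = len(x)
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
    resp = np.zeros((n, 3))
    resp[x < q1, 0] = 1.0
    resp[(x >= q1) & (x < q2), 1] = 1.0
    resp[x >= q2, 2] = 1.0
    # Guard: every component needs some mass to start.
    resp += 1e-3
    resp /= resp.sum(axis=1, keepdims=True)

    a = np.zeros(3)
    b = np.zeros(3)
    w = np.zeros(3)
    prev_ll = -np.inf
    for it in range(max_iter):
        # M-step (weighted moments)
        for k in range(3):
            r = resp[:, k]
            wk = r.sum()
            m = float((r * x).sum() / wk)
            v = float((r * (x - m) ** 2).sum() / wk)
            a[k], b[k] = _moment_ab(m, v)
            w[k] = wk / n
        # E-step
        log_pdf = np.stack(
            [np.log(w[k]) + stats.beta.logpdf(x, a[k], b[k]) for k in range(3)], axis=1
        )
        mx = log_pdf.max(axis=1, keepdims=True)
        p = np.exp(log_pdf - mx)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float((np.log(tot[:, 0]) + mx[:, 0]).sum())
        if abs(ll - prev_ll) < tol * (1 + abs(prev_ll)):
            break
        prev_ll = ll
    else:
        warnings.warn("beta-mixture EM did not converge; using best iterate", RuntimeWarning)
    order = np.argsort(a / (a + b))
    return BetaMixture3(weights=w[order], a=a[order], b=b[order])


def _state_boundaries(mix: BetaMixture3, x: np.ndarray) -> tuple[float, float]:
    """Beta values splitting the sample into U/H/M states.

    The empirical quantiles at the fitted component weights: contiguous by
    construction, which keeps the overall type-II mapping monotone.
    """
    w = mix.weights / mix.weights.sum()
    uh, hm = np.quantile(x, [w[0], w[0] + w[1]])
    if hm <= uh:
        hm = min(uh + EPS, 1 - EPS)
    return float(uh), float(hm)


def bmiq_normalize(
    beta: np.ndarray,
    design_types: np.ndarray,
    max_iter: int = 100,
    seed: int | None = None,
) -> np.ndarray:
    """BMIQ-normalize one sample's beta vector.

    Parameters
    ----------
    beta : array of beta values for one sample.
    design_types : array of "I"/"II" per probe.
    seed : unused (the fit is deterministic); kept for interface stability.

    Returns
    -------
    Normalized vector: type-I entries unchanged, type-II entries mapped onto
    the type-I state distributions. All outputs in [0, 1]; within-type-II
    rank order is preserved.
    """
    beta = np.asarray(beta, dtype=float)
    design_types = np.asarray(design_types)
    t1 = design_types == "I"
    t2 = design_types == "II"
    if not t2.any():
        return beta.copy()
    if t1.sum() < MIN_PROBES_PER_TYPE or t2.sum() < MIN_PROBES_PER_TYPE:
        raise ValueError(
            f"need >= {MIN_PROBES_PER_TYPE} probes of each design type "
            f"(got I: {int(t1.sum())}, II: {int(t2.sum())})"
        )
    if np.isnan(beta[t1 | t2]).any():
        raise ValueError("beta contains NaN; impute or drop before normalization")

    x1 = np.clip(beta[t1], EPS, 1 - EPS)
    x2 = np.clip(beta[t2], EPS, 1 - EPS)
    mix1 = fit_beta_mixture3(x1, max_iter=max_iter)
    mix2 = fit_beta_mixture3(x2, max_iter=max_iter)

    uh2, hm2 = _state_boundaries(mix2, x2)
    in_u = x2 < uh2
    in_m = x2 >= hm2
    in_h = ~in_u & ~in_m

    out2 = np.empty_like(x2)
    # U state: lower-tail quantile map II -> I.
    if in_u.any():
        q = stats.beta.cdf(x2[in_u], mix2.a[0], mix2.b[0])
        out2[in_u] = stats.beta.ppf(q, mix1.a[0], mix1.b[0])
    # M state: upper-tail quantile map II -> I.
    if in_m.any():
        q = stats.beta.sf(x2[in_m], mix2.a[2], mix2.b[2])
        out2[in_m] = 1.0 - stats.beta.ppf(q, mix1.b[2], mix1.a[2])
    # H state: affine dilation anchored at the mapped U max / M min,
    # preserving the gaps observed on the original scale.
    if in_h.any():
        xh = x2[in_h]
        min_h, max_h = float(xh.min()), float(xh.max())
        max_u = float(x2[in_u].max()) if in_u.any() else uh2
        min_m = float(x2[in_m].min()) if in_m.any() else hm2
        new_max_u = float(out2[in_u].max()) if in_u.any() else uh2
        new_min_m = float(out2[in_m].min()) if in_m.any() else hm2
        n_min_h = new_max_u + (min_h - max_u)
        n_max_h = new_min_m - (min_m - max_h)
        if max_h > min_h:
            hf = (n_max_h - n_min_h) / (max_h - min_h)
            hf = max(hf, 0.0)  # never reverse order
        else:
            hf = 1.0
        out2[in_h] = n_min_h + hf * (xh - min_h)

    out = beta.copy()
    out[t2] = np.clip(out2, 0.0, 1.0)
    return out


class BmiqNormalizer:
    """Transformer applying BMIQ per sample.

    sklearn-style: ``X`` is (n_samples, n_probes); ``design_types`` is fixed
    at construction. BMIQ has no cross-sample state, so ``fit`` only
    validates input.
    """

    def __init__(self, design_types: np.ndarray, max_iter: int = 100):
        self.design_types = np.asarray(design_types)
        self.max_iter = max_iter

    def get_params(self, deep: bool = True) -> dict:
        return {"design_types": self.design_types, "max_iter": self.max_iter}

    def set_params(self, **params) -> "BmiqNormalizer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "BmiqNormalizer":
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.design_types):
            raise ValueError("X columns must match design_types length")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.stack(
            [bmiq_normalize(row, self.design_types, max_iter=self.max_iter) for row in X]
        )

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
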