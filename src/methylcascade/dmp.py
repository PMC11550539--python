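"""Differential methylation with empirical-Bayes variance moderation.

Per probe, a two-group linear model on beta values gives the mean
difference (reported as logFC, following array convention), pooled residual
variance s^2 and residual degrees of freedom. An inverse-gamma prior on the
residual variances — hyperparameters (d0, s0^2) estimated by
trigamma-matching method of moments on log s^2 — yields the moderated
t-statistic

    t = logFC / sqrt(s_tilde^2 (1/nA + 1/nB)),
    s_tilde^2 = (d0 s0^2 + df s^2) / (d0 + df),

with d0 + df degrees of freedom. P-values are Benjamini-Hochberg adjusted
across probes; probes are called differentially methylated when adjusted
p < 0.01 and |logFC| > 0.2 (both strict).

Note the "logFC" here is a difference of mean beta values (methylation
fractions), not a log-ratio: the selection threshold of 0.2 is only
meaningful on the beta scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ModerationPrior:
    """Inverse-gamma prior on residual variances: d0 prior df (may be
    ``inf``), s0sq prior variance."""

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if self.s0sq <= 0:
            raise ValueError("s0sq must be > 0")


def fit_probe_models(beta: pd.DataFrame, groups, contrast: tuple[str, str]) -> pd.DataFrame:
    """Per-probe two-group statistics.

    ``beta`` is probes x samples; ``groups`` assigns each sample column to a
    group; ``contrast`` = (A, B) gives logFC = mean(A) - mean(B).
    """
    groups = np.asarray(groups).astype(str)
    if len(groups) != beta.shape[1]:
        raise ValueError("one group label per sample column required")
    a, b = contrast
    ma, mb = groups == a, groups == b
    if ma.sum() < 2 or mb.sum() < 2:
        raise ValueError(f"each contrasted group needs >= 2 samples (got {ma.sum()}, {mb.sum()})")
    Xa = beta.loc[:, ma].to_numpy(dtype=float)
    Xb = beta.loc[:, mb].to_numpy(dtype=float)
    na, nb = Xa.shape[1], Xb.shape[1]
    mean_a, mean_b = Xa.mean(axis=1), Xb.mean(axis=1)
    ss = ((Xa - mean_a[:, None]) ** 2).sum(axis=1) + ((Xb - mean_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    return pd.DataFrame(
        {
            "logFC": mean_a - mean_b,
            "s2": ss / df,
            "df": df,
            "nA": na,
            "nB": nb,
        },
        index=beta.index,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, as in the
    standard moderated-t hyperparameter fit)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> ModerationPrior:
    """Trigamma-matching method-of-moments estimate of (d0, s0^2) from the
    distribution of log sample variances."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("too few positive variances for prior estimation")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2) + np.log(df[ok] / 2)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(np.mean(special.polygamma(1, df[ok] / 2)))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        warnings.warn("no excess variability in variances; using d0 = inf", RuntimeWarning)
        d0 = np.inf
        s0sq = float(np.exp(e_mean))
    return ModerationPrior(d0=d0, s0sq=s0sq)


def moderate_and_test(
    probe_stats: pd.DataFrame,
    prior: ModerationPrior | None = None,
    min_probes: int = 10,
) -> tuple[ModerationPrior, pd.DataFrame]:
    """Moderated t-test across probes.

    ``probe_stats`` comes from :func:`fit_probe_models`. If ``prior`` is
    None it is estimated from the data (needs >= ``min_probes`` probes).
    Forcing ``prior.d0 = 0`` recovers the ordinary two-sample t; ``d0 =
    inf`` fixes every posterior variance at ``s0sq``.
    """
    s2 = probe_stats["s2"].to_numpy(dtype=float)
    df = probe_stats["df"].to_numpy(dtype=float)
    if prior is None:
        if len(probe_stats) < min_probes:
            raise ValueError(f"need >= {min_probes} probes to estimate the prior")
        if (s2 <= 0).all():
            raise ValueError(
                "all residual variances are zero; noise-free input cannot be tested"
            )
        prior = estimate_prior(s2, df)

    if np.isinf(prior.d0):
        s2_post = np.full_like(s2, prior.s0sq)
        df_total = np.full_like(df, np.inf)
    elif prior.d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (prior.d0 * prior.s0sq + df * s2) / (prior.d0 + df)
        df_total = prior.d0 + df

    na = probe_stats["nA"].to_numpy(dtype=float)
    nb = probe_stats["nB"].to_numpy(dtype=float)
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = probe_stats["logFC"].to_numpy() / se
    t = np.where(se == 0, np.sign(probe_stats["logFC"]) * np.inf, t)
    finite_df = np.where(np.isinf(df_total), 1e9, df_total)
    p = 2.0 * stats.t.sf(np.abs(t), finite_df)
    p = np.where(np.isnan(t), 1.0, p)
    adj = multipletests(p, method="fdr_bh")[1]

    out = probe_stats.copy()
    out["t"] = t
    out["p"] = p
    out["adj_p"] = adj
    out["significant"] = (out["adj_p"] < 0.01) & (out["logFC"].abs() > 0.2)
    return prior, out


def select_dmps(
    dmp_table: pd.DataFrame, adj_p_max: float = 0.01, min_abs_logfc: float = 0.2
) -> pd.Index:
    """Probes with adjusted p strictly below ``adj_p_max`` and |logFC|
    strictly above ``min_abs_logfc``."""
    mask = (dmp_table["adj_p"] < adj_p_max) & (dmp_table["logFC"].abs() > min_abs_logfc)
    return dmp_table.index[mask]


def annotate_regulatory(
    dmp_table: pd.DataFrame, probe_set: pd.Index, manifest: pd.DataFrame
) -> dict[str, set[str]]:
    """Map significant probes to enhancer/promoter gene sets split by
    direction (hyper: logFC > 0; hypo: logFC < 0). A probe carrying both
    flags contributes to both sets; probes with no gene are dropped."""
    sets: dict[str, set[str]] = {
        "enhancer_hyper": set(), "enhancer_hypo": set(),
        "promoter_hyper": set(), "promoter_hypo": set(),
    }
    man = manifest.loc[manifest.index.intersection(probe_set)]
    for probe in man.index:
        gene = str(man.at[probe, "gene"])
        if not gene:
            continue
        direction = "hyper" if dmp_table.at[probe, "logFC"] > 0 else "hypo"
        if bool(man.at[probe, "enhancer_flag"]):
            sets[f"enhancer_{direction}"].add(gene)
        if bool(man.at[probe, "promoter_flag"]):
            sets[f"promoter_{direction}"].add(gene)
    return sets


def fisher_ora(
    gene_list, gene_sets: dict[str, set[str]], universe
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    ``gene_list`` must be a subset of ``universe``; each set is intersected
    with the universe first. Returns per-set overlap counts, raw p and BH
    adjusted p, sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(gene_list)
    stray = genes - universe
    if stray:
        raise ValueError(f"gene_list not contained in universe, e.g. {sorted(stray)[:3]}")
    N, n = len(universe), len(genes)
    rows = []
    for name, members in gene_sets.items():
        K = len(members & universe)
        k = len(members & genes)
        # P(X >= k) under sampling n genes from N with K marked.
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["adj_p"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def venn_counts(dmp_sets: dict[str, set]) -> dict[str, int]:
    """Cardinalities of all regions of a 2- or 3-set Venn partition.

    Region keys concatenate member-set names with '&' (exclusive regions:
    elements in exactly those sets)."""
    names = list(dmp_sets)
    if not (2 <= len(names) <= 3):
        raise ValueError("venn_counts supports 2 or 3 sets")
    from itertools import combinations

    counts = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(dmp_sets[n] for n in combo))
            outside = set.union(*(dmp_sets[n] for n in names if n not in combo), set())
            counts["&".join(combo)] = len(inside - outside)
    return counts


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (set name, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
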