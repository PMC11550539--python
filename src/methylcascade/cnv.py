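"""Copy-number profiling from methylation-array intensities.

Combined (methylated + unmethylated) probe intensities scale with DNA copy
number. A query sample is compared against a panel of normal-tissue
controls: per-probe log2 ratios against the panel median, median-centered
per sample, averaged into genome-ordered bins, segmented by recursive
binary splitting, and called gain/loss when a segment mean deviates from
baseline by strictly more than the call threshold (0.15 by default).

Group summaries report per-bin gain/loss frequencies; gene-level
comparisons between groups use Fisher's exact test (Freeman-Halton for
2x3) with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)} | {"chrX": 23, "chrY": 24}


@dataclass
class CnvCallParams:
    probes_per_bin: int = 20
    tau: float = 0.15           # log2-ratio deviation required for a call
    min_bins_per_segment: int = 3
    # Sex-chromosome ratios are confounded by the sex mix of the normal
    # panel; profile autosomes only by default.
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass
class CnvProfile:
    """Per-bin ratios, segments and calls for one sample."""

    sample_id: str
    bins: pd.DataFrame       # chrom, start, end, n_probes, ratio
    segments: pd.DataFrame   # chrom, start_bin, end_bin, start, end, n_bins, mean_ratio, call
    params: CnvCallParams = field(default_factory=CnvCallParams)

    def bin_calls(self) -> np.ndarray:
        """Per-bin call derived from the covering segment."""
        calls = np.array(["neutral"] * len(self.bins), dtype=object)
        for _, seg in self.segments.iterrows():
            calls[int(seg.start_bin) : int(seg.end_bin) + 1] = seg.call
        return calls

    def gene_calls(self, manifest: pd.DataFrame) -> pd.Series:
        """Per-gene call: a gene is deleted/amplified if any overlapping
        segment is a loss/gain (loss wins over gain if both)."""
        out: dict[str, str] = {}
        man = manifest[manifest["gene"].astype(str) != ""]
        for _, seg in self.segments.iterrows():
            if seg.call == "neutral":
                continue
            hit = man[(man["chrom"] == seg.chrom) & (man["pos"] >= seg.start) & (man["pos"] <= seg.end)]
            for g in hit["gene"].unique():
                if out.get(g) != "loss":
                    out[g] = seg.call
        return pd.Series(out, dtype=object)


def compute_log2_ratio(query: pd.DataFrame | pd.Series, baseline_panel: pd.DataFrame) -> pd.DataFrame:
    """Per-probe log2 ratio of query total intensity vs the baseline median,
    median-centered per sample.

    ``query`` is probes x samples (or a Series for one sample);
    ``baseline_panel`` is probes x control samples (>= 3 controls).
    """
    if isinstance(query, pd.Series):
        query = query.to_frame()
    if baseline_panel.shape[1] < 3:
        raise ValueError("baseline panel needs >= 3 control samples")
    shared = query.index.intersection(baseline_panel.index)
    if len(shared) == 0:
        raise ValueError("query and baseline share no probes")
    q = query.loc[shared]
    b = baseline_panel.loc[shared]
    for df, name in ((q, "query"), (b, "baseline")):
        bad = df.index[(df <= 0).any(axis=1)]
        if len(bad):
            raise ValueError(f"non-positive {name} intensity at probe {bad[0]!r}")
    ratio = np.log2(q.div(b.median(axis=1), axis=0))
    return ratio - ratio.median(axis=0)


def _bin_ratios(
    ratios: pd.Series, manifest: pd.DataFrame, probes_per_bin: int,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    man = manifest.loc[manifest.index.intersection(ratios.index)].copy()
    allowed = {c for c in _CHROM_ORDER if not (autosomes_only and c in ("chrX", "chrY"))}
    man = man[man["chrom"].isin(allowed)]
    man["_order"] = man["chrom"].map(_CHROM_ORDER)
    man = man.sort_values(["_order", "pos"], kind="stable")
    rows = []
    for chrom, grp in man.groupby("chrom", sort=False):
        vals = ratios.loc[grp.index].to_numpy()
        pos = grp["pos"].to_numpy()
        n = len(vals)
        for start in range(0, n, probes_per_bin):
            sl = slice(start, min(start + probes_per_bin, n))
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[sl][0]),
                    "end": int(pos[sl][-1]),
                    "n_probes": len(vals[sl]),
                    "ratio": float(np.mean(vals[sl])),
                }
            )
    return pd.DataFrame(rows)


def _split_point(x: np.ndarray, min_size: int) -> tuple[int | None, float]:
    """Best binary split by two-sample t statistic magnitude."""
    best_i, best_t = None, 0.0
    for i in range(min_size, len(x) - min_size + 1):
        left, right = x[:i], x[i:]
        v = left.var(ddof=1) / len(left) + right.var(ddof=1) / len(right)
        if v <= 1e-18:
            t = np.inf if abs(left.mean() - right.mean()) > 0 else 0.0
        else:
            t = abs(left.mean() - right.mean()) / np.sqrt(v)
        if t > best_t:
            best_i, best_t = i, t
    return best_i, best_t


def _segment_chrom(x: np.ndarray, offset: int, params: CnvCallParams) -> list[tuple[int, int]]:
    if len(x) < 2 * params.min_bins_per_segment:
        return [(offset, offset + len(x) - 1)]
    i, _ = _split_point(x, params.min_bins_per_segment)
    if i is None:
        return [(offset, offset + len(x) - 1)]
    if abs(x[:i].mean() - x[i:].mean()) < params.tau / 2:
        return [(offset, offset + len(x) - 1)]
    return _segment_chrom(x[:i], offset, params) + _segment_chrom(x[i:], offset + i, params)


def bin_and_segment(
    ratios: pd.Series, manifest: pd.DataFrame, params: CnvCallParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average probe ratios into genome-ordered bins and segment each
    chromosome by recursive binary splitting.

    A split is accepted while the between-side mean difference is at least
    tau/2 and both sides keep ``min_bins_per_segment`` bins. Returns
    (bins, segments) in genomic order.
    """
    params = params or CnvCallParams()
    bins = _bin_ratios(ratios, manifest, params.probes_per_bin, params.autosomes_only)
    seg_rows = []
    for chrom, grp in bins.groupby("chrom", sort=False):
        x = grp["ratio"].to_numpy()
        offset = int(grp.index[0])
        for s, e in _segment_chrom(x, offset, params):
            seg_rows.append(
                {
                    "chrom": chrom,
                    "start_bin": s,
                    "end_bin": e,
                    "start": int(bins.loc[s, "start"]),
                    "end": int(bins.loc[e, "end"]),
                    "n_bins": e - s + 1,
                    "mean_ratio": float(bins.loc[s:e, "ratio"].mean()),
                }
            )
    segments = pd.DataFrame(seg_rows)
    return bins, segments


def call_segments(
    sample_id: str,
    bins: pd.DataFrame,
    segments: pd.DataFrame,
    params: CnvCallParams | None = None,
) -> CnvProfile:
    """Assign gain/loss/neutral per segment: strict ``|mean| > tau``."""
    params = params or CnvCallParams()
    segments = segments.copy()
    calls = np.where(
        segments["mean_ratio"] > params.tau, "gain",
        np.where(segments["mean_ratio"] < -params.tau, "loss", "neutral"),
    )
    segments["call"] = calls
    return CnvProfile(sample_id=sample_id, bins=bins, segments=segments, params=params)


def cnv_profile(
    query_intensities: pd.Series,
    baseline_panel: pd.DataFrame,
    manifest: pd.DataFrame,
    params: CnvCallParams | None = None,
    sample_id: str = "sample",
) -> CnvProfile:
    """Convenience: ratio -> bin -> segment -> call for one sample."""
    ratios = compute_log2_ratio(query_intensities, baseline_panel).iloc[:, 0]
    bins, segments = bin_and_segment(ratios, manifest, params)
    return call_segments(sample_id, bins, segments, params)


def summarize_group(profiles: list[CnvProfile]) -> pd.DataFrame:
    """Per-bin gain and loss frequencies across a group of profiles."""
    if not profiles:
        raise ValueError("need at least one profile")
    ref = profiles[0].bins[["chrom", "start", "end"]]
    for p in profiles[1:]:
        if not p.bins[["chrom", "start", "end"]].equals(ref):
            raise ValueError("profiles use mismatched bin schemes")
    calls = np.stack([p.bin_calls() for p in profiles])
    out = ref.copy()
    out["gain_freq"] = (calls == "gain").mean(axis=0)
    out["loss_freq"] = (calls == "loss").mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# exact tests


def _freeman_halton_2x3(table: np.ndarray) -> float:
    """Exact p for a 2x3 contingency table by full enumeration of tables
    with the observed margins; two-sided by summing probabilities <= P(obs)."""
    table = np.asarray(table, dtype=int)
    row = table.sum(axis=1)
    col = table.sum(axis=0)

    def log_p(t):
        # Multivariate hypergeometric probability of one table.
        from scipy.special import gammaln

        n = t.sum()
        return (
            gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n + 1)
            - gammaln(t + 1).sum()
        )

    lp_obs = log_p(table)
    total = 0.0
    for a in range(min(row[0], col[0]) + 1):
        for b in range(min(row[0] - a, col[1]) + 1):
            c = row[0] - a - b
            if c < 0 or c > col[2]:
                continue
            t = np.array([[a, b, c], [col[0] - a, col[1] - b, col[2] - c]])
            if (t < 0).any():
                continue
            lp = log_p(t)
            if lp <= lp_obs + 1e-9:
                total += np.exp(lp)
    return min(total, 1.0)


def fisher_exact_table(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 or 2x3 table."""
    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if table.shape == (2, 3):
        return _freeman_halton_2x3(table)
    raise ValueError(f"unsupported table shape {table.shape}")


def gene_alteration_test(group_calls_by_gene: dict, n_tests: int) -> pd.DataFrame:
    """Per-gene Fisher exact test of alteration frequency between groups.

    ``group_calls_by_gene`` maps gene -> {group -> (n_altered, n_total)}.
    Returns gene, raw p and Bonferroni-adjusted ``min(1, p * n_tests)``.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    rows = []
    for gene, groups in group_calls_by_gene.items():
        if not groups:
            raise ValueError(f"gene {gene!r} has no groups")
        alt, tot = [], []
        for g, (n_alt, n_tot) in groups.items():
            if n_tot == 0:
                raise ValueError(f"empty group {g!r} for gene {gene!r}")
            alt.append(n_alt)
            tot.append(n_tot)
        table = np.array([alt, [t - a for a, t in zip(alt, tot)]])
        p = fisher_exact_table(table)
        rows.append({"gene": gene, "p": p, "p_bonferroni": min(1.0, p * n_tests)})
    return pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
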