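"""Probe-level QC filtering and cross-platform harmonization.

Two preprocessing profiles exist in practice: ``analysis`` (the full filter
stack below, for differential methylation and related analyses) and
``classifier`` (no filtering — the cascade extracts its fixed feature set
directly, then normalizes). This module implements the ``analysis`` stack;
the classifier path lives in :mod:`methylcascade.cascade`.

Filter rules, applied in a fixed attribution order:

a. detection p-value > 0.01 in at least one sample (strict >),
b. bead count < 3 in at least 5% of samples (strict <),
c. SNP-associated probes,
d. multi-hit probes,
e. probes on chrX/chrY,
f. probes absent from the configured platform intersection.

A probe is attributed to the first rule that removes it; the surviving set
is the conjunction of all keep-conditions regardless of order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLATFORM_COLUMNS = {"450k": "on_450k", "EPICv1": "on_epicv1", "EPICv2": "on_epicv2"}

_RULES = ("detection", "beads", "snp", "multihit", "sex_chromosome", "platform_intersection")


@dataclass
class QcBatch:
    """One cohort's beta matrix with optional QC matrices (same shape)."""

    beta: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    bead_count: pd.DataFrame | None = None
    platform: str = "450k"

    def __post_init__(self) -> None:
        for name, m in (("detection_p", self.detection_p), ("bead_count", self.bead_count)):
            if m is not None and m.shape != self.beta.shape:
                raise ValueError(f"{name} must share beta's dimensions")


@dataclass
class FilterParams:
    det_p_max: float = 0.01
    min_beads: int = 3
    bead_fail_frac: float = 0.05
    drop_snp: bool = True
    drop_multihit: bool = True
    drop_sex: bool = True
    restrict_to_platforms: tuple[str, ...] = ()


@dataclass
class FilterReport:
    """Per-rule removal counts plus the surviving probe list."""

    removed: dict[str, int] = field(default_factory=dict)
    surviving: list[str] = field(default_factory=list)
    n_input: int = 0

    def __post_init__(self) -> None:
        for r in _RULES:
            self.removed.setdefault(r, 0)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def check(self) -> None:
        if self.n_removed + len(self.surviving) != self.n_input:
            raise AssertionError("filter report does not account for all probes")


def filter_probes(
    qc_batch: QcBatch,
    manifest: pd.DataFrame,
    params: FilterParams | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the QC filter stack; return surviving beta rows and a report."""
    params = params or FilterParams()
    beta = qc_batch.beta
    probes = beta.index
    missing = probes.difference(manifest.index)
    if len(missing):
        raise ValueError(f"manifest does not cover {len(missing)} probes, e.g. {missing[0]!r}")
    man = manifest.loc[probes]

    fails: dict[str, np.ndarray] = {}
    if qc_batch.detection_p is not None:
        fails["detection"] = (qc_batch.detection_p > params.det_p_max).any(axis=1).to_numpy()
    else:
        logger.warning("no detection_p matrix supplied; detection-p rule skipped")
        fails["detection"] = np.zeros(len(probes), dtype=bool)
    if qc_batch.bead_count is not None:
        frac_low = (qc_batch.bead_count < params.min_beads).mean(axis=1)
        fails["beads"] = (frac_low >= params.bead_fail_frac).to_numpy()
    else:
        logger.warning("no bead_count matrix supplied; bead-count rule skipped")
        fails["beads"] = np.zeros(len(probes), dtype=bool)
    fails["snp"] = (
        man["snp_flag"].astype(bool).to_numpy() if params.drop_snp
        else np.zeros(len(probes), bool)
    )
    fails["multihit"] = (
        man["multihit_flag"].astype(bool).to_numpy() if params.drop_multihit
        else np.zeros(len(probes), bool)
    )
    fails["sex_chromosome"] = (
        man["chrom"].isin(["chrX", "chrY"]).to_numpy() if params.drop_sex
        else np.zeros(len(probes), bool)
    )
    if params.restrict_to_platforms:
        keep = np.ones(len(probes), dtype=bool)
        for plat in params.restrict_to_platforms:
            col = PLATFORM_COLUMNS.get(plat)
            if col is None:
                raise ValueError(f"unknown platform {plat!r}")
            keep &= man[col].astype(bool).to_numpy()
        fails["platform_intersection"] = ~keep
    else:
        fails["platform_intersection"] = np.zeros(len(probes), dtype=bool)

    report = FilterReport(n_input=len(probes))
    removed_so_far = np.zeros(len(probes), dtype=bool)
    for rule in _RULES:
        newly = fails[rule] & ~removed_so_far
        report.removed[rule] = int(newly.sum())
        removed_so_far |= fails[rule]
    surviving = probes[~removed_so_far]
    report.surviving = list(surviving)
    report.check()
    return beta.loc[surviving], report


_SUFFIX_RE = re.compile(r"^(cg\d+)_[A-Za-z]+\d*$")


def collapse_replicate_suffixes(beta: pd.DataFrame) -> pd.DataFrame:
    """Collapse EPICv2 replicate-suffixed probe ids (e.g. ``cg000..._TC21``)
    to the base id, averaging replicate rows."""
    base = beta.index.map(lambda p: (_SUFFIX_RE.match(p).group(1) if _SUFFIX_RE.match(p) else p))
    if (base == beta.index).all():
        return beta
    return beta.groupby(pd.Index(base, name=beta.index.name or "probe_id"), sort=False).mean()


def harmonize_probe_sets(
    batches: list[pd.DataFrame],
    manifest: pd.DataFrame,
    target_platforms: tuple[str, ...] = ("450k",),
) -> pd.DataFrame:
    """Merge beta matrices from multiple batches onto a shared probe set.

    Replicate-suffixed ids are collapsed first; the result is restricted to
    probes present on every target platform (per the manifest) and found in
    every batch. Sample order is the concatenation of batch sample orders.
    """
    if not batches:
        raise ValueError("need at least one batch")
    collapsed = [collapse_replicate_suffixes(b) for b in batches]
    keep = pd.Series(True, index=manifest.index)
    for plat in target_platforms:
        col = PLATFORM_COLUMNS.get(plat)
        if col is None:
            raise ValueError(f"unknown platform {plat!r}")
        keep &= manifest[col]
    shared = manifest.index[keep]
    for b in collapsed:
        shared = shared.intersection(b.index)
    if len(shared) == 0:
        raise ValueError(f"empty probe intersection for platforms {target_platforms}")
    shared = manifest.index[manifest.index.isin(shared)]  # manifest order
    return pd.concat([b.loc[shared] for b in collapsed], axis=1)
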