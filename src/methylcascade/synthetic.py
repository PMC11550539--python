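"""Synthetic methylation-cohort generator.

Produces beta-value matrices, paired methylated/unmethylated intensities,
sample sheets, probe manifests and copy-number truth files with the
statistical structure the cascade pipeline assumes: class-specific CpG
blocks, a contaminating normal/immune profile diluting tumor purity,
FFPE-vs-frozen batch shifts, and platform-specific probe subsets.

Beta matrices are pandas DataFrames with probes as rows and samples as
columns; the manifest is a DataFrame indexed by probe id.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

_CHROMS = [f"chr{i}" for i in range(1, 23)]


@dataclass
class ClassArchetype:
    """Per-class mean methylation profile.

    ``informative_mask`` marks the disjoint probe block whose mean beta is
    shifted away from the shared background by the configured effect size.
    """

    class_name: str
    probe_means: np.ndarray
    informative_mask: np.ndarray

    def __post_init__(self) -> None:
        self.probe_means = np.asarray(self.probe_means, dtype=float)
        self.informative_mask = np.asarray(self.informative_mask, dtype=bool)
        if self.probe_means.min() < 0 or self.probe_means.max() > 1:
            raise ValueError("probe_means must lie in [0, 1]")
        if self.informative_mask.shape != self.probe_means.shape:
            raise ValueError("informative_mask length must equal probe count")


@dataclass
class CohortConfig:
    """Parameters of one simulated cohort.

    ``delta`` is the beta-scale separation of each class's informative
    probes from the shared background; ``batch_shift`` is added to FFPE
    samples to emulate storage-material effects.
    """

    n_probes: int
    classes: list[tuple[str, int]]
    delta: float = 0.3
    frac_informative: float = 0.02
    noise_sd: float = 0.05
    purity_range: tuple[float, float] = (0.6, 1.0)
    ffpe_fraction: float = 0.5
    batch_shift: float = 0.05
    platform_assignment: Sequence[str] | str = "450k"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.purity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("purity_range must satisfy 0 <= lo <= hi <= 1")
        if not (0 <= self.ffpe_fraction <= 1):
            raise ValueError("ffpe_fraction must be in [0, 1]")


@dataclass
class SimulatedCohort:
    """A generated cohort: beta values, intensities, metadata and CN truth."""

    beta: pd.DataFrame
    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    sample_sheet: pd.DataFrame
    manifest: pd.DataFrame
    truth_cn: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def total_intensity(self) -> pd.DataFrame:
        return self.methylated + self.unmethylated

    def copy(self) -> "SimulatedCohort":
        return SimulatedCohort(
            beta=self.beta.copy(),
            methylated=self.methylated.copy(),
            unmethylated=self.unmethylated.copy(),
            sample_sheet=self.sample_sheet.copy(),
            manifest=self.manifest.copy(),
            truth_cn=self.truth_cn.copy(),
        )

    def write(self, outdir) -> None:
        """Write beta, intensities, sample sheet, manifest and CN truth as text."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.beta.to_csv(out / "beta.csv")
        self.methylated.to_csv(out / "methylated.csv")
        self.unmethylated.to_csv(out / "unmethylated.csv")
        self.sample_sheet.to_csv(out / "sample_sheet.csv")
        self.manifest.to_csv(out / "manifest.tsv", sep="\t")
        if len(self.truth_cn):
            self.truth_cn.to_csv(out / "truth_cn.tsv", sep="\t")


def _background_means(n_probes: int, rng: np.random.Generator) -> np.ndarray:
    # Bimodal background: most CpGs are either mostly unmethylated or mostly
    # methylated, as on real arrays.
    low = rng.beta(2.0, 8.0, size=n_probes)
    high = rng.beta(8.0, 2.0, size=n_probes)
    pick_high = rng.random(n_probes) < 0.45
    return np.where(pick_high, high, low)


def make_archetypes(
    n_probes: int,
    class_names: Sequence[str],
    frac_informative: float,
    delta: float,
    seed: int,
) -> list[ClassArchetype]:
    """Build one archetype per class over a shared background.

    Each class receives a disjoint block of ``round(frac_informative *
    n_probes)`` informative probes whose mean beta is moved ``delta`` away
    from the background (towards whichever side has room, so no clipping
    occurs for delta <= 0.5).
    """
    if not (0 < frac_informative <= 1):
        raise ValueError("frac_informative must be in (0, 1]")
    if not (0 <= delta <= 1):
        raise ValueError("delta must be in [0, 1]")
    rng = np.random.default_rng(seed)
    background = _background_means(n_probes, rng)

    n_inf = int(round(frac_informative * n_probes))
    needed = n_inf * len(class_names)
    if needed > n_probes:
        raise ValueError(
            f"informative probes required ({needed} = {n_inf} x "
            f"{len(class_names)} classes) exceed n_probes ({n_probes})"
        )
    # Disjoint blocks drawn from a single permutation shared by all classes.
    order = rng.permutation(n_probes)
    archetypes = []
    for i, name in enumerate(class_names):
        block = order[i * n_inf : (i + 1) * n_inf]
        means = background.copy()
        direction = np.where(background[block] < 0.5, 1.0, -1.0)
        means[block] = np.clip(background[block] + direction * delta, 0.0, 1.0)
        mask = np.zeros(n_probes, dtype=bool)
        mask[block] = True
        archetypes.append(ClassArchetype(str(name), means, mask))
    return archetypes


def make_manifest(
    n_probes: int,
    seed: int = 0,
    frac_snp: float = 0.02,
    frac_multihit: float = 0.02,
    frac_sex: float = 0.02,
    frac_enhancer: float = 0.15,
    frac_promoter: float = 0.25,
    frac_450k_only_missing: float = 0.05,
    frac_epicv2_replicated: float = 0.02,
    n_genes: int | None = None,
) -> pd.DataFrame:
    """Generate a synthetic probe manifest.

    Probes are laid out in genome order across chr1..chr22 (a small fraction
    reassigned to chrX/chrY), with QC flags, regulatory flags, gene symbols
    and per-platform presence columns. A fraction of EPICv2 probes is marked
    as replicated (suffix-collapsing targets).
    """
    rng = np.random.default_rng(seed)
    probe_ids = np.array([f"cg{i:08d}" for i in range(n_probes)])
    # Even genome layout: consecutive probes tile chromosomes in order.
    per_chrom = int(np.ceil(n_probes / len(_CHROMS)))
    chroms = np.repeat(_CHROMS, per_chrom)[:n_probes]
    pos = np.concatenate(
        [np.arange(1, 1 + (chroms == c).sum()) * 10_000 for c in _CHROMS if (chroms == c).sum()]
    )
    sex = rng.random(n_probes) < frac_sex
    chroms = chroms.copy()
    chroms[sex] = rng.choice(["chrX", "chrY"], size=sex.sum())

    n_genes = n_genes or max(20, n_probes // 50)
    gene_pool = np.array([f"GENE{i:05d}" for i in range(n_genes)])
    gene_idx = np.minimum((np.arange(n_probes) * n_genes) // n_probes, n_genes - 1)
    genes = gene_pool[gene_idx]
    genes = np.where(rng.random(n_probes) < 0.1, "", genes)

    on_450k = rng.random(n_probes) >= frac_450k_only_missing
    on_epicv1 = rng.random(n_probes) >= 0.02
    on_epicv2 = rng.random(n_probes) >= 0.05
    man = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "design_type": np.where(rng.random(n_probes) < 0.28, "I", "II"),
            "snp_flag": rng.random(n_probes) < frac_snp,
            "multihit_flag": rng.random(n_probes) < frac_multihit,
            "enhancer_flag": rng.random(n_probes) < frac_enhancer,
            "promoter_flag": rng.random(n_probes) < frac_promoter,
            "gene": genes,
            "on_450k": on_450k,
            "on_epicv1": on_epicv1,
            "on_epicv2": on_epicv2,
            "epicv2_replicated": (rng.random(n_probes) < frac_epicv2_replicated) & on_epicv2,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return man


_PLATFORM_COL = {"450k": "on_450k", "EPICv1": "on_epicv1", "EPICv2": "on_epicv2"}


def simulate_cohort(
    config: CohortConfig,
    archetypes: Sequence[ClassArchetype] | None = None,
    contaminant_archetype: ClassArchetype | None = None,
    manifest: pd.DataFrame | None = None,
) -> SimulatedCohort:
    """Simulate a cohort under ``config``.

    Each sample's beta is the convex mixture
    ``purity * class_mean + (1 - purity) * contaminant_mean`` plus Gaussian
    noise and, for FFPE samples, the configured batch shift, clipped to
    [0, 1]. Intensities are drawn log-normal around a platform constant with
    the methylated share set by the final beta, so
    ``beta == methylated / (methylated + unmethylated)`` holds exactly.
    Probes absent from a sample's platform are set to NaN in beta.
    """
    rng = np.random.default_rng(config.seed)
    class_names = [c for c, _ in config.classes]
    if archetypes is None:
        archetypes = make_archetypes(
            config.n_probes, class_names, config.frac_informative, config.delta,
            seed=config.seed + 1,
        )
    by_name = {a.class_name: a for a in archetypes}
    missing = [c for c in class_names if c not in by_name]
    if missing:
        raise ValueError(f"archetypes missing for classes: {missing}")
    if contaminant_archetype is None:
        # Contaminant: its own informative block over the same background,
        # standing in for normal/immune infiltrate.
        contaminant_archetype = make_archetypes(
            config.n_probes, ["_contaminant"], config.frac_informative,
            config.delta, seed=config.seed + 2,
        )[0]
    if manifest is None:
        manifest = make_manifest(config.n_probes, seed=config.seed + 3)
    if len(manifest) != config.n_probes:
        raise ValueError("manifest length must equal n_probes")

    n_samples = sum(n for _, n in config.classes)
    labels: list[str] = []
    for name, n in config.classes:
        labels += [name] * n
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]

    purity = rng.uniform(config.purity_range[0], config.purity_range[1], n_samples)
    is_ffpe = rng.random(n_samples) < config.ffpe_fraction
    if isinstance(config.platform_assignment, str):
        platforms = np.array([config.platform_assignment] * n_samples)
    else:
        platforms = np.asarray(list(config.platform_assignment))
        if len(platforms) != n_samples:
            raise ValueError("platform_assignment length must equal total samples")

    cont = contaminant_archetype.probe_means
    beta = np.empty((config.n_probes, n_samples))
    for j in range(n_samples):
        mu = purity[j] * by_name[labels[j]].probe_means + (1 - purity[j]) * cont
        if is_ffpe[j]:
            mu = mu + config.batch_shift
        noise = rng.normal(0.0, config.noise_sd, config.n_probes) if config.noise_sd > 0 else 0.0
        beta[:, j] = np.clip(mu + noise, 0.0, 1.0)

    # Total intensity log-normal around a platform constant; methylated share
    # equals the final beta so the ratio invariant holds exactly.
    total = np.exp(rng.normal(np.log(5000.0), 0.2, size=beta.shape))
    meth = beta * total
    unmeth = total - meth

    beta_df = pd.DataFrame(beta, index=manifest.index, columns=sample_ids)
    for plat in np.unique(platforms):
        col = _PLATFORM_COL.get(str(plat))
        if col is None:
            raise ValueError(f"unknown platform {plat!r}")
        absent = ~manifest[col].to_numpy()
        if absent.any():
            beta_df.loc[absent, platforms == plat] = np.nan

    sheet = pd.DataFrame(
        {
            "label": labels,
            "material": np.where(is_ffpe, "FFPE", "frozen"),
            "platform": platforms,
            "purity": purity,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth_cn = pd.DataFrame(columns=["sample_id", "chrom", "start", "end", "state"])
    return SimulatedCohort(
        beta=beta_df,
        methylated=pd.DataFrame(meth, index=manifest.index, columns=sample_ids),
        unmethylated=pd.DataFrame(unmeth, index=manifest.index, columns=sample_ids),
        sample_sheet=sheet,
        manifest=manifest,
        truth_cn=truth_cn,
    )


def spike_copy_number(
    cohort: SimulatedCohort,
    region: tuple[str, int, int],
    state: int,
    sample_ids: Sequence[str],
) -> SimulatedCohort:
    """Return a copy of ``cohort`` with a copy-number state spiked into a region.

    ``region`` is (chrom, start, end) in 1-based inclusive manifest
    coordinates. Total intensities of probes in the region are scaled by
    ``state / 2`` for the named samples; beta values are untouched (copy
    number acts on intensity, not on the methylated fraction).
    """
    if state not in (0, 1, 2, 3, 4):
        raise ValueError("state must be an integer copy number in 0..4")
    chrom, start, end = region
    man = cohort.manifest
    in_region = (man["chrom"] == chrom) & (man["pos"] >= start) & (man["pos"] <= end)
    if not in_region.any():
        raise ValueError(f"region {region} contains no manifest probes")
    unknown = [s for s in sample_ids if s not in cohort.beta.columns]
    if unknown:
        raise ValueError(f"unknown sample ids: {unknown}")

    out = cohort.copy()
    # Zero copies: floor at a small fraction so intensities stay positive.
    factor = max(state, 0.02) / 2.0
    idx = man.index[in_region]
    out.methylated.loc[idx, list(sample_ids)] *= factor
    out.unmethylated.loc[idx, list(sample_ids)] *= factor
    rows = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "chrom": chrom,
            "start": start,
            "end": end,
            "state": state,
        }
    )
    out.truth_cn = pd.concat([out.truth_cn, rows], ignore_index=True)
    return out
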