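"""Reading and writing the package's tabular formats.

Beta and intensity matrices are probes x samples tables in CSV, TSV or
Parquet (by extension); the manifest is a TSV with a header and 1-based
positions. BED export of manifest coordinates is 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def read_matrix(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
        return df.set_index(df.columns[0]) if df.index.name is None and df.columns[0].lower().startswith("probe") else df
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path)
    else:
        df.to_csv(path, sep="\t" if path.suffix in (".tsv", ".txt") else ",")


def read_manifest(path) -> pd.DataFrame:
    man = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("snp_flag", "multihit_flag", "enhancer_flag", "promoter_flag",
                "on_450k", "on_epicv1", "on_epicv2"):
        if col in man.columns:
            man[col] = man[col].astype(bool)
    if "gene" in man.columns:
        man["gene"] = man["gene"].fillna("")
    return man


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def manifest_to_bed(manifest: pd.DataFrame, path) -> None:
    """Export probe coordinates as BED (0-based half-open, one base)."""
    bed = pd.DataFrame(
        {
            "chrom": manifest["chrom"],
            "start": manifest["pos"].astype(int) - 1,
            "end": manifest["pos"].astype(int),
            "name": manifest.index,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_segments_seg(segments: pd.DataFrame, sample_id: str, path) -> None:
    """Write segments in SEG format (tab-separated, 1-based inclusive)."""
    seg = pd.DataFrame(
        {
            "ID": sample_id,
            "chrom": segments["chrom"],
            "loc.start": segments["start"].astype(int),
            "loc.end": segments["end"].astype(int),
            "num.mark": segments["n_bins"].astype(int),
            "seg.mean": segments["mean_ratio"],
        }
    )
    seg.to_csv(path, sep="\t", index=False, float_format="%.4f")
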