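"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: TSV for summary statistics, LD pairs, peak
tables, gene annotation and expression bundles; GMT for gene-set
collections; STRING-style TSV for PPI edges; NIfTI for voxel maps.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .loci_map import PairwiseLdPanel
from .synthgen import ExpressionBundle

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "read_ld_pairs",
    "read_peak_table",
    "read_gene_annotation",
    "read_gmt",
    "write_gmt",
    "read_ppi_edges",
    "read_gene_list",
    "write_gene_list",
    "write_nifti",
    "read_nifti",
    "write_expression_bundle",
    "read_expression_bundle",
]

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "Z", "P", "N"]


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = {"SNP", "CHR", "BP", "P"} - set(df.columns)
    if missing:
        raise ValueError(f"sumstats missing columns: {sorted(missing)}")
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ld_pairs(path) -> PairwiseLdPanel:
    return PairwiseLdPanel(pd.read_csv(path, sep="\t"))


def read_peak_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"study_id", "x", "y", "z", "t", "n1", "n2"} - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df


def read_gene_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"gene", "chrom", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: one set per line — name, description, then member symbols."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(filter(None, parts[2:]))
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(members)])
        for name, members in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ppi_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"protein1", "protein2", "combined_score"} - set(df.columns)
    if missing:
        raise ValueError(f"PPI edge list missing columns: {sorted(missing)}")
    return df


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def write_nifti(grid: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine), str(path))


def read_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_expression_bundle(bundle: ExpressionBundle, outdir) -> None:
    """Three-TSV bundle: probe matrix, probe annotation (+ background
    call fraction), sample metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.probe_expr.to_csv(outdir / "probe_expression.tsv", sep="\t")
    bundle.above_background.astype(int).to_csv(outdir / "above_background.tsv", sep="\t")
    bundle.probe_to_gene.rename("gene").to_frame().to_csv(outdir / "probe_annotation.tsv", sep="\t")
    bundle.sample_meta.to_csv(outdir / "sample_metadata.tsv", sep="\t", index=False)


def read_expression_bundle(indir) -> ExpressionBundle:
    indir = Path(indir)
    return ExpressionBundle(
        probe_expr=pd.read_csv(indir / "probe_expression.tsv", sep="\t", index_col=0),
        above_background=pd.read_csv(indir / "above_background.tsv", sep="\t", index_col=0).astype(bool),
        probe_to_gene=pd.read_csv(indir / "probe_annotation.tsv", sep="\t", index_col=0)["gene"],
        sample_meta=pd.read_csv(indir / "sample_metadata.tsv", sep="\t"),
    )
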