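"""Synthetic data generation for every pipeline input.

Each ``simulate_*`` function is a pure function of its arguments (including
the seed) and returns in-memory objects with a known ground truth, so the
downstream stages — conjunctional FDR, LD clumping, coordinate-based
meta-analysis, expression preprocessing and PLS — can be exercised and
validated without any external downloads.

The GWAS simulator uses the standard infinitesimal mapping
``z = R (sqrt(N) * beta) + eps,  eps ~ N(0, R)`` with a block-diagonal
AR(1)-style LD correlation matrix (``corr(z_i, z_j) = r^|i-j|`` within a
block, zero across blocks).  Allele frequencies are not simulated; alleles
are emitted as placeholder A/G because nothing downstream consumes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .loci_map import BlockLdPanel

__all__ = [
    "SimulationConfig",
    "ExpressionBundle",
    "BrainSampleMap",
    "simulate_bivariate_gwas",
    "simulate_expression_atlas",
    "simulate_study_peaks",
    "simulate_annotations",
    "calibrate_effect_sd",
    "make_truth_map",
    "knn_smooth_matrix",
]

CAUSAL_CLASSES = ("null", "trait1_only", "trait2_only", "shared")

# Genomic layout of simulated blocks: SNPs every 1 kb within a block, a
# 1 Mb gap between blocks (so loci from distinct blocks never merge at the
# default 250 kb rule), blocks dealt round-robin over 22 chromosomes.
_SNP_SPACING = 1_000
_BLOCK_GAP = 1_000_000
_N_CHROMS = 22


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the bivariate GWAS simulator.

    ``mixture`` gives the four-component causal-class proportions
    (pi00, pi10, pi01, pi11): null, trait-1-only, trait-2-only, shared.
    ``within_block_decay`` is the correlation r between adjacent SNPs, so
    r² between SNPs at in-block index distance d is ``r**(2*d)``.
    """

    m_snps: int = 20_000
    block_size: int = 100
    within_block_decay: float = 0.8
    mixture: tuple[float, float, float, float] = (0.985, 0.005, 0.005, 0.005)
    effect_sd1: float | None = None
    effect_sd2: float | None = None
    shared_effect_corr: float = 1.0
    n1: int = 100_000
    n2: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        mix = np.asarray(self.mixture, dtype=float)
        if mix.shape != (4,):
            raise ValueError("mixture must have four components")
        if (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("mixture entries must be nonnegative and sum to 1")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("sample sizes must be positive")
        if self.m_snps % self.block_size != 0:
            raise ValueError("m_snps must be divisible by block_size")
        if not 0.0 <= self.within_block_decay < 1.0:
            raise ValueError("within_block_decay must lie in [0, 1)")
        if not -1.0 <= self.shared_effect_corr <= 1.0:
            raise ValueError("shared_effect_corr must lie in [-1, 1]")


def calibrate_effect_sd(
    target_mean_chi2: float,
    n: int,
    pi_causal: float,
    decay: float,
    block_size: int,
) -> float:
    """Effect SD giving approximately the target GWAS mean chi-square.

    Under the infinitesimal model E[z_i^2] = 1 + N * sd^2 * pi_causal * c,
    where c = sum_j corr(i, j)^2 accounts for LD smearing of causal effects
    onto neighbours; for an interior SNP of an AR(1) block
    c ≈ (1 + r²) / (1 − r²).
    """
    if target_mean_chi2 <= 1.0:
        raise ValueError("target mean chi-square must exceed 1")
    if pi_causal <= 0:
        raise ValueError("pi_causal must be positive")
    r2 = decay**2
    if block_size > 1 and r2 < 1:
        c_ld = (1 + r2) / (1 - r2)
    else:
        c_ld = 1.0
    return float(np.sqrt((target_mean_chi2 - 1.0) / (n * pi_causal * c_ld)))


def _block_layout(m_snps: int, block_size: int):
    """Chrom labels and 1-based positions for the block-tiled genome."""
    n_blocks = m_snps // block_size
    chroms = np.empty(m_snps, dtype=object)
    pos = np.empty(m_snps, dtype=np.int64)
    next_pos = np.ones(_N_CHROMS, dtype=np.int64)
    for b in range(n_blocks):
        c = b % _N_CHROMS
        start = next_pos[c]
        idx = slice(b * block_size, (b + 1) * block_size)
        chroms[idx] = str(c + 1)
        pos[idx] = start + _SNP_SPACING * np.arange(block_size)
        next_pos[c] = pos[idx][-1] + _BLOCK_GAP
    return chroms, pos


def simulate_bivariate_gwas(config: SimulationConfig):
    """Simulate paired GWAS summary statistics with planted pleiotropy.

    Returns ``(sumstats1, sumstats2, ld_panel, truth)``.  Sumstats are
    DataFrames with columns SNP, CHR, BP, A1, A2, Z, P, N sorted by
    (CHR, BP); truth carries per-SNP causal class, true effects and the
    block index.  Two-sided p-values: p = 2 * Phi(-|z|), floored at 1e-300.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    m, bs = cfg.m_snps, cfg.block_size
    n_blocks = m // bs
    r = cfg.within_block_decay

    # Causal classes are planted blockwise: each LD block is dealt one
    # non-null class (trait1_only / trait2_only / shared) with probability
    # proportional to the mixture, and SNPs inside it are causal of that
    # class with probability pi10+pi01+pi11.  Per-SNP class marginals
    # equal the mixture exactly, but distinct non-null classes never
    # co-locate within a block — so under pi11=0 there is no cross-trait
    # LD confounding and a conjFDR discovery implies a shared block.
    pi10, pi01, pi11 = cfg.mixture[1], cfg.mixture[2], cfg.mixture[3]
    pi_causal = pi10 + pi01 + pi11
    classes = np.zeros(m, dtype=np.int64)
    if pi_causal > 0:
        block_class = rng.choice(
            [1, 2, 3], size=n_blocks, p=np.array([pi10, pi01, pi11]) / pi_causal
        )
        causal = rng.random(m) < pi_causal
        classes = np.where(causal, np.repeat(block_class, bs), 0)
    sd1 = cfg.effect_sd1
    sd2 = cfg.effect_sd2
    pi_c1 = cfg.mixture[1] + cfg.mixture[3]
    pi_c2 = cfg.mixture[2] + cfg.mixture[3]
    if sd1 is None:
        sd1 = calibrate_effect_sd(1.6, cfg.n1, max(pi_c1, 1e-12), r, bs) if pi_c1 > 0 else 0.0
    if sd2 is None:
        sd2 = calibrate_effect_sd(1.6, cfg.n2, max(pi_c2, 1e-12), r, bs) if pi_c2 > 0 else 0.0

    active1 = (classes == 1) | (classes == 3)
    active2 = (classes == 2) | (classes == 3)
    raw1 = rng.standard_normal(m)
    raw2 = rng.standard_normal(m)
    # shared causals share a correlated standardized effect (the same
    # variant drives both traits); trait-specific effects are independent
    rho = cfg.shared_effect_corr
    shared = classes == 3
    raw2 = np.where(shared, rho * raw1 + np.sqrt(max(0.0, 1 - rho**2)) * raw2, raw2)
    beta1 = np.where(active1, (sd1 or 0.0) * raw1, 0.0)
    beta2 = np.where(active2, (sd2 or 0.0) * raw2, 0.0)

    # block correlation matrix and its Cholesky factor (shared by all blocks)
    ii = np.arange(bs)
    corr = r ** np.abs(ii[:, None] - ii[None, :]) if r > 0 else np.eye(bs)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(bs))

    def z_for(beta: np.ndarray, n: int, noise: np.ndarray) -> np.ndarray:
        mean = corr @ (np.sqrt(n) * beta.reshape(n_blocks, bs).T)
        return (mean + chol @ noise).T.ravel()

    noise1 = rng.standard_normal((bs, n_blocks))
    noise2 = rng.standard_normal((bs, n_blocks))
    z1 = z_for(beta1, cfg.n1, noise1)
    z2 = z_for(beta2, cfg.n2, noise2)

    chroms, pos = _block_layout(m, bs)
    snp_ids = np.array([f"rs{i + 1:07d}" for i in range(m)])

    def table(z: np.ndarray, n: int) -> pd.DataFrame:
        p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300)
        df = pd.DataFrame(
            {
                "SNP": snp_ids,
                "CHR": chroms,
                "BP": pos,
                "A1": "A",
                "A2": "G",
                "Z": z,
                "P": p,
                "N": n,
            }
        )
        return df.sort_values(["CHR", "BP"], key=_chrom_sort_key, kind="stable").reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": pos,
            "causal_class": np.array(CAUSAL_CLASSES)[classes],
            "beta1": beta1,
            "beta2": beta2,
            "block": np.repeat(np.arange(n_blocks), bs),
        }
    )
    panel = BlockLdPanel(
        snp_ids=snp_ids, block=np.repeat(np.arange(n_blocks), bs),
        index_in_block=np.tile(np.arange(bs), n_blocks), decay=r,
    )
    return table(z1, cfg.n1), table(z2, cfg.n2), panel, truth


def _chrom_sort_key(col: pd.Series) -> pd.Series:
    if col.name in ("CHR", "chrom"):
        return col.map(lambda c: int(c) if str(c).isdigit() else 10_000 + sum(map(ord, str(c))))
    return col


# ---------------------------------------------------------------------------
# expression atlas


@dataclass
class ExpressionBundle:
    """AHBA-style expression inputs: probe intensities, background calls,
    probe annotation and spatially localized sample metadata."""

    probe_expr: pd.DataFrame        # probes x samples, log2 intensity
    above_background: pd.DataFrame  # probes x samples, bool
    probe_to_gene: pd.Series        # probe id -> gene symbol
    sample_meta: pd.DataFrame       # sample_id, donor, structure_class, region, x, y, z


@dataclass
class BrainSampleMap:
    """Per-sample target map values and coordinates (the planted truth)."""

    coords: np.ndarray  # n_samples x 3, mm
    values: np.ndarray  # n_samples


def knn_smooth_matrix(coords: np.ndarray, k: int) -> np.ndarray:
    """Row-stochastic k-nearest-neighbour exponential smoothing operator.

    Weight of neighbour j of point i: exp(-d_ij / dbar_i) over the k nearest,
    dbar_i the mean of those distances; rows normalized to sum 1.
    """
    from scipy.spatial import cKDTree

    n = len(coords)
    k = min(k, n - 1)
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=k + 1)  # includes self at distance 0
    dbar = np.maximum(dist[:, 1:].mean(axis=1, keepdims=True), 1e-12)
    w = np.exp(-dist / dbar)
    mat = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k + 1)
    np.add.at(mat, (rows, idx.ravel()), w.ravel())
    mat /= mat.sum(axis=1, keepdims=True)
    return mat


def simulate_expression_atlas(
    n_samples: int = 200,
    n_genes: int = 2_000,
    n_signal_genes: int = 30,
    signal_strength: float = 2.0,
    autocorr_length: int = 20,
    donors: int = 2,
    n_regions: int = 12,
    probe_noise_sd: tuple[float, float] = (0.2, 1.0),
    background_rate: float = 0.95,
    poor_probe_frac: float = 0.10,
    signal_genes: np.ndarray | None = None,
    seed: int = 0,
):
    """Spatially autocorrelated expression with planted map-correlated genes.

    Samples live in a 100-mm box; spatial fields are k-nearest-neighbour
    kernel-smoothed i.i.d. noise (kernel size = ``autocorr_length``
    neighbours).  Signal genes add ``signal_strength`` x the target map.
    Every gene gets two probes — one clean and one noisy (noise SDs from
    ``probe_noise_sd``) — so differential-stability selection has work to
    do, and a random subset of probes gets a low above-background rate so
    the background filter has work to do.

    ``signal_genes`` (explicit gene indices) overrides the random draw of
    ``n_signal_genes`` — used to plant imaging signal at genes tied to
    another layer's ground truth.

    Returns ``(bundle, brain_map, truth_signal_genes)``.
    """
    if signal_genes is None and n_signal_genes > n_genes:
        raise ValueError("n_signal_genes must not exceed n_genes")
    if donors < 1 or n_samples <= 0 or n_genes <= 0:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)

    coords = rng.uniform(0.0, 100.0, size=(n_samples, 3))
    smooth = knn_smooth_matrix(coords, autocorr_length)
    target = smooth @ rng.standard_normal(n_samples)
    target = (target - target.mean()) / target.std()

    gene_fields = smooth @ rng.standard_normal((n_samples, n_genes))
    gene_fields = (gene_fields - gene_fields.mean(0)) / gene_fields.std(0)
    gene_expr = gene_fields + 0.5 * rng.standard_normal((n_samples, n_genes))
    if signal_genes is not None:
        signal_idx = np.asarray(signal_genes, dtype=int)
    else:
        signal_idx = rng.choice(n_genes, size=n_signal_genes, replace=False)
    gene_expr[:, signal_idx] += signal_strength * target[:, None]

    genes = np.array([f"GENE{i + 1:05d}" for i in range(n_genes)])
    # two probes per gene: clean then noisy
    lo, hi = probe_noise_sd
    probe_ids, probe_gene, rowstack = [], [], []
    base = 8.0 + gene_expr.T  # genes x samples, log2-intensity-like
    for j, g in enumerate(genes):
        for tag, sd in (("a", lo), ("b", hi)):
            probe_ids.append(f"P{j + 1:05d}{tag}")
            probe_gene.append(g)
            rowstack.append(base[j] + sd * rng.standard_normal(n_samples))
    probe_expr = pd.DataFrame(
        np.vstack(rowstack), index=probe_ids,
        columns=[f"S{i + 1:04d}" for i in range(n_samples)],
    )

    # above-background calls: most probes nearly always called, a
    # configurable fraction poorly detected (exercises the filter)
    n_probes = len(probe_ids)
    rate = np.full(n_probes, background_rate)
    poor = rng.random(n_probes) < poor_probe_frac
    rate[poor] = rng.uniform(0.05, 0.45, size=poor.sum())
    above = rng.random((n_probes, n_samples)) < rate[:, None]
    above_background = pd.DataFrame(above, index=probe_ids, columns=probe_expr.columns)

    # regions: nearest of n_regions random centers; donors round-robin so
    # every donor covers every region with high probability
    centers = rng.uniform(0.0, 100.0, size=(n_regions, 3))
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    region = d2.argmin(axis=1)
    donor = np.arange(n_samples) % donors
    struct = np.array(["cortex", "subcortex", "cerebellum"])[region % 3]
    sample_meta = pd.DataFrame(
        {
            "sample_id": probe_expr.columns,
            "donor": [f"D{d + 1}" for d in donor],
            "structure_class": struct,
            "region": [f"R{r + 1:02d}" for r in region],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
        }
    )
    bundle = ExpressionBundle(
        probe_expr=probe_expr,
        above_background=above_background,
        probe_to_gene=pd.Series(probe_gene, index=probe_ids, name="gene"),
        sample_meta=sample_meta,
    )
    return bundle, BrainSampleMap(coords=coords, values=target), set(genes[signal_idx])


# ---------------------------------------------------------------------------
# study peak tables


def make_truth_map(
    shape=(24, 24, 24),
    voxel_mm: float = 4.0,
    blobs=(((48.0, 48.0, 48.0), 12.0, -6.0),),
):
    """Ground-truth effect map: sum of Gaussian blobs ((center_mm, sigma_mm,
    amplitude)) on a grid with the given shape and isotropic voxel size.
    Returns (grid, affine)."""
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    mm = ijk * voxel_mm
    grid = np.zeros(shape)
    for center, sigma, amp in blobs:
        d2 = ((mm - np.asarray(center)) ** 2).sum(-1)
        grid += amp * np.exp(-d2 / (2.0 * sigma**2))
    return grid, affine


def simulate_study_peaks(
    truth_map: np.ndarray,
    affine: np.ndarray,
    n_studies: int = 20,
    peaks_per_study: int = 1,
    jitter_mm: float = 4.0,
    t_range: tuple[float, float] = (3.0, 8.0),
    n_range: tuple[int, int] = (20, 60),
    seed: int = 0,
) -> pd.DataFrame:
    """Sample per-study peak tables from a ground-truth atrophy map.

    Peaks are the strongest local extrema of |truth|, jittered uniformly by
    up to ``jitter_mm`` per axis; t magnitudes drawn in ``t_range`` and
    signed by the truth map; group sizes drawn in ``n_range``.
    """
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be nonnegative")
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    mag = np.abs(truth_map)
    localmax = (ndimage.maximum_filter(mag, size=3) == mag) & (mag > 0.05 * mag.max())
    coords_ijk = np.argwhere(localmax)
    order = np.argsort(-mag[tuple(coords_ijk.T)])
    coords_ijk = coords_ijk[order]
    if len(coords_ijk) == 0:
        raise ValueError("truth map has no local extremum")
    peaks_mm = (affine[:3, :3] @ coords_ijk.T).T + affine[:3, 3]
    signs = np.sign(truth_map[tuple(coords_ijk.T)])

    rows = []
    for s in range(n_studies):
        k = min(peaks_per_study, len(peaks_mm))
        for j in range(k):
            jit = rng.uniform(-jitter_mm, jitter_mm, size=3) if jitter_mm > 0 else 0.0
            xyz = peaks_mm[j] + jit
            t = signs[j] * rng.uniform(*t_range)
            n1 = int(rng.integers(n_range[0], n_range[1] + 1))
            n2 = int(rng.integers(n_range[0], n_range[1] + 1))
            rows.append((f"study{s + 1:03d}", *xyz, t, n1, n2))
    return pd.DataFrame(rows, columns=["study_id", "x", "y", "z", "t", "n1", "n2"])


def block_gene_annotation(truth: pd.DataFrame) -> pd.DataFrame:
    """One gene per LD block, spanning the block's bp range.

    Ties the GWAS genome to a gene universe (GENE00001..GENE{n_blocks}) so
    positional mapping of candidate SNPs lands on the gene of their block
    — the coherent truth layer for end-to-end multi-omics runs.
    """
    rows = []
    for b, sub in truth.groupby("block"):
        rows.append(
            {
                "gene": f"GENE{int(b) + 1:05d}",
                "chrom": str(sub["chrom"].iloc[0]),
                "start": int(sub["pos"].min()),
                "end": int(sub["pos"].max()),
                "strand": "+",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene annotation, gene sets, PPI


def simulate_annotations(
    n_genes: int = 300,
    genes_per_chrom: int = 50,
    gene_length: int = 5_000,
    spacing: int = 1_000,
    n_sets: int = 20,
    set_size_range: tuple[int, int] = (10, 40),
    planted_sets: dict[str, set[str]] | None = None,
    ppi_modules: tuple[int, ...] = (8,),
    ppi_module_p: float = 0.8,
    ppi_background_p: float = 0.02,
    seed: int = 0,
):
    """Gene annotation, gene-set collection and a STRING-style PPI network.

    Genes are tiled without overlap on synthetic chromosomes (1-based
    inclusive intervals, fixed gap ``spacing``); sets are uniform samples
    plus any planted sets; the PPI has planted dense modules on a sparse
    degree-heterogeneous background, scores in 0-1000.

    Returns ``(annotation_df, gene_sets_dict, ppi_edges_df)``.
    """
    if spacing < 0:
        raise ValueError("spacing must be nonnegative")
    if n_genes <= 0 or gene_length <= 0:
        raise ValueError("sizes must be positive")
    rng = np.random.default_rng(seed)

    genes = np.array([f"GENE{i + 1:05d}" for i in range(n_genes)])
    rows = []
    for i, g in enumerate(genes):
        chrom = str(i // genes_per_chrom + 1)
        k = i % genes_per_chrom
        start = 1 + k * (gene_length + spacing)
        rows.append((g, chrom, start, start + gene_length - 1, "+" if i % 2 == 0 else "-"))
    annotation = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])

    gene_sets: dict[str, set[str]] = {}
    for s in range(n_sets):
        size = int(rng.integers(set_size_range[0], set_size_range[1] + 1))
        gene_sets[f"SET{s + 1:03d}"] = set(rng.choice(genes, size=size, replace=False))
    if planted_sets:
        gene_sets.update({k: set(v) for k, v in planted_sets.items()})

    # PPI: Chung-Lu-style background with heavy-tailed expected degrees,
    # plus dense planted modules at high score
    w = rng.pareto(2.5, size=n_genes) + 1.0
    w *= np.sqrt(ppi_background_p * n_genes) / w.mean()
    edges = []
    iu, ju = np.triu_indices(n_genes, k=1)
    pij = np.minimum(1.0, w[iu] * w[ju] / (w.sum()))
    keep = rng.random(len(iu)) < pij
    for a, b in zip(iu[keep], ju[keep]):
        edges.append((genes[a], genes[b], int(rng.integers(400, 800))))
    used = 0
    for msize in ppi_modules:
        members = genes[used:used + msize]
        used += msize
        for a in range(msize):
            for b in range(a + 1, msize):
                if rng.random() < ppi_module_p:
                    edges.append((members[a], members[b], int(rng.integers(800, 1000))))
    ppi = pd.DataFrame(edges, columns=["protein1", "protein2", "combined_score"])
    ppi = ppi.drop_duplicates(subset=["protein1", "protein2"]).reset_index(drop=True)
    return annotation, gene_sets, ppi
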