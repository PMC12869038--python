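"""Conditional and conjunctional FDR on paired GWAS summary statistics.

The conditional FDR (condFDR) of a SNP for the primary trait given the
secondary trait re-ranks primary-trait p-values within strata of the
secondary trait's p-values.  The empirical-Bayes estimator used here is

    cFDR(a | b) = pi0 * a * #{P2 <= b} / #{P1 <= a and P2 <= b},

clamped to <= 1, evaluated exactly at every SNP's own (a, b) = (p1, p2)
via bivariate dominance counting (a Fenwick tree over secondary ranks,
O(M log M)).  The conjunctional FDR (conjFDR) — an upper bound on the FDR
of joint association — is the larger of the two mutual condFDR values;
SNPs with conjFDR < 0.05 are flagged significant.

Complex-LD regions (extended MHC, 8p23.1) are excluded up front as in
standard cross-trait condFDR practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionRegion",
    "DEFAULT_EXCLUSION_REGIONS",
    "exclude_regions",
    "cond_fdr",
    "conj_fdr",
    "stratified_qq",
]

P_FLOOR = 1e-300


@dataclass(frozen=True)
class ExclusionRegion:
    """1-based inclusive genomic interval to drop before condFDR."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")


# extended MHC and the 8p23.1 inversion region
DEFAULT_EXCLUSION_REGIONS = (
    ExclusionRegion("6", 25_119_106, 33_854_733),
    ExclusionRegion("8", 7_242_715, 12_483_982),
)


def _norm_chrom(c) -> str:
    s = str(c).strip()
    return s[3:] if s.lower().startswith("chr") else s


def exclude_regions(sumstats: pd.DataFrame, regions=DEFAULT_EXCLUSION_REGIONS) -> pd.DataFrame:
    """Drop SNPs falling inside any region (chrom match, start <= pos <= end)."""
    if len(sumstats) == 0:
        return sumstats.copy()
    chrom = sumstats["CHR"].map(_norm_chrom)
    pos = sumstats["BP"].to_numpy()
    drop = np.zeros(len(sumstats), dtype=bool)
    for reg in regions:
        drop |= (chrom == _norm_chrom(reg.chrom)).to_numpy() & (pos >= reg.start) & (pos <= reg.end)
    return sumstats.loc[~drop].reset_index(drop=True)


class _Fenwick:
    """Binary indexed tree over 1..n for prefix counts."""

    def __init__(self, n: int) -> None:
        self.n = n
        self.t = [0] * (n + 1)

    def add(self, i: int) -> None:
        while i <= self.n:
            self.t[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        s = 0
        while i > 0:
            s += self.t[i]
            i -= i & (-i)
        return s


def _dominance_counts(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """n_joint[i] = #{j : p1_j <= p1_i and p2_j <= p2_i} (self included)."""
    m = len(p1)
    # equal p2 values must map to the same key so <= counts handle ties exactly
    uniq, inv = np.unique(p2, return_inverse=True)
    key2 = inv + 1  # 1-based dense rank
    tree = _Fenwick(len(uniq))
    out = np.empty(m, dtype=np.int64)
    order1 = np.lexsort((key2, p1))
    i = 0
    while i < m:
        j = i
        while j < m and p1[order1[j]] == p1[order1[i]]:
            j += 1
        for k in range(i, j):  # insert the whole tied-p1 group first
            tree.add(int(key2[order1[k]]))
        for k in range(i, j):
            out[order1[k]] = tree.prefix(int(key2[order1[k]]))
        i = j
    return out


def cond_fdr(
    p_primary: np.ndarray,
    p_secondary: np.ndarray,
    pi0: float = 1.0,
    monotonize: bool = False,
) -> np.ndarray:
    """Per-SNP empirical condFDR of the primary trait given the secondary.

    Exact estimator evaluated at each SNP's own p-value pair.  ``pi0`` is
    the assumed null proportion (1 is conservative and the default).  With
    ``monotonize`` the values are made nondecreasing in p1 among SNPs
    sharing the same p2 (cumulative max along the p1 order); off by
    default so that conditioning on p2 <= 1 reduces *exactly* to the
    unconditional empirical FDR a*M/rank(a).
    """
    p1 = np.asarray(p_primary, dtype=float)
    p2 = np.asarray(p_secondary, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("p-value vectors must be aligned")
    for name, p in (("primary", p1), ("secondary", p2)):
        if (p <= 0).any():
            warnings.warn(f"{name} p-values at or below 0 floored to {P_FLOOR}")
        if (p > 1).any():
            raise ValueError(f"{name} p-values above 1")
    p1 = np.clip(p1, P_FLOOR, 1.0)
    p2 = np.clip(p2, P_FLOOR, 1.0)

    n2 = np.searchsorted(np.sort(p2), p2, side="right")  # #{P2 <= b}
    n12 = _dominance_counts(p1, p2)
    cfdr = np.minimum(1.0, pi0 * p1 * n2 / n12)
    if monotonize:
        order = np.lexsort((p2, p1))
        for val in np.unique(p2):
            sel = order[p2[order] == val]
            cfdr[sel] = np.maximum.accumulate(cfdr[sel])
    return cfdr


def conj_fdr(
    sumstats1: pd.DataFrame,
    sumstats2: pd.DataFrame,
    pi0: float = 1.0,
    sig_threshold: float = 0.05,
) -> pd.DataFrame:
    """Conjunctional FDR over the SNPs shared by two summary-statistics tables.

    Returns one row per shared SNP: snp, chr, bp, p1, p2, cfdr12 (trait 1
    given 2), cfdr21, conjfdr = max of the two, and a strict
    ``conjfdr < sig_threshold`` significance flag.
    """
    s1 = sumstats1.set_index("SNP")
    s2 = sumstats2.set_index("SNP")
    common = s1.index.intersection(s2.index)
    if len(common) == 0:
        raise ValueError("no SNPs shared between the two tables")
    s1 = s1.loc[common]
    s2 = s2.loc[common]
    p1 = s1["P"].to_numpy(dtype=float)
    p2 = s2["P"].to_numpy(dtype=float)
    cfdr12 = cond_fdr(p1, p2, pi0=pi0)
    cfdr21 = cond_fdr(p2, p1, pi0=pi0)
    conj = np.maximum(cfdr12, cfdr21)
    out = pd.DataFrame(
        {
            "SNP": common,
            "CHR": s1["CHR"].to_numpy(),
            "BP": s1["BP"].to_numpy(),
            "p1": p1,
            "p2": p2,
            "cfdr12": cfdr12,
            "cfdr21": cfdr21,
            "conjfdr": conj,
            "significant": conj < sig_threshold,
        }
    )
    return out.sort_values(["CHR", "BP"], key=_qq_chrom_key, kind="stable").reset_index(drop=True)


def _qq_chrom_key(col: pd.Series) -> pd.Series:
    if col.name == "CHR":
        return col.map(lambda c: int(c) if str(c).isdigit() else 10_000 + sum(map(ord, str(c))))
    return col


def stratified_qq(
    p1: np.ndarray,
    p2: np.ndarray,
    strata: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001),
) -> pd.DataFrame:
    """Stratified Q-Q summary of p1 conditioned on p2 thresholds.

    For each stratum threshold t, SNPs with p2 < t (all SNPs when t >= 1,
    so that stratum 1 reproduces the unconditional curve) contribute
    observed sorted -log10 p1 against expected -log10 of uniform order
    statistics k/(n+1).  Long-format rows: stratum, n_snps, expected,
    observed; empty strata yield a single row with count 0 and NaNs.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("p-value vectors must be aligned")
    frames = []
    for t in strata:
        mask = np.ones_like(p2, dtype=bool) if t >= 1.0 else (p2 < t)
        n = int(mask.sum())
        if n == 0:
            frames.append(pd.DataFrame({"stratum": [t], "n_snps": [0],
                                        "expected": [np.nan], "observed": [np.nan]}))
            continue
        obs = -np.log10(np.sort(p1[mask]))[::-1]
        exp = -np.log10(np.arange(1, n + 1) / (n + 1.0))
        frames.append(pd.DataFrame({"stratum": t, "n_snps": n, "expected": exp, "observed": obs}))
    return pd.concat(frames, ignore_index=True)
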