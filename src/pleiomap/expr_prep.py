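"""Microarray expression preprocessing (AHBA-style).

Pipeline: drop probes called below background in more than half of the
samples; represent each gene by its most differentially stable probe
(highest mean inter-donor Spearman correlation of region-averaged
profiles); normalize with the scaled robust sigmoid (SRS) per gene within
each donor, then again within each donor x structure class (cortex /
subcortex / cerebellum), yielding a samples x genes matrix in [0, 1].

Quartiles use linear interpolation (type 7), the numpy default.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import ExpressionBundle

__all__ = [
    "filter_probes_background",
    "differential_stability",
    "select_probes",
    "srs_normalize",
    "build_expression_matrix",
]

log = logging.getLogger(__name__)


def filter_probes_background(bundle: ExpressionBundle, min_frac: float = 0.5) -> list[str]:
    """Probes retained: fraction of samples above background >= min_frac.

    Exclusion requires strictly more than (1 - min_frac) of the samples
    below background, so a probe above background in exactly half of the
    samples is kept at the default.
    """
    if bundle.above_background.size == 0:
        raise ValueError("empty bundle")
    frac = bundle.above_background.mean(axis=1)
    return list(frac.index[frac >= min_frac])


def differential_stability(bundle: ExpressionBundle, probes: list[str] | None = None) -> pd.Series:
    """Differential stability per probe.

    DS(probe) = mean over donor pairs of the Spearman correlation between
    the two donors' region-averaged expression vectors, over regions both
    donors sampled.  With a single donor the fallback is the probe's mean
    intensity (logged), which preserves the argmax-selection interface.
    """
    expr = bundle.probe_expr if probes is None else bundle.probe_expr.loc[probes]
    meta = bundle.sample_meta.set_index("sample_id")
    donors = sorted(meta["donor"].unique())
    if len(donors) < 2:
        log.warning("fewer than two donors: DS falls back to mean intensity")
        return expr.mean(axis=1)

    # region-averaged profile per donor: probes x regions
    profiles = {}
    for d in donors:
        cols = meta.index[meta["donor"] == d]
        sub = expr[cols]
        profiles[d] = sub.T.groupby(meta.loc[cols, "region"]).mean().T

    ds = np.zeros(len(expr))
    n_pairs = 0
    for i in range(len(donors)):
        for j in range(i + 1, len(donors)):
            a, b = profiles[donors[i]], profiles[donors[j]]
            shared = a.columns.intersection(b.columns)
            if len(shared) < 3:
                continue
            rho = _rowwise_spearman(a[shared].to_numpy(), b[shared].to_numpy())
            ds += rho
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no donor pair shares at least three regions")
    return pd.Series(ds / n_pairs, index=expr.index, name="ds")


def _rowwise_spearman(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ra = stats.rankdata(a, axis=1)
    rb = stats.rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / den, 0.0)
    return out


def select_probes(bundle: ExpressionBundle, probes: list[str]) -> pd.Series:
    """One probe per gene: the argmax-DS probe, ties to the lowest probe id.

    Returns a Series gene -> probe id.
    """
    ds = differential_stability(bundle, probes)
    table = pd.DataFrame({"ds": ds, "gene": bundle.probe_to_gene.loc[ds.index]})
    table = table.sort_index()  # lowest probe id wins ties
    best = table.sort_values("ds", kind="stable", ascending=False).groupby("gene").head(1)
    return best.reset_index().set_index("gene")["index"].rename("probe").sort_index()


def srs_normalize(x: np.ndarray) -> np.ndarray:
    """Scaled robust sigmoid: sigmoid((x - median)/(IQR/1.35)), then
    min-max rescaled to [0, 1].  Zero IQR yields a constant 0.5 with a
    warning."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    med = np.median(x)
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        warnings.warn("zero IQR: SRS output set to constant 0.5")
        return np.full_like(x, 0.5)
    from scipy.special import expit

    s = expit((x - med) / (iqr / 1.35))
    smin, smax = s.min(), s.max()
    if smax == smin:
        return np.full_like(x, 0.5)
    return (s - smin) / (smax - smin)


def build_expression_matrix(
    bundle: ExpressionBundle,
    min_frac: float = 0.5,
) -> pd.DataFrame:
    """Filtered, probe-selected, doubly SRS-normalized samples x genes matrix.

    SRS is applied per gene across each donor's samples, then a second
    pass per gene within each (donor, structure class) group.  Sample
    order follows ``bundle.sample_meta``; the returned frame has
    sample_id as index and gene symbols as columns, values in [0, 1].
    """
    meta = bundle.sample_meta
    if meta["structure_class"].isna().any():
        raise ValueError("every sample needs a structure class")
    kept = filter_probes_background(bundle, min_frac=min_frac)
    gene_probe = select_probes(bundle, kept)
    mat = bundle.probe_expr.loc[gene_probe.to_numpy()].T  # samples x genes
    mat.columns = gene_probe.index
    mat.index.name = "sample_id"
    mat = mat.loc[meta["sample_id"]]

    values = mat.to_numpy(dtype=float)
    donor = meta["donor"].to_numpy()
    group2 = (meta["donor"] + "|" + meta["structure_class"]).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant slices within small groups
        for grouping in (donor, group2):
            for g in np.unique(grouping):
                rows = grouping == g
                if rows.sum() < 2:
                    values[rows] = 0.5
                    continue
                values[rows] = np.apply_along_axis(srs_normalize, 0, values[rows])
    return pd.DataFrame(values, index=mat.index, columns=mat.columns)
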