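"""Gene-set integration: intersections, enrichment, PPI statistics, and
the end-to-end synthetic pipeline runner.

The convergence step intersects the imaging-transcriptomic gene set with
each trait pair's pleiotropy-derived gene set, then takes the core
intersection across all traits.  Enrichment is an upper-tail
hypergeometric test per gene set with Benjamini-Hochberg adjustment.
PPI statistics compare the observed edge count of the query-induced
subgraph with a degree-configuration (Chung-Lu) expectation under a
Poisson tail, and rank nodes by betweenness centrality.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "harmonize",
    "intersect_gene_sets",
    "hypergeom_enrichment",
    "ppi_subnetwork_stats",
    "run_pipeline",
]


def harmonize(genes) -> set[str]:
    """Uppercase, whitespace-stripped, version-suffix-free gene symbols."""
    out = set()
    for g in genes:
        s = str(g).strip().upper()
        if "." in s and s.rsplit(".", 1)[1].isdigit():
            s = s.rsplit(".", 1)[0]
        if s:
            out.add(s)
    return out


def intersect_gene_sets(gmv_genes, pleio_gene_sets: dict[str, set]):
    """Per-trait overlaps with the imaging gene set, their core, and Venn counts.

    Returns ``(overlaps, core, venn)``: ``overlaps[trait]`` is
    gmv ∩ pleio[trait]; ``core`` is the intersection of all overlaps; and
    ``venn`` maps each binary membership pattern over the trait overlaps
    (e.g. '10110', one digit per trait in sorted order) to its exclusive
    region count.  Region counts sum to |union of the overlaps|.
    """
    gmv = harmonize(gmv_genes)
    if not gmv:
        warnings.warn("empty imaging gene set: all overlaps empty")
    traits = sorted(pleio_gene_sets)
    overlaps = {t: gmv & harmonize(pleio_gene_sets[t]) for t in traits}
    core = set.intersection(*overlaps.values()) if overlaps else set()
    venn: dict[str, int] = {}
    union = set().union(*overlaps.values()) if overlaps else set()
    for pattern in range(1, 2 ** len(traits)):
        bits = format(pattern, f"0{len(traits)}b")
        inside = [t for t, b in zip(traits, bits) if b == "1"]
        outside = [t for t, b in zip(traits, bits) if b == "0"]
        region = set(union)
        for t in inside:
            region &= overlaps[t]
        for t in outside:
            region -= overlaps[t]
        venn[bits] = len(region)
    return overlaps, core, venn


def hypergeom_enrichment(
    query,
    collection: dict[str, set],
    universe,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment with BH adjustment.

    With universe size N, set size K, query size n and overlap x the
    p-value is P(X >= x) for X ~ Hypergeom(N, K, n).  Query genes outside
    the universe are dropped (counted in the ``n_dropped`` attribute).
    Rows are sorted by (q, p).
    """
    uni = harmonize(universe)
    q = harmonize(query)
    dropped = len(q - uni)
    if dropped:
        warnings.warn(f"{dropped} query genes outside the universe dropped")
    q &= uni
    if len(uni) < len(q):
        raise ValueError("universe smaller than query")
    n, N = len(q), len(uni)
    rows = []
    for name in sorted(collection):
        members = harmonize(collection[name]) & uni
        K = len(members)
        x = len(q & members)
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "N": N, "K": K, "n": n, "x": x, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["q"] < fdr_alpha
        table = table.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
    table.attrs["n_dropped"] = dropped
    return table


def ppi_subnetwork_stats(
    genes,
    edges: pd.DataFrame,
    score_threshold: float = 0.4,
    null: str = "degree",
) -> dict:
    """Observed vs expected edges and betweenness for a query subnetwork.

    ``edges`` is STRING-style (protein1, protein2, combined_score);
    scores above 1 are taken to be on the 0-1000 scale and divided by
    1000.  Edges below ``score_threshold`` are dropped from the
    background.  Expected edges under the degree-configuration null:
    m_exp = sum_{i<j in query} min(1, k_i k_j / (2 E)); the density null
    (``null='density'``) uses C(n,2) times the background density.
    p_edges = P(Poisson(m_exp) >= m_obs).  Betweenness is the unnormalized
    shortest-path count on the unweighted query subgraph.
    """
    scores = edges["combined_score"].astype(float)
    if scores.max() > 1.0:
        scores = scores / 1000.0
    keep = scores >= score_threshold
    g = nx.Graph()
    g.add_edges_from(
        (str(a).strip().upper(), str(b).strip().upper())
        for a, b in edges.loc[keep.to_numpy(), ["protein1", "protein2"]].itertuples(index=False)
    )
    query = sorted(harmonize(genes))
    missing = [q for q in query if q not in g]
    sub = g.subgraph([q for q in query if q in g])
    m_obs = sub.number_of_edges()

    e_total = g.number_of_edges()
    deg = dict(g.degree())
    if null == "degree":
        m_exp = 0.0
        present = [q for q in query if q in g]
        for a, b in combinations(present, 2):
            m_exp += min(1.0, deg[a] * deg[b] / (2.0 * e_total)) if e_total else 0.0
    elif null == "density":
        n_bg = g.number_of_nodes()
        density = 2.0 * e_total / (n_bg * (n_bg - 1)) if n_bg > 1 else 0.0
        m_exp = 0.5 * len(query) * (len(query) - 1) * density
    else:
        raise ValueError("null must be 'degree' or 'density'")
    p_edges = float(stats.poisson.sf(m_obs - 1, m_exp)) if m_exp > 0 else (1.0 if m_obs == 0 else 0.0)

    betweenness = {q: 0.0 for q in query}
    betweenness.update(nx.betweenness_centrality(nx.Graph(sub), normalized=False))
    return {
        "nodes": query,
        "missing": missing,
        "m_obs": m_obs,
        "m_exp": m_exp,
        "p_edges": p_edges,
        "betweenness": betweenness,
    }


# ---------------------------------------------------------------------------
# pipeline runner

STAGES = ("simulate", "meta", "expr-prep", "pls", "conjfdr", "loci", "integrate")


def _hash_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def run_pipeline(config: dict, outdir: str | Path, seed: int | None = None) -> dict:
    """End-to-end synthetic run: simulate inputs, execute the requested
    stages in dependency order, write stage outputs plus a JSON manifest.

    ``config`` keys (all optional): ``stages`` (list, default all),
    ``gwas`` (SimulationConfig overrides), ``atlas``/``peaks``/
    ``annotations`` (generator overrides), and thresholds (``conjfdr_sig``
    0.05, ``cand_threshold`` 0.10, ``indep_r2`` 0.6, ``lead_r2`` 0.1,
    ``merge_kb`` 250, ``fwe`` 0.05, ``var_threshold`` 0.2, ``bonf`` 0.05,
    ``string_score`` 0.4).  Returns a report dict; the manifest and TSV
    outputs land in ``outdir``.
    """
    from . import expr_prep, gmv_meta, loci_map, pleio_fdr, pls_assoc, synthgen

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    stages = list(config.get("stages", STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    report: dict = {"seed": seed, "stages": stages}
    manifest: dict = {"seed": seed, "stages": stages, "config": {k: v for k, v in config.items() if k != "stages"}}

    gwas_over = dict(config.get("gwas", {}))
    gwas_cfg = synthgen.SimulationConfig(**{"seed": seed, **gwas_over})
    need_gwas = any(s in stages for s in ("simulate", "conjfdr", "loci", "integrate"))
    need_imaging = any(s in stages for s in ("meta", "pls", "integrate", "expr-prep"))

    if need_gwas or need_imaging:
        # one gene universe ties the layers together: one gene per LD
        # block; shared blocks' genes also carry the imaging signal
        ss1, ss2, panel, truth = synthgen.simulate_bivariate_gwas(gwas_cfg)
        manifest["inputs"] = {"sumstats1": _hash_frame(ss1), "sumstats2": _hash_frame(ss2)}
        annotation = synthgen.block_gene_annotation(truth)
        n_genes = len(annotation)
        shared_blocks = sorted(
            truth.loc[truth["causal_class"] == "shared", "block"].unique().astype(int)
        )
        report["n_shared_blocks"] = len(shared_blocks)
    if need_imaging:
        atlas_over = dict(config.get("atlas", {}))
        atlas_over.setdefault("n_genes", n_genes)
        atlas_over.setdefault("signal_genes", np.array(shared_blocks, dtype=int))
        bundle, brain_map, signal_genes = synthgen.simulate_expression_atlas(
            **{"seed": seed + 1, **atlas_over}
        )

    if "simulate" in stages:
        ss1.to_csv(outdir / "sumstats_trait1.tsv", sep="\t", index=False)
        ss2.to_csv(outdir / "sumstats_trait2.tsv", sep="\t", index=False)
        truth.to_csv(outdir / "gwas_truth.tsv", sep="\t", index=False)

    if "expr-prep" in stages:
        expr_matrix = expr_prep.build_expression_matrix(bundle)
        expr_matrix.to_csv(outdir / "expression_matrix.tsv", sep="\t")
        report["n_expr_samples"], report["n_expr_genes"] = expr_matrix.shape

    if "conjfdr" in stages or "loci" in stages or "integrate" in stages:
        s1 = pleio_fdr.exclude_regions(ss1)
        s2 = pleio_fdr.exclude_regions(ss2)
        res = pleio_fdr.conj_fdr(s1, s2, sig_threshold=config.get("conjfdr_sig", 0.05))
        res.to_csv(outdir / "conjfdr.tsv", sep="\t", index=False)
        qq = pleio_fdr.stratified_qq(res["p1"].to_numpy(), res["p2"].to_numpy())
        qq.to_csv(outdir / "stratified_qq.tsv", sep="\t", index=False)
        report["n_significant_snps"] = int(res["significant"].sum())

    pleio_genes: set[str] = set()
    if "loci" in stages or "integrate" in stages:
        indep, leads, lead_of = loci_map.ld_clump(
            res, panel,
            sig_threshold=config.get("conjfdr_sig", 0.05),
            indep_r2=config.get("indep_r2", 0.6),
            lead_r2=config.get("lead_r2", 0.1),
        )
        loci = loci_map.define_loci(
            res, panel, indep, leads, lead_of,
            cand_threshold=config.get("cand_threshold", 0.10),
            cand_r2=config.get("indep_r2", 0.6),
            merge_kb=config.get("merge_kb", 250),
        )
        genes_hit = loci_map.positional_map(
            loci, annotation, res[["SNP", "CHR", "BP"]],
            window_bp=config.get("window_bp", 10_000),
        )
        pleio_genes = set(genes_hit)
        loci_map.loci_to_frame(loci).to_csv(outdir / "loci.tsv", sep="\t", index=False)
        report["n_loci"] = len(loci)
        report["n_mapped_genes"] = len(genes_hit)

    if "meta" in stages or "pls" in stages or "integrate" in stages:
        truth_grid, affine = synthgen.make_truth_map()
        peaks = synthgen.simulate_study_peaks(
            truth_grid, affine, seed=seed + 3, **dict(config.get("peaks", {}))
        )
        grid = gmv_meta.GridSpec(truth_grid.shape, affine)
        maps = [
            gmv_meta.reconstruct_effect_map(peaks[peaks["study_id"] == s], grid)
            for s in peaks["study_id"].unique()
        ]
        meta_res = gmv_meta.permutation_fwe(
            maps, n_perm=config.get("n_perm", 100), seed=seed + 4
        )
        report["meta_min_fwe_p"] = float(meta_res.fwe_p.min())

    gmv_genes: set[str] = set()
    if "pls" in stages or "integrate" in stages:
        expr = expr_prep.build_expression_matrix(bundle)
        # the synthetic z-map response is the planted target field at the
        # expression sample locations
        yvals = brain_map.values
        y = (yvals - yvals.mean()) / yvals.std()
        X = expr.to_numpy()
        X = (X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1.0)
        scores = pls_assoc.bootstrap_gene_scores(
            X, y, list(expr.columns), n_boot=config.get("n_boot", 200), seed=seed + 5
        )
        scores.to_csv(outdir / "gene_scores.tsv", sep="\t", index=False)
        gmv_genes = set(scores.loc[scores["selected"], "gene"])
        report["n_pls_genes"] = len(gmv_genes)
        report["n_true_signal_genes"] = len(signal_genes)

    if "integrate" in stages:
        overlaps, core, venn = intersect_gene_sets(gmv_genes, {"trait2": pleio_genes})
        report["overlap_counts"] = {t: len(v) for t, v in overlaps.items()}
        report["core_genes"] = sorted(core)
        (outdir / "venn.json").write_text(json.dumps(venn, indent=2))
        # truth audit: a core gene should be planted on at least one side
        truth_genes = harmonize(f"GENE{b + 1:05d}" for b in shared_blocks)
        report["core_false_members"] = sorted(core - truth_genes - harmonize(signal_genes))
        _, gene_sets, ppi = synthgen.simulate_annotations(
            n_genes=n_genes,
            planted_sets={"PLANTED_SHARED": set(truth_genes)},
            seed=seed + 2,
            **dict(config.get("annotations", {})),
        )
        universe = set(annotation["gene"])
        if core:
            enr = hypergeom_enrichment(core, gene_sets, universe)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            report["top_enriched_set"] = str(enr["set"].iloc[0])
            ppi_stats = ppi_subnetwork_stats(core, ppi, config.get("string_score", 0.4))
            report["ppi_m_obs"] = ppi_stats["m_obs"]
            report["ppi_m_exp"] = round(ppi_stats["m_exp"], 4)
            report["ppi_p_edges"] = ppi_stats["p_edges"]

    manifest["report"] = report
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
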