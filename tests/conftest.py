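import numpy as np
import pandas as pd
import pytest

import pleiomap as pm


@pytest.fixture(scope="session")
def small_gwas():
    """One modest bivariate GWAS with planted shared blocks (shared across
    tests; treat as read-only)."""
    cfg = pm.SimulationConfig(m_snps=5_000, block_size=50, seed=11)
    ss1, ss2, panel, truth = pm.simulate_bivariate_gwas(cfg)
    return cfg, ss1, ss2, panel, truth


@pytest.fixture(scope="session")
def small_atlas():
    """Small synthetic expression atlas with ten planted signal genes."""
    bundle, brain_map, signal = pm.simulate_expression_atlas(
        n_samples=120, n_genes=300, n_signal_genes=10, seed=5
    )
    return bundle, brain_map, signal


@pytest.fixture(scope="session")
def expr_and_response(small_atlas):
    """Standardized expression matrix and planted spatial response."""
    bundle, brain_map, signal = small_atlas
    expr = pm.build_expression_matrix(bundle)
    X = expr.to_numpy()
    sd = X.std(axis=0)
    X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    y = brain_map.values
    y = (y - y.mean()) / y.std()
    return X, y, list(expr.columns), signal


def synthetic_supplementary_sets():
    """Synthetic stand-in for the published per-trait shared gene lists.

    Constructed so the imaging gene set and the five trait gene sets
    reproduce the printed overlap counts (GLU 20, HbA1c 17, HDL-C 78,
    LDL-C 87, TG 82) and the six-gene core (KBTBD4, FNBP4, MYBPC3,
    SLC39A13, PTPMT1, NUP160).  Synthetic: the real supplementary tables
    are not bundled; only the printed summary numbers constrain this
    construction.
    """
    core = ["KBTBD4", "FNBP4", "MYBPC3", "SLC39A13", "PTPMT1", "NUP160"]
    counts = {"GLU": 20, "HBA1C": 17, "HDLC": 78, "LDLC": 87, "TG": 82}
    filler = [f"FILLER{i:04d}" for i in range(600)]
    used = 0
    trait_sets = {}
    imaging_genes = set(core)
    for trait, n in counts.items():
        extra = filler[used: used + n - len(core)]
        used += n - len(core)
        trait_sets[trait] = set(core) | set(extra)
        imaging_genes |= set(extra)
    # pad the imaging set with genes in no trait set, and each trait set
    # with genes outside the imaging set, so the overlaps are exact
    imaging_genes |= {f"IMGONLY{i:04d}" for i in range(5000)}
    for trait in trait_sets:
        trait_sets[trait] |= {f"{trait}ONLY{i:03d}" for i in range(40)}
    return imaging_genes, trait_sets, core, counts
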