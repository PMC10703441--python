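import numpy as np
import pandas as pd
import pytest

from crosspath.msea import MseaContext
from crosspath.simulate import PlantedSet, SimConfig, gen_bundle, gene_ids


def make_gwas(markers, pvalues):
    return pd.DataFrame({"MARKER": list(markers), "PVALUE": list(pvalues)})


def make_eqtl(rows, tissue="synthetic"):
    """rows: iterable of (marker, gene) or (marker, gene, kind, fdr)."""
    out = []
    for row in rows:
        marker, gene = row[0], row[1]
        kind = row[2] if len(row) > 2 else "cis"
        fdr = row[3] if len(row) > 3 else 0.01
        out.append((marker, gene, tissue, kind, fdr))
    return pd.DataFrame(out, columns=["MARKER", "GENE", "TISSUE", "CIS_TRANS", "FDR"])


def make_ld(assignments):
    return dict(assignments)


@pytest.fixture(scope="session")
def small_bundle():
    """A modest planted bundle shared by read-only tests."""
    ids = gene_ids(SimConfig(n_genes=400, n_markers=3000))
    planted = PlantedSet(
        "PLANTED", tuple(ids[:50]), enrichment_alpha=0.2, planted_kd=ids[0]
    )
    cfg = SimConfig(
        n_genes=400, n_markers=3000, block_size=5, cis_per_gene=2,
        trans_fraction=0.1, n_sets=25, set_size_range=(10, 40),
        planted_sets=(planted,), decoys_exclude_planted=True, seed=11,
        n_samples=60,
    )
    return gen_bundle(cfg)


@pytest.fixture(scope="session")
def small_ctx(small_bundle):
    b = small_bundle
    return MseaContext.from_raw(b.gwas, b.eqtl, b.ld, tissue="synthetic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
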