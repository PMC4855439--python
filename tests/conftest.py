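"""Shared fixtures: tiny hand-built inputs plus session-scoped synthetic studies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methylome.io import filter_depth
from methylome.model import sites_frame
from methylome.simulate import (
    SyntheticConfig,
    generate_genome,
    simulate_expression,
    simulate_methylome,
    te_only_config,
)
from methylome.sites import SiteIndex

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: master seed of the in-repo synthetic fixtures
FIXTURE_SEED = 1


def make_sites(records):
    """records: (chrom, pos, strand, context, dinuc, n_meth, n_total)."""
    return sites_frame(records)


@pytest.fixture(scope="session")
def default_study():
    """Default-condition two-tissue study with depth-filtered site tables."""
    data = generate_genome(SyntheticConfig(), seed=FIXTURE_SEED)
    sites = {
        t: filter_depth(simulate_methylome(data, t), 10) for t in ("blood", "brain")
    }
    indexes = {t: SiteIndex(s) for t, s in sites.items()}
    gene_fpkm, te_fpkm = simulate_expression(data)
    return {
        "data": data,
        "sites": sites,
        "indexes": indexes,
        "gene_fpkm": gene_fpkm,
        "te_fpkm": te_fpkm,
    }


@pytest.fixture(scope="session")
def recovery_study():
    """Larger study (400 genes) for planted differential-gene recovery."""
    cfg = SyntheticConfig(
        chrom_lengths={"chr1": 2_200_000, "chr2": 2_200_000}, n_genes=400
    )
    data = generate_genome(cfg, seed=FIXTURE_SEED)
    sites = {
        t: filter_depth(simulate_methylome(data, t), 10) for t in ("blood", "brain")
    }
    indexes = {t: SiteIndex(s) for t, s in sites.items()}
    gene_fpkm, _ = simulate_expression(data)
    return {"data": data, "sites": sites, "indexes": indexes, "gene_fpkm": gene_fpkm}


@pytest.fixture(scope="session")
def te_study():
    """TE-expression coupling experiment at n = 2000 TEs (brain only)."""
    data = generate_genome(te_only_config(n_tes=2000), seed=FIXTURE_SEED)
    brain = filter_depth(simulate_methylome(data, "brain"), 10)
    simulate_expression(data)
    return {"data": data, "brain": brain, "index": SiteIndex(brain)}


@pytest.fixture()
def rng():
    return np.random.default_rng(FIXTURE_SEED)
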