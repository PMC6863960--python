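import numpy as np
import pandas as pd
import pytest

from bsamap import simgen
from bsamap.fixtures import build_dwarf_gene_fixture


@pytest.fixture(scope="session")
def gene_fixture():
    """The packaged toy dwarfing-gene fixture (session-cached; deterministic)."""
    return build_dwarf_gene_fixture()


@pytest.fixture(scope="session")
def small_experiment():
    """One small seeded simulation shared by read-only tests."""
    cfg = simgen.SimConfig(
        n_chromosomes=2, chrom_length_bp=10_000_000, map_length_morgans=0.8,
        n_markers_per_chrom=60, causal_chrom="chr2", causal_pos_bp=6_000_000,
        n_f2=400, bulk_size=20, mean_depth=34.0, seq_error=0.001, rng_seed=11,
    )
    cohort, bulks, sites = simgen.simulate_experiment(cfg)
    return cfg, cohort, bulks, sites


def make_sites(rows):
    """VariantSite table from (chrom, pos, d_ref, d_alt, n_ref, n_alt) tuples.

    ref = normal-parent allele 'A', alt = dwarf-parent allele 'T'.
    """
    recs = [
        {"chrom": c, "pos": p, "ref": "A", "alt": "T",
         "parent_hi": "A", "parent_dw": "T",
         "d_ref": dr, "d_alt": da, "n_ref": nr, "n_alt": na}
        for c, p, dr, da, nr, na in rows
    ]
    return pd.DataFrame(recs, columns=simgen.VARIANT_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
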