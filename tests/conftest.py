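import pytest

from smartrbs import FixtureSpec, GlosSpec, TirModel, gen_tir_table, glos_candidates


@pytest.fixture(scope="session")
def glos_pool_6mer():
    """Full 729-member GLOS pool for a 6-nt wild core."""
    return sorted(glos_candidates(GlosSpec("ACGTAC")))


@pytest.fixture(scope="session")
def tir_model_729(glos_pool_6mer):
    """Seeded log-uniform TIR table covering the 729-member pool."""
    spec = FixtureSpec(seed=11)
    df = gen_tir_table(glos_pool_6mer, spec)
    return TirModel(table=dict(zip(df["sequence"], df["tir"])))
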