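import numpy as np
import pytest

from dgdrp.synthetic_data import SyntheticSpec, make_benchmark


@pytest.fixture(scope="session")
def small_bundle():
    """A small but structured benchmark: 200 genes, 20 cells, 6 drugs."""
    spec = SyntheticSpec(n_genes=200, n_cells=20, n_drugs=6, n_pathways=8,
                         planted_neighborhood_size=25, seed=7)
    return make_benchmark(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_expression_tsv(tmp_path):
    """5 genes x 3 cells with known variances."""
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene\tc1\tc2\tc3\n"
        "gA\t1.0\t2.0\t3.0\n"       # var 1.0
        "gB\t5.0\t5.0\t5.0\n"       # var 0.0
        "gC\t0.0\t4.0\t8.0\n"       # var 16.0
        "gD\t1.0\t1.0\t4.0\n"       # var 3.0
        "gE\t2.0\t2.0\t2.5\n"       # var ~0.083
    )
    return path


@pytest.fixture()
def toy_ppi_tsv(tmp_path):
    path = tmp_path / "ppi.tsv"
    path.write_text(
        "protein1\tprotein2\tcombined_score\n"
        "A\tB\t950\n"
        "B\tC\t800\n"
        "C\tD\t700\n"
        "D\tE\t400\n"
    )
    return path


def numeric_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f at numpy array x."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
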