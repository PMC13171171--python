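import numpy as np
import pytest
import scipy.sparse as sp

from dropqc.io_quant import LogSummary, QuantBundle


def make_bundle(dense, barcodes=None, genes=None, symbols=None, logs=None, layers=None):
    """QuantBundle from a dense array (barcodes x genes)."""
    dense = np.asarray(dense, dtype=np.int64)
    n, g = dense.shape
    bundle = QuantBundle(
        counts_total=sp.csr_matrix(dense),
        barcodes=barcodes or [f"BC{i:04d}" for i in range(n)],
        genes=genes or [f"G{j:03d}" for j in range(g)],
        gene_symbols=symbols,
        log_meta=logs or LogSummary(),
    )
    if layers is not None:
        s, u, a = layers
        bundle.layer_S = sp.csr_matrix(np.asarray(s, dtype=np.int64))
        bundle.layer_U = sp.csr_matrix(np.asarray(u, dtype=np.int64))
        bundle.layer_A = sp.csr_matrix(np.asarray(a, dtype=np.int64))
    bundle.validate()
    return bundle


def write_usa_example_dir(path):
    """The 3-barcode x 2-gene USA fixture: b1 has S=(2,0), U=(1,0), A=(1,0)."""
    path.mkdir(parents=True, exist_ok=True)
    # columns: g1, g2, g1-U, g2-U, g1-A, g2-A
    dense = np.array(
        [
            [2, 0, 1, 0, 1, 0],  # b1
            [0, 3, 0, 1, 0, 0],  # b2
            [1, 1, 2, 0, 0, 2],  # b3
        ]
    )
    _write_mtx(path / "matrix.mtx", dense)
    (path / "barcodes.txt").write_text("b1\nb2\nb3\n")
    (path / "features.txt").write_text("g1\ng2\ng1-U\ng2-U\ng1-A\ng2-A\n")
    return dense


def _write_mtx(path, dense):
    from scipy.io import mmwrite

    mmwrite(path, sp.coo_matrix(dense), field="integer")


@pytest.fixture
def usa_dir(tmp_path):
    dense = write_usa_example_dir(tmp_path / "usa")
    return tmp_path / "usa", dense


@pytest.fixture
def plain_dir(tmp_path):
    dense = np.array([[5, 0, 2], [0, 1, 0], [3, 3, 3], [0, 0, 9]])
    d = tmp_path / "plain"
    d.mkdir()
    _write_mtx(d / "matrix.mtx", dense)
    (d / "barcodes.txt").write_text("b1\nb2\nb3\nb4\n")
    (d / "features.txt").write_text("gA\ngB\ngC\n")
    return d, dense


def midrange_bundle(
    seed=0,
    n_big=50,
    big_depth=20_000,
    n_ambient=400,
    n_real_mid=10,
    n_amb_mid=10,
    mid_depth=800,
    n_genes=40,
):
    """Bimodal experiment with planted mid-range barcodes.

    Big cells and 'real' mid-range barcodes draw from a cell profile
    concentrated on the first half of the genes; ambient barcodes and 'fake'
    mid-range barcodes draw from an ambient profile on the second half.
    Returns (bundle, dict of index arrays).
    """
    rng = np.random.default_rng(seed)
    half = n_genes // 2
    eps = 1e-3
    cell_profile = np.full(n_genes, eps)
    cell_profile[:half] += rng.dirichlet(np.full(half, 1.0))
    cell_profile /= cell_profile.sum()
    amb_profile = np.full(n_genes, eps)
    amb_profile[half:] += rng.dirichlet(np.full(half, 1.0))
    amb_profile /= amb_profile.sum()

    rows, labels = [], []
    for _ in range(n_big):
        rows.append(rng.multinomial(big_depth, cell_profile))
        labels.append("big")
    for _ in range(n_real_mid):
        rows.append(rng.multinomial(mid_depth, cell_profile))
        labels.append("real_mid")
    for _ in range(n_amb_mid):
        rows.append(rng.multinomial(mid_depth, amb_profile))
        labels.append("amb_mid")
    for _ in range(n_ambient):
        rows.append(rng.multinomial(rng.integers(5, 80), amb_profile))
        labels.append("ambient")

    perm = rng.permutation(len(rows))
    dense = np.asarray(rows, dtype=np.int64)[perm]
    labels = np.asarray(labels)[perm]
    bundle = make_bundle(dense)
    planted = {name: np.flatnonzero(labels == name) for name in np.unique(labels)}
    return bundle, planted


@pytest.fixture
def bimodal_bundle():
    return midrange_bundle(seed=7, n_real_mid=0, n_amb_mid=0)
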