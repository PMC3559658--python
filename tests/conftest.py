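import numpy as np
import pandas as pd
import pytest

from ipac import GeneTable, GenomicMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cn_matrix(values, chromosomes=None, positions=None, samples=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    probes = [f"p{i}" for i in range(n)]
    ann = pd.DataFrame({
        "chromosome": chromosomes or ["chr1"] * n,
        "position": positions if positions is not None
        else np.arange(1, n + 1) * 1000,
    }, index=pd.Index(probes, name="probe_id"))
    cols = samples or [f"S{j}" for j in range(m)]
    return GenomicMatrix(values=pd.DataFrame(values, index=ann.index,
                                             columns=cols),
                         annotations=ann, kind="copy_number")


def make_expr_matrix(values, gene_symbols, chromosomes=None, positions=None,
                     samples=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    probes = [f"e{i}" for i in range(n)]
    ann = pd.DataFrame({
        "gene_symbol": gene_symbols,
        "chromosome": chromosomes or ["chr1"] * n,
        "position": positions if positions is not None
        else np.arange(1, n + 1) * 1000,
    }, index=pd.Index(probes, name="probe_id"))
    cols = samples or [f"S{j}" for j in range(m)]
    return GenomicMatrix(values=pd.DataFrame(values, index=ann.index,
                                             columns=cols),
                         annotations=ann, kind="expression")


def make_gene_table(cn, expr, genes=None, chromosomes=None, positions=None):
    cn = np.asarray(cn, dtype=float)
    expr = np.asarray(expr, dtype=float)
    n, m = cn.shape
    index = pd.Index(genes or [f"G{i}" for i in range(n)], name="gene_symbol")
    samples = [f"S{j}" for j in range(m)]
    ann = pd.DataFrame({
        "chromosome": chromosomes or ["chr1"] * n,
        "position": positions if positions is not None
        else np.arange(1, n + 1) * 1.0e5,
    }, index=index)
    return GeneTable(cn=pd.DataFrame(cn, index=index, columns=samples),
                     expr=pd.DataFrame(expr, index=index, columns=samples),
                     annotations=ann)
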