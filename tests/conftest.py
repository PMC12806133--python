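import numpy as np
import pandas as pd
import pytest
import scipy.sparse

from triadbias import CellMatrix, ExpressionMatrix, TriadSet
from triadbias.io import TriadEntry


@pytest.fixture
def small_triads() -> TriadSet:
    return TriadSet(
        [
            TriadEntry("t1", "t1_A", "t1_B", "t1_D"),
            TriadEntry("t2", "t2_A", "t2_B", "t2_D"),
            TriadEntry("t3", "t3_A", "t3_B", "t3_D"),
        ]
    )


@pytest.fixture
def small_matrix(small_triads) -> ExpressionMatrix:
    """Two groups × two replicates over three triads with known fractions.

    t1 is balanced in both groups, t2 is A-dominant then A-suppressed,
    t3 is silent in group G2.
    """
    genes = small_triads.all_genes()
    cols = {
        "G1_r1": [10, 10, 10, 80, 10, 10, 30, 30, 40],
        "G1_r2": [10, 10, 10, 80, 10, 10, 30, 30, 40],
        "G2_r1": [20, 20, 20, 0, 50, 50, 0, 0, 0],
        "G2_r2": [20, 20, 20, 0, 50, 50, 0, 0, 0],
    }
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(
        {
            "group": ["G1", "G1", "G2", "G2"],
            "replicate": ["1", "2", "1", "2"],
        },
        index=pd.Index(list(cols), name="sample_id"),
    )
    return ExpressionMatrix(values=values, sample_meta=meta)


def make_cell_matrix(rows, barcodes, genes, flags=None, labels=None) -> CellMatrix:
    """Build a CellMatrix from a dense list-of-lists of counts."""
    counts = scipy.sparse.csr_matrix(np.asarray(rows, dtype=np.int64))
    if flags is None:
        flags = {g: "nuclear" for g in genes}
    return CellMatrix(counts, list(barcodes), list(genes), flags, labels)
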