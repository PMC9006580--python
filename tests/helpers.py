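import numpy as np
import pandas as pd
import scipy.sparse as sp

from degentraj.io import CountMatrix


def make_counts(dense, symbols=None, barcodes=None) -> CountMatrix:
    dense = np.asarray(dense)
    g, c = dense.shape
    symbols = symbols or [f"gene{i}" for i in range(g)]
    features = pd.DataFrame({"id": [f"id{i}" for i in range(g)], "symbol": symbols})
    barcodes = barcodes or [f"bc{i}" for i in range(c)]
    return CountMatrix(sp.csr_matrix(dense), features, np.array(barcodes, dtype=object))
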