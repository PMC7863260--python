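import numpy as np
import pandas as pd
import pytest

from pleioconj.sumstats import PairedStats


@pytest.fixture
def worked_five() -> PairedStats:
    """The five-SNP configuration used for hand-checked cFDR values."""
    df = pd.DataFrame({
        "variant_id": list("ABCDE"),
        "chrom": "1",
        "pos": [100, 200, 300, 400, 500],
        "z1": 0.0, "z2": 0.0,
        "p1": [0.001, 0.01, 0.2, 0.5, 0.9],
        "p2": [0.0005, 0.5, 0.001, 0.9, 0.04],
    })
    return PairedStats(df=df)


@pytest.fixture
def random_paired():
    """Factory for random independent paired stats of a given size."""
    def make(n, seed=0, p1=None, p2=None):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "variant_id": [f"rs{i}" for i in range(n)],
            "chrom": "1",
            "pos": 1000 + 5000 * np.arange(n),
            "z1": 0.0, "z2": 0.0,
            "p1": rng.uniform(size=n) if p1 is None else p1,
            "p2": rng.uniform(size=n) if p2 is None else p2,
        })
        return PairedStats(df=df)
    return make


def write_sumstats_file(path, rows, header="SNP CHR BP A1 A2 P"):
    cols = header.split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path
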