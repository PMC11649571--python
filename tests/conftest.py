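import numpy as np
import pandas as pd
import pytest

from genarch import simulate as sim


@pytest.fixture
def sumstats_file(tmp_path):
    """Small well-formed sumstats file with a couple of bad rows."""
    path = tmp_path / "trait.tsv"
    pd.DataFrame({
        "SNP": ["rs1", "rs2", "rs3", "rs4", "rs5", "rs5"],
        "CHR": [1, 1, 2, 2, 3, 3],
        "BP": [100, 200, 100, 200, 100, 100],
        "A1": ["A", "G", "C", "A", "T", "T"],
        "A2": ["G", "G", "T", "C", "C", "C"],   # rs2 has identical alleles
        "BETA": [0.02, 0.01, -0.03, 0.05, 0.0, 0.0],
        "SE": [0.01, 0.01, 0.01, 0.025, 0.02, 0.02],
        "N": [1000] * 6,
        "FRQ": [0.3, 0.4, 0.5, 0.96, 0.5, 0.5],
        "INFO": [0.99, 0.95, 0.85, 0.99, 0.97, 0.97],
    }).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def reference_frame():
    return pd.DataFrame({
        "SNP": ["rs1", "rs3", "rs4", "rs5", "rs9"],
        "CHR": [1, 2, 2, 3, 9],
        "BP": [100, 100, 200, 100, 900],
        "A1": ["A", "C", "A", "T", "A"],
        "A2": ["G", "T", "C", "C", "G"],
    })


def make_pair_panel(rg: float, seed: int, m: int = 50_000, n: float = 20_000,
                    h2: float = 0.4, overlap: float | None = None):
    """Two-trait panel with genetic correlation ``rg`` (via a shared factor)."""
    if rg == 0:
        model = None
    else:
        lo = np.sqrt(abs(rg))
        model = sim.FactorModelTruth(
            ["F"], np.array([[lo], [np.sign(rg) * lo]]), np.eye(1))
    ov = None
    if overlap is not None:
        ov = np.array([[0.0, overlap], [overlap, 0.0]])
    cfg = sim.SimConfig(
        m=m, traits=[sim.TraitSpec("A", h2, n=n), sim.TraitSpec("B", h2, n=n)],
        model=model, overlap=ov, seed=seed)
    return sim.simulate_panel(cfg)


FIVE_FACTOR_MODEL = """
F1 =~ OCD + AN + TS
F2 =~ BIP + SCZ
F3 =~ ANX + MDD
F4 =~ ADHD + AUT
F5 =~ ADHD + DYX
"""

FOUR_FACTOR_MODEL = """
F1 =~ OCD + AN + TS
F2 =~ BIP + SCZ
F3 =~ ANX + MDD
F4 =~ ADHD + AUT + DYX
"""

TARGET_CLUSTERS = sorted(map(sorted, [
    ["OCD", "AN", "TS"], ["BIP", "SCZ"], ["ANX", "MDD"], ["ADHD", "AUT", "DYX"]]))
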