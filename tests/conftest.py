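import numpy as np
import pandas as pd
import pytest

from blastasym.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic experiment (120 genes, 4 embryos)."""
    config = SimConfig(seed=123, n_genes=120, n_embryos=4)
    counts, meta, truth = simulate(config)
    return counts, meta, truth, config


@pytest.fixture()
def tiny_meta():
    """One embryo, eight blastomeres, full octant labeling."""
    rows = []
    for av in ("animal", "vegetal"):
        for dv in ("dorsal", "ventral"):
            for lr in ("left", "right"):
                rows.append({
                    "sample_id": f"E1-{av[0]}{dv[0]}{lr[0]}".upper(),
                    "embryo_id": "E1", "av": av, "dv": dv, "lr": lr,
                })
    return pd.DataFrame(rows).set_index("sample_id")


def make_results(rows):
    """Build an axis-test result table from terse tuples
    (gene, axis, embryo, q, fold, pole)."""
    df = pd.DataFrame(rows, columns=["gene_id", "axis", "embryo_id", "q", "fold",
                                     "enriched_pole"])
    df["mode"] = np.where(df["embryo_id"] == "pooled", "pooled", "per_embryo")
    df["p"] = df["q"]
    df["lrt_stat"] = 1.0
    df["df"] = 1
    df["mean_pole_1"] = 1.0
    df["mean_pole_2"] = 1.0
    df["infinite_fold"] = False
    df["converged"] = True
    return df
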