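import numpy as np
import pandas as pd
import pytest

import crossome as cx


@pytest.fixture
def tiny_matrices():
    """Small hand-written protein/lipid layers over 2 genotypes x 2 reps."""
    samples = ["Control_r1", "Control_r2", "KO01_r1", "KO01_r2"]
    prot = cx.OmicsMatrix(
        "protein",
        pd.DataFrame(
            {
                "Control_r1": [10.0, 20.0, 5.0],
                "Control_r2": [10.2, 19.8, 5.2],
                "KO01_r1": [11.0, 20.1, np.nan],
                "KO01_r2": [11.2, 19.9, 5.1],
            },
            index=["P1", "P2", "P3"],
        ),
    )
    lip = cx.OmicsMatrix(
        "lipid",
        pd.DataFrame(
            {
                "Control_r1": [15.0, 8.0],
                "Control_r2": [15.1, 8.1],
                "KO01_r1": [16.0, 8.2],
                "KO01_r2": [16.2, np.nan],
            },
            index=["PC 34:1", "CE 16:0"],
        ),
    )
    meta = cx.SampleMetadata(
        pd.DataFrame(
            {
                "genotype": ["Control", "Control", "KO01", "KO01"],
                "replicate": [1, 2, 1, 2],
            },
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return prot, lip, meta


@pytest.fixture(scope="session")
def default_panel():
    """One default-parameter synthetic panel, shared across tests."""
    return cx.simulate_panel(cx.SimConfig(seed=11))


@pytest.fixture(scope="session")
def fitted_default(default_panel):
    """Fitted model on the default panel.

    k per axis is the planted module count plus one: the connectivity filter
    legitimately retains a few weakly-structured background features, which
    get their own cluster rather than forcing a module merge.
    """
    panel = default_panel
    model = cx.CrossOmeModel(
        panel.protein,
        panel.lipid,
        panel.metadata,
        protein_annotations=panel.annotations["protein"],
        lipid_annotations=panel.annotations["lipid"],
        k_protein=6,
        k_lipid=6,
    )
    return panel, model.fit(seed=11)


def brute_force_tau_b(x, y):
    """Exhaustive all-pairs Kendall tau-b oracle (pairwise-complete)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[ok], y[ok]
    n = len(xs)
    if n < 2:
        return float("nan"), n
    conc = disc = tie_x = tie_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(xs[i] - xs[j])
            dy = np.sign(ys[i] - ys[j])
            if dx == 0:
                tie_x += 1
            if dy == 0:
                tie_y += 1
            if dx * dy > 0:
                conc += 1
            elif dx * dy < 0:
                disc += 1
    n0 = n * (n - 1) // 2
    den = (n0 - tie_x) * (n0 - tie_y)
    if den == 0:
        return float("nan"), n
    return (conc - disc) / np.sqrt(den), n
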