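import numpy as np
import pandas as pd
import pytest

from uranet import RegulatorKB, SimulationConfig, generate_kb, simulate_screen
from uranet.kb import KB_COLUMNS

# Published summary of the six upstream-regulator networks from the neuron
# drug screen (drug, regulator, own fold change, state, activation z,
# overlap p, network size); NaN fold change = regulator not in the screen data.
NEURON_SCREEN_REGULATORS = pd.DataFrame(
    [
        ("Levothyroxine", "DIO3", 4.385, "Inhibited", -2.975, 1.79e-7, 8),
        ("Hydroxyurea", "FOXM1", -3.579, "Inhibited", -3.245, 1.63e-10, 8),
        ("Dexamethasone", "PPARD", 2.522, "Activated", 3.126, 4.58e-2, 10),
        ("Dexamethasone", "STAT4", float("nan"), "Activated", 2.933, 7.36e-4, 12),
        ("Vigabatrin", "MKNK1", 1.187, "Inhibited", -3.0, 1.40e-4, 5),
        ("Pregabalin", "PGR", 1.013, "Activated", 3.376, 7.77e-9, 13),
    ],
    columns=["drug", "regulator", "fold_change", "predicted_state",
             "activation_z", "p_overlap", "n_genes"],
)


@pytest.fixture
def neuron_screen_regulators():
    return NEURON_SCREEN_REGULATORS.copy()


@pytest.fixture
def small_matrix():
    """4 genes x 4 conditions, one low-abundance gene and one constant gene."""
    rng = np.random.default_rng(7)
    values = np.array([
        [10.0, 12.0, 9.0, 11.0],
        [0.5, 0.5, 0.5, 0.5],       # fails cpm > 1
        [3.0, 3.0, 3.0, 3.0],       # constant
        [1.0, 1.0, 1.0, 7.0],       # hand-workable log2 row
    ])
    del rng
    return pd.DataFrame(values, index=["GA", "GB", "GC", "GD"],
                        columns=["d1", "d2", "d3", "d4"])


@pytest.fixture
def tiny_kb():
    edges = pd.DataFrame(
        [("R1", "GA", 1, 1.0), ("R1", "GC", 1, 1.0), ("R1", "GD", -1, 1.0),
         ("R2", "GD", 1, 1.0)],
        columns=KB_COLUMNS)
    return RegulatorKB(edges)


@pytest.fixture(scope="session")
def strong_screen():
    """Default simulated screen: ten strong programs plus singleton DEGs."""
    cfg = SimulationConfig(seed=11)
    kb = generate_kb(cfg)
    matrix, truth = simulate_screen(cfg, kb)
    return cfg, kb, matrix, truth
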