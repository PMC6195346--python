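import numpy as np
import pytest

from poregate.iv_pipeline import Sweep
from poregate.rate_model import IonCondition, PermeationParams


@pytest.fixture
def symmetric_condition():
    """Symmetric 150 mM Cl- on both membrane sides at 20 C."""
    return IonCondition(ci=150.0, co=150.0, z=-1, T=293.15)


@pytest.fixture
def symmetric_params(symmetric_condition):
    """Equal-barrier model: collapses to the sinh closed form."""
    return PermeationParams(A=1.0, sigma_h=1.0, sigma_beta=1.0,
                            condition=symmetric_condition)


@pytest.fixture
def rectifying_params(symmetric_condition):
    """Zero-ligand-like barrier profile: strong outward rectification."""
    return PermeationParams(A=1.0, sigma_h=0.2, sigma_beta=0.05,
                            condition=symmetric_condition)


@pytest.fixture
def protocol_voltages():
    return np.arange(-100.0, 121.0, 20.0)


def table_to_sweeps(table):
    """Convert a generator sweep table to Sweep objects."""
    return [
        Sweep(patch_id=r.patch_id, epoch=int(r.epoch), ligand=r.ligand,
              conc=r.conc_nM, V=r.V_mV, I=r.I_pA, I_prepulse=r.prepulse_pA,
              prepulse_V=r.prepulse_mV)
        for r in table.itertuples()
    ]
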