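import numpy as np
import pytest

from connfusion.connectivity_encoder import (ConnectivityEncoderConfig,
                                             init_connectivity_encoder)
from connfusion.io import stack_dataset
from connfusion.simulate import SimConfig, simulate_dataset
from connfusion.temporal_encoder import (TemporalEncoderConfig,
                                         init_temporal_encoder)


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 subjects, 12 ROIs, 60 time points, 3 pseudo-sites."""
    cfg = SimConfig(n_subjects=60, R=12, T=60, n_sites=3, seed=7)
    manifest, records = simulate_dataset(cfg)
    X, P, y, sites = stack_dataset(records)
    return {"cfg": cfg, "manifest": manifest, "records": records,
            "X": X, "P": P, "y": y, "sites": sites}


@pytest.fixture(scope="session")
def tiny_tcfg():
    return TemporalEncoderConfig(n_rois=12, d1=16, L1=1, heads=2, ff_dim=32,
                                 dropout=0.0)


@pytest.fixture(scope="session")
def tiny_ccfg():
    # D = 12*11/2 = 66
    return ConnectivityEncoderConfig(D=66, d2=16, L2=1, heads=2, ff_dim=32,
                                     dropout=0.0, patch_len=10)


@pytest.fixture(scope="session")
def tiny_temporal_params(tiny_tcfg):
    return init_temporal_encoder(np.random.default_rng(0), tiny_tcfg)


@pytest.fixture(scope="session")
def tiny_connectivity_params(tiny_ccfg):
    return init_connectivity_encoder(np.random.default_rng(0), tiny_ccfg)
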