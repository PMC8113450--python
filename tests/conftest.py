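import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_peptide_matrix(values: np.ndarray, n_mut: int = 3, n_ctl: int = 3,
                        proteins=None, spikes=None):
    """Wrap a (peptides x samples) array into a PeptideMatrix."""
    from wobblelab.proteome import PeptideMatrix

    n_pep, n_samp = values.shape
    assert n_samp == n_mut + n_ctl
    samples = [f"mut_{i+1}" for i in range(n_mut)] + \
              [f"ctrl_{i+1}" for i in range(n_ctl)]
    idx = pd.Index([f"pep{i}" for i in range(n_pep)], name="peptide_id")
    ints = pd.DataFrame(values, index=idx, columns=samples)
    if proteins is None:
        proteins = pd.Series([f"prot{i}" for i in range(n_pep)], index=idx)
    else:
        proteins = pd.Series(proteins, index=idx)
    if spikes is None:
        spikes = pd.Series(False, index=idx)
    else:
        spikes = pd.Series(spikes, index=idx)
    design = pd.DataFrame({"group": ["mutant"] * n_mut + ["control"] * n_ctl},
                          index=pd.Index(samples, name="sample"))
    return PeptideMatrix(intensities=ints, proteins=proteins,
                         is_spike=spikes, design=design)


@pytest.fixture
def tiny_config():
    from wobblelab.config import SimConfig
    return SimConfig(seed=42, n_genes=60, n_proteins=30,
                     peptides_per_protein_range=(2, 4), n_nodes=12)
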