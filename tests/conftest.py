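import numpy as np
import pytest

from ferretlung import synthetic


@pytest.fixture(scope="session")
def default_phantom():
    """Default-size phantom with a quarter of lung voxels emphysematous."""
    spec = synthetic.PhantomSpec(emphysema_fraction=0.25, seed=7)
    volume, truth = synthetic.make_ct_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Phantom without emphysema."""
    spec = synthetic.PhantomSpec(emphysema_fraction=0.0, seed=3)
    volume, truth = synthetic.make_ct_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def mono_trace():
    """Noise-free single-exponential forced expiration, long enough to plateau."""
    preset = synthetic.TracePreset(
        fvc_ml=30.0, taus_s=(0.2,), t_onset_s=0.1, duration_s=16.0
    )
    return preset, synthetic.make_expiration_trace(preset)


@pytest.fixture(scope="session")
def control_traces():
    """Five healthy-control maneuvers (tau = 0.2 s)."""
    return [
        synthetic.make_expiration_trace(synthetic.TracePreset(seed=i)) for i in range(5)
    ]
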