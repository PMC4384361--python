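import numpy as np
import pytest

import pausewave as pw


@pytest.fixture
def rng():
    return np.random.default_rng(1)


@pytest.fixture(scope="session")
def pause_dataset():
    """Simulated dataset with a G-rich motif and a strong pause at its first C.

    The pause process (p=0.1, tau=4 s at motif offset 2) mirrors the regime
    where ~10% of reads show a multi-second IPD on a sub-second baseline.
    """
    motif = "GGCGGCGGCGG"
    cfg = pw.SimulationConfig(
        seed=1,
        reference_length=12_000,
        n_reads=500,
        motifs=((motif, 3_000), (motif, 6_500), (motif, 10_000)),
        pauses=(pw.PauseSpec(offset=2, p_pause=0.1, tau_seconds=4.0),),
    )
    reference, reads, truth = pw.simulate_dataset(cfg)
    return cfg, motif, reference, reads, truth


@pytest.fixture(scope="session")
def null_dataset():
    """Same layout but with no pause process at all (null model)."""
    motif = "GGCGGCGGCGG"
    cfg = pw.SimulationConfig(
        seed=1,
        reference_length=12_000,
        n_reads=500,
        motifs=((motif, 3_000), (motif, 6_500), (motif, 10_000)),
        pauses=(),
    )
    reference, reads, truth = pw.simulate_dataset(cfg)
    return cfg, motif, reference, reads, truth
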