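import numpy as np
import pytest

from dupscan import HelixGeometry, generate_backbone


@pytest.fixture(scope="session")
def helix_chain():
    """A 20-residue ideal helix in a random pose."""
    return generate_backbone(20, seed=42, entry_id="hx01")


@pytest.fixture(scope="session")
def chain_pool():
    """Twenty fixture chains of varied length and geometry."""
    chains = []
    rng = np.random.default_rng(2024)
    for i in range(20):
        m = int(rng.integers(5, 80))
        geom = HelixGeometry(
            twist=99.1 + float(rng.uniform(-30, 30)),
            rise=1.5 + float(rng.uniform(-0.4, 0.4)),
        )
        chains.append(generate_backbone(m, geom, seed=i, entry_id=f"p{i:03d}"))
    return chains


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
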