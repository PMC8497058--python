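import numpy as np
import pytest

from mitoshape import MitoCell


@pytest.fixture
def random_cells():
    """Factory for random cells with log-normal component lengths."""

    def make(n_cells: int, seed: int = 0, max_components: int = 60) -> list[MitoCell]:
        rng = np.random.default_rng(seed)
        cells = []
        for i in range(n_cells):
            n = rng.integers(1, max_components + 1)
            lengths = rng.lognormal(mean=0.5, sigma=0.8, size=n)
            cells.append(MitoCell(f"r{i:05d}", "rand", lengths))
        return cells

    return make
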