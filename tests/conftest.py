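import numpy as np
import pytest
from hypothesis import settings

from protpot import composition as cp
from protpot import thermo as th
from protpot import workbench as wb

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def thermo_table() -> th.ThermoTable:
    return th.default_thermo_table()


@pytest.fixture(scope="session")
def zero_table() -> th.ThermoTable:
    return th.uniform_thermo_table(0.0)


@pytest.fixture(scope="session")
def baseline_freqs() -> dict[str, float]:
    return wb.baseline_frequencies()


@pytest.fixture(scope="session")
def small_proteome() -> list[cp.ProteinRecord]:
    """60 human-proteome-like synthetic proteins (30 up-tilted / 30 baseline)."""
    spec = wb.SyntheticSpec(seed=42, n_up=30, n_down=30)
    records, _ = wb.generate_synthetic_proteome(spec)
    return records


def random_formula(rng: np.random.Generator, charged: bool = False) -> cp.ElementalFormula:
    """A random plausible CHNOS(+charge) formula with c > 0."""
    return cp.ElementalFormula(
        c=float(rng.integers(1, 60)),
        h=float(rng.integers(0, 120)),
        n=float(rng.integers(0, 30)),
        o=float(rng.integers(0, 40)),
        s=float(rng.integers(0, 5)),
        z=float(rng.integers(-5, 6)) if charged else 0.0,
    )
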