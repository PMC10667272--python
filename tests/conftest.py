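import pytest

from titrofit import SampleSheetEntry, SimSpec, simulate_series
from titrofit.simulate import dilution_series

FIG_CONCS = dilution_series(1e-6, 2.0, 8)  # 8 two-fold dilutions, top 1 µM


def make_entry(**overrides) -> SampleSheetEntry:
    base = dict(
        location="sim-1",
        series_id="sim-1",
        ligand="lig",
        analyte="ana",
        concentrations=[(i + 1, c) for i, c in enumerate(FIG_CONCS)],
        regenerative=True,
        baseline_len=120.0,
        assoc_len=300.0,
        dissoc_fit_len=750.0,
    )
    base.update(overrides)
    return SampleSheetEntry(**base)


@pytest.fixture
def entry():
    return make_entry()


@pytest.fixture
def regen_series():
    """Noise-free regenerative titration at the reference truth
    (ka=1e5, kd=1e-4, Rmax=100, 8 two-fold dilutions from 1 µM)."""
    return simulate_series(SimSpec(regenerative=True))


@pytest.fixture
def nonregen_series():
    return simulate_series(SimSpec(regenerative=False))
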