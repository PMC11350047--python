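import numpy as np
import pytest

from dropdiv.kinetics import (
    CircuitParams,
    KineticParams,
    SpeciesSet,
    init_circuit,
)
from dropdiv.pipeline import comparator_conditions, run_sweep


@pytest.fixture
def single_circuit_params() -> KineticParams:
    return KineticParams(circuits={"AB": CircuitParams()}, k_cat=2e-3, k_h_rna=0.5)


@pytest.fixture
def delayed_init() -> SpeciesSet:
    """One time-delay circuit with 50% excess inhibitor RNA."""
    return SpeciesSet({"AB": init_circuit(0.2, 1.0, 1.5)}, enzyme=0.25)


@pytest.fixture(scope="session")
def asymmetric_sweep():
    """Five-condition comparator sweep, tenfold AB handicap (well-mixed)."""
    return run_sweep(comparator_conditions(symmetric=False))


@pytest.fixture(scope="session")
def symmetric_sweep():
    """Five-condition comparator sweep, identical circuits (well-mixed)."""
    return run_sweep(comparator_conditions(symmetric=True))
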