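import numpy as np
import pandas as pd
import pytest

from cresig.expression import ExpressionMatrix, call_regulation
from cresig.patterns import MotifPattern
from cresig.regions import extract_region_set
from cresig.simulate import (
    EffectSpec,
    PlantingSpec,
    make_genome,
    plant_motifs,
    simulate_expression,
)


@pytest.fixture(scope="session")
def small_matrix() -> ExpressionMatrix:
    data = pd.DataFrame(
        {
            "array_a": [1.0, 0.0, -0.60, np.nan, 2.5],
            "array_b": [0.3, -1.2, 0.0, 0.9, -2.0],
        },
        index=[f"g{i}" for i in range(1, 6)],
    )
    return ExpressionMatrix(data)


@pytest.fixture(scope="session")
def planted_genome():
    """200-gene genome with CACGTGTC planted in 30% of genes (exact truth)."""
    bundle = make_genome(n_genes=200, seed=11)
    spec = PlantingSpec(
        pattern="CACGTGTC",
        fraction=0.3,
        name="ABRE",
        copies={1: 0.5, 2: 0.3, 3: 0.1, 4: 0.1},
        orientation="both",
    )
    plant_motifs(bundle, spec, seed=12)
    return bundle, spec


@pytest.fixture(scope="session")
def planted_up1k(planted_genome):
    bundle, _ = planted_genome
    return extract_region_set(bundle.contigs, bundle.models, "up1k")


@pytest.fixture(scope="session")
def abre() -> MotifPattern:
    return MotifPattern("ABRE", "CACGTGTC")


@pytest.fixture(scope="session")
def planted_study(planted_genome):
    """Planted genome + expression matrix where carriers respond in array 1."""
    bundle, spec = planted_genome
    carriers = bundle.truth.carriers("ABRE")
    effect = EffectSpec(
        arrays=["array_01"], direction="induce", delta=1.5,
        responder_fraction=0.5, noise_sd=0.5, baseline_sd=0.5,
    )
    matrix, responders = simulate_expression(
        sorted(bundle.models), {"ABRE": (carriers, effect)}, n_arrays=6, seed=13,
        truth=bundle.truth,
    )
    calls = call_regulation(matrix)
    return bundle, matrix, calls, carriers, responders["ABRE"]
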