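import pytest

from kdquant.synthetic import CellTypeSpec, CohortSpec, generate_cohort
from kdquant import counts_io


@pytest.fixture(scope="session")
def small_cohort():
    """Two-cell-type cohort small enough for fast aggregation checks."""
    spec = CohortSpec(
        cell_types=[
            CellTypeSpec("astrocyte", 0.5, 0.001, 2.0, 0.56),
            CellTypeSpec("neuron", 0.5, 0.01, 2.0, 0.30),
        ],
        n_animals_per_arm=4,
        cells_per_animal=300,
        seed=7,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_pseudobulk(small_cohort):
    return counts_io.aggregate_pseudobulk(
        small_cohort.counts, small_cohort.annotations, "Target"
    )
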