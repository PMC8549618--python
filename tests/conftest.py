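import numpy as np
import pandas as pd
import pytest

from methscales import methio
from methscales.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Standard synthetic cohort: 2 rivers x 2 environments x 6 samples,
    20 planted parallel DMRs at delta=0.25, ~15x coverage."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (one 120-kb chromosome, ~4k CpGs) for replicate-heavy
    tests."""
    return simulate_cohort(
        SimulationConfig(seed=2, n_chromosomes=1, chromosome_length_bp=120_000)
    )


@pytest.fixture(scope="session")
def filtered_meth(cohort):
    return methio.filter_coverage(cohort.methylomes, min_cov=10)


def make_metadata(n_per_cell: int = 6) -> pd.DataFrame:
    rows = []
    for river in ("conuma", "quinsam"):
        for env in ("hatchery", "wild"):
            for i in range(n_per_cell):
                rows.append((f"{river[:3]}_{env[:4]}_{i:02d}", river, env))
    return pd.DataFrame(rows, columns=["sample_id", "river", "environment"])


@pytest.fixture
def metadata24():
    return make_metadata(6)


def overlaps(interval_a, interval_b) -> bool:
    """Half-open interval overlap on (chrom, start, end) triples."""
    return (
        interval_a[0] == interval_b[0]
        and interval_a[1] < interval_b[2]
        and interval_b[1] < interval_a[2]
    )
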