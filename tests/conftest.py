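import numpy as np
import pytest

from svcurate import simdata
from svcurate.svio import FALSE_CALL, TRUE_SV, SVCall


def make_call(id="sv1", chrom="chr1", start=1000, end=1500, svtype="DEL",
              genotypes=(0, 1, 2), samples=None, **kwargs) -> SVCall:
    if samples is None:
        samples = tuple(f"s{i + 1}" for i in range(len(genotypes)))
    return SVCall(id=id, chrom=chrom, start=start, end=end, svtype=svtype,
                  samples=samples, genotypes=np.array(genotypes), **kwargs)


@pytest.fixture(scope="session")
def default_config():
    return simdata.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_dataset(default_config):
    """Fully annotated default cohort (seed 1) plus curator scores."""
    calls, table = simdata.simulate_dataset(default_config)
    scores = simdata.simulate_curators(calls, default_config.curators, default_config.seed)
    return calls, table, scores


@pytest.fixture()
def small_config():
    return simdata.SimulationConfig(
        n_true_sv=10, n_false_sv=10,
        size_spectrum={"DEL": (23, 500), "DUP": (79, 500), "INV": (33, 500)},
        seed=11)
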