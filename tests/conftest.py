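import numpy as np
import pytest

from hicfountains import caller as cl
from hicfountains import contact_data as cd
from hicfountains import fixtures as fx


@pytest.fixture(scope="session")
def wedge_mask():
    return cl.build_mask(wedge_params=(41, 30.0, 0.0))


@pytest.fixture(scope="session")
def e2e(wedge_mask):
    """Full 100 Mb fixture (20 fountains, artifacts, control) run through
    the caller once and shared by the integration tests."""
    spec = fx.default_fixture_spec(seed=7, n_fountains=20)
    data = fx.generate(spec)
    reps_b = [cd.ice_balance(r) for r in data.replicates]
    merged = cd.ice_balance(fx.merge_replicates(data.replicates))
    control = cd.ice_balance(data.control)
    calls = cl.call_fountains(reps_b, merged, wedge_mask, control=control)
    return {
        "spec": spec,
        "data": data,
        "merged": merged,
        "calls": calls,
        "passed": calls[calls["passed"]],
    }


@pytest.fixture(scope="session")
def null_calls(wedge_mask):
    """Pure-noise 100 Mb fixture (no fountains, no artifacts) through the
    caller."""
    spec = fx.default_fixture_spec(seed=11, n_fountains=0, n_artifacts=0)
    data = fx.generate(spec)
    reps_b = [cd.ice_balance(r) for r in data.replicates]
    merged = cd.ice_balance(fx.merge_replicates(data.replicates))
    control = cd.ice_balance(data.control)
    return cl.call_fountains(reps_b, merged, wedge_mask, control=control)


def make_map(counts, resolution=10, chrom="chrA"):
    """Wrap a single dense matrix into a one-chromosome ContactMap."""
    counts = np.asarray(counts, dtype=float)
    return cd.ContactMap(
        resolution=resolution,
        chromsizes={chrom: counts.shape[0] * resolution},
        counts={chrom: counts},
    )


@pytest.fixture
def powerlaw_map():
    """Deterministic power-law decay map: counts = 1000 * (s+1)^-1.5."""
    n = 300
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    return make_map(1000.0 * (sep + 1.0) ** -1.5, resolution=10_000)
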