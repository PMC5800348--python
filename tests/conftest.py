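import numpy as np
import pytest

import panelcnv as p


@pytest.fixture(scope="session")
def toy_panel():
    """Deterministic 40-exon, 4-gene panel for caller-level tests."""
    return p.make_panel("toy", 40, 4)


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 60-sample single-panel cohort (300 exons) with 6 spiked events:
    het/hom deletions and duplications from single-exon to 4-exon scale."""
    panel = p.make_panel("mini", 300, 20)
    spec = p.SimulationSpec(
        n_samples_per_panel={"mini": 60},
        dispersion=0.0025,
        cnv_events=(
            p.CnvEventSpec("mini", 1, 1, 1),
            p.CnvEventSpec("mini", 1, 2, 1),
            p.CnvEventSpec("mini", 1, 4, 1),
            p.CnvEventSpec("mini", 1, 1, 0),
            p.CnvEventSpec("mini", 1, 2, 3),
            p.CnvEventSpec("mini", 1, 2, 4),
        ),
        seed=20_240_101,
    )
    return p.simulate_cohort(spec, {"mini": panel})


@pytest.fixture(scope="session")
def flat_counts(toy_panel):
    """Low-noise Poisson cohort over the toy panel (no CNVs)."""
    rng = np.random.default_rng(7)
    lam = np.full(len(toy_panel), 900.0)
    counts = rng.poisson(lam[:, None] * np.ones((len(toy_panel), 20))).astype(np.int64)
    return p.CountsMatrix(toy_panel, [f"c{i:02d}" for i in range(20)], counts)
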