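import logging

import numpy as np
import pytest

import pancmetab as pm
from pancmetab.quantification import ReferenceScan

logging.getLogger("pancmetab").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def assignments():
    return pm.load_assignments()


@pytest.fixture(scope="session")
def network():
    return pm.load_network()


@pytest.fixture(scope="session")
def synth_params():
    return pm.SpectrumSynthParams()


@pytest.fixture(scope="session")
def reference_scan(assignments, synth_params):
    return ReferenceScan(
        spectrum=pm.synthesize_reference_scan(synth_params, assignments=assignments)
    )


@pytest.fixture(scope="session")
def table2_design():
    return pm.load_design("table2")


@pytest.fixture(scope="session")
def table2_cohort(table2_design, assignments):
    """One simulated PP-vs-PA cohort (concentrations + metadata)."""
    return pm.simulate_concentrations(table2_design, seed=2024, assignments=assignments)


def null_two_group_design(stats, n_a=8, n_b=9, label_a="long", label_b="short"):
    """Two groups drawn from identical per-metabolite distributions."""
    return pm.CohortDesign(groups=(
        pm.GroupSpec(label=label_a, n=n_a, stats=dict(stats), tissue="PA",
                     survival_group=label_a if label_a in ("long", "short") else "unknown"),
        pm.GroupSpec(label=label_b, n=n_b, stats=dict(stats), tissue="PA",
                     survival_group=label_b if label_b in ("long", "short") else "unknown"),
    ))


@pytest.fixture(scope="session")
def null_survivor_design(table2_design):
    return null_two_group_design(table2_design.groups[0].stats)


def random_spectrum(rng, lo=0.5, hi=7.8):
    """A smooth random spectrum on an irregular ascending grid."""
    n = int(rng.integers(2000, 5000))
    x = np.unique(np.concatenate(([lo, hi], rng.uniform(lo, hi, n))))
    y = np.cumsum(rng.normal(0, 1, x.size)) / 10 + rng.uniform(0, 5)
    return pm.Spectrum1D(ppm=x, intensity=y, sample_id="rand", weight_mg=17.0)
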