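"""Shared fixtures: one synthetic bundle with planted truth, simulated
per-fraction reads, and the derived pileups/site calls.

Everything is generated at session scope with fixed seeds so the suite is
deterministic and no data files ship with the package.
"""

import pytest

from edkin import caller as ca
from edkin import synthetic as sy


@pytest.fixture(scope="session")
def bundle():
    return sy.generate_reference(sy.GenomeConfig(seed=11))


@pytest.fixture(scope="session")
def truth_spec():
    return sy.TruthSpec(counts={1: 30, 2: 12, 3: 8, 4: 6}, n_acceptor_edits=3)


@pytest.fixture(scope="session")
def truths(bundle, truth_spec):
    return sy.plant_editing_truth(bundle, truth_spec, seed=12)


@pytest.fixture(scope="session")
def fraction_reads(bundle, truths):
    return sy.simulate_bundle_reads(
        bundle, truths, sy.default_fractions(depth=40),
        seed=13, error_rate=0.0, hyper_fraction=0.01,
    )


@pytest.fixture(scope="session")
def pileups(bundle, fraction_reads):
    return {
        frac: ca.build_pileup(fr.mapped, bundle)
        for frac, fr in fraction_reads.items()
    }


@pytest.fixture(scope="session")
def site_calls(bundle, pileups):
    return {
        frac: ca.call_sites(pileups[frac], bundle,
                            nascent=(frac == sy.CHA_MINUS))
        for frac in pileups
    }


@pytest.fixture(scope="session")
def sites(site_calls, pileups):
    return ca.collect_sites(site_calls, pileups)
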