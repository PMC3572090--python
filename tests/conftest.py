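import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from isoscope.datasets import SequenceDataset, SequenceRecord, StrDataset, StrRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_sequence_dataset(pop_to_seqs, region="test"):
    """Build a SequenceDataset from {population: [sequence, ...]}."""
    records = []
    i = 0
    for pop, seqs in pop_to_seqs.items():
        for s in seqs:
            records.append(SequenceRecord(f"s{i:03d}", pop, s))
            i += 1
    return SequenceDataset(records, region_label=region)


def make_str_dataset(loci, pop_to_profiles):
    records = []
    i = 0
    for pop, profiles in pop_to_profiles.items():
        for p in profiles:
            records.append(StrRecord(f"y{i:03d}", pop, tuple(p)))
            i += 1
    return StrDataset(list(loci), records)


def random_sequence_dataset(rng, n_pops=2, n_per_pop=(4, 8), length=30,
                            n_variable=6):
    """Random aligned dataset: a reference with variable sites."""
    bases = np.array(list("ACGT"))
    ref = rng.choice(4, size=length)
    var_sites = rng.choice(length, size=n_variable, replace=False)
    pops = {}
    for p in range(n_pops):
        n = int(rng.integers(n_per_pop[0], n_per_pop[1] + 1))
        seqs = []
        for _ in range(n):
            seq = ref.copy()
            for site in var_sites:
                if rng.random() < 0.4:
                    seq[site] = (seq[site] + rng.integers(1, 4)) % 4
            seqs.append("".join(bases[seq]))
        pops[f"pop{p + 1}"] = seqs
    return make_sequence_dataset(pops)


@pytest.fixture(scope="session")
def study_fixture():
    from isoscope.synthetic import generate_study_fixture

    return generate_study_fixture(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
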