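import numpy as np
import pytest

from mitolineage import (MitoAlignment, build_site_index, collapse_haplotypes,
                         default_motif_table, generate_cohort, yunling_composition)


def make_alignment(seqs, ids=None, breeds=None):
    """Alignment from a list of sequence strings."""
    ids = ids or [f"s{i+1}" for i in range(len(seqs))]
    mat = np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])
    return MitoAlignment(ids, mat, breed_map=breeds or {})


def haplotypes_of(seqs, counts):
    """HaplotypeSet from explicit sequences with given multiplicities."""
    rows = [s for s, c in zip(seqs, counts) for _ in range(c)]
    aln = make_alignment(rows)
    return collapse_haplotypes(aln, build_site_index(aln))


@pytest.fixture(scope="session")
def table():
    return default_motif_table()


@pytest.fixture(scope="session")
def yunling(table):
    """The default 129-animal synthetic cohort with ground truth."""
    return generate_cohort(yunling_composition(seed=11), table)


@pytest.fixture(scope="session")
def small_cohort(table):
    from mitolineage import SyntheticConfig
    cfg = SyntheticConfig(
        seed=5,
        haplogroup_counts={"T1": 3, "T3": 4, "I1": 4, "I2": 2},
        template_counts=None,
        sub_templates={},
        private_mutation_rate=2.0,
    )
    return generate_cohort(cfg, table)
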