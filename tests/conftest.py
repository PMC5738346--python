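import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from treemarker.io_formats import GenomeSet, SeqRecordRef
from treemarker.synthetic_fixtures import FixtureSpec, generate


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_fixture():
    """A 150-kb genome with planted SSRs, genes, ESTs and one duplication."""
    spec = FixtureSpec(
        seed=5,
        scaffold_lengths=(150_000,),
        ssr_per_class={1: 2, 2: 4, 3: 4, 4: 3, 5: 2, 6: 3, 7: 2},
        n_genes=6,
        exon_counts=(3, 3, 4, 2, 3, 4),
        n_duplications=1,
        dup_ssrs_per_segment=5,
        est_substitution_rate=0.0,
    )
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_genome(*seqs: str, species_id: str = "test") -> GenomeSet:
    return GenomeSet(
        species_id,
        [SeqRecordRef(f"s{i + 1}", s) for i, s in enumerate(seqs)],
    )
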