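import pytest

from codonlens.fixtures import FixtureSpec, make_fixture
from codonlens.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small standard-code bundle: 2 families x 40 columns x 4 copies."""
    out = tmp_path_factory.mktemp("small_bundle")
    spec = FixtureSpec(
        seed=5, n_families=2, family_length=40, n_seqs_per_family=30,
        n_copies_per_family=4,
    )
    return make_fixture(spec, out)


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    """The full internal-aligner pipeline on the small bundle."""
    prefix = tmp_path_factory.mktemp("small_run") / "run"
    code, posteriors = run_pipeline(
        small_bundle.genome_fasta_path, small_bundle.profile_db_path, prefix
    )
    return small_bundle, prefix, code, posteriors
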