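import pytest

from mybtrace import SimulationConfig, simulate_bundle
from mybtrace import domain_align, repeat_scan


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default 10-subfamily / 8-species simulation with written files."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = simulate_bundle(SimulationConfig(seed=1), outdir)
    return truth, outdir


@pytest.fixture(scope="session")
def scanned(bundle):
    """Scanner output and domain alignment of the default bundle."""
    truth, outdir = bundle
    archs = repeat_scan.classify_proteins(truth.proteins)
    accepted, rejected = repeat_scan.filter_candidates(archs)
    aln = domain_align.alignment_from_architectures(truth.proteins, accepted)
    return truth, accepted, rejected, aln
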