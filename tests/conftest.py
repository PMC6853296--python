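import pytest

from cpseq.mapping import PRIORITY_ORDER, MappingConfig, map_sequential
from cpseq.preprocess import PipelineConfig, preprocess_reads
from cpseq.simulate import SimulatorConfig, build_toy_references, simulate_library


@pytest.fixture(scope="session")
def toy_refs():
    return build_toy_references(seed=11)


@pytest.fixture(scope="session")
def category_refs(toy_refs):
    return {cat: toy_refs.by_category(cat) for cat in PRIORITY_ORDER}


@pytest.fixture(scope="session")
def clean_library(toy_refs):
    """Error-free default-mode library plus its truth table."""
    cfg = SimulatorConfig(seed=7, n_reads=4000, p_ca_cleavage=1.0, error_rate=0.0)
    return simulate_library(toy_refs, cfg)


@pytest.fixture(scope="session")
def mapped_clean(toy_refs, category_refs, clean_library):
    reads, truth = clean_library
    selected, _ = preprocess_reads(reads, PipelineConfig(adapter_seq=toy_refs.adapter))
    assignments = map_sequential(selected, category_refs, MappingConfig())
    return assignments, truth
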