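import pytest

from koview.fixtures import MockTransport, UniverseSpec, generate_assignments, generate_universe
from koview.input_io import parse_assignments, trim_assignments
from koview.kegg_records import fetch_records
from koview.linker import build_annotation


@pytest.fixture(scope="session")
def small_universe():
    """30 KOs over 8 pathways, 10% pathway-less; the default test world."""
    spec = UniverseSpec(n_kos=30, n_pathways=8, membership_rate=2.0,
                        no_pathway_fraction=0.1, seed=11)
    records, text = generate_universe(spec)
    return spec, records, text


@pytest.fixture
def transport(small_universe):
    _, records, _ = small_universe
    return MockTransport(records)


@pytest.fixture
def annotation(small_universe, transport):
    """A fully linked AnnotationStore over the small universe."""
    _, records, _ = small_universe
    table = generate_assignments(records, 40, missing_fraction=0.1,
                                 unknown_fraction=0.1, seed=5)
    assignments = parse_assignments(table)
    store = fetch_records([a.ko_id for a in assignments if a.ko_id], transport)
    trim = trim_assignments(assignments, store.resolvable)
    return build_annotation(trim, store)
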