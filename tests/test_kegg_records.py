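"""Flat-file parsing, fetching, and the data-file cache."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from koview.fixtures import MockTransport, TransportFault, UniverseSpec, generate_universe
from koview.kegg_records import (
    DataFileError,
    FetchError,
    KoFlatFileError,
    KoRecord,
    PathwayRef,
    RecordStore,
    fetch_records,
    load_store,
    parse_ko_flatfile,
    records_to_flatfile,
    save_store,
)

CANONICAL = """\
ENTRY       K00001                      KO
SYMBOL      E1.1.1.1, adh
NAME        alcohol dehydrogenase
DEFINITION  alcohol dehydrogenase [EC:1.1.1.1]
PATHWAY     ko00010  Glycolysis / Gluconeogenesis
            ko00071  Fatty acid degradation
ORTHOLOGY   ignored stuff
///
"""


def test_parse_canonical_record():
    (rec,) = parse_ko_flatfile(CANONICAL)
    assert rec.ko_id == "K00001"
    assert rec.symbol == "E1.1.1.1, adh"
    assert rec.definition == "alcohol dehydrogenase [EC:1.1.1.1]"
    assert rec.pathways == (
        PathwayRef("ko00010", "Glycolysis / Gluconeogenesis"),
        PathwayRef("ko00071", "Fatty acid degradation"),
    )


def test_parse_multiline_definition_joined_with_spaces():
    text = (
        "ENTRY       K00002                      KO\n"
        "DEFINITION  a very long definition that\n"
        "            continues on the next line\n"
        "///\n"
    )
    (rec,) = parse_ko_flatfile(text)
    assert rec.definition == "a very long definition that continues on the next line"


def test_parse_record_without_pathway_block():
    text = "ENTRY       K00003                      KO\nDEFINITION  orphan\n///\n"
    (rec,) = parse_ko_flatfile(text)
    assert rec.pathways == ()


def test_parse_two_concatenated_records_in_file_order():
    text = CANONICAL + "ENTRY       K00002                      KO\nDEFINITION  x\n///\n"
    recs = parse_ko_flatfile(text)
    assert [r.ko_id for r in recs] == ["K00001", "K00002"]


def test_parse_block_without_entry_names_byte_offset():
    text = CANONICAL + "DEFINITION  stray block\n///\n"
    with pytest.raises(KoFlatFileError, match=rf"byte offset {len(CANONICAL.encode())}"):
        parse_ko_flatfile(text)


def test_parser_agrees_with_line_walking_oracle(small_universe):
    """Independent minimal oracle: scan lines, count ENTRY tokens and
    pathway-accession lines per record."""
    _, records, text = small_universe
    oracle = []
    current = None
    npath = 0
    in_pathway = False
    for line in text.splitlines():
        key = line[:12].strip()
        if key == "ENTRY":
            current = line[12:].split()[0]
            npath = 0
            in_pathway = False
        elif key == "PATHWAY":
            npath += 1
            in_pathway = True
        elif key:
            in_pathway = False
        elif line.startswith(" ") and in_pathway:
            npath += 1
        if line == "///":
            oracle.append((current, npath))
    parsed = [(r.ko_id, len(r.pathways)) for r in parse_ko_flatfile(text)]
    assert parsed == oracle


def test_serialize_parse_roundtrip_on_generated_universe(small_universe):
    _, records, text = small_universe
    assert parse_ko_flatfile(text) == records
    assert parse_ko_flatfile(records_to_flatfile(records)) == records


# --- fetching ---------------------------------------------------------------

def test_fetch_empty_request(transport):
    store = fetch_records([], transport)
    assert store.records == {} and store.unresolvable == set()


def test_fetch_batches_of_ten(small_universe):
    _, records, _ = small_universe
    t = MockTransport(records)
    kos = [f"K{i + 1:05d}" for i in range(23)]
    store = fetch_records(kos, t)
    assert len(t.history) == 3
    assert [len(b) for b in t.history] == [10, 10, 3]
    assert set(store.records) | store.unresolvable == set(kos)
    assert not set(store.records) & store.unresolvable


def test_fetch_collapses_duplicates(transport):
    store = fetch_records(["K00001"] * 25, transport)
    assert len(transport.history) == 1
    assert list(store.records) == ["K00001"]


def test_fetch_partitions_unknown_ids(small_universe):
    _, records, _ = small_universe
    t = MockTransport(records)
    store = fetch_records(["K00001", "K00002", "K00003", "K99998", "K99999"], t)
    assert set(store.records) == {"K00001", "K00002", "K00003"}
    assert store.unresolvable == {"K99998", "K99999"}


def test_fetch_retries_after_injected_fault(small_universe):
    _, records, _ = small_universe
    t = MockTransport(records, fail_on=[1])
    store = fetch_records(["K00001"], t, sleep=lambda s: None)
    assert "K00001" in store.records
    assert len(t.history) == 2  # failed attempt + successful retry


def test_fetch_error_preserves_partial_results(small_universe):
    _, records, _ = small_universe
    t = MockTransport(records, fail_on=[2, 3, 4])
    kos = [f"K{i + 1:05d}" for i in range(15)]
    with pytest.raises(FetchError) as exc_info:
        fetch_records(kos, t, retries=3, sleep=lambda s: None)
    err = exc_info.value
    assert set(err.partial.records) == set(kos[:10])
    assert err.unfetched == kos[10:]


# --- the data file ----------------------------------------------------------

def test_store_roundtrip_empty(tmp_path):
    p = save_store(RecordStore(), tmp_path / "empty.dat")
    assert p.read_text().splitlines() == ["koview-data 1"]
    loaded = load_store(p)
    assert loaded.records == {} and loaded.unresolvable == set()


def test_store_roundtrip_generated(tmp_path, small_universe):
    _, records, _ = small_universe
    store = RecordStore({r.ko_id: r for r in records}, {"K99998", "K99999"})
    p = save_store(store, tmp_path / "u.dat")
    loaded = load_store(p)
    assert loaded.records == store.records
    assert loaded.unresolvable == store.unresolvable


def test_store_roundtrip_awkward_characters(tmp_path):
    rec = KoRecord("K00001", 'sym"bo|l', "def\twith\ttabs | pipes\nand newline",
                   (PathwayRef("ko00001", "Name: with | colon & pipe"),))
    store = RecordStore({"K00001": rec})
    loaded = load_store(save_store(store, tmp_path / "a.dat"))
    assert loaded.records["K00001"] == rec


def test_load_rejects_missing_header(tmp_path):
    p = tmp_path / "bad.dat"
    p.write_text("R\tK00001\ts\td\t\n")
    with pytest.raises(DataFileError, match="line 1"):
        load_store(p)


def test_load_rejects_truncated_record(tmp_path):
    p = tmp_path / "bad.dat"
    p.write_text("koview-data 1\nR\tK00001\tonly-two-fields\n")
    with pytest.raises(DataFileError, match="line 2"):
        load_store(p)


def test_load_rejects_garbage_after_header(tmp_path):
    p = tmp_path / "bad.dat"
    p.write_text("koview-data 1\ngarbage here\n")
    with pytest.raises(DataFileError, match="line 2"):
        load_store(p)


names = st.text(alphabet=st.characters(codec="utf-8", exclude_characters="\r"),
                min_size=0, max_size=30).map(str.strip)
pathway_lists = st.lists(
    st.tuples(st.from_regex(r"(ko|map)\d{5}", fullmatch=True), names),
    max_size=5, unique_by=lambda t: t[0],
)


@settings(derandomize=True, max_examples=75)
@given(st.dictionaries(st.from_regex(r"K\d{5}", fullmatch=True),
                       st.tuples(names, names, pathway_lists), max_size=8))
def test_store_roundtrip_property(tmp_path_factory, raw):
    """save_store → load_store is the identity for arbitrary field text."""
    records = {
        ko: KoRecord(ko, sym, "d " + deftext,
                     tuple(PathwayRef(m, n) for m, n in paths))
        for ko, (sym, deftext, paths) in raw.items()
    }
    store = RecordStore(records)
    p = tmp_path_factory.mktemp("rt") / "s.dat"
    loaded = load_store(save_store(store, p))
    assert loaded.records == store.records
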