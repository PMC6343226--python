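"""KEGG Orthology flat-file parsing, fetching, and the reloadable data file.

KEGG's REST ``get`` operation returns records in a line-oriented flat-file
dialect: a 12-character left-justified field key (ENTRY, SYMBOL, NAME,
DEFINITION, PATHWAY, ...), continuation lines indented by 12 spaces, and
records terminated by a ``///`` line.  Only the fields this tool reports
are parsed; everything else (ORTHOLOGY, GENES, BRITE, MODULE, REFERENCE)
is skipped.

Fetched records are cached in a versioned, tab-delimited text data file so
that reports can be regenerated without re-contacting KEGG.
"""

from __future__ import annotations

import logging
import re
import textwrap
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence
from urllib.request import urlopen

logger = logging.getLogger(__name__)

#: Pathway accession: "ko" or "map" prefix plus five digits.
MAP_PATTERN = re.compile(r"^(ko|map)\d{5}$")

_KEY_WIDTH = 12
DATA_FILE_HEADER = "koview-data 1"

#: KEGG's documented cap on entries per multi-entry ``get`` request.
BATCH_SIZE = 10

#: Minimum spacing between live requests, honouring KEGG's rate guidance.
LIVE_REQUEST_SPACING = 0.35

KEGG_REST_BASE = "https://rest.kegg.jp"


class KoFlatFileError(ValueError):
    """A flat-file block could not be parsed; carries the byte offset."""


class DataFileError(ValueError):
    """A data file is missing its header or contains a truncated record."""


class FetchError(RuntimeError):
    """Transport failed after retries; partial results are preserved.

    Attributes
    ----------
    unfetched : list of K numbers never retrieved.
    partial : the RecordStore accumulated before the failure.
    """

    def __init__(self, unfetched: Sequence[str], partial: "RecordStore") -> None:
        super().__init__(f"could not fetch {len(unfetched)} K numbers: {', '.join(unfetched)}")
        self.unfetched = list(unfetched)
        self.partial = partial


@dataclass(frozen=True)
class PathwayRef:
    """A pathway accession ("ko"/"map" + five digits) and its display name."""

    map_id: str
    name: str

    def __post_init__(self) -> None:
        if not MAP_PATTERN.match(self.map_id):
            raise ValueError(f"malformed pathway accession: {self.map_id!r}")


@dataclass(frozen=True)
class KoRecord:
    """One KEGG Orthology entry: identity, names, and linked pathways."""

    ko_id: str
    symbol: str
    definition: str
    pathways: tuple[PathwayRef, ...] = ()

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pathways:
            if p.map_id in seen:
                raise ValueError(f"{self.ko_id}: duplicate pathway {p.map_id}")
            seen.add(p.map_id)

    @property
    def display_name(self) -> str:
        """The gene-name column of the report: SYMBOL, falling back to NAME."""
        return self.symbol


@dataclass
class RecordStore:
    """Fetched KO records plus the K numbers the source could not return."""

    records: dict[str, KoRecord] = field(default_factory=dict)
    unresolvable: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.records) & self.unresolvable
        if overlap:
            raise ValueError(f"K numbers both resolved and unresolvable: {sorted(overlap)}")

    def resolvable(self, ko_id: str) -> bool:
        return ko_id in self.records


# ---------------------------------------------------------------------------
# Flat-file parsing
# ---------------------------------------------------------------------------

def _iter_blocks(text: str):
    """Yield (byte_offset, block_lines) for each ///-terminated block."""
    offset = 0
    lines: list[str] = []
    start = 0
    for raw in text.splitlines(keepends=True):
        stripped = raw.rstrip("\r\n")
        if stripped == "///":
            if lines:
                yield start, lines
            lines = []
            start = offset + len(raw.encode())
        else:
            if not lines:
                start = offset
            lines.append(stripped)
        offset += len(raw.encode())
    if any(l.strip() for l in lines):
        yield start, lines


def parse_ko_flatfile(text: str) -> list[KoRecord]:
    """Parse a KEGG ``get`` response body into a list of :class:`KoRecord`.

    One record per ENTRY block; PATHWAY continuation lines each yield a
    :class:`PathwayRef` (first token the accession, remainder the name);
    multi-line DEFINITION text is joined with single spaces.  A block with
    no parseable ENTRY line raises :class:`KoFlatFileError` naming the byte
    offset of the block; unknown field keys are ignored.
    """
    records: list[KoRecord] = []
    for offset, lines in _iter_blocks(text):
        fields: dict[str, list[str]] = {}
        key = None
        for line in lines:
            if not line.strip():
                continue
            if line[:1] != " ":
                key = line[:_KEY_WIDTH].strip()
                value = line[_KEY_WIDTH:].strip()
                fields.setdefault(key, []).append(value)
            elif key is not None:
                fields.setdefault(key, []).append(line.strip())
        entry = fields.get("ENTRY")
        if not entry or not entry[0]:
            raise KoFlatFileError(f"block at byte offset {offset}: no parseable ENTRY line")
        entry_tokens = entry[0].split()
        ko_id = entry_tokens[0]
        if not re.match(r"^K\d{5}$", ko_id):
            raise KoFlatFileError(
                f"block at byte offset {offset}: ENTRY token {ko_id!r} is not a K number"
            )
        symbol = " ".join(" ".join(fields["SYMBOL"]).split()) if "SYMBOL" in fields else ""
        name = " ".join(" ".join(fields["NAME"]).split()) if "NAME" in fields else ""
        definition = " ".join(" ".join(fields["DEFINITION"]).split()) if "DEFINITION" in fields else ""
        pathways = []
        for pline in fields.get("PATHWAY", []):
            if not pline:
                continue
            tok, _, rest = pline.partition(" ")
            pathways.append(PathwayRef(tok, rest.strip()))
        records.append(
            KoRecord(
                ko_id=ko_id,
                symbol=symbol or name,
                definition=definition or name,
                pathways=tuple(pathways),
            )
        )
    return records


def records_to_flatfile(records: Iterable[KoRecord]) -> str:
    """Serialize records back to the canonical flat-file dialect.

    The output round-trips: ``parse_ko_flatfile(records_to_flatfile(rs))``
    reproduces ``rs`` field-for-field.  Long definitions are wrapped onto
    indented continuation lines exactly as KEGG prints them.
    """
    out: list[str] = []

    def emit(key: str, value: str) -> None:
        wrapped = textwrap.wrap(value, width=79 - _KEY_WIDTH) or [""]
        out.append(f"{key:<{_KEY_WIDTH}}{wrapped[0]}")
        for cont in wrapped[1:]:
            out.append(" " * _KEY_WIDTH + cont)

    for rec in records:
        out.append(f"{'ENTRY':<{_KEY_WIDTH}}{rec.ko_id:<28}KO")
        if rec.symbol:
            emit("SYMBOL", rec.symbol)
        emit("DEFINITION", rec.definition)
        for i, p in enumerate(rec.pathways):
            key = "PATHWAY" if i == 0 else ""
            out.append(f"{key:<{_KEY_WIDTH}}{p.map_id}  {p.name}")
        out.append("///")
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# Fetching
# ---------------------------------------------------------------------------

Transport = Callable[[Sequence[str]], str]


def rest_transport(base_url: str = KEGG_REST_BASE, spacing: float = LIVE_REQUEST_SPACING) -> Transport:
    """A live transport hitting the KEGG REST ``get`` endpoint.

    Requests are spaced by at least ``spacing`` seconds.  Never used in
    tests; the transport seam exists precisely so the suite stays offline.
    """
    last = [0.0]

    def get(batch: Sequence[str]) -> str:
        wait = spacing - (time.monotonic() - last[0])
        if wait > 0:
            time.sleep(wait)
        url = f"{base_url.rstrip('/')}/get/{'+'.join(batch)}"
        with urlopen(url) as resp:  # noqa: S310 - scheme fixed by caller
            body = resp.read().decode("utf-8")
        last[0] = time.monotonic()
        return body

    return get


def fetch_records(
    ko_ids: Sequence[str],
    transport: Transport,
    batch_size: int = BATCH_SIZE,
    retries: int = 3,
    backoff: float = 0.5,
    sleep: Callable[[float], None] = time.sleep,
) -> RecordStore:
    """Fetch KO records in batches through ``transport``.

    Duplicate requests are collapsed (first occurrence wins the order);
    every requested K number ends up either in ``records`` or in
    ``unresolvable`` — KEGG's multi-entry ``get`` silently drops unknown
    identifiers, which is how unresolvable K numbers are detected.  Each
    batch is attempted up to ``retries`` times with exponential backoff;
    a batch that still fails raises :class:`FetchError` carrying the
    partial store and the K numbers never retrieved.
    """
    ordered = list(dict.fromkeys(ko_ids))
    store = RecordStore()
    for start in range(0, len(ordered), batch_size):
        batch = ordered[start : start + batch_size]
        body = None
        for attempt in range(retries):
            try:
                body = transport(batch)
                break
            except Exception as exc:  # transport errors are opaque to us
                if attempt + 1 == retries:
                    raise FetchError(ordered[start:], store) from exc
                delay = backoff * (2**attempt)
                logger.warning("batch %r attempt %d failed (%s); retrying in %.2fs",
                               batch, attempt + 1, exc, delay)
                sleep(delay)
        assert body is not None
        got = {rec.ko_id: rec for rec in parse_ko_flatfile(body)}
        for ko in batch:
            if ko in got:
                store.records[ko] = got[ko]
            else:
                store.unresolvable.add(ko)
    return store


# ---------------------------------------------------------------------------
# Data file (the reloadable cache)
# ---------------------------------------------------------------------------

_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r", "|": "\\p"}
_UNESCAPES = {"\\\\": "\\", "\\t": "\t", "\\n": "\n", "\\r": "\r", "\\p": "|"}


def _esc(s: str) -> str:
    for lit, esc in _ESCAPES.items():
        s = s.replace(lit, esc)
    return s


def _unesc(s: str) -> str:
    out = []
    i = 0
    while i < len(s):
        if s[i] == "\\" and i + 1 < len(s):
            pair = s[i : i + 2]
            if pair in _UNESCAPES:
                out.append(_UNESCAPES[pair])
                i += 2
                continue
        out.append(s[i])
        i += 1
    return "".join(out)


def save_store(store: RecordStore, path: str | Path) -> Path:
    """Write the store to a versioned, line-oriented text data file.

    Format: a ``koview-data 1`` header line; one ``R`` line per record
    (ko, symbol, definition, pathways as ``map_id:name`` joined by ``|``,
    tab-separated, with tab/newline/pipe backslash-escaped); one ``U`` line
    per unresolvable K number.  Deliberately diffable and inspectable.
    """
    path = Path(path)
    lines = [DATA_FILE_HEADER]
    for ko in sorted(store.records):
        rec = store.records[ko]
        pw = "|".join(f"{p.map_id}:{_esc(p.name)}" for p in rec.pathways)
        lines.append(f"R\t{rec.ko_id}\t{_esc(rec.symbol)}\t{_esc(rec.definition)}\t{pw}")
    for ko in sorted(store.unresolvable):
        lines.append(f"U\t{ko}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def load_store(path: str | Path) -> RecordStore:
    """Load a data file written by :func:`save_store`.

    Raises :class:`DataFileError` naming the offending line if the version
    header is missing or a record line is truncated or unrecognized.
    """
    path = Path(path)
    # newline="" + split on "\n" only: field text may contain characters
    # (form feed, \r) that splitlines()/universal newlines would mangle.
    with open(path, encoding="utf-8", newline="") as fh:
        text = fh.read()
    lines = text.split("\n")
    if not lines or lines[0] != DATA_FILE_HEADER:
        raise DataFileError(f"{path}: line 1: missing data-file header {DATA_FILE_HEADER!r}")
    store = RecordStore()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        kind, _, rest = line.partition("\t")
        if kind == "R":
            parts = rest.split("\t")
            if len(parts) != 4:
                raise DataFileError(f"{path}: line {lineno}: truncated record line")
            ko_id, symbol, definition, pw = parts
            pathways = []
            if pw:
                for item in pw.split("|"):
                    map_id, _, name = item.partition(":")
                    pathways.append(PathwayRef(map_id, _unesc(name)))
            try:
                store.records[ko_id] = KoRecord(
                    ko_id, _unesc(symbol), _unesc(definition), tuple(pathways)
                )
            except ValueError as exc:
                raise DataFileError(f"{path}: line {lineno}: {exc}") from exc
        elif kind == "U":
            store.unresolvable.add(rest.strip())
        else:
            raise DataFileError(f"{path}: line {lineno}: unrecognized line type {kind!r}")
    return store
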