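"""KEGG pathway-map highlight URLs.

The ``show_pathway`` CGI accepts a ``multi_query`` parameter carrying one
highlight instruction per URL-encoded-CRLF-separated line, in the dialect
``entry<space>bgcolor[,fgcolor]``.  We emit one line per K number present
in the assembly and mapped to the pathway: cohort members get the light
green fill, and the focal gene — placed last — gets a distinct node fill
plus a font color, so it stands out on the rendered map.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from koview.kegg_records import MAP_PATTERN

_HEX = re.compile(r"^[0-9a-fA-F]{6}$")
_KO = re.compile(r"^K\d{5}$")

DEFAULT_BASE_URL = "https://www.kegg.jp"
CRLF = "%0d%0a"


@dataclass(frozen=True)
class HighlightColors:
    """Node/font colors as bare 6-hex-digit tokens (no leading ``#``).

    The ``#`` is added, URL-encoded as ``%23``, at render time.  Defaults:
    light green fill for cohort genes, dark red node with white font for
    the focal gene.
    """

    cohort_fill: str = "bfffbf"
    focal_fill: str = "8b0000"
    focal_font: str = "ffffff"

    def __post_init__(self) -> None:
        for c in (self.cohort_fill, self.focal_fill, self.focal_font):
            if not _HEX.match(c):
                raise ValueError(f"color must be 6 hex digits without '#': {c!r}")


@dataclass(frozen=True)
class HighlightRequest:
    """A pathway, the member K numbers to highlight, and the focal one."""

    map_id: str
    member_kos: tuple[str, ...]
    focal_ko: str

    def __post_init__(self) -> None:
        if not MAP_PATTERN.match(self.map_id):
            raise ValueError(f"malformed pathway accession: {self.map_id!r}")
        if not self.member_kos:
            raise ValueError("member_kos must be non-empty")
        if len(set(self.member_kos)) != len(self.member_kos):
            raise ValueError("member_kos contains duplicates")
        for ko in self.member_kos:
            if not _KO.match(ko):
                raise ValueError(f"malformed K number: {ko!r}")
        if self.focal_ko not in self.member_kos:
            raise ValueError(f"focal K number {self.focal_ko} not among members")


def _query_lines(members: Sequence[str], focal: str | None, colors: HighlightColors) -> list[str]:
    cohort = sorted(ko for ko in members if ko != focal)
    lines = [f"{ko}+%23{colors.cohort_fill}" for ko in cohort]
    if focal is not None:
        lines.append(f"{focal}+%23{colors.focal_fill},%23{colors.focal_font}")
    return lines


def build_highlight_url(
    req: HighlightRequest,
    colors: HighlightColors = HighlightColors(),
    base_url: str = DEFAULT_BASE_URL,
) -> str:
    """Build the pathway-map URL highlighting the focal gene.

    Each non-focal member contributes the line ``<K>+%23<cohort_fill>``;
    the focal member contributes the final line
    ``<K>+%23<focal_fill>,%23<focal_font>``.  Non-focal members appear in
    ascending K-number order, so the URL is byte-deterministic.
    """
    lines = _query_lines(req.member_kos, req.focal_ko, colors)
    query = CRLF.join(lines)
    return f"{base_url.rstrip('/')}/kegg-bin/show_pathway?map={req.map_id}&multi_query={query}"


def build_pathway_url(
    map_id: str,
    member_kos: Sequence[str],
    colors: HighlightColors = HighlightColors(),
    base_url: str = DEFAULT_BASE_URL,
) -> str:
    """Pathway-map URL with every member cohort-colored and no focal gene.

    Used by the pathway-centered report sections, where no single gene is
    singled out.
    """
    lines = _query_lines(list(dict.fromkeys(member_kos)), None, colors)
    query = CRLF.join(lines)
    url = f"{base_url.rstrip('/')}/kegg-bin/show_pathway?map={map_id}"
    return f"{url}&multi_query={query}" if query else url
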