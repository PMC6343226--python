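"""Rendering of the three-section HTML report.

Section 1, "Genes and Linked Pathways", is the gene-centered table: one
row per query gene with its K number, ortholog name, functional
definition, and every linked pathway as a hyperlink that opens the KEGG
pathway map with that gene highlighted in dark red and all other
identified genes in light green.  Sections 2 and 3 give the
pathway-centered view: the same pathways sorted by number of identified
genes and alphabetically, respectively.

The output is a single self-contained, dependency-free HTML file (inline
minimal CSS, no JavaScript) that opens identically in any browser.  All
user-derived text is HTML-escaped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from html import escape

from koview.linker import AnnotationStore, summarize_pathways
from koview.urls import (
    DEFAULT_BASE_URL,
    HighlightColors,
    HighlightRequest,
    build_highlight_url,
    build_pathway_url,
)

SECTION_HEADINGS = (
    "Genes and Linked Pathways",
    "Pathways by Number of Identified Genes",
    "Pathways in Alphabetical Order",
)

_STYLE = """
body { font-family: sans-serif; margin: 2em; }
table { border-collapse: collapse; margin-bottom: 2em; }
th, td { border: 1px solid #999; padding: 4px 8px; text-align: left; vertical-align: top; }
th { background: #eee; }
"""


@dataclass(frozen=True)
class ReportOptions:
    """Report title, highlight colors, and handling of pathway-less genes."""

    title: str = "Gene Annotation Report"
    colors: HighlightColors = field(default_factory=HighlightColors)
    include_unpathwayed: bool = True
    base_url: str = DEFAULT_BASE_URL

    def __post_init__(self) -> None:
        if not self.title:
            raise ValueError("report title must be non-empty")


def _gene_row(gene, store: AnnotationStore, options: ReportOptions) -> str:
    links = []
    for p in gene.pathways:
        _, _, member_kos = store.pathway_index[p.map_id]
        url = build_highlight_url(
            HighlightRequest(p.map_id, tuple(sorted(member_kos)), gene.ko_id),
            options.colors,
            options.base_url,
        )
        links.append(f'<a href="{escape(url, quote=True)}">{escape(p.name)}</a>')
    pathway_cell = ", ".join(links) if links else "&mdash;"
    return (
        "<tr>"
        f"<td>{escape(gene.gene_id)}</td>"
        f"<td>{escape(gene.ko_id)}</td>"
        f"<td>{escape(gene.symbol)}</td>"
        f"<td>{escape(gene.definition)}</td>"
        f"<td>{pathway_cell}</td>"
        "</tr>"
    )


def _pathway_rows(summaries, options: ReportOptions) -> list[str]:
    rows = []
    for s in summaries:
        url = build_pathway_url(s.map_id, sorted(s.member_kos), options.colors, options.base_url)
        rows.append(
            "<tr>"
            f"<td>{escape(s.map_id)}</td>"
            f'<td><a href="{escape(url, quote=True)}">{escape(s.name)}</a></td>'
            f"<td>{s.gene_count}</td>"
            "</tr>"
        )
    return rows


def render_report(store: AnnotationStore, options: ReportOptions = ReportOptions()) -> str:
    """Render the annotation store as the three-section HTML document.

    An empty store still renders a valid document with all three section
    headings and zero data rows.  Gene rows keep input-file order; genes
    whose KO maps to no pathway appear with an em-dash placeholder when
    ``include_unpathwayed`` is set, and are omitted otherwise.
    """
    gene_rows = [
        _gene_row(g, store, options)
        for g in store.genes.values()
        if g.pathways or options.include_unpathwayed
    ]
    by_count = summarize_pathways(store, "by_count")
    alphabetical = summarize_pathways(store, "alphabetical")

    parts = [
        "<!DOCTYPE html>",
        '<html lang="en">',
        "<head>",
        '<meta charset="utf-8">',
        f"<title>{escape(options.title)}</title>",
        f"<style>{_STYLE}</style>",
        "</head>",
        "<body>",
        f"<h1>{escape(options.title)}</h1>",
        f"<h2>{escape(SECTION_HEADINGS[0])}</h2>",
        '<table id="genes">',
        "<thead><tr><th>Gene ID</th><th>K number</th><th>Gene name</th>"
        "<th>Definition</th><th>Linked pathways</th></tr></thead>",
        "<tbody>",
        *gene_rows,
        "</tbody>",
        "</table>",
        f"<h2>{escape(SECTION_HEADINGS[1])}</h2>",
        '<table id="pathways-by-count">',
        "<thead><tr><th>Accession</th><th>Pathway</th><th>Genes</th></tr></thead>",
        "<tbody>",
        *_pathway_rows(by_count, options),
        "</tbody>",
        "</table>",
        f"<h2>{escape(SECTION_HEADINGS[2])}</h2>",
        '<table id="pathways-alphabetical">',
        "<thead><tr><th>Accession</th><th>Pathway</th><th>Genes</th></tr></thead>",
        "<tbody>",
        *_pathway_rows(alphabetical, options),
        "</tbody>",
        "</table>",
        "</body>",
        "</html>",
    ]
    return "\n".join(parts) + "\n"
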