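"""Parsing and trimming of KAAS-style gene→KO assignment tables.

The KEGG Automatic Annotation Server emits a two-column, tab-separated
table: column 1 is the user's gene identifier, column 2 the assigned
K number (absent when no ortholog was found).  Before any KEGG lookup
the table is trimmed: genes without a K number, and genes whose K number
cannot be resolved against the KEGG database, are removed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

logger = logging.getLogger(__name__)

#: A well-formed KEGG Orthology identifier: the letter K plus five digits.
KO_PATTERN = re.compile(r"^K\d{5}$")

#: First-column tokens that mark a header line rather than a gene.
_HEADER_TOKENS = frozenset({"gene", "gene_id", "geneid", "query", "#gene", "#query", "id"})


@dataclass(frozen=True)
class GeneAssignment:
    """One row of the assignment table: a gene and its optional K number."""

    gene_id: str
    ko_id: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if any(c in self.gene_id for c in "\t\n\r"):
            raise ValueError(f"gene_id contains forbidden whitespace: {self.gene_id!r}")
        if self.ko_id is not None and not KO_PATTERN.match(self.ko_id):
            raise ValueError(f"malformed K number: {self.ko_id!r}")


@dataclass
class TrimReport:
    """Outcome of trimming: kept rows plus the two classes of dropped rows.

    The three parts partition the input: every parsed row lands in exactly
    one of ``kept``, ``dropped_no_ko`` or ``dropped_unresolvable``.
    """

    kept: list[GeneAssignment] = field(default_factory=list)
    dropped_no_ko: list[str] = field(default_factory=list)
    dropped_unresolvable: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.kept) + len(self.dropped_no_ko) + len(self.dropped_unresolvable)


def _split_row(line: str) -> list[str]:
    # Tab is the KAAS dialect; fall back to any whitespace run so that
    # hand-edited or space-aligned tables are still accepted.
    if "\t" in line:
        fields = [f.strip() for f in line.split("\t")]
    else:
        fields = line.split()
    return [f for f in fields if f != ""] if "\t" not in line else fields


def parse_assignments(text: str) -> list[GeneAssignment]:
    """Parse raw assignment-table text into one :class:`GeneAssignment` per row.

    Blank lines are skipped.  A row with only a gene ID yields ``ko_id=None``.
    A second field that is non-empty but not a well-formed K number is demoted
    to "no KO" with a logged warning rather than aborting the run.  A first
    line that looks like a column header (recognized first token, second field
    not a K number) is skipped with a warning.
    """
    assignments: list[GeneAssignment] = []
    first_data_line = True
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip("\r\n").strip()
        if not line:
            continue
        fields = _split_row(line)
        if not fields or not fields[0]:
            continue
        gene_id = fields[0]
        ko_field = fields[1] if len(fields) > 1 else ""
        if first_data_line and ko_field and not KO_PATTERN.match(ko_field):
            if gene_id.lower() in _HEADER_TOKENS:
                logger.warning("line %d: skipping header row %r", lineno, line)
                first_data_line = False
                continue
        first_data_line = False
        if ko_field and not KO_PATTERN.match(ko_field):
            logger.warning(
                "line %d: malformed K number %r for gene %r; treating as no KO",
                lineno, ko_field, gene_id,
            )
            ko_field = ""
        assignments.append(GeneAssignment(gene_id, ko_field or None))
    return assignments


def trim_assignments(
    assignments: Sequence[GeneAssignment],
    resolvable: Callable[[str], bool],
) -> TrimReport:
    """Partition assignments into kept / no-KO / unresolvable-KO classes.

    ``resolvable`` is a total predicate over well-formed K numbers, normally
    backed by the fetched record store (a K number the KEGG database cannot
    return is unresolvable).  Input order is preserved within each part.
    """
    report = TrimReport()
    for a in assignments:
        if a.ko_id is None:
            report.dropped_no_ko.append(a.gene_id)
        elif not resolvable(a.ko_id):
            report.dropped_unresolvable.append((a.gene_id, a.ko_id))
        else:
            report.kept.append(a)
    return report


def format_assignments(assignments: Iterable[GeneAssignment]) -> str:
    """Serialize assignments back to the two-column tab-separated dialect."""
    lines = []
    for a in assignments:
        lines.append(f"{a.gene_id}\t{a.ko_id}" if a.ko_id else a.gene_id)
    return "\n".join(lines) + ("\n" if lines else "")
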