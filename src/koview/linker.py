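"""The gene-centered join: assignments × KO records → annotation table.

This is the pure transformation layer.  It joins trimmed assignments to
their KO records, maintains a pathway→members inverted index, produces
the two pathway-centered orderings (by gene count, alphabetical), and
applies keyword filters scoped to definitions and/or pathway names.
No enrichment statistics — membership counts only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

from koview.input_io import TrimReport
from koview.kegg_records import PathwayRef, RecordStore

logger = logging.getLogger(__name__)

Scope = Literal["definition", "pathway", "both"]
Order = Literal["by_count", "alphabetical"]


@dataclass(frozen=True)
class AnnotatedGene:
    """One report row: gene, K number, ortholog name, definition, pathways."""

    gene_id: str
    ko_id: str
    symbol: str
    definition: str
    pathways: tuple[PathwayRef, ...]


@dataclass
class AnnotationStore:
    """Ordered gene table plus the pathway→members inverted index.

    ``pathway_index`` maps each pathway accession to its display name, the
    set of gene IDs linked to it, and the set of K numbers those genes
    carry; it is always exactly the inversion of the genes' pathway lists.
    """

    genes: dict[str, AnnotatedGene] = field(default_factory=dict)
    pathway_index: dict[str, tuple[str, set[str], set[str]]] = field(default_factory=dict)

    def check_consistent(self) -> None:
        """Verify the index against a from-scratch recomputation."""
        rebuilt = _invert(self.genes)
        if rebuilt != self.pathway_index:
            raise AssertionError("pathway_index inconsistent with gene table")


@dataclass(frozen=True)
class PathwaySummary:
    """One pathway with its member count and member K numbers."""

    map_id: str
    name: str
    gene_count: int
    member_kos: frozenset[str]


@dataclass(frozen=True)
class FilterSpec:
    """A case-insensitive substring keyword filter.

    ``scope`` selects what the keyword is matched against: the KO
    functional definition, the names of linked pathways, or both.
    """

    keyword: str
    scope: Scope = "both"

    def __post_init__(self) -> None:
        if not self.keyword:
            raise ValueError("filter keyword must be non-empty")
        if self.scope not in ("definition", "pathway", "both"):
            raise ValueError(f"invalid filter scope: {self.scope!r}")

    def matches(self, gene: AnnotatedGene) -> bool:
        kw = self.keyword.casefold()
        if self.scope in ("definition", "both") and kw in gene.definition.casefold():
            return True
        if self.scope in ("pathway", "both"):
            return any(kw in p.name.casefold() for p in gene.pathways)
        return False


def _invert(genes: dict[str, AnnotatedGene]) -> dict[str, tuple[str, set[str], set[str]]]:
    index: dict[str, tuple[str, set[str], set[str]]] = {}
    for gene in genes.values():
        for p in gene.pathways:
            name, gids, kos = index.setdefault(p.map_id, (p.name, set(), set()))
            gids.add(gene.gene_id)
            kos.add(gene.ko_id)
    return index


def build_annotation(trim: TrimReport, store: RecordStore) -> AnnotationStore:
    """Join kept assignments to their KO records.

    Genes keep input order; duplicate gene IDs collapse last-wins with a
    warning (the table is keyed by gene ID).  A kept K number missing from
    the record store violates the trimming contract and raises.
    """
    genes: dict[str, AnnotatedGene] = {}
    for a in trim.kept:
        rec = store.records.get(a.ko_id)
        if rec is None:
            raise LookupError(
                f"trimming contract violated: kept K number {a.ko_id} "
                f"(gene {a.gene_id}) is not in the record store"
            )
        if a.gene_id in genes:
            logger.warning("duplicate gene ID %r: keeping the last assignment", a.gene_id)
            del genes[a.gene_id]  # re-insert so the row takes its last position
        genes[a.gene_id] = AnnotatedGene(
            gene_id=a.gene_id,
            ko_id=a.ko_id,
            symbol=rec.display_name,
            definition=rec.definition,
            pathways=rec.pathways,
        )
    return AnnotationStore(genes=genes, pathway_index=_invert(genes))


def summarize_pathways(store: AnnotationStore, order: Order = "by_count") -> list[PathwaySummary]:
    """Pathway-centered summaries in one of the report's two orderings.

    ``by_count`` sorts by descending gene count with ties broken by name
    ascending; ``alphabetical`` sorts by name, case-insensitively.  Both
    orderings contain the same summaries.
    """
    summaries = [
        PathwaySummary(map_id, name, len(gids), frozenset(kos))
        for map_id, (name, gids, kos) in store.pathway_index.items()
    ]
    if order == "by_count":
        summaries.sort(key=lambda s: (-s.gene_count, s.name.casefold(), s.map_id))
    elif order == "alphabetical":
        summaries.sort(key=lambda s: (s.name.casefold(), s.map_id))
    else:
        raise ValueError(f"unknown ordering: {order!r}")
    return summaries


def apply_filter(store: AnnotationStore, spec: FilterSpec) -> AnnotationStore:
    """Retain exactly the genes matching the keyword filter.

    The gene table is filtered first and the pathway index rebuilt from
    the retained genes only, so the pathway sections always describe
    exactly the genes shown.  Never adds genes; idempotent.
    """
    kept = {gid: g for gid, g in store.genes.items() if spec.matches(g)}
    if not kept:
        logger.warning("filter %r (%s) matched no genes", spec.keyword, spec.scope)
    return AnnotationStore(genes=kept, pathway_index=_invert(kept))
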