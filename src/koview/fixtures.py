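"""Synthetic KO universes, assignment tables, and a mock transport.

Everything here is deterministic given a seed, so the rest of the package
is testable (and demonstrable) entirely offline.  The generated flat-file
text is in the same dialect the real tool consumes, and fractions are
applied as exact floor counts rather than Bernoulli draws so end-to-end
tests have exact expectations (e.g. 100 genes with missing_fraction 0.2
and unknown_fraction 0.1 always yield exactly 70 kept genes).

One synthetic pathway name always contains the keyword ``circadian`` and
one always contains ``metabolism``, giving filter tests a controlled
vocabulary with known-cardinality answers.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

from koview.kegg_records import KoRecord, PathwayRef, records_to_flatfile

FILTER_KEYWORDS = ("circadian", "metabolism")

_NAME_WORDS = (
    "signaling", "biosynthesis", "degradation", "transport", "repair",
    "cycle", "secretion", "response", "processing", "assembly",
)
_SUBJECTS = (
    "Glycan", "Fatty acid", "Amino acid", "Nucleotide", "Steroid",
    "Photon", "Ion", "Peptide", "Lipid", "Sugar",
)


@dataclass(frozen=True)
class UniverseSpec:
    """Shape of a synthetic KO universe.

    ``membership_rate`` is the expected number of pathways per KO (for
    KOs that have any); ``no_pathway_fraction`` of KOs, applied as an
    exact floor count, get empty pathway lists.
    """

    n_kos: int = 30
    n_pathways: int = 8
    membership_rate: float = 2.0
    no_pathway_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_kos <= 0 or self.n_pathways <= 0:
            raise ValueError("n_kos and n_pathways must be positive")
        if not (0.0 <= self.no_pathway_fraction <= 1.0):
            raise ValueError("no_pathway_fraction must be in [0, 1]")
        if self.membership_rate < 1.0:
            raise ValueError("membership_rate must be >= 1")


def _pathway_name(i: int, rng: random.Random) -> str:
    if i < len(FILTER_KEYWORDS):
        # Controlled vocabulary: guaranteed hits for filter tests.
        return f"{FILTER_KEYWORDS[i].capitalize()} {rng.choice(_NAME_WORDS)}"
    return f"{rng.choice(_SUBJECTS)} {rng.choice(_NAME_WORDS)} {i:03d}"


def generate_universe(spec: UniverseSpec) -> tuple[list[KoRecord], str]:
    """Generate KO records K00001..K<n> over pathways ko00001..ko<m>.

    Returns the records and their canonical flat-file text; the text
    parses back (via ``parse_ko_flatfile``) to exactly the returned
    records.
    """
    rng = random.Random(spec.seed)
    pathways = [
        PathwayRef(f"ko{i + 1:05d}", _pathway_name(i, rng))
        for i in range(spec.n_pathways)
    ]
    n_empty = int(spec.no_pathway_fraction * spec.n_kos)
    empty_idx = set(rng.sample(range(spec.n_kos), n_empty))
    records = []
    for i in range(spec.n_kos):
        ko_id = f"K{i + 1:05d}"
        if i in empty_idx:
            linked: tuple[PathwayRef, ...] = ()
        else:
            # Uniform on [1, 2*rate-1] has mean = membership_rate.
            hi = max(1, round(2 * spec.membership_rate - 1))
            k = min(spec.n_pathways, rng.randint(1, hi))
            linked = tuple(sorted(rng.sample(pathways, k), key=lambda p: p.map_id))
        symbol = f"syn{i + 1}, E{(i % 6) + 1}.{(i % 4) + 1}.{(i % 3) + 1}.{i + 1}"
        definition = (
            f"synthetic enzyme {i + 1} catalyzing reaction {rng.randint(1, 999)} "
            f"[EC:{(i % 6) + 1}.{(i % 4) + 1}.{(i % 3) + 1}.{i + 1}]"
        )
        records.append(KoRecord(ko_id, symbol, definition, linked))
    return records, records_to_flatfile(records)


def generate_assignments(
    universe: Sequence[KoRecord],
    n_genes: int,
    missing_fraction: float = 0.0,
    unknown_fraction: float = 0.0,
    seed: int = 0,
) -> str:
    """Generate an assignment table over a universe, as raw table text.

    Exactly ``floor(missing_fraction * n_genes)`` rows carry no K number
    and exactly ``floor(unknown_fraction * n_genes)`` rows carry
    well-formed K numbers absent from the universe (exercising the
    unresolvable-KO trim rule); the remaining rows draw K numbers from
    the universe with replacement.  Which rows get which fate is a seeded
    shuffle, so the table interleaves the classes deterministically.
    """
    if not (0.0 <= missing_fraction <= 1.0 and 0.0 <= unknown_fraction <= 1.0):
        raise ValueError("fractions must be in [0, 1]")
    if missing_fraction + unknown_fraction > 1.0:
        raise ValueError("missing_fraction + unknown_fraction must be <= 1")
    rng = random.Random(seed)
    n_missing = int(missing_fraction * n_genes)
    n_unknown = int(unknown_fraction * n_genes)
    fates = ["missing"] * n_missing + ["unknown"] * n_unknown
    fates += ["known"] * (n_genes - len(fates))
    rng.shuffle(fates)
    known_ids = [rec.ko_id for rec in universe]
    lines = []
    for g, fate in enumerate(fates, start=1):
        gene_id = f"gene_{g:05d}"
        if fate == "missing":
            lines.append(gene_id)
        elif fate == "unknown":
            # K9xxxx identifiers are outside the generated universe.
            lines.append(f"{gene_id}\tK9{rng.randint(0, 9999):04d}")
        else:
            lines.append(f"{gene_id}\t{rng.choice(known_ids)}")
    return "\n".join(lines) + ("\n" if lines else "")


class TransportFault(RuntimeError):
    """Injected transport failure."""


class MockTransport:
    """A KO-text source backed by a generated universe.

    Given a batch of K numbers, returns the concatenated flat-file records
    for the known ones and silently omits unknown ones — matching live
    KEGG behavior for multi-entry ``get``.  Records request history for
    batching assertions, and can inject a failure on chosen request
    ordinals (1-based) to exercise retry logic; each injected fault fires
    once.
    """

    def __init__(self, universe: Sequence[KoRecord], fail_on: Sequence[int] = ()) -> None:
        self._records = {rec.ko_id: rec for rec in universe}
        self._fail_on = set(fail_on)
        self.history: list[tuple[str, ...]] = []

    def __call__(self, batch: Sequence[str]) -> str:
        self.history.append(tuple(batch))
        n = len(self.history)
        if n in self._fail_on:
            self._fail_on.discard(n)
            raise TransportFault(f"injected fault on request {n}")
        known = [self._records[ko] for ko in batch if ko in self._records]
        return records_to_flatfile(known)
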