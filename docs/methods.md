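# Methods

## What the tool computes

`koview` performs no statistics: it is a deterministic join-and-render
pipeline. Given a gene → KO assignment table and the KO records behind it,
the annotation store is the pair (ordered gene table, pathway inverted
index), where the index maps each pathway accession to the set of gene IDs
linked to it and the set of K numbers those genes carry. Pathway "coverage"
is reported as raw membership counts — deliberately no enrichment test
(hypergeometric or otherwise), because the input is typically a whole
annotated assembly, not a sample against a background.

## Pipeline and its assumptions

1. **Parsing.** The KAAS dialect is two tab-separated columns; any
   whitespace run is accepted as a fallback separator for hand-edited
   tables. A second field that is not `K` + five digits is demoted to
   "no KO" with a warning rather than aborting: a single stray row should
   not kill a genome-scale run. A recognizable header line (`gene`,
   `gene_id`, `query`, ... in column 1 with a non-K second field) is
   skipped; anything else is data.
2. **Trimming.** Genes are dropped for exactly two causes — no K number,
   or a K number the record source cannot return — and the three parts
   always partition the parsed rows. Trimming happens *after* fetching, so
   "unresolvable" is defined by the authoritative source (live KEGG or the
   loaded cache), not by a local heuristic.
3. **Fetching.** KEGG's REST `get` accepts at most 10 entries per request,
   so requests are batched at 10, sequential, spaced ≥ 0.35 s in live mode.
   Each batch gets 3 attempts with exponential backoff (0.5 s, 1 s);
   a batch that still fails raises an error carrying the partial store and
   the never-fetched K numbers, so a long run is resumable. KEGG silently
   drops unknown identifiers from multi-entry responses; a requested K
   number absent from the parsed response is therefore recorded as
   unresolvable. Requested IDs always end up in exactly one of
   records/unresolvable.
4. **Flat-file parsing.** Only ENTRY, SYMBOL, NAME, DEFINITION and PATHWAY
   are interpreted (12-column left-justified keys, indented continuations,
   `///` terminators); all other fields are skipped. Multi-line
   definitions are joined with single spaces; each PATHWAY line yields
   (accession, display name). The report's "gene name" column uses SYMBOL,
   falling back to NAME. Pathway accessions are stored as returned
   (`ko`-prefixed in KO records) with no prefix rewriting.
5. **Joining.** Duplicate gene IDs collapse last-wins with a warning (the
   table is keyed by gene ID); the surviving row keeps its position in
   input order. The inverted index is rebuilt from the gene table whenever
   the table changes, so the pathway sections always describe exactly the
   genes shown.
6. **Filtering.** Case-insensitive substring match (`casefold`), scoped to
   the definition, the linked pathway names, or both. Substring rather
   than word-boundary or regex: it maximizes recall and its behavior is
   trivially explainable. Filters are monotone (never add genes) and
   idempotent; an empty result is a valid empty report plus a warning, not
   an error.
7. **Rendering.** Static HTML, inline CSS, no JavaScript, everything
   escaped — the file must open identically in any browser. Section order:
   gene table (input order), pathways by descending gene count (ties by
   name, case-insensitively, then accession), pathways alphabetically.
   The two pathway sections are permutations of the same summaries.
   Pathway names in sections 2/3 also link to the map with all members
   cohort-colored and no focal gene; linking a pathway-centered section is
   strictly more useful than plain text. Genes whose KO maps to no pathway
   stay in section 1 with an em-dash placeholder (configurable).

## Highlight-URL grammar

`multi_query` lines follow KEGG's documented `entry bgcolor[,fgcolor]`
per-line dialect, encoded as `K…+%23<hex>` joined by `%0d%0a`. Cohort
members are emitted in ascending K-number order and the focal member last,
making URLs byte-deterministic. Colors are bare 6-hex-digit tokens;
defaults: cohort fill `bfffbf` (light green), focal node `8b0000` (dark
red), focal font `ffffff`. "Dark red" is pinned to `8b0000` as a concrete
choice; any 6-digit hex can be passed instead. Offline tests validate the
grammar by URL-decoding and re-parsing, not remote rendering.

## The data file

A versioned, line-oriented, tab-delimited text format (header
`koview-data 1`; one `R` line per record with pathways as `map:name` pairs
joined by `|`; one `U` line per unresolvable K number; backslash escapes
for tab, newline, carriage return and pipe). Text rather than pickle
because it is inspectable, diffable, language-agnostic and safe to load.
Loading validates the header and field counts and reports the offending
line number. `load(save(store))` is field-exact, which is what makes the
extract-then-render and render-from-cache paths byte-identical.

## Batch semantics

A batch job is a list of inputs, a mode, and one shared filter. The list
comes from a path-list file (one path per line, blanks skipped, relative
paths resolved against the list file) or the literal `all`, which selects
every `*.txt` in the working directory (extract mode) or every `*.dat`
(render mode), sorted by name. In render mode the assignment table is the
`.txt` sibling of each `.dat`. Outputs are written next to their inputs.
One input's failure is recorded and does not abort the rest; the exit
status is 1 if any input failed, 2 for usage errors. Inputs are processed
sequentially — parallel fetching would defeat the live-mode rate limit.

## Synthetic universes (what the generator emulates, and what not)

The fixture generator builds a KO universe (`K00001…`, pathways
`ko00001…` with synthetic names) and assignment tables over it, all
deterministic given a seed. Fractions are applied as exact floor counts,
not Bernoulli draws, so end-to-end tests have exact expectations: a
100-gene table with `missing_fraction=0.2` and `unknown_fraction=0.1`
always has exactly 20 rows without a K number and 10 with K numbers
outside the universe, hence exactly 70 report rows. For KOs that have
pathways, the number of memberships is drawn uniformly on
[1, 2·rate − 1] (mean = `membership_rate`, default 2). Two pathway names
always contain the control keywords `circadian` and `metabolism` so filter
tests have known-cardinality answers. The default test world is 30 KOs
over 8 pathways with 10 % pathway-less KOs; the heavier checks use up to
1,000 KOs, 50 pathways and 500 genes, which keeps the whole suite and the
acceptance script well under a minute on one CPU.

What passing these tests shows: the parsing, trimming, joining, counting,
URL grammar, caching and batch plumbing are exact on inputs in the real
dialects. What they do not show: anything about real KEGG content —
synthetic pathway memberships are independent draws with none of the
correlation structure of real pathways, record fields are simpler than
real KO entries (no GENES/BRITE/REFERENCE blocks, though unknown keys are
skipped by construction), and live-endpoint behavior (timeouts, HTML error
pages) is only modeled as opaque transport failures.

## Numerical and degenerate-input choices

No floating-point anywhere; determinism is byte-level. Ties in the
by-count ordering break by case-insensitive name, then accession. Empty
everything is legal: an empty table, an empty store and an empty filter
result all render a valid three-section report with zero data rows.
A single-member pathway produces a URL with only the focal line. The
`all` glob matching nothing is a no-op with a warning, not an error.
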