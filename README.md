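# koview

Gene-centered KEGG Orthology annotation reports for non-model genomes.

When a newly assembled genome or transcriptome is annotated through the KEGG
Automatic Annotation Server (KAAS), the result is a two-column table assigning
each query gene a KO (KEGG Orthology) identifier — `K` plus five digits, naming
an ortholog group with a shared molecular function. KAAS organizes its own
output by pathway, and its result pages expire after a few days. What a
genome annotator usually wants is the opposite, durable view: **one row per
gene**, carrying the gene's K number, the ortholog's name, its functional
definition, and *every* KEGG pathway that gene maps to, with links that open
the pathway map showing which parts of the pathway the assembly covers.

`koview` builds exactly that. It

1. parses the KAAS table and **trims** genes that have no K number or whose
   K number cannot be resolved in the KEGG database;
2. fetches each KO record through the KEGG REST `get` operation (flat-file
   dialect; batches of ≤ 10 entries, rate-limited, with retry), through a
   pluggable transport so everything also runs offline;
3. caches the records in a versioned, diffable text **data file** (`.dat`)
   so later reports skip the extraction step entirely;
4. joins assignments and records into the gene table plus a
   pathway → members inverted index, optionally restricted by a
   case-insensitive **keyword filter** over definitions and/or pathway names;
5. renders a self-contained three-section HTML report:
   *Genes and Linked Pathways*, *Pathways by Number of Identified Genes*,
   and *Pathways in Alphabetical Order*.

Every pathway link in section 1 is a KEGG `show_pathway` URL of the form

```
https://www.kegg.jp/kegg-bin/show_pathway?map=<mapno>&multi_query=
    K<aaaaa>+%23bfffbf %0d%0a ... %0d%0a K<focal>+%238b0000,%23ffffff
```

one URL-encoded-CRLF-separated line per K number present in the assembly and
mapped to that pathway: cohort genes get a light-green node fill (`#bfffbf`),
and the focal gene — the row's own K number, placed last — a dark-red node
with white label, so clicking a pathway name shows at a glance which steps of
the pathway the assembly covers and where the focal gene sits.

## Worked example

`koview` is both a library and a command-line tool (run `koview` with no
arguments for the interactive menus). With a small KAAS-style table

```
gene_a	K00001
gene_b	K00002
gene_c	K00005
gene_d
```

the offline demo mode (which serves KO records from a built-in synthetic
universe instead of contacting KEGG) prints:

```
$ koview --input genes.txt --offline-fixtures
WARNING trimmed 1 genes without a K number
wrote genes.html and genes.dat
```

`gene_d` has no K number and is trimmed — the warning says so. The report
`genes.html` contains one row per remaining gene; `gene_a`'s pathway link is

```
show_pathway?map=ko00010&multi_query=K00005+%23bfffbf%0d%0aK00001+%238b0000,%23ffffff
```

i.e. on pathway map ko00010 the other identified member (K00005, carried by
`gene_c`) is colored green and the focal K00001 dark red. The cache written
next to the input is plain text:

```
koview-data 1
R	K00001	syn1, E1.1.1.1	synthetic enzyme 1 ... [EC:1.1.1.1]	ko00010:Fatty acid transport 009
...
```

Re-running from the cache (`koview --data genes.dat`) skips extraction and
produces byte-identical HTML. Real KEGG data works the same way — just drop
`--offline-fixtures`.

Batch jobs: `koview --batch jobs.lst` runs every input listed in `jobs.lst`
(one path per line); `koview --all` processes every `.txt` file in the
current directory, or every `.dat` file with `--mode render`. A filter such
as `--filter-keyword circadian --filter-scope pathway` applies to all inputs
and keeps only genes linked to a pathway whose name contains the keyword.

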