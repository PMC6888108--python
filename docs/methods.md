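# Methods

## Problem setting

A paralogous protein family is given as a gapped multiple sequence
alignment whose rows are partitioned into clades (from a prior phylogenetic
analysis). The goal is to classify every alignment column by its
conservation pattern and to extract the clade-specific conserved sites —
columns where one clade is fixed for a physicochemical amino-acid category
that the other clades never use. Such sites are candidate
specificity-determining positions: they can account for paralog-specific
interaction partners or regulation.

## Category-level conservation

All conservation calls compare residue *categories*, not identities,
because functional conservation routinely tolerates exchanges inside a
physicochemical group (a site may be "V or I", "K or R", "D or E" across a
clade). The default scheme partitions the 20 standard residues into six
groups — aliphatic MILV, small hydrophilic STPAG, aromatic FYW, cysteine C,
acid/amide NDEQ, basic HRK — and is validated as a disjoint, complete cover.
Alternative schemes load from a plain `label: RESIDUES` config and must
satisfy the same partition invariants.

Gap characters, ambiguity codes (B, J, Z, X) and nonstandard residues
(U, O, `*`) are UNCATEGORIZED. Alignments aggregated from multiple genome
annotations regularly contain X, so these are not errors; they are handled
conservatively (below) rather than rejected.

## Column classification rules

For each column, per-clade tallies record the residue multiset (gaps
excluded), gap count, the set of categories present, and the count of
uncategorisable residues. With `min_clade_size` (default 2 — fixation over
a single sequence is vacuous), the rules in order of precedence are:

1. **UNIVERSAL**: no gaps and no uncategorisable residues anywhere, and all
   residues fall in one category.
2. **CLADE_SPECIFIC** for clade C: C has ≥ `min_clade_size` members, is
   internally gap-free and UNCATEGORIZED-free, all its residues share one
   category k, and k occurs in zero residues of every other clade. All
   qualifying clades are reported.
3. **CLADE_SHARED** for C: same internal requirements, but k occurs in at
   least one residue outside C.
4. **VARIABLE** otherwise.

Design choices where the rules were genuinely open:

* "Specific" means *zero* occurrences of the focal category outside the
  focal clade, not merely "not fixed elsewhere". Real site tables list
  categorically different residues in the other clades (D/E against H/R),
  which the strict reading captures; the weak reading would admit sites with
  sporadic focal-category residues elsewhere and dilute the candidate list.
* Gaps and uncategorisable residues *inside* a candidate focal clade
  disqualify it (a clade with a gap is not "conserved across the clade");
  *outside* the focal clade they count as non-matching, so a site whose
  other clades show "G or a gap" still qualifies as specific.
* A column can satisfy the specific rule for one clade and the shared rule
  for another; the column's class is CLADE_SPECIFIC (precedence), and all
  focal clades with their fixed categories are kept on the call.
* UNIVERSAL requires a gap-free column outright.

## Site table and coordinates

The site table holds one row per (column, focal clade) of the
clade-specific calls, numbered consecutively in alignment-column order.
Positions are residue numbers in the focal clade's designated reference
sequence (1-based, counting non-gap characters up to the column); the map
from columns to reference positions is a strictly increasing bijection on
the reference's non-gap columns. When no reference is flagged in the clade
map, the first clade member in file order is used — for reproducing a
published numbering the reference must be flagged explicitly.

Domains are assigned from an optional annotation of ordered, non-overlapping
regions in one reference's ungapped coordinates. Positions before the first
region are "N-terminal", between regions "linker", after the last
"C-terminal"; this mirrors how published tables label inter-domain sites
that no database record annotates. When the annotation reference is gapped
at a site's column, the last preceding reference residue is used.

Residue lists in the table ("conserved AA", "AA in other clades") are
ordered by descending frequency with alphabetical tie-break; gaps appear as
the token `gap`, ranked by count like any residue but after letters on ties.

## Inventory stage

Similarity-search hits are read from the standard 12-column tabular format.
Significance is E-value strictly below `e_max` (default 1e-30): "better
than" in E-value semantics means smaller, and the boundary is excluded.
Because the published criterion does not say whether it was applied to raw
hits or per locus, filtering also deduplicates to the best hit per subject
(lowest E-value, then highest bit score, then first occurrence); this is a
flag (`dedupe_subjects`) so raw filtering is available. For genes with
several predicted splice variants the canonical isoform is the longest
sequence (ties to the lexicographically smallest id); a user-supplied
ranking hook replaces the length criterion when a domain-layout heuristic
is available, since "closest to the canonical domain layout" is not
algorithmically specified. Paralog tallies are plain species × clade counts
with row totals.

## Distance-tree plumbing

p-distances use complete deletion: every column containing any gap is
removed globally before pairwise comparison, matching the convention of
excluding gap-containing positions from tree input. Pairwise deletion is
deliberately not the default. Neighbor joining is scikit-bio's
implementation with negative branch lengths clamped to zero; it is
deterministic for a given input matrix. The package does not do
maximum-likelihood inference or bootstrapping — the tree code exists to
*check* clade structure (monophyly via edge bipartitions of the unrooted
tree) and to place unlabelled sequences (nearest clade by mean p-distance,
with the margin to the second-best clade as a confidence score; exact ties
return AMBIGUOUS).

## Synthetic families

The generator emulates the study system: by default 3 clades × 8 sequences
× 400 columns (a typical BAR+SH3 protein length), with class fractions
universal 0.10, clade-specific 0.04, clade-shared 0.08, variable 0.78 —
conserved classes are minorities, as in real families where a few dozen of
several hundred columns are conserved. Focal-clade and universal columns
draw an ancestral residue of a sampled category and resample each sequence
within the category at `within_category_substitution_rate` (default 0.3),
producing "V or I"-style variation. At clade-specific columns the non-focal
clades inherit a common ancestral residue from the complement of the focal
category (resampled within the complement at the same rate); with exactly
two clades the other clade is drawn i.i.d. from the complement instead,
since a shared non-focal ancestor would make that clade specific too.
Clade-shared columns force at least one out-of-clade occurrence of the
focal category. Gaps go into variable columns at `gap_rate` (default 0.05)
and optionally into non-focal clades of specific columns
(`gap_rate_nonfocal`, default 0), never into focal clades.

Every planted column is verified post hoc against the classifier and
resampled on collision (bounded retries), so the planted truth and the
classifier agree exactly by construction; `verify_truth` re-checks any
family and names the first violating column. A single integer seed drives
one `numpy` generator stream; identical specs give bit-identical output.

What the generator does **not** emulate: indel processes (gaps are i.i.d.,
not evolutionary), substitution-rate heterogeneity across sites and
lineages, tree-structured within-clade descent (members are conditionally
i.i.d. around a clade ancestor), and non-uniform residue background (uniform
by default; a frequency table can be supplied). Passing tests therefore
demonstrate correctness of the classification logic and pipeline plumbing
on category-structured data, not robustness to realistic evolutionary noise
or alignment error.

## Problem sizes and numerical choices

The test suite and the acceptance script run the closure property over 100
generated families (3 clades, 4–10 sequences per clade, 100–1000 columns),
the classifier-versus-naive-oracle check over an exhaustive enumeration of
two-clade columns on a 4-letter alphabet (256 cases) plus 10,000 random
three-clade columns, neighbor-joining topology recovery over 100 random
4–8-leaf additive trees, and monophyly over families simulated with a
specificity-rich, low-noise spec (fractions 0.25/0.70/0/0.05, substitution
rate 0.01) chosen so that mean between-clade p-distance exceeds five times
the within-clade mean — the regime in which distance methods should
trivially recover the clades, which the tests assert before asserting
monophyly.

All thresholds are exposed (`e_max`, `min_clade_size`, the category
scheme); defaults are the values above. Tie-breaks are deterministic
everywhere (alphabetical for residue ordering and isoform ids, stable
original order for filtered hit tables), so every run with the same inputs
and seed is byte-reproducible.

## Known limitations

* The published 14-site SH3P table is shipped as data for the summary
  utilities; regenerating it from sequence requires the family's curated
  alignment (partly manual), which is not distributed with the package.
* No statistical test of clade specificity is performed — the calls are
  deterministic set conditions, not hypothesis tests; a column fixed by
  chance in a small clade still qualifies.
* Surface-exposure annotation of sites (which requires structural models)
  is out of scope; the site table carries sequence-level evidence only.
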