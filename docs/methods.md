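# Methods

## Coordinate conventions

All intervals are 0-based half-open in memory; GFF3 files are 1-based
inclusive on disk and converted exactly at the I/O boundary (`start-1`,
`end`). Strands are `+`/`-` only; `.` is rejected by strand-gated
operations rather than silently treated as either strand. Linearized
genome coordinates concatenate chromosomes in assembly order, placing a
gene at its chromosome offset plus its midpoint.

## Scaffold decontamination

Each scaffold's protein hits are reduced to a metazoan fraction; a hit
counts as metazoan when its lineage path contains the `Metazoa` clade
label (configurable). Unresolved or unclassified lineages count as
non-metazoan — the conservative choice for a rule that removes scaffolds
falling *below* a metazoan threshold. Scaffolds with hits and a fraction
strictly below `min_metazoan` (default 0.90) are removed; the boundary is
strict ("less than"), so exactly 90% is kept. Zero-hit scaffolds are
kept: the rule is phrased over evidence, and absence of evidence is not
treated as contamination. Hits are unweighted — each counts once
regardless of alignment score, which is retained for reporting only.
Surviving scaffolds with a trailing numeric name component are renumbered
consecutively in assembly order (width-preserving for zero-padded names);
the map is checked for injectivity and can be applied consistently to
FASTA and GFF3.

Read triage classifies reads by repeat-masked fraction with strict
boundaries: high when > 0.50, mild when > 0.25 and ≤ 0.50, low otherwise.

## Gene-model reconciliation

Overlap fractions divide the overlap length by the *shorter* of the two
intervals. This makes the fraction symmetric and makes containment the
limiting case (1.0); the alternative (divide by the model length) would
let a long model overlap many short transcripts "weakly" even when it
swallows them whole.

Round 1 works on gene spans: candidacy requires same chromosome, same
strand, and ≥ 1 bp overlap between the model span and any transcript of a
cluster. When the model overlaps transcripts from exactly one cluster,
the containment rule applies: merge if at least 40% of the cluster's
transcripts fully contain the model or are fully contained in it
(containment in either direction counts). Otherwise — including whenever
two or more clusters overlap the model — each candidate is judged by mean
transcript/model overlap, merging when it exceeds 50%. A model that fires
any rule against any cluster is dropped (a model spanning two clusters is
a fusion artifact regardless of which cluster "wins"). Every cluster
becomes a gene; the conservation law `|genes| = |clusters| + |retained
models|` is asserted at run time.

Rounds 2 and 3 switch to exon-level tests, since novel models are judged
against the *transcribed* structure of existing genes: a round-2 model is
incorporated only if none of its exons overlaps an exon of an existing
gene on the same strand (a model inside an intron is therefore
accepted). Evidence masking between rounds is strand-agnostic, matching
default interval-subtraction semantics.

De novo transcript rescue discards mappings overlapping the annotation,
groups the remainder by same-strand interval overlap, and accepts a group
as a locus when it contains an anchor-stage mapping or when at least two
distinct non-anchor stages agree (the agreement floor is a parameter;
requiring two stages controls spurious single-stage loci). Groups
collapse to the union span with merged exons; residual overlaps among the
new loci keep the longer model, breaking ties toward the lexicographically
smaller id. Final curation-level merges of erroneously split models are
out of scope; `finalize_annotation` instead warns with the list of
residual same-strand overlaps as manual-review candidates.

Priorities are iso > braker1 > braker2 > denovo throughout: a
lower-priority model can never displace an existing gene, only fill gaps.

## Cluster integrity

Member assignment keeps, per (member, gene model), the best e-value among
hits below the cutoff (default 1e-20; a relaxed pass at 1e-10 exists
because divergent members of the NK-type clusters fall between the two).
Hits overlapping no gene model are reported as unmapped, never fatal.
Order is evaluated over single-copy members only, in expected member
order along coordinates; strictly ascending *or* strictly descending both
count as ordered, because a uniformly inverted cluster is intact — the
orientation is reported separately, as is strand uniformity. Multi-copy
members (tandem expansions) therefore do not break the order check; their
copy numbers are reported. Syntenic blocks are defined permissively as
co-location on one chromosome, with no maximum-gap parameter and no
strand requirement. Identical-duplicate flagging (a misassembly signal)
compares nucleotide sequences for exact identity and is restricted to
same-chromosome pairs by default, since the misassembly suspicion is
positional. Assignments are by best alignment hit and labelled putative;
phylogenetic confirmation is out of scope.

## Self-synteny screen

Filtering order matters and is: (1) collapse isoform-level rows to
directed gene pairs keeping the best-scoring row (bitscore by default —
it is the scoring column — with an e-value option); (2) drop self-pairs;
(3) apply the analysis e-value threshold; (4) per query gene keep only
the best-e-value hit per target chromosome. Step 4 prevents two
chromosomes sharing one large gene family from appearing strongly
connected: at permissive thresholds every family member would otherwise
hit every other. E-value 0 is the most significant value; ties break by
higher bitscore, then lexicographically smaller target id, making the
output independent of input row order. The alignment table carries no
target-length column, so coverage filtering at ingest is optional and
query-relative (`alnlen/qlen`).

The contribution matrix counts *distinct genes* (not pairs): cell (x, y)
is 100 × |genes on x with a surviving pair to y| / gene_count(x) in the
default mode; a `donor` mode normalizes by the contributing chromosome's
gene count instead, since both normalization conventions appear in
practice. Summary statistics are off-diagonal mean/min/max, diagonal
mean, and the contrast ratio (diagonal mean / off-diagonal mean, infinite
when the off-diagonal mean is zero). The duplication score takes each
chromosome's arg-max off-diagonal cell, suppresses candidates below a
floor (default 5%), and reports the mutual-best matching; under a WGD the
matching pairs homologous chromosomes, under tandem-dominated duplication
no calls survive the floor.

Unplaced scaffolds can be excluded from grid and matrix by restricting
the layout to the pseudochromosomes.

## Simulator

The simulator emits the statistical structure the stages assume, not
sequences: detectability of a true paralog pair is modelled directly as a
probability rather than through a sequence-evolution model, and no
contact maps, repeats-along-sequence, or read errors are generated.
Consequences: passing recovery tests demonstrate correctness of the
filtering/decision logic under the stated noise model, not robustness to
alignment-level artifacts (chimeric alignments, domain-level hits,
annotation errors) that real data contain.

Design choices, all seeded through a single PCG64 generator per
operation call (byte-identical outputs under equal inputs):

- **Gene placement** — lengths uniform on a range, packed left-to-right
  with multinomially distributed inter-gene gaps; infeasible packing is a
  hard error.
- **WGD** — every chromosome gains a homolog named `<name>_B`, appended
  after all originals so original linearized coordinates are stable; each
  gene is retained on the homolog independently with probability
  `retention`. Empty homologs are kept.
- **Tandem arrays** — a gene seeds an array with probability `rate`;
  copies are placed immediately adjacent by re-packing the chromosome
  (downstream genes shift right, the chromosome grows), which guarantees
  adjacency without placement failures.
- **Alignment statistics** — log10 e-values uniform on [−80, −20] for
  true pairs and [−10, −4] for spurious hits, so the standard analysis
  thresholds (1e-5, 1e-60) separate signal from noise by construction;
  every gene gets a perfect self-hit; a fraction of true pairs emit an
  extra, strictly weaker isoform row to exercise collapsing.
- **Evidence noise** — `p_novel` withholds a gene from round-1 evidence
  entirely and routes it (50/50) to round-2 models or de novo mappings
  (anchor stage plus one other, so rescued loci satisfy the agreement
  floor); `p_cluster_cover` covers remaining genes with 1–5 transcripts
  jittered by up to 10% of the gene length; `p_fusion` fuses a gene with
  its next neighbour into one model, `p_split` splits a gene at its
  midpoint. With all noise off, every downstream stage recovers truth
  exactly (tested end to end).
- **Taxonomic hits** — clean scaffolds draw metazoan hits at 0.95 by
  default, contaminants at 0.30, well separated around the 0.90 rule;
  the false-removal rate of clean scaffolds is the exact binomial tail
  P(Bin(hits, p_clean) < 0.9·hits), used as a test oracle.

Default study conditions (SimConfig): 10 chromosomes × 1 Mb × 200 genes
of 2–4 kb; WGD retention 0.5 and detectability 0.9; tandem rate 0.1 with
arrays of up to 3 copies; 0.05 spurious hits per gene; 5% contaminant
scaffolds with 50 hits each. These are the conditions under which the
recovery guarantees in the test suite are stated.

## Problem sizes and runtimes

The acceptance computations use the published round-1 scale (8904
clusters + 11,451 models; sub-second), 10–20 seeds of the 10×200-gene
duplication simulations (a few seconds), 50 seeds of planted-cluster
scans, and 100-seed property sweeps for the filter oracle and the
binomial decontamination check. The whole suite runs in well under a
minute on one CPU.

## Known limitations

- The deposited-data reanalysis (off-diagonal contribution statistics of
  a real genome) runs only when the published archive files are placed
  under `data/deposited/`; they are too large to ship.
- `renumber_scaffolds` assumes a single trailing numeric component in
  scaffold names; exotic naming schemes pass through unchanged.
- The reconciliation does not attempt the final manual curation step
  (merging erroneously split models); it reports candidates instead.
- Cluster member identity is by best alignment hit; paralog-rich families
  can mis-assign without the out-of-scope phylogenetic confirmation.
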