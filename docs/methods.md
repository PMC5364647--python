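# Methods

## Network model and coordinates

A regulatory network is a strictly bipartite graph of sRNA and mRNA
nodes with one edge per putative duplex. Edge identity includes both
interacting regions, so one sRNA–mRNA pair can carry several
alternative duplex predictions (energy-based predictors emit
suboptimals); nothing merges them. All coordinates are 1-based and
inclusive, matching how binding regions are reported in the
experimental literature; conversion to 0-based half-open happens only
at format boundaries. mRNA coordinates always refer to the extracted
5'UTR sequence, never the genome; genomic provenance (contig, strand,
window, clamping) travels in node attributes.

All algorithms treat networks as immutable and return new networks.
That is not a style choice: the exploration tree stores each analysis
state content-addressed by the sha256 of its canonical serialization,
and replay-verification compares those bytes, which is only sound if no
step ever mutates a stored state. Canonical serialization sorts nodes
by id, edges by their identity key, and all JSON keys, so equal
networks serialize to equal bytes on any platform.

## 5'UTR extraction

The 5'UTR of a gene is a fixed window: `upstream_len` bases strictly
before the annotated first base plus `downstream_len` bases inside the
gene, on the coding strand (for `-` strand genes the genomic window is
mirrored and reverse-complemented). Defaults are upstream 150 nt /
downstream 60 nt — generous enough to cover most known enterobacterial
sRNA binding sites around start codons — and are logged on every run.
Windows are clamped to the contig and the clamping recorded; a window
entirely off the contig yields a skip record rather than an error, so
one bad annotation does not abort a genome-scale extraction. Input is
genome FASTA + a GFF3 subset (type filter `gene`, id from `ID=` or
`locus_tag=`); EMBL/GenBank can be converted upstream with standard
tools. No operon inference or TSS-aware UTR calling is attempted.

## Antisense alignment

The built-in predictor re-implements the classical antisense trick:
reverse-complement the UTR and run a local homology alignment, so that
an identity in alignment space is a Watson–Crick pair in the duplex.
Scoring is +2 match / +1 G·U wobble / −1 mismatch / −2 per gap
position (linear gaps — affine gains nothing at sRNA scale), with a
report threshold of 8 so at least four consecutive Watson–Crick pairs
are needed before anything is reported. All five numbers are exposed;
the defaults are deliberately permissive and intended for ranking, not
for seed detection. For planted-seed recovery experiments a stringent
scheme (mismatch −4, gap −6, threshold ≈ 2·seed length) separates
perfect seeds from the random background, whose best local score under
the permissive defaults grows large for realistic sequence lengths.
IUPAC ambiguity codes never pair. Wobble orientation matters: in
reverse-complement space the two G·U orientations appear as (G,A) and
(U,C) sRNA-vs-transformed-UTR characters.

Suboptimal hits are greedy and non-overlapping: after a hit is
reported, the sRNA and UTR positions it used are masked (dynamic
programming rows/columns forced to zero) and the matrix is recomputed,
until the best score drops below threshold or `max_hits` (default 3)
is reached. Hit scores are therefore non-increasing in report order,
and every hit's displayed pairing trace rescored in duplex space
reproduces its score exactly — a cheap end-to-end audit used in tests.
Ties in the matrix argmax resolve to the smallest (row, column), and
traceback prefers diagonal > up > left, making output deterministic.

Energy-based interaction tables (semicolon or comma separated, columns
`id1,start1,end1,id2,start2,end2,E`; side-to-role mapping and column
names configurable) are imported as-is; no thermodynamic or
accessibility model is recomputed here.

## Enrichment

For one sRNA the selection is its set of distinct mRNA partners; the
background defaults to all mRNA nodes of the network and is recorded
with the results. Each term with at least one background carrier gets
the hypergeometric upper tail `P(X ≥ k)` and the conservative
one-removed variant (the tail at `k−1`, equal to 1 whenever `k ≤ 1`,
so singleton overlaps are never significant). Benjamini–Hochberg
q-values are computed on the one-removed score by default (switchable
to the raw tail). The tail is evaluated through the survival function
of the standard hypergeometric distribution (log-space stable); tests
compare it to exact integer-binomial enumeration at 1e−12. Terms are
flat labels; if ontology propagation is wanted it must be applied to
the catalog upstream.

## Distances and Markov clustering

Region distance is the Jaccard distance between intervals as integer
position sets; annotation distance the Jaccard distance between term
sets, with two empty sets defined as maximally distant (1.0) so
unannotated partners never cluster together by vacuity. Both are
metrics, property-tested for identity, symmetry and the triangle
inequality.

MCL runs on similarity `1 − d` with canonical parameters (expansion 2,
inflation 2.0, prune 1e−5, tolerance 1e−8, self-loop weight 1.0), all
exposed. An optional `sim_threshold` zeroes weak similarities before
clustering (default 0: all positive similarities kept). Clusters are
read from the converged flow matrix as attractor systems; items
claimed by several systems (rare, near-symmetric inputs) go to the
system sending them the most flow, ties to the first in row order, and
unreached items become singletons — guaranteeing a partition. Cluster
order (and hence the stable color index) is by span start, ties by
smallest member key. Cluster spans may overlap; abutting binding sites
are expected to produce overlapping spans and tests assert this is
preserved.

## Motif filters

SIM: every sRNA with at least `min_targets` *distinct* mRNA partners is
kept with all its interactions; distinct partners (not interaction
count) is used so duplicate duplex variants cannot fake a hub. DOR has
no single formal definition; the operational reading implemented is:
restrict to mRNAs with ≥ 2 distinct regulators and the sRNAs regulating
them, then keep each connected component with at least `min_srnas`
sRNAs and `min_mrnas` mRNAs, with all interactions among kept nodes
whose mRNA is multiply-regulated. It is the simplest testable reading
of "dense overlapping regulon" and recovers planted blocks exactly.

The score filter requires an explicit comparator because "score below
a threshold" is ambiguous between energy-like scores (lower = better)
and alignment scores (higher = better); `le` is the natural direction
for free energies.

Betweenness is unnormalized undirected Brandes centrality with parallel
edges collapsed — regulation direction is not path-meaningful in a
bipartite regulator–target graph. Degree counts interactions, so
parallel duplex variants each count; this is the per-node interaction
load, the quantity the coverage curve integrates per base.

## Pipelines and the exploration tree

Steps are (category, name, params) triples validated against the
operation registry's parameter schemas; filters return sub-networks,
calculations/colorations/layouts return the same network with new
attributes. Pipelines are left-folds that keep all intermediate states.
The exploration tree adds one child per applied step (a branch per
pipeline); node notes default to the step name. Sessions store the
tree plus content-addressed network states; `verify_session` replays
every node's step path from the root and compares canonical bytes. A
session-level integer seed is recorded for provenance; every shipped
algorithm is deterministic, so it only matters for synthetic-data
steps. Whether to store full states or deltas was open; full
content-addressed states were chosen — identical states dedupe, and
verification stays a pure byte comparison.

The annotation filter needs a catalog, which is context passed at run
time, not part of the step document: catalogs are inputs, steps are
programs.

## Synthetic data: what it emulates, what it does not

The generator plants, in one seeded draw: a SIM (one sRNA with an
exact number of targets), a DOR (an sRNA block × mRNA block
bi-clique), region clusters (interactions of the focal sRNA with
regions drawn inside disjoint `center ± width` windows; overlapping
windows are rejected as infeasible), an enriched annotation term
(exactly `k` carriers among the focal targets, `K` in the background,
plus random decoy terms), and noise edges. Scores are normal draws
truncated to negative values (mean −10, sd 3 kcal/mol, a plausible
energy range for reported duplexes).

The noise model keeps the planted truth uniquely identifiable: noise
edges avoid planted nodes and each noise mRNA receives at most one
noise edge, so noise alone can never assemble a competing SIM hub or a
multiply-regulated mRNA. This is intentional — the generator defines
ground truth, and a truth set that noise could silently replicate
would make exact-recovery assertions meaningless. The corresponding
limitation: passing recovery tests shows the filters implement their
definitions, not that real networks (where motifs overlap and noise is
structured) are this clean. Likewise the generator does not simulate
sequences or duplex thermodynamics (a separate helper plants literal
antisense seeds in random UTRs for predictor tests), annotation terms
are independent labels without ontology structure, and scores are
independent of topology.

Recommended problem sizes used throughout the tests: region-cluster
recovery on a 122-nt sRNA with two windows (centers 5 and 48, width 6,
12 interactions each); motif recovery with 60 sRNAs × 600 mRNAs, a
1×20 SIM, a 3×4 DOR and 50 noise edges over 20 seeds; enrichment power
at background 1000, 50 carriers, 30 targets, 10 planted hits over 200
replicates. These sizes give unambiguous truth at interactive runtimes.

A small curated compendium of experimentally validated RyhB and FnrS
targets (E. coli), compiled from public target databases, ships with
the package for realistic gene lists in examples and tests. Its
per-gene source-support flags are a best-effort transcription of an
ambiguous source grid and are marked indicative; only the gene lists
are used programmatically. The two lists share five gene names
(marA, nagZ, sdhA, sodA, sodB) while parts of the surrounding
literature count four validated shared targets; the compendium records
the lists as published and leaves that discrepancy unresolved.

## Numerical and degenerate-input choices

- Hypergeometric tails via the survival function; BH via the standard
  step-up with monotonicity enforcement.
- MCL convergence is max-absolute change < 1e−8 between iterations;
  columns with no flow keep their mass on the diagonal.
- Degenerate bases in UTRs are kept verbatim and score as mismatches.
- Empty networks are legal everywhere: filters return empty networks,
  measures empty maps, clustering an empty list.
- Region bounds are validated at construction (1 ≤ start ≤ end, end ≤
  known RNA length at network insertion).

## Known limitations

No thermodynamic energy model, no accessibility or seed model, no
operon/TSS awareness, no ontology propagation, no interactive
rendering. The DOR definition is one defensible operationalization
among several. The built-in aligner is a ranking heuristic; for
energy-calibrated predictions import a dedicated predictor's table.
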