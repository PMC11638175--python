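# Methods

## Metadata model and validation

A submission is three flat documents — sample, experiment, analysis — each an
ordered list of records keyed by a unique `alias`. Field names are normalized
to lowercase snake case on read (spreadsheet headers vary in case and
spacing); cell values are kept verbatim. A ruleset has one ordered section of
field rules per document, each rule carrying a tier from the closed
vocabulary **mandatory / recommended / optional**: a missing mandatory field
is an error, a missing recommended field a warning (warnings never fail a
submission), optional fields are unconstrained. Value kinds add syntactic
checks: ontology terms must match the CURIE pattern `PREFIX:digits` (no
ontology service is consulted, so validation is fully offline), numbers must
parse, dates must be ISO-shaped, and `entity_ref` values must resolve to an
alias in their target document (e.g. a specimen's `derived_from` to a sample
alias).

The sample document deliberately mixes two record kinds — donor organisms and
specimens derived from them — as livestock metadata portals do. A flat
mandatory list would then be unsatisfiable (an organism has no `tissue`; a
specimen has no `sex`), so a rule may be scoped by `material`: it applies
only to records whose `material` field equals it. The packaged default
ruleset covers a minimal scRNA-seq inventory (organism/sex/breed and
tissue/derived_from on the sample side; assay type, library construction and
sample reference for experiments; file name/type/checksum and experiment
reference for analyses) and is ordinary configuration: any JSON ruleset with
the three sections can replace it.

## Entity graph and brokering

The target data model is graph-shaped: **project, biomaterial, protocol,
process, file** entities, with links in which a process consumes inputs and
produces outputs under one or more protocols. Every entity carries three
pieces of system metadata: `described_by` (a URI ending in the entity's
subcategory, pointing into a configurable schema directory), the schema
version, and a UUID. UUIDs are name-based (RFC 4122 v5, keyed on namespace ×
category × entity id) so that converting the same submission twice yields an
identical, diffable graph; a flag switches to random v4 UUIDs for
production-like behaviour.

Conversion runs five fixed stages:

1. **validate** the submission against the ruleset (fail fast on errors);
2. **clean** — drop recommended-tier fields, since the target schema
   recognises only mandatory and optional requirement levels; every removed
   (document, record, field) triple is returned in a manifest for audit;
3. **split** the documents into entities. One experiment record becomes two
   protocol entities; the full cleaned record is stored on the
   library-preparation protocol and the paired sequencing protocol carries
   only the experiment alias, so no content value is invented and flattening
   can rebuild the experiment document losslessly from the
   library-preparation entities alone. Analysis records become sequence files
   (fastq/bam) or analysis files (mtx/h5ad). A single shared collection
   protocol backs all sampling steps. The project entity is synthesized from
   a submitter-provided block (title, description, contributors, accessions)
   because the source portal has no project tab;
4. **link** — each specimen's `derived_from` becomes a sampling link
   (donor → specimen) and each experiment's files become one sequencing link
   (specimen → files); files of one library share provenance and therefore
   one link. Reference fields are retained inside entity content so that
   flatten(convert(S)) reproduces clean(S) field-for-field — a stricter
   archive pipeline would strip them, and that divergence is intentional;
5. **validate the graph**: exactly one project; well-formed, unique UUIDs;
   `described_by` consistent with the subcategory; resolvable, non-empty,
   disjoint link inputs/outputs; at least one protocol per link; an acyclic
   input→output flow (checked with networkx); no orphan files (every file is
   the output of exactly one link); every specimen reachable from a donor.
   A graph with no files passes with a warning, since metadata-only
   submissions are legitimate intermediate states.

Subcategories are drawn from a fixed registry (donor_organism,
specimen_from_organism, cell_suspension; collection/dissociation/library
preparation/sequencing protocols; generic process; sequence/analysis file;
project) — the minimal set covering an scRNA-seq assay path. Dissociation and
cell-suspension steps are modelled as optional subcategories and not emitted
by the default mapping.

## Pseudobulk collapse and barChart tracks

`collapse_by_celltype` computes C[g,t] = stat{X[g,c] : label(c)=t} with stat
∈ {mean, median}; mean is the default (it is what the upstream matrix-collapse
utilities do, and it satisfies the conservation identity Σₜ C[g,t]·nₜ =
Σ_c X[g,c] used as a test invariant); median is offered for robustness.
Cell-type columns are ordered lexicographically and that global order fixes
the meaning of every record's expression vector.

Track records are BED6 plus gene symbol, expCount and the comma-joined
per-type expression vector. Three text dialects are written: `plus3` (9
columns), `plus4` (10 columns, default — one literal `0` placeholder), and
`plus5` (11 columns, two placeholders); the placeholders exist only to match
column counts expected by downstream consumers and carry no information. The
BED score column has no canonical definition in terms of expression, so this
package defines it as round(1000 · max(exp_scores)/global_max), with 0 when
the global maximum is 0 — a display scaling that puts the most-expressed gene
at exactly 1000. Sorting is lexicographic by chromosome then numeric by
start/end (bedSort's order, so `chr10` < `chr2`). Coordinates are 0-based
half-open everywhere; GFF3 input (1-based inclusive) is shifted by start−1
on read. Expression values are taken as-is: no normalization or log
transform is applied, and the toolkit is agnostic about whether the input
matrix holds raw counts or normalized values.

## Network inference

For each gene g, an ensemble of `n_trees` regression trees (default 100)
predicts X[g,·] across cells from the TF expression values, excluding g from
its own predictor set so self-edges cannot occur. The importance of TF→g is
the TF's total variance reduction (impurity decrease, weighted by node sample
fractions) summed over a tree's splits and averaged across the ensemble —
variance reduction is the regression analogue of Gini importance. Sklearn's
`feature_importances_` normalizes each tree to sum to one; the per-tree
unnormalized importances are used here instead, as the GENIE3 scheme
prescribes. Importances are reported unnormalized by default (per-target
sums may differ); `normalize=True` rescales each target's incoming
importances to sum to one.

Ensemble defaults follow GENIE3: bootstrap resampling with `max_features =
"sqrt"`; an extremely-randomized variant (`method="extra"`) is available.
Zero-variance targets are assigned exactly 0 importance without fitting.
Per-target tree seeds are derived deterministically from the configuration
seed, and cells are sorted by id before fitting so that results are invariant
to the column order of the input matrix (bootstrap draws are index-based and
would otherwise depend on it). Edges are ranked by importance descending with
(tf, target) lexicographic tie-breaks; hub score of a regulator is the sum of
its outgoing importances. TF symbols are matched to matrix gene ids exactly
but case-insensitively; unmatched symbols are logged, not fatal.

The HTML export embeds the node-link data as a JSON `<script>` block and
renders it with a small vanilla-JS force layout in SVG — a single
self-contained file with no external fetches, suitable for sharing the
network view of an analysis.

## Synthetic data

The fixtures emulate a porcine PBMC study's *structure* at desk scale:

* **Submission** — `n_donors` (default 7) healthy pig donors, one blood
  specimen each (`UBERON:0000178`, derived_from the donor), one scRNA-seq
  experiment per specimen, two fastq records per experiment, and a project
  block citing study accession PRJEB43826. Checksums are seeded random hex;
  everything else is deterministic, so equal seeds give byte-identical
  documents. Recommended-tier fields (health status, sequencing platform)
  are present so the cleaning stage has real work to do.
* **Expression** — a planted linear network: `n_tfs`=5 TF expressions i.i.d.
  N(0,1) across `n_cells`=200 cells; `n_targets`=15 targets, each the sum of
  `parents_per_target`=2 planted parents with effect sizes ~ Uniform(1,3)
  plus N(0, 0.1²) noise; the remaining 20 genes are independent N(0,1)
  background. Cells are assigned round-robin to four PBMC-like labels
  (CD4_T, B, NK, Mono — 50 cells each), and the whole matrix is shifted by
  its global minimum so values are non-negative and count-like (a constant
  shift changes neither tree splits nor variances). The planted adjacency is
  returned as ground truth.
* **Annotation** — one 1 kb interval per gene, alternating between two
  chromosomes and two strands, non-overlapping within a chromosome.

What the fixtures do **not** emulate: scRNA-seq count distributions (dropout,
overdispersion, library-size variation), doublets, batch effects, nonlinear
or combinatorial regulation, and cell-type-specific network structure (the
planted network is shared by all cells). Passing tests therefore demonstrate
correctness of the algorithms and formats, not performance on real droplet
data. The default scale (40 genes × 200 cells, 7 donors) was chosen so the
entire suite exercises every code path in seconds; no code path depends on
scale.

## Recovery behaviour and a known scale mismatch

On the default planted network, ranking all emitted TF→target edges by
importance separates true from false edges with AUROC ≈ 0.998, and
zero-variance probes receive exactly 0. Hub identification needs care in
interpretation: because tree importance measures *variance* reduction, the
edge TF→target contributes on the order of effect² (TF variance is 1), so a
regulator's hub score tracks the **sum of squared** planted effects. A
regulator with many weak edges can have the largest sum of raw effects while
another with fewer, stronger edges has the largest sum of squared effects —
at the default seed the inferred top hub is the squared-effect leader, not
the raw-effect leader. This is a property of impurity-based importance, not
an estimation error; per-target normalized importances weight targets more
equally and behave differently.

## Numerical choices

* Collapse relies on pandas groupby aggregation; it matches a naive per-type
  loop to < 1e-12 and conserves totals to < 1e-9 relative (tested).
* BED expression values are written with `numpy.format_float_positional`
  (exact shortest decimal, no trailing zeros: `1.5,0,2`), so write → read is
  lossless.
* Single-tree check: with one usable predictor, one depth-1 tree and no
  bootstrap, the fitted importance equals the exhaustive best-split variance
  reduction to floating-point accuracy.
* Tie-breaks are deterministic everywhere: stable sorts, lexicographic edge
  and hub tie-breaks, fixed cell-type column order.
* Degenerate inputs: constant predictor matrices yield all-zero importances
  (not an error); empty analysis documents yield file-less graphs that pass
  validation with a warning; an empty edge table exports a valid "no edges"
  page.

## Limitations

* Ruleset semantics are per-field and syntactic; cross-field constraints and
  live ontology lookups are out of scope.
* The entity graph covers a single-assay scRNA-seq path; multi-round
  processing chains (file → file processes) are validated but never produced
  by the broker.
* Network inference assumes the TF list is given; it does not discover novel
  regulators, and importance scores are comparable within a run only.
* Text BED only; binary bigBED encoding and browser rendering belong to
  downstream tools.
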