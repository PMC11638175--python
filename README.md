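# scbroker

A desk-scale toolkit for making single-cell transcriptomics submissions from
agricultural genomics FAIR: it validates FAANG-style metadata (three flat
documents — sample, experiment, analysis — governed by a
mandatory/recommended/optional ruleset), brokers a validated submission into
an HCA-style experimental entity graph (project, biomaterial, protocol,
process and file entities connected by process links), generates per-cell-type
barChart BED expression tracks for genome browsers, and infers ranked
TF→target gene regulatory networks from a single-cell expression matrix with
GENIE3-style tree ensembles.

It is aimed at data wranglers and bioinformaticians who curate livestock
single-cell datasets and want to move them between metadata standards, view
cell-type expression in a genomic context, and run a first-pass network
analysis — entirely offline, with synthetic fixtures standing in for a real
cohort.

## What it computes

**Metadata brokering.** A submission S is validated against a three-section
ruleset (field tiers: mandatory → error when absent, recommended → warning,
optional → free; ontology terms checked as CURIEs `PREFIX:digits`; entity
references resolved across documents). Conversion then runs five fixed
stages — validate → clean → split → link → validate graph — where *clean*
drops recommended-tier fields (the target schema knows only mandatory and
optional), *split* maps organism records to `donor_organism` biomaterials,
specimens to `specimen_from_organism`, experiments to library-preparation and
sequencing protocols, analysis records to file entities, and injects system
metadata (`described_by` schema URI, schema version, deterministic name-based
UUIDs), and *link* realizes `derived_from`/`sample_ref`/`experiment_ref` as
process links. The round trip flatten(convert(S)) = clean(S) holds
field-for-field.

**Tracks.** A genes×cells matrix X and cell labels ℓ collapse to a
genes×cell-types matrix C with C[g,t] = mean({X[g,c] : ℓ(c)=t}) (or median),
joined to gene annotations and written as barChart BED: BED6 plus gene
symbol, expCount and a comma-joined per-type expression vector, with
score = round(1000 · maxₜ C[g,t] / max C) and records sorted by
(chrom, start) as bedSort orders them.

**Networks.** For each gene g, a random forest predicts X[g,·] from the TF
expressions (g excluded from its own predictors). The importance of TF→g is
the TF's total variance reduction over the tree, averaged across the
ensemble's trees. Edges are ranked by importance; a regulator's hub score is
the sum of its outgoing importances; results export as TSV and as a
self-contained interactive HTML network page.

## Worked example

```python
import scbroker as sb
from scbroker import fixtures, grn, tracks

# 7-donor PBMC-like submission → entity graph
sub, project = fixtures.make_submission()
result = sb.convert(sub, sb.default_ruleset(), project)
print(len(result.graph.entities), len(result.graph.links),
      result.metadata_report.status, result.graph_report.status)
# 58 14 pass pass

# planted-network matrix (40 genes × 200 cells) → CD4 T-cell network
matrix, labels, truth = fixtures.make_expression()
cd4 = grn.select_cells(matrix, labels, "CD4_T")
edges = grn.infer_network(cd4, [f"TF{i}" for i in range(1, 6)],
                          grn.GRNConfig(n_trees=100, seed=7))
print(grn.rank_edges(edges, 3).to_string(index=False))
#  tf target  importance  rank
# TF2    G12    6.177194     1
# TF2     G2    6.029193     2
# TF2    G13    4.615893     3
```

The 58 entities are 1 project, 14 biomaterials (7 donors + 7 specimens),
15 protocols, 14 files and 14 processes; the 14 links are one sampling and
one sequencing link per donor. In the edge table, `importance` is the mean
per-tree variance reduction TF2 contributes when predicting each target —
TF2 is a planted parent of G12, G2 and G13 in the synthetic truth.

The same workflows are available from the shell:

```bash
scbroker fixtures --out fx/ --seed 7
scbroker validate --sample fx/sample.tsv --experiment fx/experiment.tsv \
    --analysis fx/analysis.tsv --ruleset fx/ruleset.json
scbroker convert  --sample fx/sample.tsv --experiment fx/experiment.tsv \
    --analysis fx/analysis.tsv --project fx/project.json --out graph/
scbroker track --matrix fx/exprMatrix.tsv --meta fx/meta.tsv \
    --annotation fx/annotation.bed --out track.bed
scbroker grn --matrix fx/exprMatrix.tsv --meta fx/meta.tsv --celltype CD4_T \
    --tfs fx/tfs.txt --trees 100 --seed 7 --top 50 --out edges.tsv --html net.html
```

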