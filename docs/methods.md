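# Methods

`ednet` implements an integrated prioritisation procedure for
endothelial-dysfunction (ED) genes: candidate genes are funnelled through
epigenomic and regulatory evidence, scored in a multi-plate high-content
knockdown screen, combined across readouts by direction-aware robust rank
aggregation, and finally propagated over a weighted protein-interaction
network whose node significance is calibrated against degree-preserving
random networks. This note records the model behind each stage, the
parameters that matter, what the synthetic data do and do not emulate, and
the numerical choices made where the design was genuinely open.

## 1. Regulatory-region integration and the gene funnel

**Consensus voting.** Replicate peak sets (ATAC-seq or ChIP-seq) are
reduced to consensus regions by a base-pair coverage sweep: a base belongs
to the consensus when peaks from at least `min_support` replicates cover
it (each replicate counts once per base, however many of its peaks overlap
there). `min_support = 1` is the interval union and `min_support = n` the
n-way intersection; the default is the majority, `ceil(n/2)`. An
all-replicate overlap semantics is available by setting
`min_support = n`. Coordinates are 0-based half-open (BED convention)
throughout, and the sweep coalesces events at identical coordinates so
abutting intervals stay contiguous.

**Cross-condition intersection by containment.** A region is "shared"
across conditions only when, for every other condition, some peak pair
with it satisfies containment — one interval lying entirely within the
other. Partial overlap does not count. Containment is accepted in either
direction by default (a strict one-directional mode is a flag), and the
smaller (contained) interval of each match chain is reported. The scan is
anchored on every condition in turn and results deduplicated, which makes
the output independent of condition order. The same containment rule
re-centres ChIP evidence onto open-chromatin ATAC intervals
(`center_on_atac`), reporting the ATAC coordinates with their supporting
ChIP interval.

**Annotation.** Each peak is assigned exactly one feature at its midpoint
with precedence promoter/TSS > 5'UTR > 3'UTR > exon > intron > intergenic;
the promoter is TSS ± 3,000 bp (`promoter_window`) on either strand.
Within a precedence class, the gene with the nearest TSS wins. Non-promoter
peaks are assigned to the nearest TSS within 100 kb; beyond that no gene
is assigned. Peaks on chromosomes absent from the gene models are
annotated intergenic with a warning.

**DEG and regulon filters.** Differentially expressed genes are those with
adjusted p ≤ 0.05 and |log2 fold change| ≥ 1.5 (direction retained). The
funnel keeps DEGs that carry a peak assignment, then intersects with a
TRRUST-like TF→target table: rows whose TF is among the motif-predicted
TFs and whose target is among the peak-supported DEGs survive, and the
final panel is the union of surviving TFs and targets (TF / non-TF counts
reported).

## 2. Screen statistics

Each plate carries 8 control wells (siRNA scramble under the IL-1β/OxPAPC
stimulus) and one well per perturbed gene; wells, not images, are the
replication unit (per-well values are medians over images). The analysis
chain is:

1. **Normalisation** — each well's readout divided by the mean of the
   plate's control wells (so a control-typical well reads 1.0).
2. **Z-scores** — standard scores of the normalised values, computed per
   plate over all wells of that plate (sample SD, n−1). Per-plate scoring
   absorbs plate-to-plate variation, which is the point of the
   normalisation; a `--z-scope global` flag standardises across plates
   instead.
3. **Outlier removal** — wells with |Z| > 3 in a readout are dropped for
   that readout, with a removal log. Note a consequence visible in small
   synthetic screens: when very few genes carry effects, plate variance is
   low and a strong true effect can itself exceed |Z| = 3 and be removed.
   In hit-rich screens (the regime emulated by default) plate variance
   reflects true biology and planted effects survive the rule.
4. **Bootstrap Wilcoxon** — the design is unbalanced (8× more control
   wells), so each (condition, readout) is tested by resampling 8 control
   Z-values with replacement 1,000 times, running the two-sided rank-sum
   test each time, BH-adjusting across conditions within each iteration
   (one shared control resample per iteration; a flag disables the
   adjustment), and reporting the median p over iterations. Hits are
   median p < 0.05.

The rank-sum p is exact (enumeration via the Mann–Whitney count
recurrence) when the combined sample is tie-free and both group sizes are
≤ 25, else a tie-corrected normal approximation with continuity correction
is used. Both paths agree with `scipy.stats.mannwhitneyu` to 1e-12 and
1e-9 respectively (asserted in tests). The resampling step usually
duplicates control values, which routes most bootstrap iterations through
the tie-aware path by construction.

A viability `death_index` (100 × stain-positive / total nuclei) is
provided for the companion cell-death assay.

## 3. Direction-aware robust rank aggregation

Genes are ranked within each readout by their median Z: for the pro-ED
direction ICAM1 and ROS descending (inflammation and oxidative stress
first) and VE-cadherin and nuclei counts ascending (junction loss and
cell loss first); the anti-ED direction reverses all four. Ties get
mid-ranks; ranks are normalised by the number of genes.

For one gene with sorted normalised ranks r₍₁₎ ≤ … ≤ r₍ₙ₎ over n lists,
the consensus score is the order-statistic probability

    rho = min_k P(at least k of n uniform ranks ≤ r₍ₖ₎)
        = min_k [1 − BinomCDF(k−1; n, r₍ₖ₎)],

small when the gene sits improbably high across lists. Significance comes
from a permutation null that re-assigns measurements to genes
independently within each list (`joint_rows=True` permutes whole rows
instead); a gene's p is (1 + #{null rho ≤ observed}) / (1 + n_perm)
against its own permuted scores, and the analytic Bonferroni-style bound
min(1, n·rho) is reported alongside. Genes significant only in the pro
(anti) direction at α = 0.05 form the pro-ED (anti-ED) list; a gene
significant in both directions is flagged inconsistent and assigned to
neither.

Seed importance for the propagation stage is −log10(aggregation p),
floored at 0 and renormalised to sum 1 (uniform seeding is a flag).

## 4. Network propagation with a degree-preserving null

Edges of the weighted, undirected interaction network are first corrected
for hub bias,

    w'_ij = w_ij / (d_i · d_j)^γ,

with d the weighted degree of the *input* network and γ = 0.5 by default
(the symmetric-normalisation convention; γ is configurable and γ = 0
disables the correction). Propagation scores solve the personalised
PageRank fixed point

    s = (1 − α) · W s + α · e,

with W the column-normalised transition matrix, e the normalised
seed-importance vector, and restart probability α = 0.15 (damping 0.85,
the convention of the personalised-PageRank function family; `--restart`
overrides). Power iteration stops at L1 change < 1e-12 or 10⁴ iterations;
scores sum to 1, and mass reaching degree-0 nodes is routed back through
the restart vector.

**Null ensemble.** Node significance is the exceedance of the empirical
score over the same propagation on `n_random` (default 1,000)
degree-preserving random networks: topology by edge-swap MCMC (≥ 10×|E|
accepted swaps; degenerate topologies where swaps cannot mix fall back to
stub matching with rejection of non-simple outcomes), fresh edge weights
resampled from the original weight distribution (a similarity-provider
callable can supply pair-specific weights instead), and the hub
correction re-applied per random network. Connectivity of the ensemble
members is not enforced. The empirical p is

    p_i = 1 − #{random networks with s_empirical,i > s_random,i} / n_random,

with ties counting against the empirical score. Nodes at p < 0.01 induce
the output subnetwork after removal of isolated nodes. Both clustering
statistics — average local clustering (degree < 2 contributing 0) and
global transitivity — are reported for extracted subnetworks, since
published "clustering coefficient" values do not always state which
definition they use.

**Scale effect worth knowing.** On small networks (≲ 400 nodes) the seed
nodes themselves are only partially re-identified: a seed's score is
dominated by its restart mass, which the degree-preserving null
reproduces, so the seed's empirical excess is marginal. Non-seed module
members, which receive their score entirely through edges, recover at
~100% regardless. At 1,000 nodes (the package's desk-scale analogue of a
genome-scale interactome) a dense 25-node module with 10 seeds is fully
re-identified at p < 0.01 with 200 random networks. This is a property of
the statistic at small n, not of the implementation.

## 5. Enrichment statistics

Overlap between a gene set and a network's nodes is the upper-tail
hypergeometric probability within an explicitly stated background (the
full input network's node set by default; depletion is a flag), with
per-cell Pearson residuals (obs − exp)/√exp and the odds ratio. Term
over-representation applies the same tail per term with BH adjustment.

Gene-to-gene functional similarity uses information content over a term
DAG: IC(t) = −log(freq(t)) with annotation frequency propagated to
ancestors, Lin term similarity 2·IC(MICA)/(IC(t₁)+IC(t₂)), and
best-match-average between gene term sets. This is a deliberately
simple, pluggable provider — `compare_similarity_distributions` accepts
any precomputed similarity matrix, so a topology-aware measure can be
dropped in. Two networks are compared by each node's mean within-network
pairwise similarity, two-sided rank-sum test between the node-level
distributions. Genes annotated only to the root have zero similarity to
everything (IC(root) = 0); genes with no annotation are dropped with a
warning; in a corpus where every gene shares every term all ICs are 0 and
similarities degenerate to 0.

## 6. Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the pipeline assumes,
with every planted signal recorded in a ground-truth manifest that
analysis stages never read:

- **Screen** — 5 plates × (8 control wells + one well per gene, 81 genes
  by default). Raw intensities are log-normal (imaging intensities are
  positive and right-skewed): log-value = channel baseline + per-plate
  shift (SD 0.25) + gene effect × noise SD + noise (SD 0.25). Effects are
  additive on the log scale in SD units; a pro-ED knockdown is
  (+3, +3, −3, −3) SD on (ICAM1, ROS, VECAD, NUCLEI) and an anti-ED
  knockdown the negation; 10 of each are planted by default.
- **Peaks** — planted regions placed in disjoint genomic slots; each
  replicate peak spans its region plus a condition-specific flank
  (50 + 40·condition-index bp) with centre jitter ≤ 10 bp. Flank steps
  dominate the jitter, so peaks over the same region nest across
  conditions and the containment intersection recovers every planted
  common region; private regions appear in one condition only.
- **DE tables** — planted genes get log2FC ≥ 2 and padj ≤ 0.01;
  background genes |log2FC| < 0.5 and padj ≥ 0.2, so the standard cut
  recovers exactly the planted set.
- **Network** — preferential-attachment backbone (400 nodes, m = 3 by
  default) with a planted module (10 pro genes + 15 other nodes) whose
  internal edges are added at density 0.5; weights uniform in (0.1, 1].
- **Ontology** — a toy single-root DAG of 3 branches × depth 3; module
  genes are annotated within one branch, other genes at random.

Not emulated: raw images or reads, count-level noise (DE tables are
outputs, not DESeq2 inputs), spatial plate effects (edge wells), dose–
response structure for drugs, correlated readouts beyond the planted
effect signature, and realistic interactome topology beyond the
scale-free degree law. Passing tests therefore demonstrate that the
statistics recover signals of the planted form under the assumed noise
model — not that they would do so on any particular real screen.

## 7. Determinism and problem sizes

Every stochastic stage derives its seed as SHA-256(global seed : stage
name) mod 2³¹, so a rerun of `run-all` with one config reproduces every
output file byte for byte (checksums recorded in `manifest.json`). The
test suite and `scripts/acceptance.py` run the same machinery at reduced
problem sizes chosen to keep the full suite in minutes on one CPU:
bootstrap/permutation counts of 100–500 where the default is 1,000,
null ensembles of 30–200 networks, screens of 30–81 genes, and networks
of 100–1,000 nodes; the dense-module recovery experiment runs at 1,000
nodes with 200 random networks for the scale reason in §4. The
full-default pipeline (n_boot = n_perm = n_random = 1,000) is what
`scripts/acceptance.py` executes first.

## 8. Known limitations

- The containment ("one interval resides entirely within the other")
  intersection is stricter than plain overlap; region recovery depends on
  peak width variation across conditions, which the generator guarantees
  but real data need not.
- Seed-node significance under the configuration-model null is
  conservative on small networks (§4).
- The semantic-similarity provider is intentionally minimal (Lin + BMA on
  a toy DAG); distributional comparisons on real annotations should use a
  full GO with a topology-aware measure via the pluggable matrix input.
- The network is treated as undirected even where source interactions are
  directed (kinase→substrate), and null-network connectivity is not
  enforced.
- BH-within-iteration for the bootstrap Wilcoxon reflects one reading of
  "Wilcoxon followed by BH correction with bootstrapping"; the other
  order (adjust the median p across conditions afterwards) is available
  by flag.
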