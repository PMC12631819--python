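# Methods

## Feature space

**Gap features (G, 724).** For an ordered nucleotide pair X, Y and a gap
k ≥ 0, the feature `k-XY` counts 1-based positions i with residue(i) = X and
residue(i + k + 1) = Y, i.e. exactly k residues strictly between the pair
(so `37-GC` relates positions such as (2, 40): 40 − 2 − 1 = 37). The default
set spans k = 0…40 for all 16 ordered pairs, organised as 16 per-pair
subgroups of 41 features (656), plus a 17th composition subgroup of 4
mononucleotide and 64 trinucleotide counts (68), for 724 features in 17
subgroups. Counts are raw integers; scaling happens at render time. For
every gap k the 16 pair counts sum to max(L − k − 1, 0), which the tests
assert as a conservation law.

**Descriptor features (D, 753 in 14 subgroups).** 314 classical descriptors:

| subgroup | n | content |
|---|---|---|
| orf | 10 | longest-ORF length/coverage/integrity, log-length, per-frame lengths and coverages |
| kmer_codon | 128 | 64 global trinucleotide fractions + 64 in-frame codon fractions inside the longest ORF |
| entropy | 8 | Shannon entropy of the k-mer distribution, k = 1…4, raw and normalised |
| autocorrelation | 48 | P(both positions are base b) for 4 bases × lags 1–12 |
| composition | 20 | mono- and dinucleotide fractions |
| secondary_structure | 40 | Nussinov-fold statistics: paired fraction, stems, hairpins, per-base and per-pair-type fractions, run lengths, positional profile, stem/loop histograms |
| eiip_spectrum | 36 | period-3 power, mean power, SNR, spectral entropy, 32-bin power profile |
| structure_graph | 24 | degree statistics, adjacency/Laplacian spectra, path-length indices of the backbone + base-pair graph |

and 439 CTD descriptors from 20 per-nucleotide physicochemical properties in
6 subgroups (hydrogen bonding, basicity, polar surface area, partition
coefficient, solubility-related, atom-path-length indices). A property with
g classes contributes g composition fractions, g(g−1)/2 transition rates and
5g positional quantiles (first/25/50/75/last occurrence, nearest-rank rule,
1-based positions divided by L; zeros for absent classes); the registry has
one 2-class, sixteen 3-class and three 4-class properties, i.e.
1·13 + 16·21 + 3·30 = 439. The per-nucleotide constants are approximate
descriptor values for the free bases, frozen in
`src/rnagrid/data/ctd_properties.tsv`; the class partitions order the four
bases from low to high property value. An ORF runs from an AUG to the first
in-frame stop (stop included); if no complete ORF exists in a frame the
longest AUG-to-end stretch counts with integrity 0.

Secondary-structure and graph descriptors are computed on a centred window
of at most 200 nt: the Nussinov recursion (maximum canonical base pairing
with AU/GC/GU pairs and a minimum hairpin loop of 3, deterministic
traceback) is cubic in length, and the statistics extracted from it saturate
well below transcript scale. An optional external engine delegates to the
RNAfold executable (thermodynamic minimum free energy) when present and
raises an explicit error directing back to the builtin engine when absent.

## Templates and rendering

A template is fit once per feature set on a reference corpus: feature ×
sequence matrix → cosine similarity among features (all-zero rows get
similarity 0 with a logged warning) → 2D embedding with distance
1 − similarity → grid of rows = ⌈√n⌉, cols = ⌈n/rows⌉ (28 × 27 for 753,
27 × 27 for 724) → exact rectangular linear assignment of embedded points
(affinely rescaled to the box of cell centres) minimising total squared
Euclidean distance, via `scipy.optimize.linear_sum_assignment`. Two
embeddings are provided: UMAP (package default, fixed `random_state`) and
classical multidimensional scaling, which is fully deterministic and is what
the test suite and the acceptance script use; the grid geometry is identical
under either. Per-feature min/max ranges are fit on the template corpus and
stored; rendering writes clip((v − min)/(max − min), 0, 1) into the
feature's cell, 0 for constant features, and exact 0 into unassigned cells.
Rendering is monotone in each feature's raw value. Channel splitting places
each subgroup's cells in its own channel; the channels sum back to the
image exactly.

Intensity scaling is per-feature rather than per-image so that a feature's
intensity is comparable across sequences; the choice is recorded in the
template file, which serialises to versioned JSON and round-trips exactly.

## Classifier

Per path: a 3 × 3 same-padding convolution with a single filter condenses
the channel stack to one map; then two blocks of
[max-pool → three parallel 3 × 3 convolutions → channel concatenation]:
block 1 pools 2 × 2 stride 2 with ceil padding (28 × 27 and 27 × 27 both →
14 × 14) and convolves valid (→ 12 × 12, 3 × 4 = 12 maps); block 2 pools
3 × 3 stride 1 (→ 10 × 10) and convolves same with 64 filters per branch
(→ 192 maps of 10 × 10). Global max pooling gives a 192-vector per path;
concatenation gives the 384-vector feeding a dense softmax layer.
The block wiring is the package's own choice among the many that satisfy
the endpoint constraints (192 maps of 10 × 10 from both input grids, a
384-dimensional joint embedding); filter counts live in `ModelConfig` and
the endpoint constraints are enforced by tests, which also verify the
analytic gradients against central finite differences at float64.

Training: categorical cross-entropy, Adam, minibatches with seeded shuffling
— deterministic for a fixed seed. Default hyperparameters follow the grid
used for model selection (batch size ∈ {32, 64, 96}, learning rate ∈
{1e-5, 1e-4, 2e-4, 5e-4}, selection by MCC; `grid_search` implements the
sweep). The learning-property test trains at 2e-3 for 30 epochs: with the
single-filter bottleneck the loss surface is flat early on, and small rates
only lengthen the plateau without changing the outcome; the test's purpose
is the pipeline's ability to learn, not rate sensitivity. Compute precision
defaults to float32 (float64 for gradient checks). Metrics (SPE, SEN, PRE,
ACC, MCC, Mann–Whitney AUC with midranks; macro-averaged one-vs-rest plus
the multiclass MCC generalisation for k > 2) are implemented from their
closed forms and cross-checked against scikit-learn in tests; degenerate
denominators report 0 with a warning.

## Interpretation

Permutation importance treats one image cell (in its subgroup channel) as
one feature. OCEL is the model's loss on the intact evaluation set; PCEL is
the mean loss over `n_permutations` (default 5) shuffles of that cell across
samples; IS = PCEL − OCEL. A cell constant across samples has IS exactly 0.
Because a permuted descriptor cell cannot affect the gap-feature path, the
other path's embedding is cached, which halves the cost without changing any
value; permutation repeats run as one stacked forward pass.

Top-N evaluation clusters samples on the top-N ranked feature columns with
Ward-linkage (Euclidean) agglomerative clustering cut at the number of
classes and reports the adjusted Rand index against the true labels.

Pairwise mutation analysis enumerates position pairs either exhaustively in
a window or as the occurrences of a named gap feature; each pair yields the
3 × 3 double mutants, scored by the full pipeline (featurise → render →
predict), and the contribution C = P_original − mean of the nine mutant
scores. Scanning (i, j) and (j, i) produces the same mutant set and hence
identical results.

## Synthetic data

The generator emulates the labelled corpora the three tasks need. Coding
task: a coding-like sequence carries an in-frame ORF (AUG + stop-free sense
codons + stop) covering ≥ 50 % of its length, with a stylised 3:1 codon bias
toward G/C-ending codons; its noncoding-like partner is an exact
dinucleotide-preserving shuffle (Altschul–Erickson Eulerian-walk
construction), which destroys ORF/periodicity signal while preserving all 16
dinucleotide counts — so composition alone cannot separate the classes.
Taxonomy task: k classes, each defined by three class-specific 8-mers
planted at ~1 occurrence per 80 nt on an IID background. Circular-vs-linear
task: one class enriched for a stylised back-splice junction motif. Defaults
are 300–600 nt and a 60 nt minimum so all gaps up to 40 are populated.

What passing on these corpora shows: the pipeline can extract, render and
learn planted, localised sequence signals end to end. What it does not
show: performance on real transcriptomes, whose class signals are weaker,
confounded by length and composition biases, and not reducible to a single
planted motif or ORF; no claim about benchmark performance is made or
tested.

## Problem sizes and numerical choices

The test suite exercises the learning property at 500 sequences per class
(300–600 nt), a 70/30 split, templates fit on 200 training sequences with
the MDS embedding, and 30 training epochs; the acceptance script rebuilds
the descriptor template from a 1,000-sequence corpus. Ties in max-pooling
resolve to the first maximum; cosine similarity clips to [−1, 1]; the
assignment cost uses squared Euclidean distance to cell centres; CTD
quantiles use the nearest-rank rule; FASTA input normalises T→U and
uppercases, with degenerate IUPAC bases handled by policy (reject /
drop-record / seeded random resolution).

## Known limitations

- The Nussinov engine maximises pair count, not free energy; its statistics
  are coarse structure proxies (RNAfold integration is optional).
- CTD property constants are approximate descriptor values; swapping in
  measured tables only requires editing the registry TSV.
- The NumPy network trains on CPU at small-corpus scale; it is not meant for
  hundred-thousand-sequence training runs.
- Permutation importance at single-cell granularity scales linearly in
  features × permutations × evaluation-set size; use the `features` argument
  to restrict scans when iterating.
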