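# rnagrid

Image-like representation of RNA sequences for interpretable deep-learning
classification.

`rnagrid` addresses three recurring RNA classification problems — coding
potential (mRNA vs ncRNA), small-ncRNA taxonomy, and circular vs linear
lncRNA — with a single pipeline aimed at researchers who want not just a
label but an account of *which* sequence features drive it:

1. **Feature space (1477 dimensions).** Each sequence is expanded into
   724 *gap features* — counts of ordered nucleotide pairs `k-XY`, the pair
   X…Y with exactly *k* residues strictly between them, for all 16 ordered
   pairs and gaps k = 0…40, plus a mononucleotide/trinucleotide composition
   subgroup (17 subgroups in total) — and 753 *descriptor features* in 14
   subgroups spanning three classes: sequence-intrinsic (ORF statistics,
   codon/k-mer usage, entropy, autocorrelation, composition), structure-based
   (Nussinov secondary structure, EIIP power spectrum, structure-graph
   topology) and physicochemical Composition–Transition–Distribution (CTD)
   descriptors derived from 20 per-nucleotide property tables.
2. **Feature-to-image templates.** For each feature set, the feature ×
   sequence matrix of a reference corpus is turned into a cosine-similarity
   matrix among features; features are embedded in 2D (distance
   1 − similarity) and placed bijectively onto a grid of
   rows = ⌈√n⌉, cols = ⌈n/rows⌉ — 28 × 27 for the 753 descriptor features and
   27 × 27 for the 724 gap features — by exact linear assignment
   (Jonker–Volgenant family) minimising squared distance to cell centres.
   Each sequence then renders as two intensity images via per-feature
   min-max scaling.
3. **Dual-path multi-channel CNN.** The two images are split into subgroup
   channels (14 for the descriptor image, 17 for the gap image) and fed to
   two independent convolutional paths, each ending in 192 feature maps of
   10 × 10; global max pooling and concatenation give a 384-vector feeding a
   softmax head trained with categorical cross-entropy. The network
   (forward, backward, Adam) is implemented in NumPy and verified against
   numerical gradients.
4. **Interpretation.** Permutation feature importance
   (IS = PCEL − OCEL, the loss increase when a feature's image cell is
   shuffled across samples), top-N feature evaluation by hierarchical
   clustering adjusted Rand score, and in-silico pairwise mutagenesis: for a
   nucleotide pair (i, j), all 3 × 3 double mutants are scored and the pair's
   contribution is

   C = P_original − (1/9) Σᵢ Σⱼ P_{i,j}

   with P the model's coding-potential score (CPS).

A synthetic-corpus generator (planted ORFs with codon bias vs
dinucleotide-preserving shuffles; motif-defined classes) makes the whole
pipeline runnable and testable without any external download.

## Worked example

```python
import numpy as np
import rnagrid as rg

corpus = rg.generate_synthetic_corpus(150, "coding", (300, 600), seed=4)
seqs, y = corpus.sequences, corpus.y()
tpl_d = rg.build_template(seqs[:100], "D", method="mds", seed=0)
tpl_g = rg.build_template(seqs[:100], "G", method="mds", seed=0)
print("D-template grid:", tpl_d.grid, "| G-template grid:", tpl_g.grid)

xd, xg = rg.render_corpus_channels(seqs, tpl_d, tpl_g)
rng = np.random.default_rng(0)
idx = rng.permutation(len(seqs)); tr, te = idx[:210], idx[210:]
cfg = rg.ModelConfig(n_classes=2, epochs=30, learning_rate=2e-3, seed=0)
model = rg.DualPathModel(cfg, xd.shape[1:], xg.shape[1:])
model.train(xd[tr], xg[tr], y[tr])
rep = rg.compute_metrics(y[te], model.predict_proba(xd[te], xg[te])[:, 1])
print(f"held-out ACC {rep.acc:.3f}  MCC {rep.mcc:.3f}  AUC {rep.auc:.3f}")

scorer = rg.SequenceScorer(model, tpl_d, tpl_g, positive_class=0)
res = rg.scan_pair(seqs[0], scorer, 5, 20)
print(f"pair (5, 20): P_original {res.p_original:.3f}  "
      f"P_mutated {res.p_mutated:.3f}  C {res.c_pair:+.3f}")
```

prints

```
D-template grid: (28, 27) | G-template grid: (27, 27)
held-out ACC 0.733  MCC 0.544  AUC 0.849
pair (5, 20): P_original 0.787  P_mutated 0.781  C +0.006
```

The two grids are the fixed template shapes for 753 and 724 features. The
held-out metrics show the classifier separating planted-ORF sequences from
their dinucleotide-preserving shuffles at this small corpus size (at
500 sequences per class the same pipeline reaches held-out MCC ≈ 0.84, see
`tests/test_acceptance.py`). The mutation scan of positions (5, 20) of a
coding-like sequence shows a pair whose nine double mutants barely move the
coding-potential score (C ≈ 0), i.e. a pair the model does not rely on.

The same pipeline is scriptable from the shell:

```bash
rnagrid simulate --n-per-class 100 --seed 1 --out run/
rnagrid build-template --fasta run/corpus.fasta --feature-set D --out run/tpl_D.json
rnagrid build-template --fasta run/corpus.fasta --feature-set G --out run/tpl_G.json
rnagrid train --fasta run/corpus.fasta --labels run/labels.tsv \
    --template-d run/tpl_D.json --template-g run/tpl_G.json --out run/model
rnagrid mutscan --fasta run/corpus.fasta --model run/model/model.npz \
    --template-d run/tpl_D.json --template-g run/tpl_G.json \
    --gfeature 37-GC --out run/scan
```

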