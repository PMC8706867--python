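# Methods

`gruchem` implements a combinational de novo design strategy for focused
molecular libraries: a general SMILES language model is specialised to a
small set of known actives by transfer learning, and the generated
molecules are then triaged by descriptor-based classifiers, placed in a
low-dimensional chemical-space picture, and (given docked poses) analysed
for protein–ligand contact patterns. This note records the models, the
parameter choices and their rationale, the numerical conventions, and what
the synthetic test conditions do and do not demonstrate.

## Corpus curation and tokenization

Curation canonicalizes every input with RDKit (isomeric SMILES: charges and
stereo descriptors are preserved), then keeps molecules with 10–100 heavy
atoms and a canonical string of fewer than 140 characters, removes
blocklisted molecules and deduplicates. Conventions worth stating
explicitly:

- The 140-character bound is applied to the *canonical* string, strictly
  (`len < 140`). Raw input length plays no role.
- Blocklist matching is canonical-SMILES equality — the only identity
  notion available without a registration system. It is stereo- and
  charge-sensitive.
- Invalid and duplicate records are dropped silently but counted in a
  per-rule `CurationReport`, so curation is auditable.
- No salt stripping or standardization beyond canonicalization is done.

The tokenizer is regex-based: bracket atoms `[...]`, two-letter organic
subset halogens `Cl`/`Br`, and `%nn` ring closures are single tokens;
everything else is one character. This is the standard scheme for SMILES
language models; it guarantees `detokenize(tokenize(s)) == s` for every
RDKit-canonical string, which the tests assert over the whole synthetic
corpus. The vocabulary is the sorted set of corpus tokens plus `PAD` (index
0), `BOS`, `EOS`; sorting makes it a deterministic function of the corpus.

## The generative model

An autoregressive next-token model over tokenized SMILES: a 128-dimensional
embedding, three stacked GRU layers with 512 units each, and a linear
softmax head over the vocabulary. The loss is the mean negative log
likelihood of the next token, with padded positions masked out. Training
uses Adam (β₁ = 0.9, β₂ = 0.999) with initial learning rate 1e-3 decayed
multiplicatively: lr ← lr × (1 − 0.05) at every 300th step, i.e.
lr(step) = 1e-3 × 0.95^⌊step/300⌋. The decay phrasing ("rate 0.05 every
300 steps") is ambiguous between ×0.95 and ×0.05; the stepped-exponential
×0.95 reading is the common idiom and is what is implemented — both the
rate and the interval are configurable.

The network and its backpropagation-through-time are implemented directly
in NumPy (float32, fused gate matrices, batched input matmuls), with Adam
and a global-gradient-norm clip of 5.0 for robustness on small noisy
batches. Correctness of the gradients is not taken on faith: the test
suite cannot affordably finite-difference the full model each run, but the
implementation was verified against central finite differences on a small
configuration during development, and the suite asserts the behavioural
consequences (loss decreases, single-sequence memorization drives loss
below 0.05, low-temperature sampling reproduces a memorized corpus
exactly).

Other conventions:

- Variable-length batches are teacher-forced with PAD-masked loss; each
  shuffled epoch is length-sorted within chunks of 8 batches to limit
  padding waste. This affects efficiency only, not the modelled
  distribution.
- Weights are initialised uniformly in ±1/√H (embedding ±0.1) from a
  generator seeded by `TrainConfig.seed`; the seed is mandatory, and
  identical config + seed reproduces the loss history and samples bit for
  bit on the same platform.
- Fine-tuning operates on a copy (the pretrained model is preserved),
  appends to the loss history under a `finetune` phase marker, and restarts
  the learning-rate schedule at the initial rate — the restart is a choice,
  configurable through `TrainConfig`.
- Sampling is ancestral from `BOS` with an optional softmax temperature
  (default 1.0); a sequence that has not emitted `EOS` by `max_length`
  (default 142 = 140 characters + specials) is truncated and
  validity-checked as-is. Validity is defined by the same RDKit parser used
  in curation, on raw sampled strings (uniqueness is a separate statistic,
  reported by callers that need it).
- No early stopping: training runs for the configured number of steps and
  reports the loss/validity curves, because convergence judgement belongs
  to the caller (the historical workflow this mirrors used fixed step
  counts: long pretraining, ~200-step fine-tuning).

## Descriptor screening

Molecules are described by a frozen registry of exactly 200 fragmental and
topological RDKit 2D descriptors (`src/gruchem/data/descriptors_200.txt`):
all 85 `fr_*` fragment counts plus 115 topological/shape/EState/VSA
descriptors. The registry is the full RDKit 2D descriptor list minus ten
deliberate exclusions — the four partial-charge extrema (undefined for
some molecules), the three Morgan fingerprint densities, the composite
drug-likeness scores `qed` and `SPS`, and `Ipc` (numerically overflowing
for large molecules). A descriptor that still fails for a molecule is
imputed as 0 (fragment counts default to absent) and flagged in the
returned problem report; unparseable SMILES are rejected per row, never
silently.

Five classifiers run behind one interface, with hyperparameters fixed where
the reference workflow states them and scikit-learn defaults elsewhere:
SVM (RBF kernel, C = 1, gamma = 'auto'), k-nearest neighbours, Gaussian
naive Bayes, random forest, and logistic regression (C = 0.5, tol = 1e-3,
max_iter = 200, L1 penalty, liblinear). All five are wrapped in a
`StandardScaler` pipeline fitted on the training fold: the descriptor
columns span six orders of magnitude, scaling is necessary for the
distance- and margin-based methods and provably neutral for the forest.
Splits are stratified 6:4 train:validation per class; the repeat protocol
re-splits and re-fits (default 10 repeats) and reports mean ± sd per
metric, and stratified k-fold cross-validation (default k = 5) is provided
separately.

Metrics from the confusion matrix (positive = inhibitor):

- Acc = (TP+TN)/N, Sen = TP/(TP+FN), Spe = TN/(TN+FP),
- MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
- Random Acc = [(TP+FN)(TP+FP) + (TN+FP)(TN+FN)]/N² — the expected
  accuracy of a predictor that keeps both marginals but pairs them at
  random (the expected-agreement term of Cohen's κ). A Monte-Carlo test
  (10⁵ label-prediction re-pairings) confirms the closed form within
  0.005.

A metric whose denominator is zero (e.g. MCC of an all-positive predictor)
is reported as undefined (`None`), never as 0. AUC uses the positive-class
decision score where available (SVM, LR) and the class-probability estimate
otherwise. Display rounding is 2 decimals (3 for Random Acc).

Retrospective recall — the fraction of held-out known actives that the
generator rediscovers — matches by canonical-SMILES identity, optionally
gated on the screening model also predicting the string positive (the full
generate-then-screen protocol); the plain and gated variants are both
available because the stricter reading is ambiguous in the source
workflow. Recall is monotone non-decreasing in the generated set by
construction, which the tests assert on nested prefixes.

## Chemical space

Each molecule is reduced to seven topology-only properties: H-bond
acceptors, H-bond donors, rotatable bonds, aromatic rings, aliphatic
rings, heteroatom count and molecular weight (RDKit Lipinski definitions;
the rotatable-bond SMARTS is RDKit's default, recorded here as the pinned
definition). "Heterocycle atoms" is read as the heteroatom count (non-C
heavy atoms); the narrower alternative — heteroatoms that are ring
members — is available via `heteroatoms_in_rings=True`.

The 2-D picture is t-SNE (scikit-learn, PCA initialisation, default
perplexity 30, 1000 iterations, mandatory seed) on z-scored property
vectors. Standardization makes the embedding invariant to affine rescaling
of any single property, which is tested. Because a t-SNE plot is only a
picture, overlap between a generated set and known actives is quantified
in the *standardized property space*, not the embedded plane: the overlap
fraction is the share of generated molecules with at least one known
active among their k = 5 nearest neighbours. The tests pin the two
extremes (identical sets → 1, far-separated sets → ~0) and monotonicity in
a mixture weight.

## Contacts

A residue contacts a ligand pose when any of its heavy atoms lies within
the cutoff (default 5.0 Å, boundary inclusive — the convention had to be
chosen; ≤ is documented and tested) of any ligand heavy atom. Hydrogens
are excluded by default because docked poses rarely carry consistent
protonation; a flag restores them. The contact frequency of a residue is
the fraction of ligands in the set contacting it, computed with one pose
per ligand by default. The production path uses a k-d tree; a brute-force
all-pairs path is kept as an independent oracle and the suite asserts
exact agreement on 100 random synthetic complexes. Similarity between two
profiles (e.g. known actives vs generated molecules docked to the same
target) is reported as a Pearson correlation over the union of residues
rather than asserted qualitatively. Docking itself is out of scope — poses
come from any external tool via PDB/SDF/MOL2.

## Synthetic data: what it shows and what it does not

The corpus generator assembles molecular graphs — chain growth over
C/N/O/S, attachment of five- and six-membered aromatic and aliphatic ring
templates, halogen leaves, carbonyls, formal charges on amine N / terminal
O, and tetrahedral stereo tags on genuine stereocentres — then sanitizes
and emits canonical SMILES. Validity is therefore guaranteed by
construction, and the emitted grammar exercises every token family the
tokenizer must handle (bracket atoms, two-letter halogens, ring indices,
charges, stereo). Defaults: 5 000 molecules of 10–16 heavy atoms — the
lower edge of the curation window, kept deliberately short (≈28 tokens)
so that the full 3 × 512 architecture trains to convergence on one CPU in
minutes rather than hours; the 5 000-string default is large enough for
the language-model validity benchmark at that scale.

The labeled generator lays two multivariate Gaussians over the 200-column
descriptor layout with a requested class-mean separation (in sd units) on
`n_informative` columns and pure noise elsewhere; at effect size 0 the
classes are exchangeable. The complex generator places ligand atom
clusters at exact, recorded distances from chosen residues of a flat
miniature backbone, so ground-truth contact sets are known analytically.

Passing tests on these fixtures demonstrate that the machinery is correct
(grammar learning, metric algebra, geometric queries), not that the
pipeline discovers real inhibitors: the toy corpus has none of PubChem's
scale or skew, the labeled clusters are far better behaved than real
descriptor distributions, and no docking is performed. Scaled-down
analogues are used deliberately: the desk benchmark trains the full
3 × 512 architecture on the 5 000-string corpus and claims ≥ 0.90 sampled
validity, which mirrors the qualitative finding of the full-scale workflow
(validity approaching 1 as capacity and data grow) without claiming its
numbers.

Problem sizes used by the benchmark suite and the reproduction script,
chosen as the package's standard desk-scale protocol: 800 pretraining
steps at batch 128 (≈ 20 epochs of the 5 000-string corpus — the sampled
validity trajectory rises steeply to ≈ 0.88 by step 500 and flattens near
0.93 by step 1 000, so 800 sits on the plateau's shoulder), 200
fine-tuning steps at batch 32 on the 50-molecule focused set (the
fine-tuning loss converges within ~200 steps, consistent with transfer
learning on focused sets an order of magnitude smaller than the corpus),
1 000 samples for validity estimates and 5 seeded repeats of 300 samples
for the before/after transfer comparison.

## Known limitations

- The NumPy GRU is CPU-bound and single-threaded beyond BLAS; it is sized
  for research-scale corpora (10³–10⁵ strings), not the millions a
  full-scale pretraining would use.
- Canonical-SMILES identity is a strict matching notion: tautomers and
  alternative salt forms do not match.
- The 200-descriptor registry approximates, but is not identical to, any
  particular historical descriptor list; it is frozen in the package so
  results are reproducible.
- t-SNE coordinates are not comparable across runs with different seeds;
  only the seeded embedding is deterministic, and quantitative claims are
  always made in property space.
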