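# Methods

This note documents the models and procedures implemented in `seqtok`,
the parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions that make every run
reproducible.

## Boundary-free tokenization

Biological sequences have two representation levels — characters and whole
sequences — with no word boundaries in between.  All trainers and
segmenters therefore treat each sequence as a single uninterrupted token
stream: merges and matches may span the entire sequence, and no
continuation marker (the `##` of NLP WordPiece) is used, since there are
no word-internal positions to mark.

Every vocabulary reserves `<pad>` (id 0) and `<unk>` (id 1) and always
contains the single alphabet characters, so any cleaned in-alphabet
sequence is tokenizable.  Non-standard residues (IUPAC DNA ambiguity
codes; B, J, O, U, X, Z in proteins) are mapped to a single unknown-marker
character (`?`) at cleaning time; the marker always becomes an `<unk>`
token, never participates in merges or probability estimates, and splits
the stream on either side of it.  This keeps vocabularies closed without
inventing behavior for characters the training alphabet does not define.

### BPE

The base vocabulary is the alphabet plus specials.  Each round counts all
adjacent token pairs across the corpus (with multiplicity, including
overlapping occurrences within homopolymer runs), adopts the most frequent
pair as a merge rule, re-segments, and repeats until the vocabulary
reaches the requested size or no pair occurs at least twice.  Ties are
broken toward the lexicographically smaller merged token — the criterion
is otherwise underdetermined, and byte-identical retraining is a hard
requirement here.  Inference replays merges in adoption order
(implemented as lowest-rank-first, which is equivalent), left-to-right
within a rank.

Pair counts are maintained incrementally (only sequences containing the
adopted pair are recounted), which keeps training a 3200-token dictionary
on a few-hundred-thousand-character corpus in the tens of seconds.

### WordPiece

The identical loop, except the adopted pair maximizes
`f12 / (f1 * f2)` where all three frequencies come from the *current*
segmentation; ties break by larger `f12`, then lexicographically.
Inference is greedy longest-prefix matching against the vocabulary.

A practical consequence worth knowing: because the score rewards pairs
whose parts are rare, on high-entropy corpora WordPiece preferentially
descends into rarely-repeated substrings (and learns many redundant
overlapping fragments of genuinely repeated elements) before exploiting
frequent pairs.  Its fold reductions on near-random backgrounds are
therefore systematically below BPE's at equal dictionary size — visible in
the harness sweeps, and inherent to the adoption score rather than a
defect of the trainer.

### Unigram

Tokens carry probabilities `p(t)`; a segmentation z of sequence x scores
`g(z) = ∏ p(t_j)`, `h(x)` is the maximum over all segmentations, and the
corpus loss is `−Σ log h(x_i)` with every corpus sequence counted once
(duplicates count separately).  Training:

1. **Seeding.** All substrings up to length 8 are counted; the
   `seed_multiplier × target` most frequent are kept (default multiplier
   10), always including the single characters.  Probabilities start at
   normalized substring frequencies.
2. **EM.** `em_rounds` (default 2) of forward–backward over the full
   segmentation lattice re-estimate `p(t)` from expected token counts.
   Sums are accumulated in log space; tokens with vanishing expected count
   are floored rather than dropped so the lattice stays connected.
3. **Pruning.** Each removable (multi-character) token is scored by its
   Viterbi usage count times the gap between its log-probability and the
   best alternative segmentation of its own text under the remaining
   vocabulary — the standard fast approximation to the exact
   leave-one-out loss increase, which would require re-segmenting the
   whole corpus per candidate.  The `shrink_fraction` (default 0.25) of
   tokens with the smallest increase are dropped, never below the target
   size, and never the single characters.  Steps 2–3 alternate until the
   target size is reached, ending with a final EM pass; the stored
   probabilities sum to one within 1e-9.

Viterbi segmentation breaks exact score ties toward fewer tokens, then
toward the lexicographically smaller token at the decision point.  The
tests verify Viterbi against exhaustive enumeration of all 2^(L−1)
segmentations for sequences up to length 12.

### k-mer baselines

Fixed dictionaries of all |Σ|^k words; for k > 1 the single characters are
retained so a trailing fragment shorter than k remains tokenizable.
Segmentation is non-overlapping left-to-right windows, tail as single
characters.

## Encoding and compression

Fixed-length encoding truncates the token-id list at `max_len` and
right-pads with the pad id; no begin/end-of-sequence tokens are inserted
(any classifier-specific specials are the consumer's concern).  Fold
reduction is defined per sequence (characters / tokens) and then averaged;
the ratio-of-totals variant is exposed alongside because the two differ
under length heterogeneity, and which one a published axis uses is often
ambiguous.

## Evaluation statistics

- **MCC**: the binary formula
  `(TN·TP − FN·FP) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))` with the convention
  MCC = 0 when a denominator factor vanishes.  Multiclass tasks use the
  multi-category generalization over the K×K confusion matrix, whose K=2
  case coincides with the binary formula (asserted in tests); a single
  headline MCC is thereby defined for any K.
- **AUC**: rank-based (Mann–Whitney) with ties counted ½; multiclass AUC
  is macro-averaged one-vs-rest and reported separately from MCC.
- **Spearman**: Pearson correlation of average-rank vectors; undefined
  (an error, not a NaN) for constant input.
- **Alignment validity**: equal row lengths, no column gapped in both
  rows, and each row equal to its source after gap removal (both ASCII
  hyphen and en-dash count as gaps).  Invalidity is a verdict with a
  reason, not an exception.
- **Column score**: columns are identified by the pair of source
  coordinates they align; a gap side is anchored to the preceding source
  coordinate.  This anchoring makes CS(a, a) = 1 and the score
  order-insensitive — the minimal properties any column-matching
  definition must satisfy — without assuming anything further about how
  columns "match".
- **Coverage**: VA/TA, also exposed as an exact rational.
- **Wilcoxon signed-rank**: zero differences dropped, average ranks for
  tied magnitudes, and the exact two-sided null distribution computed by
  subset-sum dynamic programming for n ≤ 25 (half-integer ranks are
  doubled to stay integral); beyond that, the usual normal approximation
  with continuity correction.  All-zero differences return p = 1 with a
  degenerate flag.

## Synthetic data

The classification generator draws i.i.d. background characters (uniform
by default, or a supplied frequency vector), plants each class's motifs at
positions drawn from a configurable law, and inserts shared repetitive
elements across all classes.  Planting is by overwriting at
non-overlapping positions: class motifs are placed first and are always
intact (the class signal is guaranteed by construction); repeats are
placed in the remaining room and skipped when none is left.  Default
conditions: 2 motifs of 8–12 residues per class, 4 shared repeat elements
of 15 residues each present with probability 0.5, sequence lengths 80–120
— about a third of each sequence is repetitive, a deliberately
conservative stand-in for real genomes (where repeats exceed half the
sequence) and for homologous protein families (where members share most
of their length).  Multiclass experiments default to 9 classes with
180/20/20 train/validation/test sequences per class, a desk-scale
reduction of a 1800/100/100 superfamily benchmark.

Because the background is i.i.d. — maximally incompressible — fold
reductions measured here are *lower bounds* on what the same dictionary
sizes achieve on real, homology-rich corpora; conversely the planted
motifs make classification easier than real family assignment.  Passing
tests demonstrate that the pipeline recovers planted structure under
realistic noise, not that real-data scores are reproduced.

The regression generator plants 0–4 disjoint occurrences of one motif and
sets the target to `effect_size × count + N(0, noise_sd)`, resampling any
background that contains the motif by chance so the count is exact.

The alignment simulator draws, per pair, a root length (uniform 150–300
nt), a substitution distance (0.05–0.15 per site), insertion and deletion
rates (0–0.05 events per substitution) and Zipf exponents A (1.01–2.0)
for indel lengths.  The root is uniform DNA; the descendant applies
Jukes–Cantor substitutions (per-site difference probability
¾(1 − e^(−4d/3))), then Poisson(rate × d × L) deletion and insertion
events with lengths from a power law P(k) ∝ k^(−A) truncated at 50
(untruncated Zipf with A near 1 has no usable mass; the cap also bounds
memory) and uniform positions.  The emitted alignment records the event
history, so every output passes validity by construction and CS against
itself is 1.  The simulator aims for structural fidelity to this class of
indel simulations — uniform parameter draws, power-law indel lengths, a
known true alignment — not for numeric agreement with any particular
ABC-based tool, whose exact placement conventions differ.

All generators use a single `numpy` Generator stream per call, so
identical parameters and seed give identical output across platforms.

## Harness

For each (task, tokenizer, dictionary size) the harness trains the
tokenizer on the training split only, encodes all splits, fits the
learner on train, selects its regularization on the validation split
(ties to the first candidate), and reports test metrics plus compression
statistics over the whole dataset.  The bundled learner is a
bag-of-token-ids linear model — multinomial logistic regression for
classification, ridge for regression — chosen because it is fully
deterministic, fast enough for multi-seed sweeps on one CPU, and linear,
so gradient×input attributions are exact.  The learner interface is
pluggable; transformer-style hyperparameters (layers, heads, hidden size,
learning rate presets 1e-3/1e-4/1e-5) are accepted in the configuration
and forwarded, so a sequence-model learner can be dropped in without
changing experiment code.  A bag-of-tokens learner ignores token order;
tasks whose signal is purely positional would need such a replacement.

## Interpretation

Attribution scores arrive per token (from integrated gradients of a
sequence model, or the bundled exact linear attributions, normalized per
sequence to max |score| = 1 so the threshold is scale-free).  Selection
keeps tokens with |score| > 0.2; histograms count, per character
position, the sequences with a selected token covering it.  Motif
annotation slides a 15-character window with stride 1 (the most sensitive
choice) and requires a specific token to be selected, with a consistent
sign, in at least ⌈8 × cohort/100⌉ distinct sequences — the 8-of-100 rule
pro-rated to the cohort actually analyzed.  Runs of consecutive
qualifying window positions for the same (token, sign) merge into one
annotation anchored at the modal occurrence start; enriched and depleted
tokens are reported separately, since the *absence* signal of a depleted
token is biologically meaningful in its own right.

## Numerical and reproducibility conventions

- Trainers are deterministic: fixed tie-breaks everywhere, no RNG; a
  model saved, loaded and re-saved is byte-identical.
- Log-domain accumulation for all lattice computations; probability
  floors (1e-12 relative) rather than hard zeros during EM.
- Exact integer arithmetic where the quantity is rational (pair counts,
  confusion matrices, coverage, the signed-rank DP).
- Problem sizes used by the test and acceptance workloads — 2000
  sequences for the compression sweep, 1000 simulated alignments, 5 seeds
  × 3 methods × 3 dictionary sizes for the tradeoff experiment — were
  chosen to give stable statistics on a single CPU; all scale linearly if
  enlarged.

## Known limitations

- No byte-level fallback and no subword regularization (sampled
  segmentations); Unigram seeding is the plain most-frequent-substrings
  heuristic, not suffix-automaton accelerated, so trained vocabularies
  will differ from implementations with other seeding/shrink schedules
  even at equal loss.
- WordPiece's rare-pair preference (above) makes its dictionaries
  corpus-bound on small data.
- The bundled learner cannot represent positional or contextual
  interactions between tokens.
- The indel simulator is nucleotide-only and Jukes–Cantor; amino-acid
  substitution matrices and codon models are out of scope.
- Corpus streaming is absent: corpora are held in memory, which is fine
  up to millions of characters but not for archive-scale training.
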