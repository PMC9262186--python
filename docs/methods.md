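# Methods

## The problem

Intrinsic (rho-independent) transcription terminators end bacterial
transcription without accessory proteins. Their anatomy is conserved: a
GC-rich stem-loop hairpin, an A-rich tract (A-tail) immediately 5' of it,
and a U-rich tract (U-tail) 3' of it that pauses the polymerase while the
hairpin folds and disrupts the elongation complex. Experimentally validated
terminator sets are small (hundreds of sequences per species), which limits
what a neural network can learn from them directly. `termscan` implements a
structure-constrained pre-training strategy: inverse folding generates an
essentially unlimited supply of sequences that share the terminator's
*secondary structure* but not its sequence biases, a classifier is first
trained to recognise that structure, and the resulting weights initialise
the training on actual terminator sequences.

## Secondary-structure model

The internal folder is a weighted maximum-pairing (Nussinov-style) dynamic
program over pseudoknot-free structures: pair weights G-C = 3, A-U = 2,
G-U = 1, minimum hairpin loop 3 nt. This is deliberately *not* a
thermodynamic nearest-neighbour model: the simple objective makes the
optimum reproducible by brute-force enumeration on short sequences, so the
folder — and everything that depends on it — is testable against an
independent oracle. Traceback is deterministic (leftmost pairing partner
preferred; pairing preferred over leaving a base unpaired at equal score).
Co-optimal structures exist (e.g. in symmetric sequences), so tests assert
optimality of the returned weight rather than identity of the pair set.
Production pre-training can swap in the thermodynamic RNAinverse backend
(ViennaRNA bindings) via `inverse_fold(..., backend="vienna")`.

### Inverse folding

`inverse_fold` runs an adaptive stochastic local search: the candidate
sequence starts from a random draw (unpaired positions biased towards A,
target pairs seeded with complementary dinucleotides, GC-weighted), and
each move either rewrites a randomly chosen target pair with a pairing
dinucleotide or mutates a *defect* position — one where the candidate's
fold currently disagrees with the target. Target-unpaired defects are
usually quieted to A, because A can pair with nothing but U and therefore
rarely creates new spurious pairs. A move is accepted whenever the
base-pair distance between the candidate's fold and the target does not
increase. The search stalls occasionally in plateau states where a pad
G or C ties with a stem position for the same partner; after 1,200
iterations without improvement the search restarts from a fresh random
initialisation, sharing the overall iteration budget (default 20,000).
With these choices, random hairpin targets with stems up to 10 bp converge
to distance 0 in roughly 1,000-2,000 iterations on average; the achieved
distance is always reported honestly rather than raised as an error.

### Pre-training data

`generate_pretraining_set` draws targets round-robin from a list of
dot-bracket structures, inverse-folds each positive to distance 0, and
adds an equal number of uniform-random negatives with exactly the same
length multiset. Each class is split 85% / 15% into a pre-training
partition and a held-out partition used solely to early-stop the
pre-training. Because the positives are constrained only by structure,
their GC content sits near 0.5 — far below real terminator stems — which
is the point: the network learns pairing geometry, not composition.

One subtlety matters under the maximum-pairing model: a sequence whose
fold equals a hairpin-with-long-unpaired-tails target *exactly* cannot
contain any pairable dinucleotide among its unpaired positions, so such
positives are necessarily depleted of U (and pairing potential) outside
the stem. A classifier pre-trained on full-length targets then learns
"blank matrix outside one stripe ⇒ positive" — a composition shortcut
that does not transfer to terminator records, whose random flanks carry
normal pairing speckle. The remedy mirrors how the real training data is
built: inverse-fold only the structural *element* (A-tail through U-tail)
and embed it in uniform-random context padding up to the model input
length (`pad_to=75`, symmetric, extra base 3'). The element still refolds
to its target at distance 0; the padded record's overall composition is
indistinguishable from the negatives'. This is the configuration used in
all shipped workflows.

## Synthetic data

The generator's defaults describe a plausible GC-rich hairpin terminator:
A-tail 6-10 nt (80% A), stem 7-12 bp with GC fraction 0.8 (Watson-Crick
complementary), loop 3-7 nt, U-tail 6-10 nt (80% U), all padded to 75 nt
with uniform-random flanks, the extra base on the 3' side. No published
per-section length distributions exist for the curated terminator sets, so
these are one-time choices in the range the literature describes
qualitatively, not fitted values. Records are rejection-sampled (about 25%
rejection at defaults) until the folded maximum-pairing optimum contains
every annotated stem pair: a uniform-random pad occasionally complements
the stem and would displace a stem pair with a co-optimal alternative,
making the record's own annotation false. The full padded record generally
folds to a *superset* of the annotation — random tails admit additional
weighted pairs — which is why the containment property, not base-pair
distance 0, is the generator's contract.

tRNA-like records inverse-fold a 76-nt cloverleaf template (7-bp acceptor
stem, 4-bp D-arm, 5-bp anticodon arm, 5-bp T-arm) and pad it to 95 nt.

Synthetic genomes are uniform-random nucleotide strings with terminator
*cores* (A-tail through U-tail; pads are discarded since the genome itself
supplies context) implanted non-overlapping with at least 75 nt spacing,
so no scan window spans two elements. The termination site of an element
is the 3' end of its core on its strand. Transcripts wrap each element
with 100-400 nt random flanks, truncated at midpoints between neighbours
so each element lies in exactly one transcript.

What this emulates — and does not: the fixtures have the right anatomy,
element density and coordinate bookkeeping, but uniform background (real
genomes have skewed composition and other hairpin-forming elements),
perfectly clean labels, and no transcription-level noise in the site
positions. Passing tests therefore demonstrate the correctness of the
machinery and the qualitative behaviour of the method, not its accuracy on
curated *E. coli*/*B. subtilis* data.

## Classifiers

Two topologies share one head: convolution (30 filters, kernel 10, ReLU,
valid padding) -> max-pool (5) -> dropout 0.2 -> flatten -> dense 360
(ReLU) -> dense 30 (sigmoid) -> single sigmoid output; Adamax on binary
cross-entropy. The one-hot CNN consumes the L x 4 one-hot sequence matrix
with a 1-D convolution; the pairing-matrix CNN consumes the L x L
self-pairing potential matrix (G-C 1, A-U 0.66, G-U 0.33, otherwise 0,
symmetric, zero diagonal) with a 10 x 10 convolution and 5 x 5 pooling.
In the pairing matrix every potential stem appears as an anti-diagonal
stripe, which is what gives the 2-D network its structural prior. No
masking is applied near the diagonal; N encodes to zeros so genome scans
tolerate assembly gaps.

The networks are implemented in a small internal NumPy engine
(`termscan._nn`): im2col matmuls for the 1-D convolution, cache-blocked
jitted direct kernels for the single-channel 2-D convolution and pooling
(channels-first layout; roughly 7x faster than im2col at this input size
on one core), inverted dropout, Glorot-uniform initialisation, and Adamax
with step size 2e-3 (the rate recommended for Adamax in the optimizer's
original description; the learning rate is configurable). Unstated
training details are explicit, configurable defaults: batch size 32,
epoch cap 200, early-stopping patience 5. Training monitors test-set
accuracy, keeps the best-epoch weights, and stops after `patience` epochs
without improvement. All randomness (init, shuffling, dropout) flows from
explicit seeds; runs are bit-reproducible on a fixed BLAS configuration.

Two robustness details matter for such small networks. First, when test
accuracy saturates early, several epochs tie at the best value; early
stopping restores the *latest* weights among the tied epochs (the
most-trained equally-accurate model), while ties do not extend the
patience window. Second, fine-tuning occasionally dives into the
class-prior basin — constant output at the majority-class rate — when it
starts from a confidently-wrong state; `pretrain_finetune` detects this
(best test accuracy never clears the majority fraction) and restarts the
fine-tuning from the pre-trained weights with a derived seed, up to twice,
keeping the whole procedure deterministic for a fixed seed. Training from
random initialisation is also slow to leave that plateau when the batch
size is large (few optimizer steps per epoch) — the scaled runs below
therefore train with batch 32.

## Evaluation

Monte Carlo cross-validation: 10 independent 0.70/0.15/0.15
train/test/validation shuffles (the split fractions printed as percentages
in some descriptions are read as fractions; 70/15/15 is the only reading
consistent with the stated set sizes). Point metrics (precision, recall,
specificity, F1) use the 0.5 threshold; AUPRC is average precision.
Model variants are compared with a two-sided Wilcoxon rank-sum test:
exact enumeration of the rank-sum distribution for combined n <= 12
(two-sided p = twice the smaller tail, capped at 1), tie-corrected normal
approximation without continuity correction otherwise.

## In-silico mutagenesis

Section mutations replace floor(length/2) (at least 1) positions of one of
the seven sections (left pad, A-tail, 5' stem, loop, 3' stem, U-tail,
right pad) with different bases, 15 mutants per record; the relative
activation impact is 1 - x̄_S/x̄_0. The original-sequence mean x̄_0 is
computed once per record set (it needs no replication). Structure
mutations pick k stem pairs and rewrite both partners — retaining the
pairing (uniform over the canonical+wobble dinucleotides with both
positions changed; by enumeration at least 4 such options exist for every
original pair) or disrupting it (uniform over non-pairing dinucleotides,
both changed; at least 5 options) — and the pairing impact is
1 - x̄_d/x̄_r. For binary detectors the same formulas apply to detection
rates (fraction of sequences with >= 1 hit).

## Genome scan

Transcribed regions are elongated by 150 nt on each end (clamped at contig
boundaries), the sense strand is scanned with a 75-nt window at a 3-nt
step, and maximal runs of adjacent windows scoring above 0.5 fuse into
hits (a single sub-threshold window breaks a run — "neighbouring" means
consecutive step positions). A hit carries the union span, its central
nucleotide and the maximum window score. Against a termination-site list,
a hit is a true positive if its center lies within a distance threshold
(10, 15, 35, 50, 100, 150, 250 nt) of the nearest site and a false
positive otherwise; sites with no hit within the threshold are false
negatives. "True negatives" are undefined in this matching scheme.
Matching is not one-to-one: several hits may credit one site, and recall
counts distinct detected sites. The PR curve sweeps a secondary cutoff
over fused-hit scores; AUPRC is step-wise average precision. Because the
hit center sits on the hairpin, tens of nt upstream of the actual 3' end,
the 35-nt threshold is the natural operating point.

A base-rate caveat: a 50 kb scan evaluates on the order of 10^4 windows,
so even a classifier with 99.8% window-level specificity produces tens of
false hits at the fixed 0.5 call threshold. The matrix CNN *ranks* windows
nearly perfectly (scan AUPRC ~0.97 on the synthetic genome) but its
threshold calibration lets a small fraction of strong random hairpins
through — structures that genuinely exist in uniform background and lack
only the tails. The scan-recovery check therefore scans with the trained
one-hot CNN, whose sensitivity to tail composition suppresses exactly
those false hits (precision ~0.7 at recall 1.0 on the 50 kb fixture); on
real data a practitioner would raise the secondary score cutoff instead.

## Problem sizes for the scaled runs

The acceptance checks and `scripts/acceptance.py` run the whole method at
desk scale: 600 synthetic positives / 1800 uniform negatives at 75 nt
(the 1:3 class ratio of the curated data), a 300+300 inverse-folded
pre-training set built from 20 terminator structures, 10 Monte Carlo
replicates, batch 32 with an epoch cap of 12 and patience 3 (the synthetic
task converges in a few epochs), and a 50 kb genome with 20 implanted
elements for the scan. These sizes are the package's chosen scaled-down
analogues of the original full-data experiments.

## Known limitations

- The maximum-pairing folder ignores stacking energies and loop penalties;
  inverse-folded positives are exact only under this model. The ViennaRNA
  backend provides thermodynamic inverse folding where realism matters.
- The synthetic task is much easier than curated data; absolute metric
  values on it say nothing about performance on real genomes. In
  particular, both topologies saturate near AUPRC 1 on it (the U-rich tail
  alone is almost fully diagnostic at this sample size), so per-replicate
  comparisons between model variants sit within the splitting noise —
  pre-training's decisive advantage belongs to the data-scarce regime of
  real curated sets, which this generator does not emulate.
- The divergence-restart check in `pretrain_finetune` is accuracy-based
  and can accept a run that classifies well at the 0.5 threshold but
  ranks poorly (low AUPRC); rare residual semi-collapsed replicates are
  possible.
- The pairing-matrix encoding weights unordered pairs; the anti-transpose
  symmetry under reverse complement is exact only up to wobble pairs
  (complementation maps G-U onto non-pairing C-A).
- Minus-strand elements are supported throughout but off by default in the
  genome generator.
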