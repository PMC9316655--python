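# Methods

## Pipeline overview

`specfid` annotates metabolites from MS/MS spectra in three phases.
*Spectral processing* turns a library spectrum into a fixed-length
vector: intensities are max-scaled into [0, 100]; peaks above the
precursor m/z are removed; spectra with fewer than `min_peaks` (5) peaks
above `min_rel_intensity` (2%) of the base peak, from disallowed
instrument types, or with neutral mass outside [`mass_min`, `mass_max`]
= [100, 1010] Da are rejected; spectra of the same compound (full
InChIKey) are merged for training; and peak intensities are accumulated
over `bin_count` (1174) unit-width integer m/z bins.  *Training* fits a
multi-label model mapping the binned vector to the 528-bit composite
fingerprint MACCS(166) ‖ FP3(55) ‖ FP4(307).  *Annotation* retrieves
candidates from a local compound table whose monoisotopic mass lies
within `ppm_tolerance` (20 ppm) of the neutral mass implied by the
precursor under some mode-compatible adduct, optionally keeps only
candidates with the query's molecular formula, and ranks them by
Tanimoto similarity TP/(TP+FP+FN) between the predicted fingerprint and
each candidate's computed fingerprint.  Both-zero positions drop out of
that score by construction, which matters because set bits are rare.

## Preprocessing conventions

- *Scaling* is max-normalization with an implicit minimum of zero
  (x ↦ 100·x/max).  A literal (x−min)/(max−min) rescale would zero the
  weakest real peak and interact destructively with the relative-
  intensity filter.
- *Relative intensity* for the 2% rule is measured against the base peak
  **after** super-precursor peaks are removed, so a spurious high-mass
  peak cannot mask genuine ones.  The alternative reference (total ion
  current) was rejected as it makes the rule depend on peak count.
- *Bin assignment* is floor(m/z) into half-open bins [b, b+1), b =
  `bin_start` … `bin_start`+`bin_count`−1, defaults [1, 1175) giving
  exactly 1174 bins.  Binning conserves total in-range intensity.
- *Mass window* applies to the neutral monoisotopic mass derived from
  the precursor m/z and the adduct's mass shift, falling back to the
  recorded exact mass when the adduct is unknown.
- *Merging* pools member peak lists (each already scaled), accumulates
  peaks landing in the same integer bin (representative m/z =
  intensity-weighted mean), and rescales to 100.  The merged precursor
  is averaged over the most frequent adduct group.  Evaluation always
  skips merging so the model is judged on individual spectra.
- *Zero-bin removal* (columns identically zero across the training
  matrix) applies only to the flat baselines; the convolutional model
  needs consecutive bins and always consumes the full vector.

## Fingerprints

MACCS keys come from RDKit, whose 167-slot output has an unused bit 0
that is dropped, giving the canonical 166.  FP3 and FP4 are SMARTS
pattern sets computed by the OpenBabel CLI; its hex dump packs bits into
32-bit words printed most-significant-word first, LSB-first within a
word, and words beyond the pattern counts (55/307) are truncated —
short output would be zero-padded.  Structures are canonicalized through
RDKit before both backends so they see identical molecules; InChI input
is converted to SMILES.  Segment lengths are enforced regardless of
backend, so the composite is always exactly 528 bits.

Degenerate similarity inputs (both vectors all-zero) score 0.0 rather
than raising, so batch ranking never aborts; F1 likewise maps degenerate
denominators to 0.

## The convolutional predictor

The network is: embedding(vocab 101 → 32 dims) → Conv1D(32 filters,
kernel 5, ReLU) → MaxPool(2) → Conv1D(64, kernel 5, ReLU) → MaxPool(2) →
Dropout(0.5) → Flatten → four dense ReLU layers (1024/512/512/528) → 528
sigmoid outputs; loss is binary cross-entropy averaged over all outputs,
optimizer Adam, metric binary accuracy.  All 528 bits are predicted
simultaneously; bit i is set when its probability reaches the threshold
(default 0.5, `>=` at the boundary).

The embedding front-end requires integer tokens, so scaled intensities
are rounded to the 101-symbol vocabulary 0..100 (`quantize_for_embedding`).
How continuous intensities should enter an embedding layer is genuinely
open; the alternative reading — no embedding, raw intensities as a
single channel scaled to [0, 1] — is kept behind
`CnnConfig.use_embedding = False` rather than silently chosen.
"Four hidden layers" is read as four dense layers *before* the sigmoid
output; counting the output among them would leave three.

The engine is plain numpy (no deep-learning framework dependency):
im2col convolution, argmax-routed pooling gradients, inverted dropout,
and Adam, with every random draw (init, shuffling, dropout masks) from
one seeded generator — a fixed seed reproduces initial weights and
training logs bit-for-bit, and gradient correctness is pinned by a
finite-difference test.  Two numerical choices matter on sparse
multi-label targets, where the all-zeros solution is a strong attractor:
ReLU layers use He-normal initialization (Glorot under-scales stacked
ReLU activations) and embeddings use N(0, 0.3) (an init much smaller
than unit scale lets the signal vanish through the conv/pool/dense chain
and training stalls at constant-prevalence outputs).  Training aborts
with a diagnostic if the loss goes non-finite.

Unstated hyperparameters (filter counts, kernel widths, pool sizes,
dense widths, epochs, batch size, learning rate) live in `CnnConfig`
with the defaults above; nothing is hard-coded.

## Baselines and strategies

LR and SVM are per-bit one-vs-rest classifiers (logistic regression;
linear SVM — linear for tractability at 528 outputs, kernel
configurable), with bits constant in training predicted as that
constant.  SLP is a single dense sigmoid layer trained with BCE/Adam on
the same engine; MLP is a dense multilabel network (scikit-learn).  All
consume the zero-bin-reduced matrix.

Instrument context is (energy, resolution, mode): energy splits strictly
at 30 eV (< 30 low, ≥ 30 high; records without parseable energy default
to low, flagged); Orbitrap and Q-TOF are high resolution, ion trap and
QqQ low (unknown types default to high, flagged); ionization mode must
be present.  Three deployment strategies: one model on plain bins; one
model on bins + the three binary context entries (order: energy,
resolution, mode); eight models, one per context cell, routed at
prediction time.  A cell with fewer than `min_cell_compounds` distinct
compound skeletons is skipped with a warning, and prediction for an
empty cell falls back to the populated cell matching mode first, then
resolution, then energy — mode changes spectra most, energy least.

## Annotation and evaluation

The default adduct set is [M+H]+, [M+Na]+, [M+NH4]+ (positive) and
[M−H]−, [M+Cl]− (negative), with standard mass shifts; fully
user-extensible.  Retrieval runs against a local TSV/CSV table (id,
inchikey, smiles, formula, monoisotopic_mass, optional cached
fingerprint) so annotation works offline.  Formula comparison is
element-multiset equality, not string equality.  Ranking ties break
deterministically: smaller ppm mass error, then lexicographic InChIKey.
Top-k hits match at the InChIKey first-block (2-D skeleton) level,
consistent with structure-disjoint evaluation; full-key matching is a
flag.

Splits operate on InChIKey first blocks: shuffled blocks are assigned
greedily (split) or dealt round-robin (k-fold) so no skeleton spans
sides; the same-skeleton constraint is the stricter reading of fold
construction and is the default, with naive folding available.  F1 and
Tanimoto are averaged per spectrum (per-compound aggregation by flag).
Top-k accuracy is reported under two denominators: all queries, and only
queries whose candidate list contains the truth — a compound missing
from the database can never be ranked, whatever the predictor does.

`ReferenceCorpus` records the accounting of the public training resource
this pipeline is designed around (per-library LC-MS/MS spectrum counts
by ionization mode for the MoNA repository and the NIST 20 library, and
the ~80/20 structure-disjoint compound split); its derived totals are
checked for internal consistency in the test suite.

## Synthetic corpora and the desk-scale benchmark

Real training resources are large and partly proprietary, so the test
bed is a *planted code*: each fingerprint bit excites one or more m/z
bins (assignment dealt round-robin from a shuffled bin pool, so several
bits may share a bin — many-to-few — but no bin is oversubscribed by
sampling accident), and a compound's spectrum is the union of bins
excited by its set bits.  Generator defaults: base intensity 100,
additive Gaussian intensity noise σ = 5, bin dropout probability 0.1,
per-bit fingerprint prevalence 0.1, precursor measurement error σ = 1.5
mDa.  Noiseless, dropout-free generation followed by preprocessing
reconstructs each fingerprint's support exactly; that identity anchors
the pipeline tests.

The standard benchmark (`make_benchmark`) uses 300 compounds × 5 spectra
(~1,200 train / ~300 structure-disjoint test after the 80/20 split), all
eight context cells populated uniformly.  Two deliberate design choices:

- compound masses are drawn from ~30 tight clusters (±2 mDa), so
  mass-window retrieval returns crowded candidate lists (mean ≈ 11)
  and ranking is actually exercised — with uniform masses nearly every
  list has length 1 and top-1 accuracy is vacuous;
- masses start at 500 Da while mapping bins lie in [50, 490], so no
  planted peak is ever lost to the super-precursor filter.

What the generator does *not* emulate: real fragmentation chemistry
(neutral losses, bond-breaking rules), isotope envelopes, correlated
noise, instrument-specific peak shapes, or any dependence of the
spectrum on the context cell beyond metadata.  Passing tests therefore
demonstrate that the machinery — preprocessing, learning, retrieval,
ranking, bookkeeping — is correct and that the network can extract a
planted spectrum–fingerprint relationship at small sample size; they do
not certify annotation accuracy on real spectra, which depends on data
scale and on how well real fragmentation encodes substructures.

Desk-scale training (`experiment.DESK_CNN`) shrinks the network to
16/32 filters and a 256/128/128/528 dense head, 25 epochs, batch 16,
learning rate 3e-3 — sized so the full benchmark experiment (corpus
generation, training, annotation, scoring) completes in minutes on one
CPU.  At ~240 training compounds the network generalizes only partially
to unseen skeletons (training-set Tanimoto approaches 1 while test-set
Tanimoto stays modest): with few distinct compounds, memorization
competes with rule learning.  The acceptance gates are therefore
relative — the trained network must beat the all-zeros and
per-bit-prevalence predictors on test Tanimoto, and mass-based top-1
ranking must beat the 1/|candidate-list| random-choice expectation —
not absolute accuracy targets, which at this scale would measure corpus
size rather than correctness.

## Known limitations

- FP3/FP4 depend on the external `obabel` executable; without it only
  the MACCS segment could be computed, and fingerprint computation
  raises instead of silently degrading.
- The collision-energy parser intentionally refuses normalized collision
  energy (NCE %) values; converting them to eV needs instrument
  calibration curves that metadata does not carry.
- Candidate retrieval assumes singly charged adducts.
- No mzML/mzXML raw-data input; spectra enter as MSP/MGF peak lists.
- k-fold cross-validation retrains one model per fold; at full network
  size that is expensive on CPU.
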