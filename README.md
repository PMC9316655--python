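# specfid

Molecular fingerprint prediction from tandem mass spectra, and
Tanimoto-ranked metabolite annotation.

## The problem

Untargeted LC-MS/MS metabolomics produces fragment spectra for thousands
of features, but spectral libraries cover only a fraction of known
metabolites, so direct spectral matching leaves most features
unannotated.  An alternative is to learn the relationship between a
spectrum and the *molecular fingerprint* of the compound that produced
it: a binary vector marking the presence of substructures and chemical
properties.  A predicted fingerprint can then rank candidate compounds
retrieved from a database by precursor mass or molecular formula, even
when the true compound's reference spectrum was never acquired.

`specfid` implements that pipeline end to end, for researchers building
or evaluating annotation workflows:

1. **Spectral I/O** — MSP (NIST dialect) and MGF readers/writers with a
   synonym table for the 16 metadata fields found in public libraries,
   and a collision-energy parser that copes with vendor formats.
2. **Preprocessing** — max-scaling of intensities into [0, 100], removal
   of peaks above the precursor m/z, rejection of spectra with fewer
   than 5 peaks above 2% relative intensity or with neutral mass outside
   [100, 1010] Da, per-compound merging keyed by InChIKey, and binning
   into 1174 unit-width integer m/z bins.
3. **Fingerprints** — the 528-bit composite MACCS(166) ‖ FP3(55) ‖
   FP4(307), computed with RDKit (MACCS) and OpenBabel (FP3/FP4).
4. **Models** — a 12-layer 1-D convolutional multi-label network
   (embedding, two convolution/max-pooling stages, dropout, flatten,
   four ReLU dense layers, 528 sigmoid outputs; binary cross-entropy,
   Adam), implemented in numpy with seeded determinism, plus LR / SLP /
   SVM / MLP baselines; three deployment strategies (single model,
   single model + 3 context inputs, eight models routed by
   collision-energy regime, resolution, and ionization mode).
5. **Annotation** — candidate retrieval from a local compound table
   within a ppm window over configurable adducts, optional formula
   filtering, and Tanimoto ranking

   Tanimoto = TP / (TP + FP + FN),

   which ignores positions where both fingerprints are zero.
6. **Evaluation** — structure-disjoint splits at the InChIKey
   first-block level, k-fold cross-validation, mean F1/Tanimoto of
   fingerprint prediction, and top-k ranking accuracy under two
   denominators (all queries vs. queries whose candidate list contains
   the truth).
7. **Synthetic corpora** — a planted fingerprint→spectrum code that
   makes the whole loop testable offline at desk scale.

## Worked example

```sh
python examples/03_annotate_spectrum.py
```

```
2 candidate(s) within 20 ppm of m/z 181.0707:
  glucose   via ['[M+H]+'] (0.1 ppm)
  fructose  via ['[M+H]+'] (0.1 ppm)
Tanimoto ranking:
  1. glucose   score 1.000
  2. fructose  score 0.909
top-1 hit for glucose: True
```

The query precursor (181.0707, positive mode) implies a neutral mass of
180.0634 Da under [M+H]+; both hexoses match within 20 ppm, caffeine
(194.08 Da) does not.  The predicted fingerprint — here glucose's own
computed fingerprint, standing in for a model output — scores 1.0
against glucose and 0.909 against its isomer, so the correct compound
ranks first even though mass alone cannot separate the two.

The other examples show parsing/binning (`01`), fingerprint computation
and similarity (`02`), and a miniature train-and-evaluate experiment
(`04`).  The same pipeline is scriptable from the shell:

```sh
specfid synth --out corpus --n-compounds 60 --seed 7
specfid train --spectra corpus/train.msp --db corpus/compounds.tsv --out model --seed 7
specfid annotate --spectra corpus/test.msp --db corpus/compounds.tsv --model model --out ranked
specfid evaluate --out run --seed 7        # end-to-end miniature experiment
```

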