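# Methods

## Problem and model

The package decides, from sequence alone, whether an RNA transcript is
a long non-coding RNA (lncRNA) or an mRNA. The discriminating signal
comes from three places. First, coding transcripts carry a long open
reading frame with biased codon and 6-mer usage; because the annotated
CDS of many mRNAs differs from their longest conventional ORF, four ORF
types are located per transcript (T0 conventional ATG→stop; T1 ATG to
transcript end with no downstream in-frame stop; T2 any stop-terminated
codon run; T3 the longer of T1/T2), and length, coverage, hexamer, and
relative-codon-bias statistics are extracted from each. Second, mRNAs
and lncRNAs fold differently: from a dot-bracket secondary structure
the package derives the paired ratio, the GC content of paired bases, a
loop decomposition, and SASS k-mer scores that couple each window of
sequence with the structure characters underneath it. Third, the
peptides encoded by the max ORFs differ physicochemically between the
two classes (isoelectric point, molecular weight, GRAVY, aromaticity,
instability index).

These 57 features (21 sequence + 16 structure + 20 protein) feed a
binary XGBoost classifier; the deployed default is a 28-feature subset
(14 + 6 + 8). lncRNA is the positive class throughout, and the
prediction threshold is 0.5 with ties assigned to lncRNA, since the
positive class is what the tool exists to find.

## Conventions and parameter choices

* **Alphabet.** All sequences are normalized to uppercase DNA (U→T) at
  input; SASS tokens therefore use T internally even though structure
  tools print U. Transcripts shorter than 200 nt or longer than
  20,000 nt, or containing symbols outside A/C/G/T, are filtered with
  reason codes; both length bounds are inclusive (so 200 and 20,000 are
  kept — a deliberate reading of "shorter than 200 / longer than
  20,000").
* **ORFs.** Start codon set {ATG}; stop set {TAA, TAG, TGA}; the stop
  codon is counted inside the ORF length (an exposed convention —
  `orf.py` documents it so the alternative can be tested). Only forward
  frames are scanned, as assembled transcripts are stranded. T1 is read
  as "no in-frame stop downstream of the ATG" (the trailing codon
  segment), not "ignore interior stops"; with that reading T1/T3
  translations are guaranteed stop-free. Absent ORFs contribute zeros
  to every derived feature so vectors stay total.
* **Hexamer table.** Coding counts scan each training CDS with window
  6, step 3 (codon-aligned); non-coding counts scan each lncRNA with
  step 1. The transcript-level score scans each of the three frames at
  step 3 (mirroring the codon-aligned counting rule) and takes the
  frame maximum; ORF scores use the ORF's own frame only. Zero-count
  keys contribute bounded log-ratios: 0 if both classes are zero, −1 if
  only the coding probability is zero, +1 if only the non-coding one
  is. Natural logarithms throughout.
* **Relative codon bias.** The outer exponent is 1/L with L the ORF
  length in codons (the product runs over codons, so this is the
  geometric mean of the per-codon (1+d) factors). Computed in log space
  for numerical stability; an observed codon implies nonzero positional
  frequencies, so the ratio is always defined.
* **Fickett score.** Position values are the max/(min+1) codon-phase
  asymmetry per base over the whole transcript; content values are base
  fractions; both map through the 1982 lookup tables embedded in
  `_fickett_data.py` (with source citation) and combine as Σ p·w.
* **Loops.** A pair enclosing no helix closes a hairpin; one enclosing
  a single helix closes an interior loop (unpaired on both sides), a
  bulge (one side), or a stack (neither side — not counted, since the
  feature set defines no stacking count); two or more enclosed helices
  close a multibranch loop. The exterior region is not a loop. Loop
  coverages divide counts by transcript length.
* **Protein features.** Computed by Biopython ProtParam, whose pKa,
  average-mass, Kyte-Doolittle, and DIWV tables are the standard
  published constants for these statistics. Degenerate peptides (empty;
  length 1 for the instability index) score 0. The GC content of a
  structure with zero paired bases is likewise defined as 0.
* **Preprocessing.** z-scores use the population standard deviation
  (divide by n), applied to held-out data with training statistics
  only; a constant training column maps to 0. SMOTE is implemented
  in-package following the canonical procedure (k = 5 minority
  neighbors by default, reduced with a warning when the minority class
  is tiny); synthetic rows are x + u·(x_nn − x), u ~ U[0,1], and
  original rows are never modified.
* **Feature selection and tuning.** RFECV drops one lowest-gain-
  importance feature per round, recording mean stratified k-fold CV
  accuracy per subset size, and keeps the peak (ties → smaller subset).
  Hyperparameters come from a small documented grid (trees {100, 300,
  500} × depth {4, 6, 8} × learning rate {0.05, 0.1, 0.3}); fixture-
  scale runs use a reduced grid ({200} × {4, 6} × {0.1}) and 5-fold CV,
  a problem-size choice recorded in `model.SMALL_GRID`. Stratified,
  seeded CV splits make every run reproducible; the classifier runs
  single-threaded with a fixed seed, so retraining is bit-reproducible.
* **Model bundle.** A directory of versioned text artifacts: manifest
  (schema subset, feature list, scaler statistics, structure mode),
  hexamer and SASS probability tables as TSV, and the serialized
  booster JSON. Prediction needs nothing else.

## Synthetic data generator

`fixtures.generate_dataset` emulates the two classes at the level this
classifier sees them. mRNA-like records embed an ATG→stop ORF covering
at least half the transcript (uniform fraction in [0.5, 0.8]), with
body codons drawn from a dataset-specific skewed codon distribution — a
Dirichlet(0.3) draw over the 61 sense codons, exponentially tilted so
its expected GC matches the class target — flanked by i.i.d. UTRs; CDS
coordinates are recorded for hexamer training. lncRNA-like records are
i.i.d. base draws, with a stop codon substituted into any frame's
stop-free run longer than 30 codons so spurious ORFs stay short.
Defaults: 2000 transcripts per class, lengths uniform on 200–600 nt,
GC targets 0.52 (mRNA) and 0.42 (lncRNA) — composition contrasts in
the range reported for mammalian transcript classes. Everything derives
from one seeded generator, so output is byte-reproducible.

Structures come from the package's deterministic maximum-base-pairing
folder (Nussinov-style dynamic program; canonical pairs AT/GC/GT,
minimum hairpin gap 3, pairing-preferring leftmost traceback), applied
in consecutive 120-nt windows — RNA pairing is predominantly local, and
windowing keeps folding linear in transcript length. The reported
pseudo-MFE is minus the pair count and is explicitly not a
thermodynamic free energy; bundles record which structure source they
were trained on.

What fixture results show: that the implementation recovers a known
generative separation end to end (held-out accuracy and AUC near 1 at
the default study size), that each scorer matches independent oracles,
and that the pipeline is deterministic. What they do not show:
performance on real transcriptomes. Real lncRNAs share UTR-like
composition, splice structure, repeats, and RNAfold-quality structures
with mRNAs, none of which the generator models; benchmark-grade
accuracy claims require training on real GENCODE/RefSeq corpora with
RNAfold structures.

## Problem sizes used by the test suite and acceptance script

Unit tests run on 60+60 and 500+500 record datasets; the end-to-end
signal-recovery check and `scripts/acceptance.py` use the full default
study (2000+2000, stratified 75/25 split, 5-fold CV over the reduced
grid). Oracle-equivalence suites use 500 random sequences/structures
per comparison.

## Known limitations

* The 57-feature full schema is a reconstruction assembled in
  `schema.py`; it is isolated there so the composition can be revised
  in one place without touching extraction code.
* The fallback folder maximizes pair count, not free energy; MFE-based
  features are only meaningful when structures come from RNAfold
  output, and windowed folding truncates long-range pairs.
* Pseudoknots are not representable in dot-bracket input and are
  rejected by the parser.
* Only single-label binary classification is supported; no calibration
  of the predicted probabilities is attempted.
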