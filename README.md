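# lncid

Alignment-free classification of long non-coding RNAs (lncRNAs) versus
protein-coding mRNAs from transcript sequence alone. The package is
aimed at transcriptomics workflows (bulk or single-cell RNA-Seq
assembly pipelines) that produce novel transcript models and need to
call coding potential without cross-species alignment.

## What it computes

For each transcript the library extracts three feature blocks:

* **Sequence-intrinsic features (21).** GC content; the Fickett
  testcode statistic; four open-reading-frame types — T0 (conventional
  ATG→stop), T1 (ATG to transcript end, no downstream in-frame stop),
  T2 (any non-stop codon run ending in a stop), T3 (longer of T1/T2) —
  with max lengths `L_orf` and coverages `L_orf / L_t`; average T0 ORF
  length and coverage; hexamer usage scores, the mean log-likelihood
  ratio `(1/m) Σ log(P(X)_coding / P(X)_noncoding)` over 6-mers
  (frame-maximized for the transcript, single-frame for each ORF); and
  the relative codon bias `RCB = (Π (1 + d_xyz))^(1/L_codon) − 1` of
  each max ORF.
* **Secondary-structure features (16).** From an RNAfold-style
  dot-bracket string: MFE, paired ratio, hairpin/interior/bulge/
  multibranch loop counts and coverages, GC content of paired bases,
  and five SASS k-mer scores — tokens joining k sequence characters
  with the k aligned structure characters (`"GG" + ".(" → "GG.("`),
  scored as mean mRNA/lncRNA log-likelihood ratios for k = 1..5.
* **Protein features (20).** Isoelectric point, molecular weight,
  GRAVY, aromaticity, and instability index of the peptides translated
  from the four max ORFs (via Biopython ProtParam).

A gradient-boosted tree classifier (XGBoost) is trained on z-scored
features after SMOTE class balancing, with optional recursive feature
elimination; the shipped default schema is a 28-feature subset
(14 sequence + 6 structure + 8 protein features). lncRNA is the
positive class; predictions report `P(lncRNA)` with a 0.5 threshold.

## Worked example

Train and evaluate on a generated synthetic dataset — no downloads
needed (real structures would come from RNAfold output via
`--structures`):

```bash
lncid fixtures --out fx --n-mrna 500 --n-lncrna 500 --seed 7
lncid train   --input fx/transcripts.fa --labels fx/labels.tsv \
              --structures fx/structures.tsv --mode rnafold-file \
              --schema top28 --seed 7 --folds 5 --quick --out fx/bundle
lncid predict --input fx/transcripts.fa --bundle fx/bundle \
              --structures fx/structures.tsv --mode rnafold-file \
              --out fx/predictions.tsv
lncid evaluate --predictions fx/predictions.tsv --labels fx/labels.tsv \
              --out fx/metrics.tsv
```

The final command logs a summary like

```
... INFO accuracy 1.0000, MCC 1.0000, AUC 1.0000
```

(training-set evaluation of an easily separable synthetic dataset —
see `docs/methods.md` for what fixture results do and do not show),
and `fx/predictions.tsv` holds one row per transcript:

```
id          length  predicted_label  lncRNA_probability
mrna_00000  255     mRNA             0.001960
...
lnc_00000   406     lncRNA           0.998040
```

The same pipeline is available as library calls
(`lncid.train_pipeline`, `lncid.predict`, `lncid.compute_metrics`).

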