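"""Fickett (1982) lookup tables for the coding-potential testcode statistic.

Breakpoints, probabilities, and weights are taken from Fickett,
"Recognition of protein coding regions in DNA sequences", Nucleic Acids
Research 10(17), 1982 (Tables 1-2), in the form propagated by the CPAT
coding-potential tool. For each base there is a position table (indexed
by the max/min+1 codon-phase asymmetry value) and a content table
(indexed by the base fraction); each maps to the probability that a
sequence with that value is coding, and carries a weight reflecting the
discriminative power of that component.
"""

# Position parameter: thresholds scanned in order; the first threshold
# less than or equal to the observed value selects the probability.
POSITION_BREAKPOINTS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

POSITION_PROB = {
    "A": (0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36),
    "C": (0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38),
    "G": (0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.66, 0.63, 0.48, 0.48),
    "T": (0.51, 0.60, 0.69, 0.64, 0.62, 0.67, 0.58, 0.48, 0.39, 0.24),
}

POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

CONTENT_BREAKPOINTS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)

CONTENT_PROB = {
    "A": (0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19),
    "C": (0.50, 0.63, 0.59, 0.50, 0.46, 0.45, 0.47, 0.56, 0.59, 0.33),
    "G": (0.21, 0.40, 0.47, 0.50, 0.52, 0.56, 0.57, 0.52, 0.44, 0.23),
    "T": (0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.52, 0.57, 0.60, 0.51),
}

CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
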