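"""Canonical feature schema: names, ordering, and named subsets.

The full schema holds 57 features in three blocks:

* 21 sequence-intrinsic features (SIFs): GC content, Fickett score, the
  four max ORF lengths and coverages, average T0 ORF length and
  coverage, the frame-maximized transcript hexamer score, the four ORF
  hexamer scores, and the four relative codon bias values;
* 16 secondary-structure features (SSFs): MFE, paired ratio, the four
  loop counts and coverages, GC content of paired nucleotides, and the
  five SASS k-mer scores;
* 20 protein features (PFs): isoelectric point, molecular weight,
  GRAVY, aromaticity, and instability index for each of the four
  translated max ORFs.

TOP_28 is the default deployed subset (14 SIFs + 6 SSFs + 8 PFs);
NO_SSF_22 is TOP_28 with its six SSFs removed, for running without
secondary structures. The exact identity of the 57 full-schema features
is a reconstruction and deliberately isolated here so it can be revised
in one place.
"""

from __future__ import annotations

SIF_FEATURES: tuple[str, ...] = (
    "gc_content",
    "fickett_score",
    "orf_t0_length", "orf_t1_length", "orf_t2_length", "orf_t3_length",
    "orf_t0_coverage", "orf_t1_coverage", "orf_t2_coverage", "orf_t3_coverage",
    "orf_avg_length", "orf_avg_coverage",
    "hexamer_score",
    "hexamer_score_orf_t0", "hexamer_score_orf_t1",
    "hexamer_score_orf_t2", "hexamer_score_orf_t3",
    "rcb_t0", "rcb_t1", "rcb_t2", "rcb_t3",
)

SSF_FEATURES: tuple[str, ...] = (
    "mfe",
    "paired_ratio",
    "loop_hairpin_count", "loop_interior_count", "loop_bulge_count", "loop_multi_count",
    "loop_hairpin_coverage", "loop_interior_coverage",
    "loop_bulge_coverage", "loop_multi_coverage",
    "gc_content_paired",
    "sass_k1_score", "sass_k2_score", "sass_k3_score", "sass_k4_score", "sass_k5_score",
)

PF_FEATURES: tuple[str, ...] = tuple(
    f"orf_{t}_{kind}"
    for t in ("t0", "t1", "t2", "t3")
    for kind in ("pi", "mw", "gravy", "aromaticity", "instability")
)

FULL_57: tuple[str, ...] = SIF_FEATURES + SSF_FEATURES + PF_FEATURES

#: The deployed default subset: 14 SIFs + 6 SSFs + 8 PFs.
TOP_28: tuple[str, ...] = (
    # SIFs (14)
    "gc_content",
    "fickett_score",
    "orf_t0_length", "orf_t1_length", "orf_t2_length",
    "orf_t0_coverage", "orf_t1_coverage", "orf_t3_coverage",
    "hexamer_score_orf_t0", "hexamer_score_orf_t1",
    "hexamer_score_orf_t2", "hexamer_score_orf_t3",
    "rcb_t0", "rcb_t1",
    # SSFs (6)
    "sass_k1_score", "sass_k2_score", "sass_k3_score",
    "sass_k4_score", "sass_k5_score",
    "gc_content_paired",
    # PFs (8)
    "orf_t0_pi", "orf_t0_mw", "orf_t0_aromaticity", "orf_t0_instability",
    "orf_t1_mw", "orf_t1_instability",
    "orf_t2_mw", "orf_t3_mw",
)

#: TOP_28 minus its SSFs, for structure-free operation.
NO_SSF_22: tuple[str, ...] = tuple(f for f in TOP_28 if f not in SSF_FEATURES)

SUBSETS: dict[str, tuple[str, ...]] = {
    "full57": FULL_57,
    "top28": TOP_28,
    "no-ssf22": NO_SSF_22,
}

assert len(FULL_57) == 57
assert len(TOP_28) == 28
assert len(NO_SSF_22) == 22


def subset_features(name: str) -> tuple[str, ...]:
    try:
        return SUBSETS[name]
    except KeyError:
        raise ValueError(f"unknown schema subset {name!r}; "
                         f"choose from {sorted(SUBSETS)}") from None


def ssf_columns(names) -> list[str]:
    """The SSF members of an ordered feature list."""
    ssf = set(SSF_FEATURES)
    return [n for n in names if n in ssf]
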