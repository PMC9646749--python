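"""Sequence-intrinsic features: GC content, Fickett score, relative codon
bias, and class-conditional hexamer tables/scores.

The hexamer table stores, for every 6-mer over {A,C,G,T}, its probability
in coding sequence (CDS of training mRNAs, scanned codon-wise with step
3) and in non-coding sequence (training lncRNAs, scanned with step 1).
A transcript's hexamer score is the mean natural-log likelihood ratio
coding/non-coding over its hexamers, maximized over the three reading
frames; ORF hexamer scores use the ORF's own single frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _fickett_data as _fd
from .orf import ORF_TYPES, OrfSet

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

HEXAMER_TABLE_SIZE = 4 ** 6  # 4096 dense keys


def gc_content(sequence: str) -> float:
    """Fraction of G and C bases in the sequence."""
    if not sequence:
        raise ValueError("empty sequence")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


def _lookup(value: float, breakpoints, probs) -> float:
    for threshold, p in zip(breakpoints, probs):
        if value >= threshold:
            return p
    return probs[-1]


def fickett_position_value(sequence: str, base: str) -> float:
    """max/(min+1) asymmetry of a base's counts over the three codon phases."""
    counts = [0, 0, 0]
    for i, ch in enumerate(sequence):
        if ch == base:
            counts[i % 3] += 1
    return max(counts) / (min(counts) + 1)


def fickett_score(sequence: str) -> float:
    """Fickett testcode statistic over the whole transcript.

    Four position values (codon-phase asymmetry per base) and four
    content values (base fractions) are each mapped through the embedded
    1982 lookup tables to coding probabilities, then combined as a
    weighted sum.
    """
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    score = 0.0
    length = len(sequence)
    for base in _BASES:
        pos_value = fickett_position_value(sequence, base)
        score += _lookup(pos_value, _fd.POSITION_BREAKPOINTS,
                         _fd.POSITION_PROB[base]) * _fd.POSITION_WEIGHT[base]
        content = sequence.count(base) / length
        score += _lookup(content, _fd.CONTENT_BREAKPOINTS,
                         _fd.CONTENT_PROB[base]) * _fd.CONTENT_WEIGHT[base]
    return score


def relative_codon_bias(orf_sequence: str) -> float:
    """Relative codon bias of an ORF.

    For each codon (x, y, z) the deviation d = (f(x,y,z) - f1 f2 f3) /
    (f1 f2 f3) measures how far the codon's frequency departs from the
    product of the positional base frequencies within the same ORF. The
    statistic is the geometric mean of (1 + d) over all codons, minus 1;
    it is 0 whenever codon usage factorizes over positions. Empty input
    (absent ORF) returns 0.
    """
    if not orf_sequence:
        return 0.0
    if len(orf_sequence) % 3 != 0 or len(orf_sequence) < 3:
        raise ValueError("ORF length must be a positive multiple of 3")
    n_codons = len(orf_sequence) // 3
    codon_counts: dict[str, int] = {}
    pos_counts = [dict.fromkeys(_BASES, 0) for _ in range(3)]
    for i in range(0, len(orf_sequence), 3):
        codon = orf_sequence[i:i + 3]
        codon_counts[codon] = codon_counts.get(codon, 0) + 1
        for k in range(3):
            pos_counts[k][codon[k]] += 1
    log_sum = 0.0
    for codon, count in codon_counts.items():
        f_obs = count / n_codons
        f_exp = (pos_counts[0][codon[0]] * pos_counts[1][codon[1]]
                 * pos_counts[2][codon[2]]) / n_codons ** 3
        # observed codon implies every positional frequency is nonzero
        log_sum += count * math.log(f_obs / f_exp)
    return math.exp(log_sum / n_codons) - 1.0


def encode_hexamer(hexamer: str) -> int:
    idx = 0
    for ch in hexamer:
        idx = idx * 4 + _BASE_INDEX[ch]
    return idx


def decode_hexamer(index: int) -> str:
    chars = []
    for _ in range(6):
        chars.append(_BASES[index % 4])
        index //= 4
    return "".join(reversed(chars))


def _log_likelihood_ratios(p_coding: np.ndarray, p_noncoding: np.ndarray) -> np.ndarray:
    """Per-key log(p_coding/p_noncoding) with bounded zero-count handling.

    Both probabilities zero -> 0; only coding zero -> -1; only
    non-coding zero -> +1.
    """
    llr = np.zeros(len(p_coding))
    both = (p_coding > 0) & (p_noncoding > 0)
    llr[both] = np.log(p_coding[both] / p_noncoding[both])
    llr[(p_coding == 0) & (p_noncoding > 0)] = -1.0
    llr[(p_coding > 0) & (p_noncoding == 0)] = 1.0
    return llr


@dataclass
class HexamerTable:
    """Dense class-conditional 6-mer probability table (4096 keys)."""

    p_coding: np.ndarray
    p_noncoding: np.ndarray
    n_coding_seqs: int = 0
    n_noncoding_seqs: int = 0

    def __post_init__(self) -> None:
        if len(self.p_coding) != HEXAMER_TABLE_SIZE or len(self.p_noncoding) != HEXAMER_TABLE_SIZE:
            raise ValueError("hexamer table must have 4096 entries per class")
        self._llr = _log_likelihood_ratios(np.asarray(self.p_coding, dtype=float),
                                           np.asarray(self.p_noncoding, dtype=float))

    def log_ratio(self, hexamer: str) -> float:
        return float(self._llr[encode_hexamer(hexamer)])

    def swapped(self) -> "HexamerTable":
        return HexamerTable(self.p_noncoding.copy(), self.p_coding.copy(),
                            self.n_noncoding_seqs, self.n_coding_seqs)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hexamer\tp_coding\tp_noncoding\n")
            for i in range(HEXAMER_TABLE_SIZE):
                fh.write(f"{decode_hexamer(i)}\t{self.p_coding[i]:.12g}"
                         f"\t{self.p_noncoding[i]:.12g}\n")

    @classmethod
    def from_tsv(cls, path) -> "HexamerTable":
        p_c = np.zeros(HEXAMER_TABLE_SIZE)
        p_n = np.zeros(HEXAMER_TABLE_SIZE)
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("hexamer"):
                raise ValueError(f"{path}: not a hexamer table")
            for line in fh:
                hexamer, pc, pn = line.split("\t")
                idx = encode_hexamer(hexamer)
                p_c[idx] = float(pc)
                p_n[idx] = float(pn)
        return cls(p_c, p_n)


def _count_windows(sequences: Iterable[str], step: int) -> tuple[np.ndarray, int]:
    counts = np.zeros(HEXAMER_TABLE_SIZE, dtype=np.int64)
    n_seqs = 0
    for seq in sequences:
        n_seqs += 1
        for i in range(0, len(seq) - 5, step):
            window = seq[i:i + 6]
            if set(window) <= set(_BASES):
                counts[encode_hexamer(window)] += 1
    return counts, n_seqs


def build_hexamer_table(coding_seqs: Sequence[str], noncoding_seqs: Sequence[str]) -> HexamerTable:
    """Build the hexamer table from CDS strings (step 3) and lncRNA
    sequences (step 1), normalizing counts to per-class probabilities."""
    coding_counts, n_c = _count_windows(coding_seqs, step=3)
    noncoding_counts, n_n = _count_windows(noncoding_seqs, step=1)
    total_c = coding_counts.sum()
    total_n = noncoding_counts.sum()
    if total_c == 0 or total_n == 0:
        raise ValueError("a class contributed zero hexamers")
    return HexamerTable(coding_counts / total_c, noncoding_counts / total_n,
                        n_coding_seqs=n_c, n_noncoding_seqs=n_n)


def _frame_score(sequence: str, table: HexamerTable, offset: int) -> Optional[float]:
    total = 0.0
    m = 0
    for i in range(offset, len(sequence) - 5, 3):
        total += table.log_ratio(sequence[i:i + 6])
        m += 1
    if m == 0:
        return None
    return total / m


def hexamer_score_transcript(sequence: str, table: HexamerTable) -> float:
    """Mean log-likelihood-ratio hexamer score, maximized over the three
    reading frames (step 3 within each frame). Sequences shorter than 6
    nt score 0."""
    scores = [s for off in range(3)
              if (s := _frame_score(sequence, table, off)) is not None]
    return max(scores) if scores else 0.0


def hexamer_score_orf(orfs: OrfSet, table: HexamerTable) -> dict[str, float]:
    """Hexamer score of each max ORF in its own reading frame (step 3).

    Absent ORFs (or ORFs shorter than 6 nt) contribute 0.
    """
    out: dict[str, float] = {}
    for t in ORF_TYPES:
        orf = orfs.get(t)
        score = 0.0
        if orf is not None:
            frame_score = _frame_score(orf.sequence, table, 0)
            if frame_score is not None:
                score = frame_score
        out[f"hexamer_score_orf_{t}"] = score
    return out
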