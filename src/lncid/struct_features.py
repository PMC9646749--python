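"""Secondary-structure features from dot-bracket strings.

Given an RNAfold-style dot-bracket structure this module derives the
paired-nucleotide ratio, the GC content of paired bases, a loop
decomposition (hairpin / interior / bulge / multibranch counts and
per-nucleotide coverages), and the sequence-and-secondary-structure
(SASS) k-mer tables and scores for k = 1..5. A SASS k-mer joins k
aligned sequence characters with the k structure characters underneath
("GG" over ".(" tokenizes as "GG.("); its score is the mean natural-log
likelihood ratio of mRNA over lncRNA token probabilities.

A deterministic maximum-base-pairing folder (Nussinov-style dynamic
program) is included so that synthetic fixtures can carry structures
without external folding software. Its output is a maximum-pairing
structure, not a thermodynamic minimum-free-energy prediction, and the
pseudo-MFE it reports (minus the pair count) is flagged as such wherever
it is persisted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import TranscriptRecord, check_balanced

UNPAIRED = -1

SASS_SEQ_ALPHABET = "ACGT"
SASS_STRUCT_ALPHABET = ".()"

#: Dense SASS key-space size per k: 4^k sequence combinations x 3^k
#: structure combinations -> 12, 144, 1728, 20736, 248832 for k = 1..5.
SASS_DENSE_SIZES = {k: (4 ** k) * (3 ** k) for k in range(1, 6)}

SASS_KS = (1, 2, 3, 4, 5)


def parse_dotbracket(structure: str) -> np.ndarray:
    """Stack-match a dot-bracket string into a pair table.

    Entry i holds the partner index of base i, or -1 if unpaired.
    Raises ValueError (with position) on unbalanced input.
    """
    pair = np.full(len(structure), UNPAIRED, dtype=np.int64)
    stack: list[int] = []
    for pos, ch in enumerate(structure):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            j = stack.pop()
            pair[j] = pos
            pair[pos] = j
        elif ch != ".":
            raise ValueError(f"invalid structure symbol {ch!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pair


def paired_ratio(pair_table: np.ndarray) -> float:
    """Fraction of nucleotides that are base-paired."""
    if len(pair_table) == 0:
        raise ValueError("empty pair table")
    return float((pair_table != UNPAIRED).sum() / len(pair_table))


def gc_content_paired(sequence: str, pair_table: np.ndarray) -> float:
    """GC fraction among paired nucleotides; 0 when nothing is paired."""
    paired = pair_table != UNPAIRED
    n_paired = int(paired.sum())
    if n_paired == 0:
        return 0.0
    gc = sum(1 for i in np.flatnonzero(paired) if sequence[i] in "GC")
    return gc / n_paired


@dataclass
class LoopDecomposition:
    n_hairpin: int = 0
    n_interior: int = 0
    n_bulge: int = 0
    n_multi: int = 0
    #: audit trail: (loop type, closing pair (i, j))
    members: list[tuple[str, tuple[int, int]]] = field(default_factory=list)


def _children(pair_table: np.ndarray, i: int, j: int) -> tuple[list[tuple[int, int]], int, int]:
    """Top-level pairs strictly inside (i, j), plus unpaired counts on the
    5' side of the first child and 3' side of the last child."""
    children: list[tuple[int, int]] = []
    unpaired_before = 0
    unpaired_after = 0
    k = i + 1
    while k < j:
        partner = int(pair_table[k])
        if partner == UNPAIRED:
            if not children:
                unpaired_before += 1
            else:
                unpaired_after += 1
            k += 1
        else:
            if children:
                unpaired_after = 0
            children.append((k, partner))
            k = partner + 1
    return children, unpaired_before, unpaired_after


def decompose_loops(pair_table: np.ndarray) -> LoopDecomposition:
    """Classify the loop closed by each base pair.

    A pair enclosing no helices closes a hairpin; one enclosing a single
    helix closes an interior loop (unpaired on both sides), a bulge
    (unpaired on exactly one side), or a stack (no unpaired bases, not
    counted as a loop); two or more enclosed helices close a multibranch
    loop. The exterior region is not a loop.
    """
    out = LoopDecomposition()
    for i in np.flatnonzero(pair_table > np.arange(len(pair_table))):
        i = int(i)
        j = int(pair_table[i])
        children, before, after = _children(pair_table, i, j)
        if len(children) == 0:
            out.n_hairpin += 1
            out.members.append(("hairpin", (i, j)))
        elif len(children) == 1:
            if before > 0 and after > 0:
                out.n_interior += 1
                out.members.append(("interior", (i, j)))
            elif before > 0 or after > 0:
                out.n_bulge += 1
                out.members.append(("bulge", (i, j)))
            # else: stacking pair, not counted
        else:
            out.n_multi += 1
            out.members.append(("multibranch", (i, j)))
    return out


LOOP_FEATURE_NAMES = (
    "loop_hairpin_count", "loop_interior_count", "loop_bulge_count", "loop_multi_count",
    "loop_hairpin_coverage", "loop_interior_coverage", "loop_bulge_coverage", "loop_multi_coverage",
)


def loop_features(pair_table: np.ndarray, transcript_length: int) -> dict[str, float]:
    """Loop counts plus coverages (count / transcript length)."""
    dec = decompose_loops(pair_table)
    counts = {
        "loop_hairpin_count": float(dec.n_hairpin),
        "loop_interior_count": float(dec.n_interior),
        "loop_bulge_count": float(dec.n_bulge),
        "loop_multi_count": float(dec.n_multi),
    }
    feats = dict(counts)
    for name, value in counts.items():
        feats[name.replace("_count", "_coverage")] = value / transcript_length
    return feats


def sass_tokenize(sequence: str, structure: str, k: int) -> list[str]:
    """Slide a width-k, two-row window over the sequence/structure array.

    Each token is the k sequence characters concatenated with the k
    aligned structure characters; a length-L input yields L - k + 1
    tokens.
    """
    if len(sequence) != len(structure):
        raise ValueError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    return [sequence[i:i + k] + structure[i:i + k]
            for i in range(len(sequence) - k + 1)]


def _token_llr(p_m: float, p_l: float) -> float:
    if p_m > 0 and p_l > 0:
        return math.log(p_m / p_l)
    if p_m > 0:
        return 1.0
    if p_l > 0:
        return -1.0
    return 0.0


@dataclass
class SassTable:
    """Sparse class-conditional SASS k-mer probability table."""

    k: int
    p_mrna: dict[str, float]
    p_lncrna: dict[str, float]

    @property
    def dense_size(self) -> int:
        return SASS_DENSE_SIZES[self.k]

    def log_ratio(self, token: str) -> float:
        return _token_llr(self.p_mrna.get(token, 0.0), self.p_lncrna.get(token, 0.0))

    def swapped(self) -> "SassTable":
        return SassTable(self.k, dict(self.p_lncrna), dict(self.p_mrna))

    def to_tsv(self, path) -> None:
        keys = sorted(set(self.p_mrna) | set(self.p_lncrna))
        with open(path, "w") as fh:
            fh.write(f"# sass k={self.k}\n")
            fh.write("token\tp_mRNA\tp_lncRNA\n")
            for key in keys:
                fh.write(f"{key}\t{self.p_mrna.get(key, 0.0):.12g}"
                         f"\t{self.p_lncrna.get(key, 0.0):.12g}\n")

    @classmethod
    def from_tsv(cls, path) -> "SassTable":
        with open(path) as fh:
            comment = fh.readline()
            if not comment.startswith("# sass k="):
                raise ValueError(f"{path}: not a SASS table")
            k = int(comment.strip().split("=")[1])
            fh.readline()  # header
            p_m: dict[str, float] = {}
            p_l: dict[str, float] = {}
            for line in fh:
                token, pm, pl = line.rstrip("\n").split("\t")
                pm = float(pm)
                pl = float(pl)
                if pm:
                    p_m[token] = pm
                if pl:
                    p_l[token] = pl
        return cls(k, p_m, p_l)


def _count_tokens(records: Iterable[TranscriptRecord], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in records:
        if rec.structure is None:
            raise ValueError(f"record {rec.id!r} has no structure")
        for token in sass_tokenize(rec.sequence, rec.structure, k):
            counts[token] = counts.get(token, 0) + 1
    return counts


def build_sass_tables(
    mrna_records: Sequence[TranscriptRecord],
    lncrna_records: Sequence[TranscriptRecord],
    ks: Sequence[int] = SASS_KS,
) -> dict[int, SassTable]:
    """Count SASS k-mers over full transcripts per class and normalize."""
    if not mrna_records or not lncrna_records:
        raise ValueError("both classes must be non-empty")
    tables: dict[int, SassTable] = {}
    for k in ks:
        m_counts = _count_tokens(mrna_records, k)
        l_counts = _count_tokens(lncrna_records, k)
        m_total = sum(m_counts.values())
        l_total = sum(l_counts.values())
        if m_total == 0 or l_total == 0:
            raise ValueError(f"a class contributed zero SASS {k}-mers")
        tables[k] = SassTable(
            k,
            {t: c / m_total for t, c in m_counts.items()},
            {t: c / l_total for t, c in l_counts.items()},
        )
    return tables


def sass_score(sequence: str, structure: Optional[str], k: int, table: SassTable) -> float:
    """Mean log-likelihood ratio over the transcript's SASS k-mers.

    Transcripts without a structure score 0 (supports the no-SSF mode).
    """
    if structure is None:
        return 0.0
    tokens = sass_tokenize(sequence, structure, k)
    if not tokens:
        return 0.0
    return sum(table.log_ratio(t) for t in tokens) / len(tokens)


# ---------------------------------------------------------------------------
# maximum base-pairing folder (fixtures support)

_CAN_PAIR_SUM = (3, 5)  # A+T = 0+3, G+C = 2+1, G+T = 2+3 under A0 C1 G2 T3
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}

MIN_HAIRPIN = 3  # minimum unpaired gap enclosed by a pair
FOLD_MAX_LEN = 2000


def _pairs_ok(a: int, b: int) -> bool:
    s = a + b
    return s == 3 or s == 5


def _nussinov_py(enc, min_gap: int):
    n = len(enc)
    table = np.zeros((n, n), dtype=np.int32)
    for d in range(min_gap + 1, n):
        for i in range(n - d):
            j = i + d
            best = table[i, j - 1]
            for k in range(i, j - min_gap):
                s = enc[k] + enc[j]
                if s == 3 or s == 5:
                    v = 1
                    if k + 1 <= j - 1:
                        v += table[k + 1, j - 1]
                    if k > i:
                        v += table[i, k - 1]
                    if v > best:
                        best = v
            table[i, j] = best
    return table

try:  # numba accelerates the O(n^3) fill; the pure-Python path is identical
    from numba import njit

    _nussinov_fill = njit(cache=False)(_nussinov_py)
except Exception:  # pragma: no cover
    _nussinov_fill = _nussinov_py

_warmed_up = False


def _fold_span(sequence: str) -> list[tuple[int, int]]:
    enc = np.array([_ENC[c] for c in sequence], dtype=np.int8)
    n = len(enc)
    if n <= MIN_HAIRPIN + 1:
        return []
    table = _nussinov_fill(enc, MIN_HAIRPIN)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_HAIRPIN or table[i, j] == 0:
            continue
        target = table[i, j]
        chosen = None
        # prefer pairing; among pairings take the leftmost partner for j
        for k in range(i, j - MIN_HAIRPIN):
            if _pairs_ok(int(enc[k]), int(enc[j])):
                v = 1
                if k + 1 <= j - 1:
                    v += table[k + 1, j - 1]
                if k > i:
                    v += table[i, k - 1]
                if v == target:
                    chosen = k
                    break
        if chosen is None:
            stack.append((i, j - 1))
        else:
            pairs.append((chosen, j))
            if chosen > i:
                stack.append((i, chosen - 1))
            if chosen + 1 <= j - 1:
                stack.append((chosen + 1, j - 1))
    return pairs


def fallback_fold(sequence: str, window: Optional[int] = None) -> tuple[str, float]:
    """Deterministic maximum base-pairing fold for fixture structures.

    Canonical pairs (AT, GC, GT wobble) with a minimum hairpin gap of 3;
    traceback prefers pairing and the leftmost partner, so output is
    deterministic. The returned pseudo-MFE is minus the pair count and is
    NOT an RNAfold free energy. With ``window`` set, the sequence is
    folded in consecutive windows of that many nucleotides and the
    structures concatenated (local folding); without it the whole
    sequence is folded, subject to a quadratic-memory length guard.
    """
    if set(sequence) - set("ACGT"):
        raise ValueError("fallback folder requires an A/C/G/T sequence")
    if window is None:
        if len(sequence) > FOLD_MAX_LEN:
            raise ValueError(
                f"sequence of {len(sequence)} nt exceeds the fallback folder "
                f"guard ({FOLD_MAX_LEN} nt); use RNAfold or a window"
            )
        spans = [(0, len(sequence))]
    else:
        if window <= MIN_HAIRPIN + 1:
            raise ValueError("window too small to form a pair")
        spans = [(s, min(s + window, len(sequence)))
                 for s in range(0, len(sequence), window)]
    structure = ["."] * len(sequence)
    n_pairs = 0
    for start, end in spans:
        for i, j in _fold_span(sequence[start:end]):
            structure[start + i] = "("
            structure[start + j] = ")"
            n_pairs += 1
    out = "".join(structure)
    check_balanced(out)
    return out, float(-n_pairs)
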