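"""Independent reference implementations used as test oracles.

Each function recomputes a quantity by direct enumeration or the
printed formula, structured differently from the library code so the
two can disagree.
"""

from __future__ import annotations

import math
from itertools import product

STOPS = {"TAA", "TAG", "TGA"}


# --- ORF enumeration ------------------------------------------------------

def enumerate_orf_candidates(seq: str) -> dict[str, list[tuple[int, int, int]]]:
    """Every (frame, start, end) candidate per ORF type, by brute force.

    T0: every ATG paired with the first in-frame stop downstream of it
    (no intervening stop, by construction). T2: every codon position
    that opens a stop-free run, paired with the terminating stop. T1:
    every ATG with no in-frame stop downstream, through the last
    complete codon.
    """
    out: dict[str, list[tuple[int, int, int]]] = {"t0": [], "t1": [], "t2": []}
    n = len(seq)
    for frame in range(3):
        starts = list(range(frame, n - 2, 3))
        codons = [seq[i:i + 3] for i in starts]
        stop_pos = [i for i, c in enumerate(codons) if c in STOPS]
        for ci, codon in enumerate(codons):
            nxt = next((s for s in stop_pos if s >= ci), None)
            if codon == "ATG":
                if nxt is None:
                    out["t1"].append((frame, starts[ci], starts[-1] + 3))
                else:
                    out["t0"].append((frame, starts[ci], starts[nxt] + 3))
            if codon not in STOPS and nxt is not None:
                # opens a run only if previous codon is a stop or none
                if ci == 0 or codons[ci - 1] in STOPS:
                    out["t2"].append((frame, starts[ci], starts[nxt] + 3))
        # non-run-opening T2 candidates are strictly shorter, so the max
        # over run-opening candidates equals the max over all candidates
    return out


def best_orfs(seq: str) -> dict[str, tuple[int, int, int] | None]:
    """Max candidate per type under (length desc, frame asc, start asc)."""
    cands = enumerate_orf_candidates(seq)

    def pick(items):
        if not items:
            return None
        return max(items, key=lambda c: (c[2] - c[1], -c[0], -c[1]))

    out = {t: pick(cands[t]) for t in ("t0", "t1", "t2")}
    t3_pool = [c for c in (out["t1"], out["t2"]) if c is not None]
    out["t3"] = pick(t3_pool) if t3_pool else None
    return out


# --- hexamer / SASS / RCB direct-formula scorers --------------------------

def llr(p_num: float, p_den: float) -> float:
    if p_num > 0 and p_den > 0:
        return math.log(p_num / p_den)
    if p_num > 0:
        return 1.0
    if p_den > 0:
        return -1.0
    return 0.0


def hexamer_score_oracle(seq: str, p_coding: dict[str, float],
                         p_noncoding: dict[str, float]) -> float:
    """Three-frame step-3 enumeration, max of per-frame mean LLR."""
    best = None
    for frame in range(3):
        terms = []
        i = frame
        while i + 6 <= len(seq):
            h = seq[i:i + 6]
            terms.append(llr(p_coding.get(h, 0.0), p_noncoding.get(h, 0.0)))
            i += 3
        if terms:
            score = sum(terms) / len(terms)
            best = score if best is None else max(best, score)
    return 0.0 if best is None else best


def sass_score_oracle(seq: str, struct: str, k: int,
                      p_m: dict[str, float], p_l: dict[str, float]) -> float:
    tokens = [seq[i:i + k] + struct[i:i + k] for i in range(len(seq) - k + 1)]
    if not tokens:
        return 0.0
    return sum(llr(p_m.get(t, 0.0), p_l.get(t, 0.0)) for t in tokens) / len(tokens)


def rcb_oracle(orf: str) -> float:
    """All-64-codon direct evaluation of the relative codon bias product."""
    codons = [orf[i:i + 3] for i in range(0, len(orf), 3)]
    n = len(codons)
    f1 = {b: sum(c[0] == b for c in codons) / n for b in "ACGT"}
    f2 = {b: sum(c[1] == b for c in codons) / n for b in "ACGT"}
    f3 = {b: sum(c[2] == b for c in codons) / n for b in "ACGT"}
    prod = 1.0
    for c in codons:
        f_obs = codons.count(c) / n
        f_exp = f1[c[0]] * f2[c[1]] * f3[c[2]]
        d = (f_obs - f_exp) / f_exp
        prod *= (1.0 + d)
    return prod ** (1.0 / n) - 1.0


# --- loop decomposition by recursive descent ------------------------------

def loop_counts_recursive(structure: str) -> dict[str, int]:
    """Recursive tree-walk classification of loops in a dot-bracket string."""
    pairs = {}
    stack = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs[stack.pop()] = i
    counts = {"hairpin": 0, "interior": 0, "bulge": 0, "multi": 0}

    def children_of(i: int, j: int):
        kids = []
        k = i + 1
        while k < j:
            if k in pairs:
                kids.append((k, pairs[k]))
                k = pairs[k] + 1
            else:
                k += 1
        return kids

    def visit(i: int, j: int):
        kids = children_of(i, j)
        if not kids:
            counts["hairpin"] += 1
        elif len(kids) == 1:
            (a, b), = kids
            left = a - i - 1
            right = j - b - 1
            if left and right:
                counts["interior"] += 1
            elif left or right:
                counts["bulge"] += 1
        else:
            counts["multi"] += 1
        for a, b in kids:
            visit(a, b)

    # exterior level: visit each top-level pair; the exterior is no loop
    k = 0
    while k < len(structure):
        if k in pairs:
            visit(k, pairs[k])
            k = pairs[k] + 1
        else:
            k += 1
    return counts


# --- exhaustive nested-pairing search (tiny n) ----------------------------

def max_nested_pairs(seq: str, min_gap: int = 3) -> int:
    """Exhaustive recursion over all nested canonical pairings."""
    ok = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i <= min_gap:
            return 0
        best = rec(i, j - 1)
        for k in range(i, j - min_gap):
            if (seq[k], seq[j]) in ok:
                cand = 1
                if k > i:
                    cand += rec(i, k - 1)
                if k + 1 <= j - 1:
                    cand += rec(k + 1, j - 1)
                best = max(best, cand)
        return best

    return rec(0, len(seq) - 1)


# --- rank-statistic AUC ----------------------------------------------------

def auc_rank_oracle(y, scores) -> float:
    """Mann-Whitney formulation: P(score_pos > score_neg) + 0.5 P(equal)."""
    pos = [s for t, s in zip(y, scores) if t == 1]
    neg = [s for t, s in zip(y, scores) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_sequence(rng, length: int, bases: str = "ACGT") -> str:
    return "".join(bases[i] for i in rng.integers(0, len(bases), size=length))
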