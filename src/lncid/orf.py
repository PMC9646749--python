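"""Four-type open reading frame detection and ORF length/coverage features.

Besides the conventional start-to-stop ORF (type 0), three relaxed ORF
types capture coding signal in transcripts whose annotated CDS differs
from the longest conventional ORF:

* T0 -- first ATG of a stop-terminated codon segment through its stop.
* T1 -- first ATG of the trailing (stop-free) segment through the last
  complete codon; no stop codon downstream in frame.
* T2 -- a stop-terminated segment from its first codon through its stop;
  no start codon required.
* T3 -- the longer of the best T1 and best T2.

Only the three forward reading frames are scanned (transcripts are
stranded). Stop codons are counted inside the ORF length. For each type
the longest ORF over all frames is kept, ties broken by lower frame then
smaller start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

ORF_TYPES = ("t0", "t1", "t2", "t3")


@dataclass(frozen=True)
class Orf:
    type: str  # "t0" | "t1" | "t2" | "t3"
    frame: int  # 0, 1, 2
    start: int  # 0-based, inclusive
    end: int  # exclusive
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.length % 3 != 0 or self.length < 3:
            raise ValueError(f"ORF length {self.length} invalid")


@dataclass
class OrfSet:
    t0: Optional[Orf] = None
    t1: Optional[Orf] = None
    t2: Optional[Orf] = None
    t3: Optional[Orf] = None
    all_t0: list[Orf] = field(default_factory=list)

    def get(self, orf_type: str) -> Optional[Orf]:
        return getattr(self, orf_type)


def _better(a: Optional[Orf], b: Orf) -> Orf:
    """Longest wins; ties resolved by lower frame then smaller start."""
    if a is None:
        return b
    if (b.length, -b.frame, -b.start) > (a.length, -a.frame, -a.start):
        return b
    return a


def find_typed_orfs(sequence: str) -> OrfSet:
    """Locate the maximal ORF of each type across the three forward frames."""
    out = OrfSet()
    n = len(sequence)
    for frame in range(3):
        codon_starts = range(frame, n - 2, 3)
        seg_start: Optional[int] = None  # nt index of first codon in segment
        seg_atg: Optional[int] = None  # nt index of first ATG in segment
        for pos in codon_starts:
            codon = sequence[pos:pos + 3]
            if codon in STOP_CODONS:
                stop_end = pos + 3
                if seg_start is not None:
                    orf = Orf("t2", frame, seg_start, stop_end,
                              sequence[seg_start:stop_end])
                    out.t2 = _better(out.t2, orf)
                if seg_atg is not None:
                    orf = Orf("t0", frame, seg_atg, stop_end,
                              sequence[seg_atg:stop_end])
                    out.all_t0.append(orf)
                    out.t0 = _better(out.t0, orf)
                seg_start = None
                seg_atg = None
            else:
                if seg_start is None:
                    seg_start = pos
                if seg_atg is None and codon == START_CODON:
                    seg_atg = pos
        # trailing segment: no terminating stop in this frame
        if seg_atg is not None:
            last_end = codon_starts[-1] + 3 if len(codon_starts) else frame
            orf = Orf("t1", frame, seg_atg, last_end, sequence[seg_atg:last_end])
            out.t1 = _better(out.t1, orf)
    if out.t1 is not None or out.t2 is not None:
        best = out.t1
        for cand in (out.t2,):
            if cand is not None:
                best = cand if best is None else _better(best, cand)
        assert best is not None
        out.t3 = Orf("t3", best.frame, best.start, best.end, best.sequence)
    return out


ORF_FEATURE_NAMES = (
    "orf_t0_length", "orf_t1_length", "orf_t2_length", "orf_t3_length",
    "orf_t0_coverage", "orf_t1_coverage", "orf_t2_coverage", "orf_t3_coverage",
    "orf_avg_length", "orf_avg_coverage",
)


def orf_length_coverage_features(orfs: OrfSet, transcript_length: int) -> dict[str, float]:
    """Max ORF lengths, coverages, and the T0 average length/coverage.

    Coverage is ORF length over transcript length; an absent ORF
    contributes 0 to every derived value.
    """
    if transcript_length < 1:
        raise ValueError("transcript length must be >= 1")
    feats: dict[str, float] = {}
    for t in ORF_TYPES:
        orf = orfs.get(t)
        length = float(orf.length) if orf is not None else 0.0
        feats[f"orf_{t}_length"] = length
        feats[f"orf_{t}_coverage"] = length / transcript_length
    if orfs.all_t0:
        avg = sum(o.length for o in orfs.all_t0) / len(orfs.all_t0)
    else:
        avg = 0.0
    feats["orf_avg_length"] = avg
    feats["orf_avg_coverage"] = avg / transcript_length
    return feats
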