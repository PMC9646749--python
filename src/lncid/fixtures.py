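"""Deterministic synthetic transcript generator.

Every pipeline stage (probability tables, training, evaluation) can run
on generated data with no downloads. mRNA-like records embed a long
ATG-to-stop open reading frame whose codons follow a skewed, dataset-
specific codon usage (a Dirichlet draw, exponentially tilted so the
expected GC matches the class target); untranslated flanks and
lncRNA-like records are i.i.d. base draws at their class GC target,
with stop codons salted into long stop-free runs so spurious ORFs stay
short. Structures come from the deterministic maximum-pairing folder,
applied in local windows.

These records are explicitly synthetic: they reproduce the broad
composition/ORF/structure contrasts between mRNAs and lncRNAs but none
of the biology of real GENCODE/RefSeq transcripts, whose benchmark
numbers require the real corpora.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .orf import STOP_CODONS
from .seqio import POSITIVE_LABEL, TranscriptRecord
from .struct_features import fallback_fold

_BASES = "ACGT"
SENSE_CODONS = tuple(
    "".join(c) for c in itertools.product(_BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
)
_STOPS = tuple(sorted(STOP_CODONS))
_GC_PER_CODON = np.array([c.count("G") + c.count("C") for c in SENSE_CODONS], dtype=float)


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    n_mrna: int = 2000
    n_lncrna: int = 2000
    length_range: tuple[int, int] = (200, 600)
    orf_fraction: float = 0.5  # minimum T0 coverage of generated mRNAs
    codon_bias_concentration: float = 0.3  # Dirichlet alpha; smaller = stronger bias
    gc_mrna: float = 0.52
    gc_lncrna: float = 0.42
    seed: int = 0
    fold_window: Optional[int] = 120
    max_orf_run_codons: int = 30  # lncRNA stop-salting threshold

    def __post_init__(self) -> None:
        if not (0.0 < self.orf_fraction <= 1.0):
            raise ValueError("ORF fraction must be in (0, 1]")
        lo, hi = self.length_range
        if lo < 200 or hi < lo:
            raise ValueError("length range must satisfy 200 <= lo <= hi")


def _tilted_codon_probs(raw: np.ndarray, gc_target: float) -> np.ndarray:
    """Exponentially tilt codon probabilities so E[GC per base] = target."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        t = (lo + hi) / 2
        w = raw * np.exp(t * _GC_PER_CODON)
        p = w / w.sum()
        if (p * _GC_PER_CODON).sum() / 3.0 < gc_target:
            lo = t
        else:
            hi = t
    return p


def _base_probs(gc_target: float) -> np.ndarray:
    return np.array([(1 - gc_target) / 2, gc_target / 2,
                     gc_target / 2, (1 - gc_target) / 2])


def _random_bases(rng: np.random.Generator, n: int, probs: np.ndarray) -> str:
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=probs)])


def _salt_stop_codons(sequence: str, rng: np.random.Generator, max_run: int) -> str:
    """Replace one codon inside any frame's stop-free run longer than
    max_run codons with a random stop, keeping spurious ORFs short."""
    seq = list(sequence)
    for _ in range(3):  # frames interact; a few passes reach a fixed point
        changed = False
        for frame in range(3):
            run = 0
            for pos in range(frame, len(seq) - 2, 3):
                codon = "".join(seq[pos:pos + 3])
                if codon in STOP_CODONS:
                    run = 0
                    continue
                run += 1
                if run > max_run:
                    stop = _STOPS[rng.integers(0, 3)]
                    seq[pos:pos + 3] = list(stop)
                    run = 0
                    changed = True
        if not changed:
            break
    return "".join(seq)


def _make_mrna(rng: np.random.Generator, spec: FixtureSpec,
               codon_probs: np.ndarray, index: int) -> TranscriptRecord:
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    min_frac = spec.orf_fraction
    frac = float(rng.uniform(min_frac, min(0.9, min_frac + 0.3)))
    n_codons = max(3, math.ceil(frac * length / 3))  # ceil keeps coverage >= frac
    n_codons = min(n_codons, length // 3)
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2, p=codon_probs)
    orf = "ATG" + "".join(SENSE_CODONS[i] for i in body) + _STOPS[rng.integers(0, 3)]
    remaining = length - len(orf)
    utr5_len = int(rng.integers(0, remaining + 1))
    base_p = _base_probs(spec.gc_mrna)
    utr5 = _random_bases(rng, utr5_len, base_p)
    utr3 = _random_bases(rng, remaining - utr5_len, base_p)
    sequence = utr5 + orf + utr3
    return TranscriptRecord(
        id=f"mrna_{index:05d}",
        sequence=sequence,
        label="mRNA",
        cds=(utr5_len, utr5_len + len(orf)),
    )


def _make_lncrna(rng: np.random.Generator, spec: FixtureSpec, index: int) -> TranscriptRecord:
    lo, hi = spec.length_range
    length = int(rng.integers(lo, hi + 1))
    sequence = _random_bases(rng, length, _base_probs(spec.gc_lncrna))
    sequence = _salt_stop_codons(sequence, rng, spec.max_orf_run_codons)
    return TranscriptRecord(id=f"lnc_{index:05d}", sequence=sequence,
                            label=POSITIVE_LABEL)


def generate_dataset(spec: FixtureSpec, fold: bool = True) -> list[TranscriptRecord]:
    """Generate labeled mRNA-like and lncRNA-like transcripts.

    Reproducible given the spec seed; with ``fold`` on, each record
    carries a fallback-fold structure (windowed) and its pseudo-MFE.
    """
    rng = np.random.default_rng(spec.seed)
    codon_probs = _tilted_codon_probs(
        rng.dirichlet(np.full(len(SENSE_CODONS), spec.codon_bias_concentration)),
        spec.gc_mrna,
    )
    records = [_make_mrna(rng, spec, codon_probs, i) for i in range(spec.n_mrna)]
    records += [_make_lncrna(rng, spec, i) for i in range(spec.n_lncrna)]
    if fold:
        for rec in records:
            rec.structure, rec.mfe = fallback_fold(rec.sequence, window=spec.fold_window)
    return records


def write_dataset(records, fasta_path, structures_path=None, labels_path=None) -> None:
    from . import seqio

    seqio.write_fasta(records, fasta_path)
    if structures_path is not None:
        seqio.write_structures(records, structures_path)
    if labels_path is not None:
        seqio.write_labels(records, labels_path)
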