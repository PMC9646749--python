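"""Physicochemical features of the putative proteins encoded by max ORFs.

Each max ORF is translated with the standard genetic code (terminal stop
dropped) and five properties of the predicted peptide are computed:
theoretical isoelectric point (pH), molecular weight (Da, average
masses), GRAVY (Kyte-Doolittle grand average of hydropathy),
aromaticity (Phe+Trp+Tyr fraction), and the Guruprasad instability
index. The numerical work is delegated to Biopython's ProtParam, whose
published constant tables (pKa sets, average residue masses,
Kyte-Doolittle hydropathies, DIWV dipeptide weights) are the standard
references for these quantities.

Degenerate peptides (empty, or length 1 for the instability index)
yield 0 so that feature vectors stay total for transcripts without a
usable ORF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .orf import ORF_TYPES, Orf, OrfSet


@dataclass(frozen=True)
class Peptide:
    residues: str
    source_orf_type: Optional[str] = None

    def __len__(self) -> int:
        return len(self.residues)


def translate_orf(orf_sequence: str, source_orf_type: Optional[str] = None) -> Peptide:
    """Translate an ORF (standard code); a terminal stop is stripped.

    The segment-based ORF definitions guarantee no internal stop codon,
    so the peptide is stop-free. Empty input yields an empty peptide.
    """
    if len(orf_sequence) % 3 != 0:
        raise ValueError("ORF length must be divisible by 3")
    if not orf_sequence:
        return Peptide("", source_orf_type)
    residues = str(Seq(orf_sequence).translate())
    if residues.endswith("*"):
        residues = residues[:-1]
    if "*" in residues:
        raise ValueError("internal stop codon in ORF translation")
    return Peptide(residues, source_orf_type)


def isoelectric_point(peptide: Peptide) -> float:
    """pH at which the peptide's net charge is zero (0 for empty input)."""
    if len(peptide) == 0:
        return 0.0
    return float(ProteinAnalysis(peptide.residues).isoelectric_point())


def molecular_weight(peptide: Peptide) -> float:
    """Average-mass molecular weight in Daltons (0 for empty input)."""
    if len(peptide) == 0:
        return 0.0
    return float(ProteinAnalysis(peptide.residues).molecular_weight())


def gravy(peptide: Peptide) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value)."""
    if len(peptide) == 0:
        return 0.0
    return float(ProteinAnalysis(peptide.residues).gravy())


def aromaticity(peptide: Peptide) -> float:
    """Fraction of aromatic residues (Phe, Trp, Tyr)."""
    if len(peptide) == 0:
        return 0.0
    return float(ProteinAnalysis(peptide.residues).aromaticity())


def instability_index(peptide: Peptide) -> float:
    """Guruprasad instability index, (10/L) * sum of DIWV dipeptide weights.

    Peptides shorter than two residues have no dipeptide and score 0.
    """
    if len(peptide) < 2:
        return 0.0
    return float(ProteinAnalysis(peptide.residues).instability_index())


PROTEIN_FEATURE_KINDS = ("pi", "mw", "gravy", "aromaticity", "instability")

_FEATURE_FUNCS = {
    "pi": isoelectric_point,
    "mw": molecular_weight,
    "gravy": gravy,
    "aromaticity": aromaticity,
    "instability": instability_index,
}


def peptide_features(peptide: Peptide) -> dict[str, float]:
    return {kind: func(peptide) for kind, func in _FEATURE_FUNCS.items()}


def protein_features_for_orfset(orfs: OrfSet) -> dict[str, float]:
    """The 20-value protein block: 5 features for each of the 4 ORF types.

    Absent ORFs contribute zeros.
    """
    out: dict[str, float] = {}
    for t in ORF_TYPES:
        orf: Optional[Orf] = orfs.get(t)
        peptide = translate_orf(orf.sequence, t) if orf is not None else Peptide("", t)
        for kind, value in peptide_features(peptide).items():
            out[f"orf_{t}_{kind}"] = value
    return out
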