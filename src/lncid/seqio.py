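"""Transcript FASTA input, filtering, structure attachment, and prediction output.

Transcripts are held as :class:`TranscriptRecord` objects: an id, an
uppercase DNA-alphabet sequence (U is normalized to T on input), and
optionally an RNAfold-style dot-bracket secondary structure with its
minimum free energy (MFE, kcal/mol), a class label, and -- for mRNA
training records -- the half-open CDS interval on the transcript.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

VALID_ALPHABET = frozenset("ACGT")

#: lncRNA is the positive class throughout the package.
POSITIVE_LABEL = "lncRNA"
NEGATIVE_LABEL = "mRNA"

#: Default transcript length bounds (nt), inclusive at both ends.
MIN_LENGTH = 200
MAX_LENGTH = 20000


class FastaParseError(ValueError):
    pass


@dataclass
class TranscriptRecord:
    """One RNA transcript, optionally with structure, label, and CDS."""

    id: str
    sequence: str
    structure: Optional[str] = None
    mfe: Optional[float] = None
    label: Optional[str] = None
    cds: Optional[tuple[int, int]] = None  # half-open, 0-based, on transcript

    def __post_init__(self) -> None:
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: structure length {len(self.structure)} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.cds is not None:
            start, end = self.cds
            if not (0 <= start <= end <= len(self.sequence)):
                raise ValueError(f"record {self.id!r}: CDS {self.cds} out of bounds")
            if (end - start) % 3 != 0:
                raise ValueError(f"record {self.id!r}: CDS length not divisible by 3")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def cds_sequence(self) -> Optional[str]:
        if self.cds is None:
            return None
        return self.sequence[self.cds[0]:self.cds[1]]


def normalize_sequence(raw: str) -> str:
    """Uppercase and map U to T; other symbols pass through untouched."""
    return raw.upper().replace("U", "T")


def read_fasta(path) -> list[TranscriptRecord]:
    """Read transcripts from a FASTA file.

    Ids are the first whitespace-delimited header token; sequences are
    normalized (uppercase, U->T) but invalid symbols are retained so the
    filter stage can reject them with a reason rather than silently
    dropping records.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header '>' "
                    f"before sequence data"
                )
            break
    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {entry.id!r}")
        seen.add(entry.id)
        records.append(TranscriptRecord(id=entry.id, sequence=normalize_sequence(str(entry.seq))))
    return records


def write_fasta(records: Iterable[TranscriptRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i:i + 70] + "\n")


# reason codes used by filter_transcripts
TOO_SHORT = "too_short"
TOO_LONG = "too_long"
INVALID_SYMBOL = "invalid_symbol"


def filter_transcripts(
    records: Sequence[TranscriptRecord],
    min_len: int = MIN_LENGTH,
    max_len: int = MAX_LENGTH,
) -> tuple[list[TranscriptRecord], list[tuple[TranscriptRecord, str]]]:
    """Partition records into (kept, rejected-with-reason).

    Kept records satisfy ``min_len <= L_t <= max_len`` (inclusive bounds)
    and use only the A/C/G/T alphabet. Rejection reasons are
    ``too_short``, ``too_long``, or ``invalid_symbol``.
    """
    kept: list[TranscriptRecord] = []
    rejected: list[tuple[TranscriptRecord, str]] = []
    for rec in records:
        if len(rec) < min_len:
            rejected.append((rec, TOO_SHORT))
        elif len(rec) > max_len:
            rejected.append((rec, TOO_LONG))
        elif not set(rec.sequence) <= VALID_ALPHABET:
            rejected.append((rec, INVALID_SYMBOL))
        else:
            kept.append(rec)
    return kept, rejected


def check_balanced(structure: str) -> None:
    """Raise ValueError (with position) on unbalanced dot-bracket strings."""
    depth = 0
    for pos, ch in enumerate(structure):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at position {pos}")
        elif ch != ".":
            raise ValueError(f"invalid structure symbol {ch!r} at position {pos}")
    if depth != 0:
        raise ValueError(f"unbalanced structure: {depth} '(' left open")


_MFE_RE = re.compile(r"\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def _parse_rnafold_text(path) -> dict[str, tuple[str, Optional[float]]]:
    """Parse RNAfold standard output (>id / sequence / dot-bracket (MFE))."""
    result: dict[str, tuple[str, Optional[float]]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header at line {i + 1}")
        rec_id = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated RNAfold block for {rec_id!r}")
        struct_line = lines[i + 2]
        m = _MFE_RE.search(struct_line)
        mfe = float(m.group(1)) if m else None
        structure = struct_line.split()[0] if " " in struct_line else _MFE_RE.sub("", struct_line)
        structure = structure.strip()
        result[rec_id] = (structure, mfe)
        i += 3
    return result


def _parse_structure_tsv(path) -> dict[str, tuple[str, Optional[float]]]:
    """Parse a three-column id / structure / mfe table (no header)."""
    result: dict[str, tuple[str, Optional[float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected id<TAB>structure[<TAB>mfe]")
            mfe = float(parts[2]) if len(parts) > 2 and parts[2] != "" else None
            result[parts[0]] = (parts[1], mfe)
    return result


def attach_structures(
    records: Sequence[TranscriptRecord], structure_path
) -> tuple[Sequence[TranscriptRecord], list[str]]:
    """Attach dot-bracket structures and MFEs from a structure file.

    The file may be RNAfold output text or a three-column TSV. Matched
    records gain ``structure``/``mfe`` in place; the ids of records with
    no structure entry are returned for reporting.
    """
    with open(structure_path) as fh:
        first = fh.read(1)
    table = (_parse_rnafold_text if first == ">" else _parse_structure_tsv)(structure_path)
    unmatched: list[str] = []
    for rec in records:
        if rec.id not in table:
            unmatched.append(rec.id)
            continue
        structure, mfe = table[rec.id]
        if len(structure) != len(rec.sequence):
            raise ValueError(
                f"record {rec.id!r}: structure length {len(structure)} "
                f"!= sequence length {len(rec.sequence)}"
            )
        try:
            check_balanced(structure)
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
        rec.structure = structure
        rec.mfe = mfe
    return records, unmatched


def write_predictions(
    records: Sequence[TranscriptRecord],
    probabilities: Sequence[float],
    path,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Write the prediction table (id, length, predicted_label, lncRNA_probability).

    Probabilities at or above the threshold are called lncRNA (ties go to
    the positive class). Row order follows the input order.
    """
    if len(records) != len(probabilities):
        raise ValueError(
            f"{len(records)} records but {len(probabilities)} probabilities"
        )
    table = pd.DataFrame(
        {
            "id": [rec.id for rec in records],
            "length": [len(rec) for rec in records],
            "predicted_label": [
                POSITIVE_LABEL if p >= threshold else NEGATIVE_LABEL
                for p in probabilities
            ],
            "lncRNA_probability": [round(float(p), 6) for p in probabilities],
        }
    )
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return table


def read_labels(path) -> dict[str, tuple[str, Optional[tuple[int, int]]]]:
    """Read a label table: id, label, optional cds_start / cds_end columns."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, tuple[str, Optional[tuple[int, int]]]] = {}
    for _, row in df.iterrows():
        cds = None
        if "cds_start" in df.columns and pd.notna(row.get("cds_start")):
            cds = (int(row["cds_start"]), int(row["cds_end"]))
        out[str(row["id"])] = (str(row["label"]), cds)
    return out


def write_labels(records: Iterable[TranscriptRecord], path) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.id,
                "label": rec.label,
                "cds_start": rec.cds[0] if rec.cds else "",
                "cds_end": rec.cds[1] if rec.cds else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_structures(records: Iterable[TranscriptRecord], path) -> None:
    """Write id / structure / mfe TSV for records that carry a structure."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.structure is None:
                continue
            mfe = "" if rec.mfe is None else f"{rec.mfe:g}"
            fh.write(f"{rec.id}\t{rec.structure}\t{mfe}\n")


def apply_labels(records: Sequence[TranscriptRecord], labels) -> None:
    """Attach labels (and CDS intervals) from a read_labels mapping."""
    for rec in records:
        if rec.id in labels:
            label, cds = labels[rec.id]
            rec.label = label
            if cds is not None:
                rec.cds = cds
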