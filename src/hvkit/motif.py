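"""Signature-motif scanner for candidate voltage-gated proton channels.

The diagnostic signature is two-fold: an aspartate near the middle of the
first transmembrane segment, and the motif R-x-W-R-x-x-R inside a later
transmembrane segment. Transmembrane segments are predicted with a plain
Kyte-Doolittle hydropathy scan — deliberately simple, dependency-free, and
deterministic; all parameters are exposed.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "SignatureHit",
    "KYTE_DOOLITTLE",
    "S4_MOTIF_PATTERN",
    "predict_tm_segments",
    "find_s4_motif",
    "scan_signature",
    "scan_fasta",
]

#: Kyte & Doolittle hydropathy scale; X (unknown residue) scores 0.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5, "X": 0.0,
}

_VALID_ALPHABET = frozenset(KYTE_DOOLITTLE)
_NUCLEOTIDE_ALPHABET = frozenset("ACGTUN")

#: R, any, W, R, any, any, R
S4_MOTIF_PATTERN = re.compile(r"(?=(R.WR..R))")

MIN_SCAN_LENGTH = 50


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; normalized to uppercase and validated against
    the 20 standard residues plus X. Nucleotide-looking input is rejected,
    never silently translated."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        letters = set(seq)
        # A/C/G/T are all valid residues too, so only a reasonably long
        # sequence drawn purely from the nucleotide alphabet with several
        # distinct letters is called DNA/RNA and rejected
        if (len(seq) >= 12 and letters <= _NUCLEOTIDE_ALPHABET
                and len(letters - {"N"}) >= 3):
            raise ValueError(
                f"record {self.id!r} looks like a nucleotide sequence; "
                "provide amino acids")
        bad = letters - _VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains invalid residues: "
                f"{''.join(sorted(bad))}")


@dataclass
class SignatureHit:
    """Scan outcome for one record; ``is_full_signature`` requires the S4
    motif inside a predicted TM segment plus an Asp in the central third of
    an earlier TM segment."""

    s4_motif_start: int
    s4_motif_string: str
    tm_segments: List[Tuple[int, int]]
    s1_candidate_asp_positions: List[int]
    is_full_signature: bool


def predict_tm_segments(record: ProteinRecord, window: int = 19,
                        threshold: float = 1.6) -> List[Tuple[int, int]]:
    """Hydropathy-based transmembrane segment prediction.

    A residue belongs to a segment when the window centered on it has mean
    Kyte-Doolittle hydropathy above ``threshold``; maximal runs of such
    residues are merged when separated by fewer than 3 residues and kept
    when at least 15 residues long. Returns half-open intervals; sequences
    shorter than the window yield an empty list."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    seq = record.sequence
    n = len(seq)
    if n < window:
        return []
    scores = np.array([KYTE_DOOLITTLE[a] for a in seq])
    kernel = np.ones(window) / window
    means = np.convolve(scores, kernel, mode="valid")  # index i = window start
    above = means > threshold

    half = window // 2
    raw: List[Tuple[int, int]] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            raw.append((i + half, j + half + 1))  # run of window centers
            i = j + 1
        else:
            i += 1

    merged: List[Tuple[int, int]] = []
    for start, end in raw:
        if merged and start - merged[-1][1] < 3:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return [(s, e) for s, e in merged if e - s >= 15]


def find_s4_motif(record: ProteinRecord) -> List[Tuple[int, str]]:
    """All (position, matched string) occurrences of R-x-W-R-x-x-R,
    overlapping matches included."""
    seq = record.sequence
    return [(m.start(), seq[m.start():m.start() + 7])
            for m in S4_MOTIF_PATTERN.finditer(seq)]


def _central_third(start: int, end: int) -> Tuple[int, int]:
    length = end - start
    lo = start + length // 3
    hi = end - length // 3
    return lo, hi


def scan_signature(record: ProteinRecord, window: int = 19,
                   threshold: float = 1.6) -> Optional[SignatureHit]:
    """Full signature test for one record.

    The earliest S4 motif lying entirely inside a predicted TM segment is
    the anchor; aspartates within the central third of any TM segment
    N-terminal to the anchor segment complete the signature. If motifs
    exist but no anchor or Asp qualifies, the hit is reported with
    ``is_full_signature=False``; no motif at all returns ``None``."""
    motifs = find_s4_motif(record)
    if not motifs:
        return None
    segments = predict_tm_segments(record, window=window, threshold=threshold)

    for pos, s in motifs:
        seg_idx = next((k for k, (a, b) in enumerate(segments)
                        if a <= pos and pos + 7 <= b), None)
        if seg_idx is None:
            continue
        asp_positions = []
        for a, b in segments[:seg_idx]:
            lo, hi = _central_third(a, b)
            asp_positions.extend(
                i for i in range(lo, hi) if record.sequence[i] == "D")
        if asp_positions:
            return SignatureHit(s4_motif_start=pos, s4_motif_string=s,
                                tm_segments=segments,
                                s1_candidate_asp_positions=sorted(asp_positions),
                                is_full_signature=True)

    pos, s = motifs[0]
    return SignatureHit(s4_motif_start=pos, s4_motif_string=s,
                        tm_segments=segments,
                        s1_candidate_asp_positions=[],
                        is_full_signature=False)


def scan_fasta(path, window: int = 19, threshold: float = 1.6) -> pd.DataFrame:
    """Scan every record of a FASTA file; one row per record in file order
    (duplicates are not collapsed). Records shorter than 50 residues are
    reported but not scanned."""
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        record = ProteinRecord(id=rec.id, sequence=str(rec.seq))
        if len(record.sequence) < MIN_SCAN_LENGTH:
            rows.append({"id": record.id, "length": len(record.sequence),
                         "motif_start": -1, "motif": "", "tm_count": 0,
                         "full_signature": False})
            continue
        hit = scan_signature(record, window=window, threshold=threshold)
        rows.append({
            "id": record.id,
            "length": len(record.sequence),
            "motif_start": hit.s4_motif_start if hit else -1,
            "motif": hit.s4_motif_string if hit else "",
            "tm_count": len(hit.tm_segments) if hit
                        else len(predict_tm_segments(record, window, threshold)),
            "full_signature": bool(hit.is_full_signature) if hit else False,
        })
    return pd.DataFrame(
        rows, columns=["id", "length", "motif_start", "motif", "tm_count",
                       "full_signature"])
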