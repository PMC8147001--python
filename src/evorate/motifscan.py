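"""IQ-like calmodulin-binding motif scan for protein sequences.

Calmodulin (CaM) regulates many channels through an amphipathic helix whose
consensus is the IQ motif [FILV]Qxxx[RK]Gxxx[RK]; "IQ-like" variants relax
the glycine and second basic anchor.  The scanner reports consensus-class
matches of both patterns:

    IQ_full:  [FILV]Qxxx[RK]Gxxx[RK]   (11 residues)
    IQ_like:  [FILVM]Qxxx[RK]xxxx      (10 residues)

scanning left to right, preferring the stricter (longer) class at each
position and skipping past a match so reported hits never overlap.  The
anchor of a hit is the position of its [FILVM]-Q dipeptide (= the match
start).  A hit can additionally be flagged as C-terminal when its anchor
lies within a trailing window of the sequence (default 21 residues, the
span a short terminal truncation would remove).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .errors import AlphabetError
from .seqio import AMINO_ACIDS

IQ_FULL_PATTERN = re.compile(r"[FILV]Q[A-Z]{3}[RK]G[A-Z]{3}[RK]")
IQ_LIKE_PATTERN = re.compile(r"[FILVM]Q[A-Z]{3}[RK][A-Z]{4}")

IQ_FULL_LEN = 11
IQ_LIKE_LEN = 10

DEFAULT_CTERM_WINDOW = 21


@dataclass
class MotifHit:
    """One motif match: 0-based half-open coordinates into the sequence."""

    start: int
    end: int
    matched: str
    pattern_class: str  # "IQ_full" or "IQ_like"
    anchor: int  # position of the [FILVM]-Q dipeptide

    def __post_init__(self) -> None:
        assert self.start <= self.anchor < self.end


def _validate(seq: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in AMINO_ACIDS:
            raise AlphabetError(f"illegal residue {ch!r} at position {pos}")
    return seq


def _class_at(seq: str, pos: int) -> tuple[str, int] | None:
    """Strictest motif class starting at ``pos``, or None."""
    if IQ_FULL_PATTERN.match(seq, pos):
        return "IQ_full", IQ_FULL_LEN
    if IQ_LIKE_PATTERN.match(seq, pos):
        return "IQ_like", IQ_LIKE_LEN
    return None


def find_iq_like(seq: str) -> list[MotifHit]:
    """All non-overlapping IQ/IQ-like motif hits, strictest class first.

    Positions are scanned left to right; at each position the full IQ
    consensus is tried before the relaxed one, and scanning resumes past
    the end of any accepted match.
    """
    seq = _validate(seq)
    hits: list[MotifHit] = []
    pos = 0
    while pos <= len(seq) - IQ_LIKE_LEN:
        found = _class_at(seq, pos)
        if found is None:
            pos += 1
            continue
        pattern_class, length = found
        hits.append(
            MotifHit(
                start=pos,
                end=pos + length,
                matched=seq[pos : pos + length],
                pattern_class=pattern_class,
                anchor=pos,
            )
        )
        pos += length
    return hits


def report_cterminal(
    hits: list[MotifHit], seq_length: int, window: int = DEFAULT_CTERM_WINDOW
) -> list[bool]:
    """Flag hits whose anchor lies within the final ``window`` residues."""
    if window <= 0:
        raise ValueError("window must be positive")
    return [hit.anchor >= seq_length - window for hit in hits]


def scan_alignment_members(
    members: dict[str, str], window: int = DEFAULT_CTERM_WINDOW
) -> pd.DataFrame:
    """Scan a set of (ungapped) sequences and tabulate all hits.

    Gap and unknown characters are removed before scanning; coordinates
    refer to the ungapped sequence.
    """
    rows = []
    for taxon, seq in members.items():
        clean = seq.upper().replace("-", "").replace("X", "")
        hits = find_iq_like(clean)
        flags = report_cterminal(hits, len(clean), window)
        for hit, is_cterm in zip(hits, flags):
            rows.append(
                {
                    "taxon": taxon,
                    "start": hit.start,
                    "end": hit.end,
                    "class": hit.pattern_class,
                    "matched": hit.matched,
                    "c_terminal": is_cterm,
                }
            )
    return pd.DataFrame(
        rows, columns=["taxon", "start", "end", "class", "matched", "c_terminal"]
    )
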