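"""Per-codon-position nucleotide composition of barcode alignments.

The codon position of alignment column c is ((c - frame_offset) mod 3) + 1.
Gaps and ambiguity codes are excluded from denominators, so frequencies over
{A, C, G, T} sum to one at every position.  Insect mitochondrial COI is
strongly A+T biased, most extremely at third positions, which is the
feature these profiles quantify.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .seq_io import BarcodeAlignment, BarcodeRecord

__all__ = ["CompositionProfile", "composition_profile", "zero_base_check", "profiles_to_frame"]

BASES = ("A", "C", "G", "T")
POSITIONS = ("all", "1", "2", "3")


@dataclass
class CompositionProfile:
    """Base frequencies by codon position for one scope (dataset/genus/sequence)."""

    scope: str
    label: str
    freq: dict[str, dict[str, float]]  # position -> base -> frequency
    counts: dict[str, int]             # position -> unambiguous bases counted

    @property
    def at_content(self) -> dict[str, float]:
        return {pos: self.freq[pos]["A"] + self.freq[pos]["T"] for pos in POSITIONS}


def _codon_positions(length: int, frame_offset: int) -> np.ndarray:
    cols = np.arange(length)
    return ((cols - frame_offset) % 3) + 1


def _profile_from_counts(
    scope: str, label: str, counts: np.ndarray
) -> CompositionProfile:
    """counts: (4 positions-incl-all? no: 3, 4 bases) -> profile with 'all' row."""
    tot = counts.sum(axis=0)
    table = np.vstack([tot, counts])  # rows: all, 1, 2, 3
    freq: dict[str, dict[str, float]] = {}
    npos: dict[str, int] = {}
    for row, pos in zip(table, POSITIONS):
        denom = row.sum()
        if denom == 0:
            raise ValueError(f"no unambiguous bases at codon position {pos}")
        freq[pos] = {b: float(row[k] / denom) for k, b in enumerate(BASES)}
        npos[pos] = int(denom)
    return CompositionProfile(scope=scope, label=label, freq=freq, counts=npos)


def _count_matrix(records: list[BarcodeRecord], pos_of: np.ndarray) -> np.ndarray:
    """(3 codon positions, 4 bases) pooled counts over the given records."""
    counts = np.zeros((3, 4), dtype=np.int64)
    for rec in records:
        arr = np.array(list(rec.sequence), dtype="U1")
        for k, base in enumerate(BASES):
            hit = arr == base
            for p in (1, 2, 3):
                counts[p - 1, k] += int((hit & (pos_of == p)).sum())
    return counts


def composition_profile(
    aln: BarcodeAlignment,
    scope: str = "dataset",
    grouping: Mapping[str, str] | None = None,
    averaged: bool = False,
) -> list[CompositionProfile]:
    """Composition profiles at the requested scope.

    scope='dataset' pools all columns of all sequences (one profile);
    'genus' yields one per genus (grouping defaults to the records' genus
    fields); 'sequence' one per record.  With ``averaged=True`` the dataset
    and genus scopes average per-sequence frequency profiles unweighted
    instead of pooling counts (both readings of a "mean composition" are
    available; pooling is the default).
    """
    if aln.length < 3:
        raise ValueError("alignment shorter than one codon")
    pos_of = _codon_positions(aln.length, aln.frame_offset)

    if scope == "sequence":
        return [
            _profile_from_counts("sequence", r.seq_id, _count_matrix([r], pos_of))
            for r in aln.records
        ]

    if scope == "dataset":
        groups = {"dataset": list(aln.records)}
    elif scope == "genus":
        if grouping is None:
            grouping = aln.genus_of()
        groups = {}
        for r in aln.records:
            groups.setdefault(grouping[r.seq_id], []).append(r)
    else:
        raise ValueError(f"unknown scope {scope!r}")

    out = []
    for label, members in sorted(groups.items()):
        if not averaged:
            out.append(
                _profile_from_counts(scope, label, _count_matrix(members, pos_of))
            )
        else:
            per_seq = [
                _profile_from_counts("sequence", m.seq_id, _count_matrix([m], pos_of))
                for m in members
            ]
            freq = {
                pos: {
                    b: float(np.mean([p.freq[pos][b] for p in per_seq]))
                    for b in BASES
                }
                for pos in POSITIONS
            }
            npos = {pos: sum(p.counts[pos] for p in per_seq) for pos in POSITIONS}
            out.append(CompositionProfile(scope=scope, label=label, freq=freq, counts=npos))
    return out


def zero_base_check(
    profiles: list[CompositionProfile],
) -> list[tuple[str, str, str]]:
    """(label, position, base) triples whose frequency is exactly zero.

    Flags taxa like the study's third-position-G-free genera; only codon
    positions 1-3 are scanned (the 'all' row is implied by them).
    """
    out = []
    for prof in profiles:
        for pos in ("1", "2", "3"):
            for base in BASES:
                if prof.freq[pos][base] == 0.0:
                    out.append((prof.label, pos, base))
    return out


def profiles_to_frame(profiles: list[CompositionProfile]) -> pd.DataFrame:
    """Long-to-wide table: rows = taxa, columns = base x codon position."""
    rows = {}
    for prof in profiles:
        row = {}
        for pos in POSITIONS:
            for base in BASES:
                row[f"{base}{'' if pos == 'all' else pos}"] = prof.freq[pos][base]
            row[f"AT{'' if pos == 'all' else pos}"] = prof.at_content[pos]
        rows[prof.label] = row
    return pd.DataFrame.from_dict(rows, orient="index")
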