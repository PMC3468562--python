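"""Numt (nuclear mitochondrial pseudogene) screening for COI barcodes.

A genuine mitochondrial COI fragment is an intact protein-coding sequence:
no insertions or deletions, no internal stop codons under the invertebrate
mitochondrial genetic code (translation table 5, where TGA is Trp and
AGA/AGG are Ser), and substitutions concentrated at third codon positions.
A nuclear copy escapes coding constraint, so it betrays itself through
frameshifts, premature stops, a flattened codon-position substitution
profile and amino-acid changes.  This module screens each record against a
majority-rule consensus and reports the evidence per sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy.special import gammaln
from scipy.stats import chisquare

from .distances import count_pair, k2p
from .seq_io import BarcodeAlignment, BarcodeRecord

__all__ = [
    "NumtReport",
    "ClockParams",
    "translate",
    "consensus_record",
    "best_frame",
    "screen",
    "screen_alignment",
    "insertion_scan",
    "strip_insertions",
    "exact_multinomial_test",
    "divergence_time",
]

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
_STOPS5 = set(_TABLE5.stop_codons)  # {'TAA', 'TAG'}

#: Codon-position substitution profile of functional insect COI used as the
#: default expectation for the "suspect" test (positions 1:2:3).
DEFAULT_POSITION_PROFILE = (5.0, 1.0, 18.0)


@dataclass(frozen=True)
class ClockParams:
    """Two-rate linear clock for dating a nuclear-transfer event.

    ``substitution_rate`` applies along the functional mitochondrial
    lineage and ``pseudogene_rate`` along the nuclear copy after transfer,
    both in substitutions/site per ``time_unit``.  No default rates ship:
    the constants are a user decision.
    """

    substitution_rate: float
    pseudogene_rate: float
    time_unit: str = "year"

    def __post_init__(self) -> None:
        if self.substitution_rate <= 0 or self.pseudogene_rate <= 0:
            raise ValueError("clock rates must be positive")


@dataclass
class NumtReport:
    """Per-sequence pseudogene evidence.

    ``verdict`` is 'fail' iff a hard flag (internal stop or indel) is set,
    'suspect' when only the codon-position substitution profile is
    anomalous, else 'pass'.  ``first_stop_codon`` is 1-based.
    """

    seq_id: str
    frame_used: int
    has_internal_stop: bool
    first_stop_codon: int | None
    has_indel: bool
    codon_ratio: tuple[int, int, int]
    protein_diffs: int
    k2p_to_reference: float
    suspect_p: float | None
    verdict: str


def translate(seq: str, frame: int = 0) -> str:
    """Translate degapped nucleotides under the invertebrate mito code.

    The trailing incomplete codon is dropped; codons containing ambiguity
    are rendered 'X'; stops are '*'.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if not seq:
        raise ValueError("empty input sequence")
    s = seq.upper().replace("-", "").replace(".", "")
    s = s[frame:]
    s = s[: len(s) - len(s) % 3]
    out = []
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if codon in _STOPS5:
            out.append("*")
        elif codon in _TABLE5.forward_table:
            out.append(_TABLE5.forward_table[codon])
        else:
            out.append("X")
    return "".join(out)


def consensus_record(aln: BarcodeAlignment, seq_ids: Iterable[str] | None = None) -> BarcodeRecord:
    """Majority-rule consensus with gap as a votable state.

    Ties involving the gap state resolve to gap (a column only some members
    carry is treated as an insertion), base-only ties resolve alphabetically.
    """
    if seq_ids is not None:
        aln = aln.subset(seq_ids)
    mat = aln.matrix()
    states = ("A", "C", "G", "T", "-")
    cons = []
    for col in mat.T:
        counts = {s: int((col == s).sum()) for s in states}
        top = max(counts.values())
        winners = [s for s in states if counts[s] == top]
        cons.append("-" if "-" in winners else winners[0])
    return BarcodeRecord(seq_id="__consensus__", sequence="".join(cons))


def best_frame(seq: str, fallback: int = 0) -> int:
    """Frame (0..2) minimising internal stops; ties resolve to ``fallback``
    first, then the smallest frame."""
    stops = {}
    for f in (0, 1, 2):
        prot = translate(seq, f)
        stops[f] = prot[:-1].count("*") if prot else 0
    mn = min(stops.values())
    candidates = [f for f, s in stops.items() if s == mn]
    return fallback if fallback in candidates else min(candidates)


def exact_multinomial_test(
    counts: Sequence[int], probs: Sequence[float]
) -> float:
    """Two-sided exact multinomial goodness-of-fit p-value.

    Sums the probability of every outcome at most as probable as the
    observed one.  Falls back to the chi-square approximation above
    n = 500 draws, where enumeration is pointless and the approximation
    excellent.
    """
    counts = np.asarray(counts, dtype=int)
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    n = int(counts.sum())
    if n == 0:
        return 1.0
    if n > 500:
        expected = n * probs
        return float(chisquare(counts, expected).pvalue)

    # enumerate all compositions of n into k bins, vectorised log-pmf
    k = len(probs)
    if k != 3:
        raise NotImplementedError("exact test implemented for 3 categories")
    a = np.repeat(np.arange(n + 1), np.arange(n + 1, 0, -1))
    b = np.concatenate([np.arange(n - i + 1) for i in range(n + 1)])
    c = n - a - b
    comps = np.stack([a, b, c], axis=1)
    with np.errstate(divide="ignore"):
        logp = (
            gammaln(n + 1)
            - gammaln(comps + 1).sum(axis=1)
            + (comps * np.log(np.where(probs > 0, probs, 1))).sum(axis=1)
        )
        # categories with zero probability only allow zero counts
        impossible = (comps[:, probs == 0] > 0).any(axis=1) if (probs == 0).any() else np.zeros(len(comps), bool)
    logp[impossible] = -np.inf
    obs_idx = np.where((comps == counts).all(axis=1))[0][0]
    obs_logp = logp[obs_idx]
    pv = float(np.exp(logp[logp <= obs_logp + 1e-12]).sum())
    return min(pv, 1.0)


def _reference_codon_positions(ref: str, frame: int) -> dict[int, int]:
    """Aligned column -> codon position, numbered along the reference's
    degapped sequence so that insertion columns (reference gaps) do not
    shift the frame downstream."""
    out = {}
    d_idx = 0
    for col, ch in enumerate(ref):
        if ch not in "-.":
            out[col] = ((d_idx - frame) % 3) + 1
            d_idx += 1
    return out


def screen(
    record: BarcodeRecord,
    reference: BarcodeRecord,
    frame: int = 0,
    expected_profile: Sequence[float] = DEFAULT_POSITION_PROFILE,
    suspect_alpha: float = 0.01,
) -> NumtReport:
    """Screen one record against a (consensus) reference.

    Hard flags: an indel (gap mismatch against the reference, or degapped
    length not a multiple of 3) or an internal stop codon give verdict
    'fail'.  Without hard flags, a codon-position substitution profile that
    an exact multinomial test rejects against ``expected_profile`` at
    ``suspect_alpha`` gives 'suspect'; otherwise 'pass'.
    """
    if len(record.sequence) != len(reference.sequence):
        raise ValueError(
            f"record {record.seq_id!r} and reference lengths differ "
            f"({len(record.sequence)} vs {len(reference.sequence)})"
        )
    rec = record.sequence.upper()
    ref = reference.sequence.upper()

    gap_rec = np.array([ch in "-." for ch in rec])
    gap_ref = np.array([ch in "-." for ch in ref])
    has_indel = bool((gap_rec != gap_ref).any())
    degapped = record.degapped
    if len(degapped) % 3 != 0:
        has_indel = True

    prot = translate(degapped, frame)
    internal = prot[:-1] if prot else ""
    has_stop = "*" in internal
    first_stop = internal.index("*") + 1 if has_stop else None

    # codon-position substitution spectrum vs reference (aligned columns
    # where both are unambiguous bases; positions follow the reference's
    # degapped reading frame)
    pos_of = _reference_codon_positions(ref, frame)
    bases = set("ACGT")
    n = [0, 0, 0]
    for col, (x, y) in enumerate(zip(rec, ref)):
        if x in bases and y in bases and x != y:
            n[pos_of[col] - 1] += 1
    codon_ratio = (n[0], n[1], n[2])

    prot_ref = translate(reference.degapped, frame)
    m = min(len(prot), len(prot_ref))
    protein_diffs = sum(1 for a, b in zip(prot[:m], prot_ref[:m]) if a != b)

    try:
        d = k2p(count_pair(record, reference))
    except ValueError:
        d = float("nan")

    suspect_p = None
    verdict = "pass"
    if has_stop or has_indel:
        verdict = "fail"
    elif sum(n) > 0:
        suspect_p = exact_multinomial_test(n, expected_profile)
        if suspect_p < suspect_alpha:
            verdict = "suspect"

    return NumtReport(
        seq_id=record.seq_id,
        frame_used=frame,
        has_internal_stop=has_stop,
        first_stop_codon=first_stop,
        has_indel=has_indel,
        codon_ratio=codon_ratio,
        protein_diffs=protein_diffs,
        k2p_to_reference=d,
        suspect_p=suspect_p,
        verdict=verdict,
    )


def screen_alignment(
    aln: BarcodeAlignment,
    reference: BarcodeRecord | None = None,
    frame: int | None = None,
    grouping: Mapping[str, str] | None = None,
    expected_profile: Sequence[float] = DEFAULT_POSITION_PROFILE,
    suspect_alpha: float = 0.01,
) -> list[NumtReport]:
    """Screen every record against a majority-rule consensus.

    With ``grouping`` (seq_id -> species) each record is screened against
    its own species' consensus -- the comparison the codon-position profile
    expectation is calibrated for, since at large divergences multiple hits
    flatten the observed mismatch spectrum.  Without it (or with an explicit
    ``reference``) the dataset-wide consensus is used.  When ``frame`` is
    None the frame minimising internal stops in the reference is chosen
    (ties resolve to the alignment's frame_offset).
    """
    if reference is not None:
        refs = {None: reference}
        group_of = {r.seq_id: None for r in aln.records}
    elif grouping is not None:
        group_of = {r.seq_id: grouping[r.seq_id] for r in aln.records}
        refs = {
            g: consensus_record(aln, [s for s, gg in group_of.items() if gg == g])
            for g in set(group_of.values())
        }
    else:
        refs = {None: consensus_record(aln)}
        group_of = {r.seq_id: None for r in aln.records}
    if frame is None:
        any_ref = next(iter(refs.values()))
        frame = best_frame(any_ref.degapped, fallback=aln.frame_offset)
    return [
        screen(rec, refs[group_of[rec.seq_id]], frame, expected_profile, suspect_alpha)
        for rec in aln.records
    ]


def insertion_scan(record: BarcodeRecord, reference: BarcodeRecord) -> list[int]:
    """1-based aligned columns where the record has a residue against a
    reference gap (candidate insertions)."""
    if len(record.sequence) != len(reference.sequence):
        raise ValueError("record and reference lengths differ")
    out = []
    for col, (x, y) in enumerate(zip(record.sequence, reference.sequence), start=1):
        if x not in "-." and y in "-.":
            out.append(col)
    return out


def strip_insertions(
    record: BarcodeRecord, reference: BarcodeRecord
) -> BarcodeRecord:
    """Replace the record's insertion columns with gaps (the manual
    'delete the inserted site' follow-up), enabling a re-screen."""
    cols = set(insertion_scan(record, reference))
    seq = "".join(
        "-" if (i + 1) in cols else ch for i, ch in enumerate(record.sequence)
    )
    from dataclasses import replace as _replace

    return _replace(record, sequence=seq)


def divergence_time(d: float, params: ClockParams) -> float:
    """Time since nuclear transfer under the two-rate linear clock.

    Divergence accumulates along both lineages at their own rates, so
    T = d / (substitution_rate + pseudogene_rate); linear in d.  NaN input
    (a saturated distance) propagates.
    """
    if math.isnan(d):
        return float("nan")
    if d < 0:
        raise ValueError("distance must be nonnegative")
    return d / (params.substitution_rate + params.pseudogene_rate)
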