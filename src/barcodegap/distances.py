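"""Kimura two-parameter distances and their transition/transversion split.

For a pair of aligned sequences let L be the number of columns where both
members carry an unambiguous A/C/G/T (pairwise deletion), P = transitions/L
and Q = transversions/L.  The K2P distance and its components are

    d   = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]
    d_s = -1/2 ln(1 - 2P - Q) + 1/4 ln(1 - 2Q)      (transitions)
    d_v = -1/2 ln(1 - 2Q)                            (transversions)

with d = d_s + d_v.  When either log argument is non-positive the pair is
saturated and the distance is flagged undefined (NaN), never raised, so that
community-scale pooling can proceed with an audit count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_io import BarcodeAlignment, BarcodeRecord

__all__ = [
    "PairCounts",
    "DistanceMatrix",
    "count_pair",
    "k2p",
    "k2p_transition",
    "k2p_transversion",
    "p_distance",
    "r_value",
    "RValue",
    "pairwise_matrix",
    "pairwise_counts",
    "group_summary",
    "GroupSummary",
    "encode_alignment",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
#: purines {A,G} encode to even, pyrimidines {C,T} to odd under this order
_PURINE = np.array([True, False, True, False])

MATRIX_KINDS = ("k2p_total", "k2p_transition", "k2p_transversion", "p_distance")


@dataclass(frozen=True)
class PairCounts:
    """Per-pair valid-site, transition and transversion tallies."""

    L: int
    n_ts: int
    n_tv: int

    def __post_init__(self) -> None:
        if self.L < 0 or self.n_ts < 0 or self.n_tv < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_ts + self.n_tv > self.L:
            raise ValueError("n_ts + n_tv exceeds L")

    @property
    def P(self) -> float:
        return self.n_ts / self.L if self.L else float("nan")

    @property
    def Q(self) -> float:
        return self.n_tv / self.L if self.L else float("nan")


@dataclass
class DistanceMatrix:
    """Labeled symmetric matrix of one distance kind.

    Saturated (undefined) entries are carried as NaN; they are explicit
    flags, never silently dropped by summaries.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "k2p_total"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(self.values - self.values.T), initial=0.0)
        if asym > 1e-12:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym})")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.labels), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def undefined_pairs(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(len(self.labels), k=1)
        bad = np.isnan(self.values[iu])
        return [
            (self.labels[i], self.labels[j])
            for i, j, b in zip(iu[0], iu[1], bad)
            if b
        ]

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major order (NaN included)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            labels=list(labels), values=self.values[np.ix_(idx, idx)], kind=self.kind
        )


def encode_alignment(aln: BarcodeAlignment) -> np.ndarray:
    """(n, L) int8 array: A,C,G,T -> 0..3, gap/ambiguity -> -1."""
    mat = aln.matrix()
    out = np.full(mat.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[mat == base] = code
    return out


def _encode_seq(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype="S1").astype("U1")
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == base] = code
    return out


def count_pair(a: BarcodeRecord | str, b: BarcodeRecord | str) -> PairCounts:
    """Tally comparable sites, transitions and transversions for one pair.

    Pairwise deletion: any column where either member is a gap or a
    non-ACGT symbol is excluded from L.
    """
    sa = a.sequence if isinstance(a, BarcodeRecord) else a
    sb = b.sequence if isinstance(b, BarcodeRecord) else b
    if len(sa) != len(sb):
        raise ValueError("sequences must have equal aligned lengths")
    ea, eb = _encode_seq(sa), _encode_seq(sb)
    valid = (ea >= 0) & (eb >= 0)
    L = int(valid.sum())
    if L == 0:
        raise ValueError("no comparable sites between the pair")
    diff = valid & (ea != eb)
    # transition: both purines or both pyrimidines; parity trick on encoding
    same_class = (ea % 2) == (eb % 2)
    n_ts = int((diff & same_class).sum())
    n_tv = int(diff.sum()) - n_ts
    return PairCounts(L=L, n_ts=n_ts, n_tv=n_tv)


def _k2p_args(c: PairCounts) -> tuple[float, float]:
    return 1.0 - 2.0 * c.P - c.Q, 1.0 - 2.0 * c.Q


def k2p(c: PairCounts) -> float:
    """Total K2P distance; NaN flags saturation (log argument <= 0)."""
    w1, w2 = _k2p_args(c)
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_transition(c: PairCounts) -> float:
    w1, w2 = _k2p_args(c)
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * math.log(w1) + 0.25 * math.log(w2)


def k2p_transversion(c: PairCounts) -> float:
    _, w2 = _k2p_args(c)
    if w2 <= 0.0:
        return float("nan")
    return -0.5 * math.log(w2)


def p_distance(c: PairCounts) -> float:
    return (c.n_ts + c.n_tv) / c.L


_DIST_FUNC: dict[str, Callable[[PairCounts], float]] = {
    "k2p_total": k2p,
    "k2p_transition": k2p_transition,
    "k2p_transversion": k2p_transversion,
    "p_distance": p_distance,
}


@dataclass(frozen=True)
class RValue:
    """Mean per-pair transition/transversion count ratio."""

    value: float
    n_used: int
    n_excluded: int  # pairs with zero transversions


def r_value(pairs: Iterable[PairCounts]) -> RValue:
    """Unweighted mean of n_ts/n_tv over pairs; zero-transversion pairs
    are excluded from the mean and counted."""
    ratios = []
    excluded = 0
    for c in pairs:
        if c.n_tv == 0:
            excluded += 1
        else:
            ratios.append(c.n_ts / c.n_tv)
    if not ratios:
        raise ValueError(
            f"R undefined: all {excluded} pairs have zero transversions"
        )
    return RValue(value=float(np.mean(ratios)), n_used=len(ratios), n_excluded=excluded)


def _pair_tallies(enc: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (L, n_ts, n_tv) matrices for all pairs of encoded rows."""
    n = enc.shape[0]
    valid = enc >= 0
    same_class = enc % 2
    L = np.zeros((n, n), dtype=np.int64)
    TS = np.zeros((n, n), dtype=np.int64)
    TV = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        v = valid[i] & valid[i + 1 :]
        diff = v & (enc[i] != enc[i + 1 :])
        ts = diff & (same_class[i] == same_class[i + 1 :])
        L[i, i + 1 :] = v.sum(axis=1)
        TS[i, i + 1 :] = ts.sum(axis=1)
        TV[i, i + 1 :] = diff.sum(axis=1) - TS[i, i + 1 :]
    L += L.T
    TS += TS.T
    TV += TV.T
    np.fill_diagonal(L, valid.sum(axis=1))
    return L, TS, TV


def pairwise_counts(aln: BarcodeAlignment) -> dict[tuple[str, str], PairCounts]:
    """PairCounts for every unordered pair, keyed by (seq_id_i, seq_id_j)
    in input order."""
    enc = encode_alignment(aln)
    L, TS, TV = _pair_tallies(enc)
    ids = aln.seq_ids
    out = {}
    for i in range(len(ids) - 1):
        for j in range(i + 1, len(ids)):
            if L[i, j] == 0:
                raise ValueError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            out[(ids[i], ids[j])] = PairCounts(
                L=int(L[i, j]), n_ts=int(TS[i, j]), n_tv=int(TV[i, j])
            )
    return out


def pairwise_matrix(
    aln: BarcodeAlignment, kind: str = "k2p_total", deletion: str = "pairwise"
) -> DistanceMatrix:
    """Distance matrix over all pairs; saturated entries flagged NaN.

    ``deletion='complete'`` first drops every column containing any gap or
    ambiguity in any record, then proceeds as usual.
    """
    if kind not in _DIST_FUNC:
        raise ValueError(f"unknown distance kind {kind!r}")
    if len(aln) < 2:
        raise ValueError("need at least 2 records")
    enc = encode_alignment(aln)
    if deletion == "complete":
        keep = (enc >= 0).all(axis=0)
        if not keep.any():
            raise ValueError("complete deletion removed every column")
        enc = enc[:, keep]
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")

    Lm, TS, TV = _pair_tallies(enc)
    n = enc.shape[0]
    ids = aln.seq_ids
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(Lm > 0, TS / np.maximum(Lm, 1), np.nan)
        Q = np.where(Lm > 0, TV / np.maximum(Lm, 1), np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        if kind == "k2p_total":
            vals = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(np.abs(w1) * np.sqrt(np.abs(w2))), np.nan)
        elif kind == "k2p_transition":
            vals = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(np.abs(w1)) + 0.25 * np.log(np.abs(w2)), np.nan)
        elif kind == "k2p_transversion":
            vals = np.where(w2 > 0, -0.5 * np.log(np.abs(w2)), np.nan)
        else:  # p_distance
            vals = P + Q
    iu = np.triu_indices(n, k=1)
    zeroL = Lm[iu] == 0
    if zeroL.any():
        i, j = iu[0][zeroL][0], iu[1][zeroL][0]
        raise ValueError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
    vals = np.where(vals == 0, 0.0, vals)  # normalise -0.0 from log(1)
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(labels=list(ids), values=vals, kind=kind)


# ---------------------------------------------------------------------------
# grouped summaries (within-/between-taxon statistics and 3-category pools)
# ---------------------------------------------------------------------------

@dataclass
class GroupSummary:
    """Within-taxon, between-taxon-pair and pooled distance statistics.

    ``per_taxon`` columns: taxon, n_seqs, n_pairs, mean, max (NaN for
    singletons).  ``per_pair`` columns: taxon_a, taxon_b, n_pairs, mean, min.
    ``pools`` maps conspecific / congeneric / intergeneric to the defined
    distances in each category.  ``n_undefined`` counts NaN pairs excluded.
    """

    kind: str
    per_taxon: pd.DataFrame
    per_pair: pd.DataFrame
    pools: dict[str, np.ndarray]
    n_undefined: int

    def pool_stats(self) -> pd.DataFrame:
        rows = []
        for cat, vals in self.pools.items():
            if len(vals):
                rows.append(
                    dict(category=cat, n=len(vals), min=float(vals.min()),
                         max=float(vals.max()), mean=float(vals.mean()))
                )
            else:
                rows.append(dict(category=cat, n=0, min=np.nan, max=np.nan, mean=np.nan))
        return pd.DataFrame(rows)


def group_summary(
    m: DistanceMatrix,
    grouping: Mapping[str, str],
    genus_of: Mapping[str, str] | None = None,
) -> GroupSummary:
    """Partition pairwise distances by taxon membership.

    ``grouping`` maps every seq_id to a taxon (species); ``genus_of`` maps
    seq_id to genus (defaults to the first token of the taxon name).  The
    three pools are conspecific, congeneric-heterospecific and intergeneric;
    undefined (NaN) entries are excluded everywhere with a count.
    """
    missing = [l for l in m.labels if l not in grouping]
    if missing:
        raise ValueError(f"grouping does not cover labels: {missing[:5]}")
    taxa = np.array([grouping[l] for l in m.labels])
    if genus_of is None:
        genera = np.array([grouping[l].split()[0] for l in m.labels])
    else:
        genera = np.array([genus_of[l] for l in m.labels])

    n = len(m.labels)
    iu, ju = np.triu_indices(n, k=1)
    d = m.values[iu, ju]
    defined = ~np.isnan(d)
    n_undefined = int((~defined).sum())
    same_sp = taxa[iu] == taxa[ju]
    same_gen = genera[iu] == genera[ju]

    pools = {
        "conspecific": d[defined & same_sp],
        "congeneric": d[defined & ~same_sp & same_gen],
        "intergeneric": d[defined & ~same_gen],
    }

    taxon_rows = []
    for taxon in pd.unique(taxa):
        members = taxa == taxon
        sel = defined & same_sp & members[iu]
        vals = d[sel]
        taxon_rows.append(
            dict(
                taxon=taxon,
                n_seqs=int(members.sum()),
                n_pairs=int(sel.sum()),
                mean=float(vals.mean()) if len(vals) else np.nan,
                max=float(vals.max()) if len(vals) else np.nan,
            )
        )
    per_taxon = pd.DataFrame(taxon_rows)

    pair_rows = []
    uniq = list(pd.unique(taxa))
    for a_i in range(len(uniq) - 1):
        for b_i in range(a_i + 1, len(uniq)):
            a, b = uniq[a_i], uniq[b_i]
            sel = defined & (
                ((taxa[iu] == a) & (taxa[ju] == b))
                | ((taxa[iu] == b) & (taxa[ju] == a))
            )
            vals = d[sel]
            if not len(vals):
                continue
            pair_rows.append(
                dict(
                    taxon_a=a, taxon_b=b, n_pairs=int(sel.sum()),
                    mean=float(vals.mean()), min=float(vals.min()),
                )
            )
    per_pair = pd.DataFrame(
        pair_rows, columns=["taxon_a", "taxon_b", "n_pairs", "mean", "min"]
    )
    return GroupSummary(
        kind=m.kind, per_taxon=per_taxon, per_pair=per_pair,
        pools=pools, n_undefined=n_undefined,
    )
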