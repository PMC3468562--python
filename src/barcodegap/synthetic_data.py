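"""Synthetic COI barcode communities with known truth.

The generator emulates the divergence structure of a mosquito barcode
survey: a genus -> species -> individual hierarchy evolved under a
Kimura two-parameter substitution process with per-codon-position rate
multipliers (third positions fastest), transition/transversion bias kappa,
A+T-rich equilibrium composition (extreme at third positions), and
optionally injected numt pseudogene copies carrying frameshifts or
premature stop codons.  Every emitted sequence is covered by a truth table
(species/genus labels, true model distances, injected lesions), so each
analysis stage can be tested against programmed ground truth without any
downloads.

Depth parameters are expected pairwise distances (substitutions/site along
the connecting path); they are converted internally to the branch lengths
of the hierarchy.  Functional lineages reject stop-creating mutations, so
clean sequences are guaranteed to screen as intact coding sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .distances import DistanceMatrix
from .seq_io import BarcodeAlignment, BarcodeRecord

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "NumtTruth",
    "simulate_community",
    "simulate_pair",
    "inject_numt",
    "inject_numts",
    "split_species",
]

_BASES = "ACGT"
_STOP_CODONS = ("TAA", "TAG")  # invertebrate mito code: TGA is Trp

#: Default per-position equilibrium base frequencies (A, C, G, T).  Chosen
#: to reproduce the compositional signature of insect COI: ~69% A+T over
#: all positions, ~93% at third positions, more A (and less T) at first
#: than second positions.
DEFAULT_BASE_FREQS = (
    (0.33, 0.15, 0.27, 0.25),
    (0.20, 0.28, 0.16, 0.36),
    (0.467, 0.040, 0.026, 0.467),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for a simulated barcode community.

    Depths are expected pairwise K2P-model distances: conspecific 0.004
    (cf. observed within-species averages of ~0.4%), congeneric 0.08 and
    intergeneric 0.16 (inside the 2.3-21.8% congeneric and >=10.9%
    intergeneric ranges of mosquito COI).  kappa = alpha/beta = 1.4 gives a
    transition/transversion count ratio R ~ 0.7.  position_rates 5:1:18 is
    the codon-position substitution profile of functional COI.
    """

    n_genera: int = 5
    species_per_genus: int = 4
    individuals_per_species: int = 4
    conspecific_depth: float = 0.004
    congeneric_depth: float = 0.08
    intergeneric_depth: float = 0.16
    kappa: float = 1.4
    position_rates: tuple[float, float, float] = (5.0, 1.0, 18.0)
    base_freqs: tuple[tuple[float, float, float, float], ...] = DEFAULT_BASE_FREQS
    seq_length: int = 651
    numt_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            0.0 <= self.conspecific_depth
            < self.congeneric_depth
            < self.intergeneric_depth
        ):
            raise ValueError("depths must satisfy conspecific < congeneric < intergeneric")
        if any(r <= 0 for r in self.position_rates):
            raise ValueError("position_rates must be positive")
        for fr in self.base_freqs:
            if abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError("base_freqs must sum to 1 per position")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.seq_length < 3:
            raise ValueError("seq_length too short")


@dataclass(frozen=True)
class NumtTruth:
    """Record of one injected pseudogene lesion."""

    seq_id: str
    lesion: str                # 'stop' | 'insert' | 'delete' | 'none'
    position: int | None       # 1-based codon (stop) or column (indel)
    frame: int = 0


@dataclass
class TruthTable:
    """Programmed ground truth for a simulated community."""

    species: dict[str, str]
    genus: dict[str, str]
    true_distance: DistanceMatrix
    numts: list[NumtTruth] = field(default_factory=list)

    def numt_ids(self) -> set[str]:
        return {t.seq_id for t in self.numts if t.lesion != "none"}


# ---------------------------------------------------------------------------
# the K2P substitution process
# ---------------------------------------------------------------------------

def _k2p_probs(d: np.ndarray, kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (P_transition, P_transversion_total) after branch length d.

    With rates alpha (transition) and beta (each transversion), kappa =
    alpha/beta and d = (alpha + 2 beta) t:
        P_ts = 1/4 + 1/4 e^(-4 beta t) - 1/2 e^(-2 (alpha+beta) t)
        P_tv = 1/2 - 1/2 e^(-4 beta t)
    which plug back into the K2P estimator to recover exactly d.
    """
    bt = d / (kappa + 2.0)          # beta * t
    at = kappa * bt                 # alpha * t
    e1 = np.exp(-4.0 * bt)
    e2 = np.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.5 - 0.5 * e1
    return p_ts, p_tv


def _evolve(
    codes: np.ndarray,
    d_site: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One draw of the K2P process along a branch, site by site.

    ``codes`` uses A,C,G,T -> 0..3 (transition partner is (x+2) mod 4;
    transversion partners are the two bases of opposite parity).
    """
    p_ts, p_tv = _k2p_probs(d_site, kappa)
    u = rng.random(codes.size)
    out = codes.copy()
    ts_hit = u < p_ts
    tv_hit = (u >= p_ts) & (u < p_ts + p_tv)
    out[ts_hit] = (codes[ts_hit] + 2) % 4
    if tv_hit.any():
        pick = rng.integers(0, 2, size=int(tv_hit.sum()))
        # opposite-parity partners of x: (x+1)%4 and (x+3)%4
        step = np.where(pick == 0, 1, 3)
        out[tv_hit] = (codes[tv_hit] + step) % 4
    return out


def _codon_view(codes: np.ndarray) -> np.ndarray:
    L3 = codes.size - codes.size % 3
    return codes[:L3].reshape(-1, 3)


def _is_stop(codons: np.ndarray) -> np.ndarray:
    """Boolean per codon: TAA or TAG (codes T=3, A=0, G=2)."""
    return (codons[:, 0] == 3) & (codons[:, 1] == 0) & (
        (codons[:, 2] == 0) | (codons[:, 2] == 2)
    )


def _evolve_functional(
    codes: np.ndarray,
    d_site: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> np.ndarray:
    """Evolve a branch while rejecting outcomes that create in-frame stops."""
    child = _evolve(codes, d_site, kappa, rng)
    codons = _codon_view(child)
    bad = np.flatnonzero(_is_stop(codons))
    for idx in bad:
        sl = slice(3 * idx, 3 * idx + 3)
        for _ in range(max_tries):
            redo = _evolve(codes[sl], d_site[sl], kappa, rng)
            if not _is_stop(redo.reshape(1, 3))[0]:
                child[sl] = redo
                break
        else:  # pragma: no cover - parent codon is stop-free, so this ends
            child[sl] = codes[sl]
    return child


def _draw_root(
    length: int,
    base_freqs: Sequence[Sequence[float]],
    rng: np.random.Generator,
) -> np.ndarray:
    pos = np.arange(length) % 3
    codes = np.empty(length, dtype=np.int64)
    for p in range(3):
        sel = pos == p
        codes[sel] = rng.choice(4, size=int(sel.sum()), p=np.asarray(base_freqs[p]))
    codons = _codon_view(codes)
    for idx in np.flatnonzero(_is_stop(codons)):
        while True:
            redo = np.array(
                [rng.choice(4, p=np.asarray(base_freqs[p])) for p in range(3)]
            )
            if not _is_stop(redo.reshape(1, 3))[0]:
                codes[3 * idx : 3 * idx + 3] = redo
                break
    return codes


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _encode(seq: str) -> np.ndarray:
    lut = {b: i for i, b in enumerate(_BASES)}
    return np.array([lut[ch] for ch in seq], dtype=np.int64)


# ---------------------------------------------------------------------------
# community simulation
# ---------------------------------------------------------------------------

def simulate_community(cfg: SimulationConfig) -> tuple[BarcodeAlignment, TruthTable]:
    """Simulate a barcode community; deterministic given cfg.seed.

    Branch lengths follow from the depth parameters: individuals hang
    b_i = conspecific/2 below species ancestors, species b_s =
    (congeneric - conspecific)/2 below genus ancestors, and genera b_g =
    (intergeneric - congeneric)/2 below the root, so expected path lengths
    between individuals equal the configured depths exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    b_i = cfg.conspecific_depth / 2.0
    b_s = (cfg.congeneric_depth - cfg.conspecific_depth) / 2.0
    b_g = (cfg.intergeneric_depth - cfg.congeneric_depth) / 2.0

    mult = np.asarray(cfg.position_rates, float)
    mult = mult / mult.mean()
    d_mult = mult[np.arange(cfg.seq_length) % 3]

    root = _draw_root(cfg.seq_length, cfg.base_freqs, rng)

    records: list[BarcodeRecord] = []
    species_of: dict[str, str] = {}
    genus_of: dict[str, str] = {}
    sp_index: dict[str, int] = {}
    gen_index: dict[str, int] = {}
    counter = 0
    for g in range(cfg.n_genera):
        genus_name = f"Genus{g + 1:02d}"
        g_anc = _evolve_functional(root, b_g * d_mult, cfg.kappa, rng)
        for s in range(cfg.species_per_genus):
            sp_name = f"{genus_name} species{s + 1:02d}"
            s_anc = _evolve_functional(g_anc, b_s * d_mult, cfg.kappa, rng)
            for k in range(cfg.individuals_per_species):
                counter += 1
                seq = _evolve_functional(s_anc, b_i * d_mult, cfg.kappa, rng)
                sid = f"G{g + 1:02d}S{s + 1:02d}I{k + 1:02d}"
                records.append(
                    BarcodeRecord(
                        seq_id=sid,
                        sequence=_decode(seq),
                        species=sp_name,
                        genus=genus_name,
                        site=f"Site{(k % 3) + 1}",
                        accession=f"SYN{counter:06d}",
                    )
                )
                species_of[sid] = sp_name
                genus_of[sid] = genus_name
                sp_index[sid] = g * cfg.species_per_genus + s
                gen_index[sid] = g

    ids = [r.seq_id for r in records]
    n = len(ids)
    sp_arr = np.array([sp_index[i] for i in ids])
    gen_arr = np.array([gen_index[i] for i in ids])
    true = np.full((n, n), cfg.intergeneric_depth)
    same_gen = gen_arr[:, None] == gen_arr[None, :]
    same_sp = sp_arr[:, None] == sp_arr[None, :]
    true[same_gen] = cfg.congeneric_depth
    true[same_sp] = cfg.conspecific_depth
    np.fill_diagonal(true, 0.0)

    aln = BarcodeAlignment(records, frame_offset=0)
    truth = TruthTable(
        species=species_of,
        genus=genus_of,
        true_distance=DistanceMatrix(labels=ids, values=true, kind="true_model"),
    )

    if cfg.numt_rate > 0:
        n_numts = int(round(cfg.numt_rate * n))
        targets = rng.choice(ids, size=n_numts, replace=False)
        lesions = []
        kinds = ["stop", "insert", "delete"]
        for t, target in enumerate(sorted(targets)):
            lesions.append((target, kinds[t % 3]))
        aln, truth = inject_numts(aln, truth, lesions, rng)
    return aln, truth


def simulate_pair(
    d_true: float,
    kappa: float = 1.4,
    position_rates: tuple[float, float, float] = (1.0, 1.0, 1.0),
    length: int = 650,
    seed: int = 0,
    base_freqs: Sequence[Sequence[float]] | None = None,
) -> tuple[BarcodeRecord, BarcodeRecord]:
    """A sequence pair with expected K2P distance d_true.

    Uniform position rates by default: under rate homogeneity the plug-in
    K2P estimate of the realized pair is unbiased for d_true, which is what
    estimator-recovery tests need.  The K2P estimator saturates stochastically
    well before d = 2, so larger requests are rejected as out of domain.
    """
    if d_true < 0:
        raise ValueError("d_true must be nonnegative")
    if d_true > 2.0:
        raise ValueError("d_true beyond the K2P estimator's useful domain")
    rng = np.random.default_rng(seed)
    if base_freqs is None:
        a = rng.choice(4, size=length)
    else:
        pos = np.arange(length) % 3
        a = np.empty(length, dtype=np.int64)
        for p in range(3):
            sel = pos == p
            a[sel] = rng.choice(4, size=int(sel.sum()), p=np.asarray(base_freqs[p]))
    mult = np.asarray(position_rates, float)
    mult = mult / mult.mean()
    d_site = d_true * mult[np.arange(length) % 3]
    b = _evolve(a, d_site, kappa, rng)
    return (
        BarcodeRecord(seq_id="pair_a", sequence=_decode(a)),
        BarcodeRecord(seq_id="pair_b", sequence=_decode(b)),
    )


# ---------------------------------------------------------------------------
# numt injection
# ---------------------------------------------------------------------------

def inject_numt(
    record: BarcodeRecord,
    lesion: tuple[str, int] | str,
    rng: np.random.Generator,
    background_d: float = 0.02,
    kappa: float = 1.4,
) -> tuple[BarcodeRecord, NumtTruth]:
    """Turn one record into a numt copy.

    ``lesion`` is ('stop', codon_k), ('insert', position), ('delete',
    position) with 1-based coordinates, or 'none'.  Background substitutions
    at position-uniform relaxed rates mimic unconstrained pseudogene
    evolution.  An insertion grows the sequence by one base; the caller is
    responsible for re-gapping the surrounding alignment (see
    ``inject_numts``).
    """
    if isinstance(lesion, str):
        kind, pos = lesion, None
    else:
        kind, pos = lesion
    arr = np.array(list(record.sequence.upper()), dtype="U1")
    nongap = ~np.isin(arr, ("-", "."))
    d2a = np.flatnonzero(nongap)  # degapped index -> aligned column
    n_res = d2a.size
    codes = _encode("".join(arr[nongap]))
    codes = _evolve(codes, np.full(codes.size, background_d), kappa, rng)
    arr[nongap] = list(_decode(codes))

    # lesion coordinates are 1-based in the record's degapped sequence
    if kind == "none":
        out = "".join(arr)
    elif kind == "stop":
        if pos is None or not (1 <= pos <= n_res // 3):
            raise ValueError(f"stop codon index out of range: {pos}")
        for col, base in zip(d2a[3 * (pos - 1) : 3 * pos], "TAA"):
            arr[col] = base
        out = "".join(arr)
    elif kind == "insert":
        if pos is None or not (1 <= pos <= n_res + 1):
            raise ValueError(f"insertion position out of range: {pos}")
        col = d2a[pos - 1] if pos <= n_res else len(arr)
        new_base = _BASES[rng.integers(0, 4)]
        out = "".join(arr[:col]) + new_base + "".join(arr[col:])
    elif kind == "delete":
        if pos is None or not (1 <= pos <= n_res):
            raise ValueError(f"deletion position out of range: {pos}")
        arr[d2a[pos - 1]] = "-"
        out = "".join(arr)
    else:
        raise ValueError(f"unknown lesion kind {kind!r}")
    return (
        replace(record, sequence=out),
        NumtTruth(seq_id=record.seq_id, lesion=kind, position=pos),
    )


def inject_numts(
    aln: BarcodeAlignment,
    truth: TruthTable,
    lesions: Iterable[tuple[str, str] | tuple[str, str, int]],
    rng: np.random.Generator,
    background_d: float = 0.02,
    kappa: float = 1.4,
) -> tuple[BarcodeAlignment, TruthTable]:
    """Apply lesions to named community members, keeping the alignment valid.

    Each lesion is (seq_id, kind[, position]); positions default to the
    middle of the sequence (stop: middle codon).  Insertions add one column
    to the whole alignment (gap in every other record).
    """
    by_id = {r.seq_id: r for r in aln.records}
    new_truth = list(truth.numts)
    inserted_cols: list[int] = []  # 0-based, in current coordinates
    records = {r.seq_id: r.sequence for r in aln.records}
    L = aln.length

    for spec in lesions:
        sid, kind = spec[0], spec[1]
        pos = spec[2] if len(spec) > 2 else None
        if sid not in by_id:
            raise KeyError(sid)
        if pos is None:
            pos = (L // 6) if kind == "stop" else (L // 2)
            pos = max(pos, 1)
        rec = replace(by_id[sid], sequence=records[sid])
        mutated, t = inject_numt(rec, (kind, pos), rng, background_d, kappa)
        if kind == "insert":
            # one new column for everyone else, at the aligned column where
            # the target's degapped position ``pos`` sits
            res_cols = [i for i, ch in enumerate(records[sid]) if ch not in "-."]
            col = res_cols[pos - 1] if pos <= len(res_cols) else len(records[sid])
            for other in records:
                if other != sid:
                    s = records[other]
                    records[other] = s[:col] + "-" + s[col:]
            records[sid] = mutated.sequence
            L += 1
        else:
            records[sid] = mutated.sequence
        new_truth.append(t)

    new_records = [
        replace(r, sequence=records[r.seq_id]) for r in aln.records
    ]
    new_aln = BarcodeAlignment(new_records, frame_offset=aln.frame_offset)
    new_tt = TruthTable(
        species=truth.species,
        genus=truth.genus,
        true_distance=truth.true_distance,
        numts=new_truth,
    )
    return new_aln, new_tt


def split_species(
    aln: BarcodeAlignment,
    truth: TruthTable,
    species: str,
    extra_depth: float = 0.03,
    kappa: float = 1.4,
    position_rates: tuple[float, float, float] = (5.0, 1.0, 18.0),
    seed: int = 0,
) -> tuple[BarcodeAlignment, TruthTable]:
    """Split one species into two lineages separated by ``extra_depth``.

    Half of the species' individuals accrue extra (stop-rejected) divergence,
    emulating a cryptic-species pair hidden under one morphological name.
    The truth table's model distances from the moved individuals to all
    other sequences grow by extra_depth.
    """
    rng = np.random.default_rng(seed)
    members = [sid for sid, sp in truth.species.items() if sp == species]
    if len(members) < 2:
        raise ValueError(f"species {species!r} needs >= 2 individuals to split")
    moved = members[: len(members) // 2]
    mult = np.asarray(position_rates, float)
    mult = mult / mult.mean()
    d_site = extra_depth * mult[np.arange(aln.length) % 3]

    new_records = []
    for r in aln.records:
        if r.seq_id in moved:
            codes = _encode(r.sequence)
            codes = _evolve_functional(codes, d_site, kappa, rng)
            new_records.append(replace(r, sequence=_decode(codes)))
        else:
            new_records.append(r)

    labels = truth.true_distance.labels
    vals = truth.true_distance.values.copy()
    moved_idx = [labels.index(m) for m in moved]
    for i in moved_idx:
        vals[i, :] += extra_depth
        vals[:, i] += extra_depth
    for i in moved_idx:
        for j in moved_idx:
            vals[i, j] = truth.true_distance.values[i, j]
    np.fill_diagonal(vals, 0.0)
    new_truth = TruthTable(
        species=truth.species,
        genus=truth.genus,
        true_distance=DistanceMatrix(labels=labels, values=vals, kind="true_model"),
        numts=list(truth.numts),
    )
    return BarcodeAlignment(new_records, frame_offset=aln.frame_offset), new_truth
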