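"""Barcoding-gap species delimitation.

Pairwise distances are partitioned into conspecific, congeneric
(heterospecific, same genus) and intergeneric pools.  A 2% total-K2P
threshold separates within- from between-species divergence in mosquito
COI, and a 1.1% transversion-distance boundary refines it: species whose
maximum within-species divergence exceeds the thresholds are cryptic-species
candidates, and species pairs closer than the thresholds are synonymy
candidates (low transversion divergence between morphologically similar
species marks plesiomorphic pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import (
    DistanceMatrix,
    GroupSummary,
    PairCounts,
    count_pair,
    group_summary,
    k2p,
)
from .seq_io import BarcodeAlignment, BarcodeRecord

__all__ = [
    "Thresholds",
    "GapSummary",
    "gap_summary",
    "classify",
    "Assignment",
    "flag_taxa",
    "TaxonFlags",
    "ts_tv_curve",
    "DEFAULT_EXCLUDED_SUBGROUP",
]

#: Culex mimeticus-group taxa excluded from the headline pool statistics
#: (anomalous, possibly Wolbachia-swept barcodes); configurable.
DEFAULT_EXCLUDED_SUBGROUP = (
    "Culex mimulus",
    "Culex mimeticus",
    "Culex murrelli",
)


@dataclass(frozen=True)
class Thresholds:
    """Species-delimitation thresholds (proportions, not percent)."""

    theta_k2p: float = 0.02
    theta_tv: float = 0.011

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_tv < self.theta_k2p < 1.0):
            raise ValueError("need 0 < theta_tv < theta_k2p < 1")


@dataclass
class GapSummary:
    """Pooled distance distributions and barcoding-gap statistics.

    ``pools[kind][category]`` holds the defined distances of each category
    for kind in {k2p_total, k2p_transversion}.  The headline ratio is mean
    congeneric over mean conspecific total K2P; the pct_* fields quantify
    how cleanly the 2% threshold separates the pools.
    """

    pools: dict[str, dict[str, np.ndarray]]
    thresholds: Thresholds
    excluded_taxa: tuple[str, ...]
    n_undefined: int

    @property
    def ratio_congeneric_over_conspecific(self) -> float:
        con = self.pools["k2p_total"]["conspecific"]
        cog = self.pools["k2p_total"]["congeneric"]
        if len(con) == 0 or len(cog) == 0 or con.mean() == 0:
            return float("nan")
        return float(cog.mean() / con.mean())

    @property
    def pct_conspecific_below_theta(self) -> float:
        con = self.pools["k2p_total"]["conspecific"]
        if len(con) == 0:
            return float("nan")
        return float(100.0 * (con < self.thresholds.theta_k2p).mean())

    @property
    def pct_congeneric_above_theta(self) -> float:
        cog = self.pools["k2p_total"]["congeneric"]
        if len(cog) == 0:
            return float("nan")
        return float(100.0 * (cog > self.thresholds.theta_k2p).mean())

    def stats_frame(self) -> pd.DataFrame:
        rows = []
        for kind, cats in self.pools.items():
            for cat, vals in cats.items():
                rows.append(
                    dict(
                        kind=kind, category=cat, n=len(vals),
                        min=float(vals.min()) if len(vals) else np.nan,
                        max=float(vals.max()) if len(vals) else np.nan,
                        mean=float(vals.mean()) if len(vals) else np.nan,
                    )
                )
        return pd.DataFrame(rows)


def gap_summary(
    m_total: DistanceMatrix,
    m_tv: DistanceMatrix,
    grouping: Mapping[str, str],
    thresholds: Thresholds = Thresholds(),
    exclusions: Iterable[str] = (),
    genus_of: Mapping[str, str] | None = None,
) -> GapSummary:
    """Pool pairwise distances into the three categories.

    ``exclusions`` lists taxa removed before pooling (e.g. an anomalous
    subgroup and known cryptic-species candidates); pools use defined
    distances only, with an audit count of undefined pairs.
    """
    excluded = tuple(exclusions)
    keep = [l for l in m_total.labels if grouping[l] not in excluded]
    if len(keep) < 2:
        raise ValueError("exclusions removed (nearly) all sequences")
    sub_total = m_total.subset(keep)
    sub_tv = m_tv.subset(keep)
    pools: dict[str, dict[str, np.ndarray]] = {}
    n_undef = 0
    for m in (sub_total, sub_tv):
        gs = group_summary(m, grouping, genus_of)
        pools[m.kind] = gs.pools
        n_undef += gs.n_undefined
    return GapSummary(
        pools=pools, thresholds=thresholds,
        excluded_taxa=excluded, n_undefined=n_undef,
    )


@dataclass
class Assignment:
    """Outcome of nearest-neighbour classification for one query."""

    query_id: str
    species: str | None
    status: str  # assigned | unassigned | ambiguous
    neighbours: list[tuple[str, str, float]]  # (species, seq_id, distance), top 3
    tied_species: tuple[str, ...] = ()


def classify(
    query: BarcodeRecord,
    refs: BarcodeAlignment,
    thresholds: Thresholds = Thresholds(),
    collapse_subspecies: bool = False,
) -> Assignment:
    """Assign a query to the species of its nearest reference.

    The query must share the references' aligned coordinate system.  The
    assignment is made iff the nearest K2P distance is below theta_k2p;
    exact ties across different species give status 'ambiguous' with all
    tied species reported.  Deterministic and invariant to reference order
    (candidates are sorted by (distance, seq_id)).
    """
    species_map = refs.species_of(collapse_subspecies)
    hits: list[tuple[float, str, str]] = []
    n_undef = 0
    for ref in refs.records:
        try:
            d = k2p(count_pair(query, ref))
        except ValueError:
            d = float("nan")
        if np.isnan(d):
            n_undef += 1
            continue
        hits.append((d, ref.seq_id, species_map[ref.seq_id]))
    if not hits:
        raise ValueError(
            f"all {n_undef} reference distances undefined for {query.query_id if hasattr(query, 'query_id') else query.seq_id!r}"
        )
    hits.sort(key=lambda t: (t[0], t[1]))
    best_d = hits[0][0]
    tied = sorted({sp for d, _, sp in hits if d == best_d})
    neighbours = [(sp, sid, d) for d, sid, sp in hits[:3]]

    if best_d >= thresholds.theta_k2p:
        return Assignment(query.seq_id, None, "unassigned", neighbours)
    if len(tied) > 1:
        return Assignment(
            query.seq_id, None, "ambiguous", neighbours, tied_species=tuple(tied)
        )
    return Assignment(query.seq_id, tied[0], "assigned", neighbours)


@dataclass
class TaxonFlags:
    """Cryptic-species and synonymy candidates.

    ``cryptic`` rows: taxon, max_k2p, max_tv, strong (max transversion
    distance also above theta_tv).  ``synonymy`` rows: taxon_a, taxon_b,
    mean_k2p, mean_tv, plesiomorphic_pair (mean transversion <= theta_tv).
    """

    cryptic: pd.DataFrame
    synonymy: pd.DataFrame


def flag_taxa(
    summary_total: GroupSummary,
    summary_tv: GroupSummary,
    thresholds: Thresholds = Thresholds(),
) -> TaxonFlags:
    """Flag taxa from grouped statistics of the total-K2P and transversion
    matrices.

    Cryptic candidate: within-species MAX total K2P > theta_k2p, sub-flagged
    'strong' when the within-species max transversion distance > theta_tv.
    Synonymy candidate: between-species MEAN total K2P < theta_k2p,
    sub-flagged 'plesiomorphic pair' when the mean transversion distance is
    <= theta_tv.
    """
    tv_max = dict(zip(summary_tv.per_taxon["taxon"], summary_tv.per_taxon["max"]))
    cryptic_rows = []
    for _, row in summary_total.per_taxon.iterrows():
        if np.isnan(row["max"]):
            continue
        if row["max"] > thresholds.theta_k2p:
            mtv = tv_max.get(row["taxon"], np.nan)
            cryptic_rows.append(
                dict(
                    taxon=row["taxon"],
                    max_k2p=row["max"],
                    max_tv=mtv,
                    strong=bool(not np.isnan(mtv) and mtv > thresholds.theta_tv),
                )
            )
    cryptic = pd.DataFrame(cryptic_rows, columns=["taxon", "max_k2p", "max_tv", "strong"])

    tv_pair = {
        frozenset((a, b)): m
        for a, b, m in zip(
            summary_tv.per_pair["taxon_a"],
            summary_tv.per_pair["taxon_b"],
            summary_tv.per_pair["mean"],
        )
    }
    syn_rows = []
    for _, row in summary_total.per_pair.iterrows():
        if row["mean"] < thresholds.theta_k2p:
            mtv = tv_pair.get(frozenset((row["taxon_a"], row["taxon_b"])), np.nan)
            syn_rows.append(
                dict(
                    taxon_a=row["taxon_a"],
                    taxon_b=row["taxon_b"],
                    mean_k2p=row["mean"],
                    mean_tv=mtv,
                    plesiomorphic_pair=bool(not np.isnan(mtv) and mtv <= thresholds.theta_tv),
                )
            )
    synonymy = pd.DataFrame(
        syn_rows,
        columns=["taxon_a", "taxon_b", "mean_k2p", "mean_tv", "plesiomorphic_pair"],
    )
    return TaxonFlags(cryptic=cryptic, synonymy=synonymy)


def ts_tv_curve(
    d_total: np.ndarray,
    d_ts: np.ndarray,
    d_tv: np.ndarray,
    bins: Sequence[float] | int = 20,
) -> tuple[pd.DataFrame, float | None]:
    """Binned mean transition/transversion distances against total divergence.

    Returns (table, crossover) where ``table`` has one row per non-empty bin
    (bin_left, bin_right, n, mean_ts, mean_tv) and ``crossover`` is the left
    edge of the first bin whose mean transversion distance reaches the mean
    transition distance (None if the curves never cross).
    """
    d_total = np.asarray(d_total, float)
    d_ts = np.asarray(d_ts, float)
    d_tv = np.asarray(d_tv, float)
    ok = ~(np.isnan(d_total) | np.isnan(d_ts) | np.isnan(d_tv))
    d_total, d_ts, d_tv = d_total[ok], d_ts[ok], d_tv[ok]
    if d_total.size == 0:
        raise ValueError("no defined pairs to bin")
    edges = (
        np.histogram_bin_edges(d_total, bins=bins)
        if isinstance(bins, int)
        else np.asarray(bins, float)
    )
    idx = np.clip(np.digitize(d_total, edges) - 1, 0, len(edges) - 2)
    rows = []
    crossover = None
    for b in range(len(edges) - 1):
        sel = idx == b
        if not sel.any():
            continue
        mts, mtv = float(d_ts[sel].mean()), float(d_tv[sel].mean())
        rows.append(
            dict(bin_left=float(edges[b]), bin_right=float(edges[b + 1]),
                 n=int(sel.sum()), mean_ts=mts, mean_tv=mtv)
        )
        if crossover is None and mtv >= mts:
            crossover = float(edges[b])
    return pd.DataFrame(rows), crossover
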