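"""Barcoding-gap pooling, threshold classification and taxon flagging."""

import numpy as np
import pandas as pd
import pytest

from barcodegap.distances import (
    DistanceMatrix,
    group_summary,
    pairwise_matrix,
)
from barcodegap.gap_analysis import (
    Thresholds,
    classify,
    flag_taxa,
    gap_summary,
    ts_tv_curve,
)
from barcodegap.seq_io import BarcodeAlignment, BarcodeRecord


def matrix_from(labels, entries, kind="k2p_total"):
    n = len(labels)
    vals = np.zeros((n, n))
    for (a, b), d in entries.items():
        i, j = labels.index(a), labels.index(b)
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(labels, vals, kind)


@pytest.fixture
def two_species_matrices():
    labels = ["a1", "a2", "b1", "b2"]
    within = {("a1", "a2"): 0.005, ("b1", "b2"): 0.005}
    between = {
        (x, y): 0.08 for x in ("a1", "a2") for y in ("b1", "b2")
    }
    m_total = matrix_from(labels, {**within, **between})
    m_tv = matrix_from(
        labels,
        {k: v / 3 for k, v in {**within, **between}.items()},
        "k2p_transversion",
    )
    grouping = {"a1": "Aedes a", "a2": "Aedes a", "b1": "Aedes b", "b2": "Aedes b"}
    return m_total, m_tv, grouping


class TestThresholds:
    def test_defaults(self):
        t = Thresholds()
        assert t.theta_k2p == 0.02 and t.theta_tv == 0.011

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            Thresholds(theta_k2p=0.01, theta_tv=0.02)


class TestGapSummary:
    def test_constructed_ratio(self, two_species_matrices):
        m_total, m_tv, grouping = two_species_matrices
        gs = gap_summary(m_total, m_tv, grouping)
        con = gs.pools["k2p_total"]["conspecific"]
        cog = gs.pools["k2p_total"]["congeneric"]
        assert sorted(con) == [0.005, 0.005]
        assert len(cog) == 4 and set(cog) == {0.08}
        assert gs.ratio_congeneric_over_conspecific == pytest.approx(16.0)
        assert gs.pct_conspecific_below_theta == 100.0
        assert gs.pct_congeneric_above_theta == 100.0

    def test_all_singletons_ratio_undefined(self):
        labels = ["a", "b"]
        m = matrix_from(labels, {("a", "b"): 0.08})
        mtv = matrix_from(labels, {("a", "b"): 0.02}, "k2p_transversion")
        gs = gap_summary(m, mtv, {"a": "Aedes a", "b": "Aedes b"})
        assert len(gs.pools["k2p_total"]["conspecific"]) == 0
        assert np.isnan(gs.ratio_congeneric_over_conspecific)

    def test_exclusions_remove_taxa(self, two_species_matrices):
        m_total, m_tv, grouping = two_species_matrices
        gs = gap_summary(m_total, m_tv, grouping, exclusions=("Aedes a",))
        assert len(gs.pools["k2p_total"]["congeneric"]) == 0
        assert sorted(gs.pools["k2p_total"]["conspecific"]) == [0.005]

    def test_pools_exhaust_defined_pairs(self, community_aln, community_truth):
        m_total = pairwise_matrix(community_aln, "k2p_total")
        m_tv = pairwise_matrix(community_aln, "k2p_transversion")
        gs = gap_summary(
            m_total, m_tv, community_truth.species, genus_of=community_truth.genus
        )
        n = len(community_aln)
        pools = gs.pools["k2p_total"]
        assert sum(len(v) for v in pools.values()) == n * (n - 1) // 2


class TestClassify:
    @pytest.fixture
    def refs(self, community_aln):
        return community_aln

    def test_identical_query_assigned_at_zero(self, refs, community_truth):
        q = refs.records[0]
        query = BarcodeRecord("query", q.sequence)
        a = classify(query, refs)
        assert a.status == "assigned"
        assert a.species == community_truth.species[q.seq_id]
        assert a.neighbours[0][2] == 0.0

    def test_distant_query_unassigned(self, refs):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=refs.length))
        a = classify(BarcodeRecord("query", seq), refs)
        assert a.status == "unassigned" and a.species is None

    def test_tie_reports_ambiguous(self):
        base = "A" * 300
        refs = BarcodeAlignment(
            [
                BarcodeRecord("r1", "G" + base[1:], species="Aedes a"),
                BarcodeRecord("r2", base[:1] + "G" + base[2:], species="Aedes b"),
            ]
        )
        # query is one transition (~0.3%) from each reference
        a = classify(BarcodeRecord("q", base), refs)
        assert a.status == "ambiguous"
        assert a.tied_species == ("Aedes a", "Aedes b")

    def test_reference_order_invariance(self, refs):
        q = BarcodeRecord("query", refs.records[10].sequence)
        rev = BarcodeAlignment(list(reversed(refs.records)), frame_offset=0)
        a1, a2 = classify(q, refs), classify(q, rev)
        assert (a1.status, a1.species, a1.neighbours) == (
            a2.status, a2.species, a2.neighbours
        )

    def test_lowering_theta_never_assigns_more(self, refs):
        rng = np.random.default_rng(4)
        for _ in range(5):
            src = refs.records[rng.integers(len(refs))]
            arr = list(src.sequence)
            for pos in rng.choice(len(arr), size=12, replace=False):
                arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
            q = BarcodeRecord("q", "".join(arr))
            loose = classify(q, refs, Thresholds(0.02, 0.011))
            tight = classify(q, refs, Thresholds(0.005, 0.001))
            if loose.status == "unassigned":
                assert tight.status == "unassigned"


class TestFlagTaxa:
    def _summaries(self, labels, total_entries, tv_entries, grouping):
        m_total = matrix_from(labels, total_entries)
        m_tv = matrix_from(labels, tv_entries, "k2p_transversion")
        return (
            group_summary(m_total, grouping),
            group_summary(m_tv, grouping),
        )

    def test_cryptic_strong_candidate(self):
        # a species with within-species max K2P 2.98% and transversion 1.11%
        labels = ["d1", "d2"]
        grouping = {"d1": "Aedes dorsalis", "d2": "Aedes dorsalis"}
        st, stv = self._summaries(
            labels, {("d1", "d2"): 0.0298}, {("d1", "d2"): 0.0111}, grouping
        )
        flags = flag_taxa(st, stv)
        assert list(flags.cryptic["taxon"]) == ["Aedes dorsalis"]
        assert bool(flags.cryptic["strong"].iloc[0]) is True
        assert len(flags.synonymy) == 0

    def test_synonymy_plesiomorphic_pair(self):
        # species pair at mean K2P 1.86% / transversion 0.37%
        labels = ["m1", "s1"]
        grouping = {"m1": "Culex minor", "s1": "Culex spiculosus"}
        st, stv = self._summaries(
            labels, {("m1", "s1"): 0.0186}, {("m1", "s1"): 0.0037}, grouping
        )
        flags = flag_taxa(st, stv)
        assert len(flags.synonymy) == 1
        row = flags.synonymy.iloc[0]
        assert {row["taxon_a"], row["taxon_b"]} == {"Culex minor", "Culex spiculosus"}
        assert bool(row["plesiomorphic_pair"]) is True

    def test_low_divergence_species_unflagged(self):
        labels = ["x1", "x2", "y1"]
        grouping = {"x1": "Aedes x", "x2": "Aedes x", "y1": "Aedes y"}
        st, stv = self._summaries(
            labels,
            {("x1", "x2"): 0.005, ("x1", "y1"): 0.09, ("x2", "y1"): 0.09},
            {("x1", "x2"): 0.001, ("x1", "y1"): 0.03, ("x2", "y1"): 0.03},
            grouping,
        )
        flags = flag_taxa(st, stv)
        assert len(flags.cryptic) == 0 and len(flags.synonymy) == 0


class TestTsTvCurve:
    def test_zero_transversions_flat_curve(self):
        d = np.array([0.01, 0.02, 0.05])
        table, crossover = ts_tv_curve(d, d, np.zeros(3), bins=3)
        assert (table["mean_tv"] == 0).all()
        assert crossover is None

    def test_binned_means_match_groupby_oracle(self, community_aln):
        m_total = pairwise_matrix(community_aln, "k2p_total")
        m_ts = pairwise_matrix(community_aln, "k2p_transition")
        m_tv = pairwise_matrix(community_aln, "k2p_transversion")
        dt, ds, dv = m_total.condensed(), m_ts.condensed(), m_tv.condensed()
        edges = np.linspace(0, np.nanmax(dt) + 1e-9, 11)
        table, _ = ts_tv_curve(dt, ds, dv, bins=edges)
        df = pd.DataFrame({"d": dt, "ds": ds, "dv": dv}).dropna()
        df["bin"] = np.clip(np.digitize(df["d"], edges) - 1, 0, len(edges) - 2)
        oracle = df.groupby("bin")[["ds", "dv"]].mean()
        for _, row in table.iterrows():
            b = int(np.digitize((row["bin_left"] + row["bin_right"]) / 2, edges) - 1)
            assert row["mean_ts"] == pytest.approx(oracle.loc[b, "ds"], abs=1e-12)
            assert row["mean_tv"] == pytest.approx(oracle.loc[b, "dv"], abs=1e-12)

    def test_transversion_dominated_process_crosses(self):
        """With kappa < 1 transversions overtake transitions as divergence grows."""
        from barcodegap.distances import count_pair, k2p, k2p_transition, k2p_transversion
        from barcodegap.synthetic_data import simulate_pair

        dt, ds, dv = [], [], []
        for i, d_true in enumerate(np.linspace(0.01, 0.45, 30)):
            a, b = simulate_pair(d_true, kappa=0.4, length=900, seed=100 + i)
            c = count_pair(a, b)
            dt.append(k2p(c)); ds.append(k2p_transition(c)); dv.append(k2p_transversion(c))
        table, crossover = ts_tv_curve(np.array(dt), np.array(ds), np.array(dv), bins=6)
        assert crossover is not None
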