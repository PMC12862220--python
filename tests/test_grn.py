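"""GRN construction: peak selection, binding and footprint scores, networks."""

import numpy as np
import pandas as pd
import pytest

from biphase import grn
from biphase.config import CATEGORIES

QUI = CATEGORIES.index("Qui")
ACT = CATEGORIES.index("Act_enhancer")


def _peaks(rows):
    return pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end", "summit_offset"])


class TestSelectRegulatoryPeaks:
    def test_peak_fully_in_active_bins_kept_and_recentered(self):
        cats = {"chr1": np.full(100, ACT)}
        out = grn.select_regulatory_peaks(_peaks([("p1", "chr1", 1000, 1600, 300)]), cats)
        assert len(out) == 1
        assert (out.iloc[0].start, out.iloc[0].end) == (1200, 1400)

    def test_forty_percent_overlap_dropped(self):
        cats = {"chr1": np.full(100, QUI)}
        cats["chr1"][5] = ACT  # bins 1000..1200 active: 200/500 = 40%
        out = grn.select_regulatory_peaks(_peaks([("p1", "chr1", 1000, 1500, 100)]), cats)
        assert out.empty

    def test_overlap_fraction_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(60)
        cats = {"chr1": rng.choice([QUI, ACT, CATEGORIES.index("Pois")], size=2000)}
        active = {ACT, CATEGORIES.index("Pois")}
        peaks = _peaks([
            (f"p{i}", "chr1", int(s), int(s) + int(rng.integers(200, 1200)),
             int(rng.integers(0, 200)))
            for i, s in enumerate(rng.integers(0, 350_000, size=50))
        ])
        kept = set(grn.select_regulatory_peaks(peaks, cats).peak_id)
        for p in peaks.itertuples(index=False):
            covered = sum(
                max(0, min(p.end, (b + 1) * 200) - max(p.start, b * 200))
                for b in range(p.start // 200, -(-p.end // 200))
                if int(cats["chr1"][b]) in active
            )
            assert (covered / (p.end - p.start) >= 0.5) == (p.peak_id in kept)

    def test_summit_outside_peak_rejected(self):
        cats = {"chr1": np.full(100, ACT)}
        with pytest.raises(ValueError, match="p1"):
            grn.select_regulatory_peaks(_peaks([("p1", "chr1", 1000, 1600, 900)]), cats)


class TestBindingScore:
    def test_zero_z_gives_half(self):
        assert grn.binding_score(0.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_saturates_to_one(self):
        assert grn.binding_score(50.0, 0.0, 0.0) == pytest.approx(1.0, abs=1e-9)

    def test_strictly_monotone_in_each_input(self):
        rng = np.random.default_rng(61)
        triples = rng.normal(size=(1000, 3))
        base = grn.binding_score(triples[:, 0], triples[:, 1], triples[:, 2])
        for k in range(3):
            bumped = triples.copy()
            bumped[:, k] += 0.5
            up = grn.binding_score(bumped[:, 0], bumped[:, 1], bumped[:, 2])
            assert np.all(up > base)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            grn.binding_score(np.nan, 0.0, 0.0)


class TestFootprint:
    def test_flat_profile_scores_zero(self):
        assert grn.footprint_score(np.full(10, 3.0), 2, 4) == 0.0

    def test_arithmetic_from_definition(self):
        profile = np.array([10.0] * 4 + [5.0] * 2 + [10.0] * 4)
        assert grn.footprint_score(profile, 2, 4) == pytest.approx(5.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            grn.footprint_score(np.ones(7), 2, 4)

    def test_bimodal_threshold_separates_components(self):
        rng = np.random.default_rng(62)
        scores = np.concatenate([rng.normal(0, 0.5, 300), rng.normal(5, 0.5, 100)])
        thr = grn.bound_threshold(scores, seed=0)
        assert 1.0 < thr < 4.0

    def test_degenerate_scores_fall_back_to_quantile(self):
        rng = np.random.default_rng(63)
        scores = rng.normal(0, 0.5, 200)  # unimodal: components nearly coincide
        thr = grn.bound_threshold(scores, seed=0)
        assert thr <= np.quantile(scores, 0.95)

    def test_truncated_site_skipped_with_warning(self):
        sites = pd.DataFrame({"tf": ["t"], "chrom": ["chr1"], "start": [0], "end": [20]})
        with pytest.warns(UserWarning, match="truncated"):
            s = grn.footprint_scores_for_sites(sites, {"chr1": np.ones(100)})
        assert np.isnan(s.iloc[0])


def _domains(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _sites(rows):
    return pd.DataFrame(rows, columns=["tf", "chrom", "start", "end", "motif_score",
                                       "binding_score", "bound"])


class TestSignalNetwork:
    def test_no_sites_near_genes_gives_no_edges(self):
        sites = _sites([("tf1", "chr1", 900_000, 900_020, 10.0, 0.9, True)])
        doms = _domains([("g1", "chr1", 1000, 5000)])
        tpm = pd.Series({"tf1": 10.0, "g1": 5.0})
        assert grn.build_signal_network(sites, doms, tpm, "larva").empty

    def test_duplicate_sites_aggregate_by_mean(self):
        doms = _domains([("g1", "chr1", 1000, 5000), ("g2", "chr1", 20_000, 24_000)])
        tpm = pd.Series({"tf1": 10.0, "g1": 5.0, "g2": 7.0})
        one = _sites([("tf1", "chr1", 2000, 2020, 10.0, 0.8, True),
                      ("tf1", "chr1", 21_000, 21_020, 10.0, 0.4, True)])
        two = _sites([("tf1", "chr1", 2000, 2020, 10.0, 0.8, True),
                      ("tf1", "chr1", 2100, 2120, 10.0, 0.8, True),
                      ("tf1", "chr1", 21_000, 21_020, 10.0, 0.4, True)])
        a = grn.build_signal_network(one, doms, tpm, "larva").set_index("target")
        b = grn.build_signal_network(two, doms, tpm, "larva").set_index("target")
        pd.testing.assert_series_equal(a.probability_score, b.probability_score)

    def test_tf_without_expression_dropped_with_warning(self):
        doms = _domains([("g1", "chr1", 1000, 5000)])
        sites = _sites([("tfX", "chr1", 2000, 2020, 10.0, 0.9, True)])
        tpm = pd.Series({"g1": 5.0})
        with pytest.warns(UserWarning, match="tfX"):
            out = grn.build_signal_network(sites, doms, tpm, "larva")
        assert out.empty

    def test_planted_edges_rank_above_decoys(self, default_dataset):
        """AUC of true vs decoy candidate edges from raw z-scored site signals."""
        from sklearn.metrics import roc_auc_score

        ds = default_dataset
        scored = grn.score_sites(
            ds.motifs,
            {c: v[:, 0] for c, v in ds.tracks["larva"]["merged"].items()},
            {c: v[:, 2] for c, v in ds.tracks["larva"]["merged"].items()},
        )
        doms = grn.gene_domains(ds.genes)
        tpm_proxy = ds.counts[[c for c in ds.counts if c.startswith("larva")]].mean(axis=1)
        edges = grn.build_signal_network(scored, doms, tpm_proxy, "larva")
        truth = {tuple(e) for e in ds.manifest["true_edges"]}
        labels = [int((r.tf, r.target) in truth) for r in edges.itertuples()]
        assert 0 < sum(labels) < len(labels)
        auc = roc_auc_score(labels, edges.probability_score.values)
        assert auc >= 0.9


class TestFilterTopEdges:
    def test_scores_one_to_eight_keep_seven_and_eight(self):
        edges = pd.DataFrame({"tf": ["t"] * 8, "target": list("abcdefgh"),
                              "probability_score": np.arange(1.0, 9.0)})
        kept = grn.filter_top_edges(edges, q=0.75)
        assert sorted(kept.probability_score) == [7.0, 8.0]
        assert np.quantile(edges.probability_score, 0.75) == pytest.approx(6.25)

    def test_all_equal_scores_keep_nothing_with_warning(self):
        edges = pd.DataFrame({"tf": ["t"] * 4, "target": list("abcd"),
                              "probability_score": [0.5] * 4})
        with pytest.warns(UserWarning, match="quantile"):
            assert grn.filter_top_edges(edges).empty

    def test_retained_fraction_bounded_for_continuous_scores(self):
        rng = np.random.default_rng(64)
        for _ in range(100):
            n = int(rng.integers(4, 200))
            edges = pd.DataFrame({"tf": ["t"] * n, "target": [f"g{i}" for i in range(n)],
                                  "probability_score": rng.random(n)})
            frac = len(grn.filter_top_edges(edges)) / n
            assert frac <= 0.25 + 1 / n

    def test_matches_sortbased_oracle(self):
        rng = np.random.default_rng(65)
        scores = rng.random(500)
        edges = pd.DataFrame({"tf": ["t"] * 500, "target": [f"g{i}" for i in range(500)],
                              "probability_score": scores})
        kept = set(grn.filter_top_edges(edges).target)
        cut = np.quantile(scores, 0.75)
        expected = {f"g{i}" for i, s in enumerate(scores) if s > cut}
        assert kept == expected


class TestFootprintNetwork:
    def test_no_bound_sites_gives_empty_network(self):
        sites = _sites([("tf1", "chr1", 2000, 2020, 10.0, 0.9, False)])
        doms = _domains([("g1", "chr1", 1000, 5000)])
        assert grn.build_footprint_network(sites, doms, "larva").empty

    def test_single_bound_site_in_promoter_gives_single_edge(self):
        sites = _sites([("tf1", "chr1", 2000, 2020, 10.0, 0.9, True)])
        doms = _domains([("g1", "chr1", 1000, 5000)])
        out = grn.build_footprint_network(sites, doms, "larva")
        assert len(out) == 1 and out.iloc[0].tf == "tf1" and out.iloc[0].target == "g1"

    def test_matches_bruteforce_interval_join(self):
        rng = np.random.default_rng(66)
        doms = _domains([(f"g{i}", "chr1", int(s), int(s) + 4000)
                         for i, s in enumerate(range(0, 200_000, 10_000))])
        sites = _sites([
            (f"tf{int(rng.integers(3))}", "chr1", int(p), int(p) + 20, 10.0, 0.5,
             bool(rng.random() < 0.5))
            for p in rng.integers(0, 210_000, size=100)
        ])
        out = grn.build_footprint_network(sites, doms, "larva")
        got = set(zip(out.tf, out.target))
        expected = set()
        for s in sites.itertuples(index=False):
            if not s.bound:
                continue
            mid = (s.start + s.end) // 2
            for d in doms.itertuples(index=False):
                if s.start < d.end and d.start < s.end:
                    expected.add((s.tf, d.gene_id))
        assert got == expected


class TestCombineAndSummary:
    @staticmethod
    def _edges(pairs, evidence, stage="larva"):
        return pd.DataFrame({
            "tf": [p[0] for p in pairs], "target": [p[1] for p in pairs],
            "probability_score": [0.9] * len(pairs), "evidence": evidence, "stage": stage,
        })

    def test_disjoint_union_sums_counts(self):
        a = self._edges([("t1", "g1")], "signal")
        b = self._edges([("t2", "g2")], "footprint")
        out = grn.combine_networks(a, b, ["g1", "g2"])
        assert len(out) == 2

    def test_shared_edge_merges_evidence(self):
        a = self._edges([("t1", "g1")], "signal")
        b = self._edges([("t1", "g1")], "footprint")
        out = grn.combine_networks(a, b, ["g1"])
        assert len(out) == 1
        assert out.iloc[0].evidence == "footprint,signal"

    def test_intersection_mode(self):
        a = self._edges([("t1", "g1"), ("t1", "g2")], "signal")
        b = self._edges([("t1", "g1")], "footprint")
        out = grn.combine_networks(a, b, ["g1", "g2"], mode="intersection")
        assert list(zip(out.tf, out.target)) == [("t1", "g1")]

    def test_empty_target_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grn.combine_networks(self._edges([], "signal"), self._edges([], "footprint"), [])

    def test_outdegree_counts_distinct_targets(self):
        edges = self._edges([("t1", "g1"), ("t1", "g2"), ("t1", "g3"), ("t1", "g3")], "signal")
        s = grn.network_summary({"larva": edges, "adult": edges})
        assert s.outdegree["larva"]["t1"] == 3
        assert s.shared_fraction == 1.0

    def test_shared_set_is_bruteforce_intersection(self):
        rng = np.random.default_rng(67)
        tfs = [f"t{i}" for i in range(10)]
        nets = {}
        for stage in ("larva", "adult"):
            pairs = [(rng.choice(tfs), f"g{int(rng.integers(20))}") for _ in range(30)]
            nets[stage] = self._edges(pairs, "signal", stage)
        s = grn.network_summary(nets)
        assert s.shared_tfs == set(nets["larva"].tf) & set(nets["adult"].tf)
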