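"""Region annotation, window-level differential signal, and gene linkage."""

import numpy as np
import pandas as pd
import pytest

from biphase import linkage
from biphase.config import MARKS


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "is_tf"])


def _regions(rows):
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


class TestAnnotateRegions:
    GENES = _genes([
        ("g1", "chr1", 50_000, 56_000, "+", False),
        ("g2", "chr1", 300_000, 304_000, "-", False),
    ])

    def test_region_in_upstream_promoter_window(self):
        out = linkage.annotate_regions(_regions([("r1", "chr1", 49_500, 49_900)]), self.GENES)
        assert out.iloc[0].feature == "promoter"
        assert out.iloc[0].nearest_gene == "g1"

    def test_region_in_gene_body_beyond_tss_offset(self):
        out = linkage.annotate_regions(_regions([("r1", "chr1", 52_000, 52_500)]), self.GENES)
        assert out.iloc[0].feature == "genic"

    def test_far_region_gets_none(self):
        out = linkage.annotate_regions(_regions([("r1", "chr1", 700_000, 700_400)]), self.GENES)
        assert out.iloc[0].feature == "none"
        assert out.iloc[0].distance_bp > 100_000

    def test_distal_within_cutoff(self):
        out = linkage.annotate_regions(_regions([("r1", "chr1", 150_000, 150_400)]), self.GENES)
        assert out.iloc[0].feature == "distal"

    def test_minus_strand_promoter_is_above_end(self):
        out = linkage.annotate_regions(_regions([("r1", "chr1", 304_500, 305_000)]), self.GENES)
        assert out.iloc[0].feature == "promoter"
        assert out.iloc[0].nearest_gene == "g2"

    def test_promoter_precedence_over_genic(self):
        # overlaps both g1's genic span and g1's promoter window
        out = linkage.annotate_regions(_regions([("r1", "chr1", 49_900, 51_000)]), self.GENES)
        assert out.iloc[0].feature == "promoter"

    def test_matches_bruteforce_oracle_on_random_toys(self):
        rng = np.random.default_rng(21)
        genes = _genes([
            (f"g{i}", "chr1", int(s), int(s) + int(rng.integers(1000, 5000)),
             "+" if rng.random() < 0.5 else "-", False)
            for i, s in enumerate(np.sort(rng.integers(20_000, 900_000, size=12)))
        ])
        regions = _regions([
            (f"r{i}", "chr1", int(p), int(p) + int(rng.integers(100, 2000)))
            for i, p in enumerate(rng.integers(0, 1_100_000, size=120))
        ])
        got = linkage.annotate_regions(regions, genes)

        def oracle(start, end):
            best = ("none", "", np.inf)
            for row in genes.itertuples(index=False):
                p0, p1 = linkage.promoter_interval(row)
                if start < p1 and p0 < end:
                    d = abs((row.start if row.strand == "+" else row.end) - (start + end) / 2)
                    if best[0] != "promoter" or d < best[2]:
                        best = ("promoter", row.gene_id, d)
            if best[0] == "promoter":
                return best[0]
            for row in genes.itertuples(index=False):
                g0, g1 = linkage.genic_interval(row)
                if start < g1 and g0 < end:
                    return "genic"
            dmin = min(
                0 if (start < row.end and row.start < end)
                else (row.start - end if end <= row.start else start - row.end)
                for row in genes.itertuples(index=False)
            )
            return "distal" if dmin <= 100_000 else "none"

        for region, feature in zip(regions.itertuples(index=False), got.feature):
            assert feature == oracle(region.start, region.end)

    def test_shuffled_input_gives_identical_results(self):
        rng = np.random.default_rng(22)
        regions = _regions([
            (f"r{i}", "chr1", int(p), int(p) + 500)
            for i, p in enumerate(rng.integers(0, 500_000, size=40))
        ])
        a = linkage.annotate_regions(regions, self.GENES).set_index("region_id")
        b = linkage.annotate_regions(
            regions.sample(frac=1, random_state=1), self.GENES
        ).set_index("region_id")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())


def _toy_tracks(rng, genes, n_bins, rates_by_stage, n_rep=3, bin_bp=200):
    """Poisson replicate tracks with per-stage per-bin ATAC rates (other marks flat)."""
    tracks = {}
    for stage, rate in rates_by_stage.items():
        reps = []
        for _ in range(n_rep):
            arr = rng.poisson(5.0, size=(n_bins, 4)).astype(float)
            arr[:, 0] = rng.poisson(rate)
            reps.append({"chr1": arr})
        tracks[stage] = reps
    return tracks


class TestWindowSignalChange:
    def test_identical_replicates_yield_no_significant_genes(self):
        genes = _genes([(f"g{i}", "chr1", 10_000 + 20_000 * i, 14_000 + 20_000 * i, "+", False)
                        for i in range(5)])
        rng = np.random.default_rng(30)
        reps = [{"chr1": rng.poisson(4.0, size=(600, 4)).astype(float)} for _ in range(3)]
        tracks = {"larva": reps, "adult": [{c: a.copy() for c, a in r.items()} for r in reps]}
        out = linkage.window_signal_change(tracks, genes)
        assert not out.significant.any()

    def test_planted_eightfold_atac_increase_detected(self):
        """50 planted windows among 200 (TMM needs a majority unchanged)."""
        rng = np.random.default_rng(31)
        genes = _genes([(f"g{i}", "chr1", 10_000 + 10_000 * i, 13_000 + 10_000 * i, "+", False)
                        for i in range(200)])
        n_bins = 10_100
        base = np.full(n_bins, 2.0)
        boosted = base.copy()
        planted = set(range(50))
        for i in planted:  # window bins of the first 50 genes
            b0 = (10_000 + 10_000 * i - 5000) // 200
            b1 = -(-(13_000 + 10_000 * i) // 200)
            boosted[b0:b1] *= 8.0
        tracks = _toy_tracks(rng, genes, n_bins, {"larva": base, "adult": boosted})
        out = linkage.window_signal_change(tracks, genes)
        atac = out[out["mark"] == "ATAC"].set_index("gene_id")
        hits = atac[atac.significant & (atac.log2fc > 0)]
        assert sum(f"g{i}" in hits.index for i in planted) >= 45
        null_sig = atac.loc[[f"g{i}" for i in range(50, 200)]].significant
        assert null_sig.mean() <= 0.1

    def test_swapping_stage_labels_negates_log2fc(self):
        rng = np.random.default_rng(32)
        genes = _genes([("g0", "chr1", 10_000, 13_000, "+", False)])
        tracks = _toy_tracks(rng, genes, 100, {"larva": np.full(100, 3.0),
                                               "adult": np.full(100, 9.0)})
        fwd = linkage.window_signal_change(tracks, genes, contrast=("adult", "larva"))
        rev = linkage.window_signal_change(tracks, genes, contrast=("larva", "adult"))
        np.testing.assert_allclose(fwd.log2fc.values, -rev.log2fc.values, atol=1e-12)


def _de(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "log2fc", "p_value", "fdr", "enriched_class"]
    ).set_index("gene_id")


def _changes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "mark", "log2fc", "fdr", "significant",
                                       "not_tested"])


class TestLinkEnrichedGenes:
    def test_larva_enriched_gene_with_larva_high_k4_only(self):
        de = _de([("g1", -2.0, 1e-4, 1e-3, "larva_enriched")])
        ch = _changes([
            ("g1", "ATAC", 0.1, 0.9, False, False),
            ("g1", "H3K4me3", -1.5, 0.01, True, False),
            ("g1", "H3K27ac", 0.0, 1.0, False, False),
            ("g1", "H3K27me3", 0.0, 1.0, False, False),
        ])
        out = linkage.link_enriched_genes(de, ch)
        row = out.iloc[0]
        assert row.linkage == "active"
        assert row["H3K4me3"] and not row["ATAC"] and not row["H3K27ac"]

    def test_enriched_gene_with_no_significant_feature_unlinked(self):
        de = _de([("g1", 2.0, 1e-4, 1e-3, "adult_enriched")])
        ch = _changes([("g1", m, 0.5, 0.5, False, False) for m in MARKS])
        assert linkage.link_enriched_genes(de, ch).iloc[0].linkage == "unlinked"

    def test_repressive_mark_higher_in_opposite_stage_links(self):
        de = _de([("g1", -2.0, 1e-4, 1e-3, "larva_enriched")])
        ch = _changes([("g1", m, 0.0, 1.0, False, False) for m in MARKS[:3]]
                      + [("g1", "H3K27me3", 1.4, 0.01, True, False)])
        assert linkage.link_enriched_genes(de, ch).iloc[0].linkage == "repressive_only"

    def test_gene_missing_from_changes_flagged(self):
        de = _de([("g1", 2.0, 1e-4, 1e-3, "adult_enriched")])
        ch = _changes([("g2", m, 0.0, 1.0, False, False) for m in MARKS])
        row = linkage.link_enriched_genes(de, ch).iloc[0]
        assert row.linkage == "unlinked" and row.missing_changes

    def test_twelve_gene_toy_membership_matches_enumeration(self):
        """Hand-enumerated memberships over a constructed 12-gene set."""
        rng = np.random.default_rng(40)
        rows_de, rows_ch, expected = [], [], {}
        for i in range(12):
            g = f"g{i}"
            stage_sign = -1.0 if i % 2 == 0 else 1.0      # even: larva-enriched
            cls = "larva_enriched" if stage_sign < 0 else "adult_enriched"
            rows_de.append((g, 2 * stage_sign, 1e-4, 1e-3, cls))
            member = set()
            for j, m in enumerate(MARKS[:3]):
                sig = (i + j) % 3 == 0
                lfc = stage_sign * 1.0 if sig else 0.0
                rows_ch.append((g, m, lfc, 0.01 if sig else 0.9, sig, False))
                if sig:
                    member.add(m)
            rep_sig = i % 4 == 0
            rows_ch.append((g, "H3K27me3", -stage_sign * 1.0 if rep_sig else 0.0,
                            0.01 if rep_sig else 0.9, rep_sig, False))
            if rep_sig:
                member.add("H3K27me3")
            expected[g] = member
        out = linkage.link_enriched_genes(_de(rows_de), _changes(rows_ch)).set_index("gene_id")
        for g, member in expected.items():
            got = {m for m in MARKS if out.loc[g, m]}
            assert got == member
            if member & set(MARKS[:3]):
                assert out.loc[g, "linkage"] == "active"
            elif member:
                assert out.loc[g, "linkage"] == "repressive_only"
            else:
                assert out.loc[g, "linkage"] == "unlinked"

    def test_summary_fractions_sum_to_one(self):
        de = _de([("g1", -2.0, 1e-4, 1e-3, "larva_enriched"),
                  ("g2", 2.0, 1e-4, 1e-3, "adult_enriched")])
        ch = _changes([("g1", m, -1.0, 0.01, True, False) for m in MARKS[:3]]
                      + [("g1", "H3K27me3", 0.0, 1.0, False, False)]
                      + [("g2", m, 0.0, 1.0, False, False) for m in MARKS])
        s = linkage.linkage_summary(linkage.link_enriched_genes(de, ch))
        assert s.sum() == pytest.approx(1.0)
        assert s["active"] == pytest.approx(0.5)


class TestExpressionMarkCorrelation:
    def test_identical_vectors_give_r_one(self):
        de = _de([(f"g{i}", v, 0.5, 0.5, "not_significant")
                  for i, v in enumerate([1.0, -2.0, 0.5, 3.0])])
        ch = _changes([(f"g{i}", "H3K4me3", v, 0.5, False, False)
                       for i, v in enumerate([1.0, -2.0, 0.5, 3.0])])
        r, p = linkage.expression_mark_correlation(de, ch, "H3K4me3")
        assert r == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(50)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        de = _de([(f"g{i}", v, 0.5, 0.5, "not_significant") for i, v in enumerate(x)])
        ch = _changes([(f"g{i}", "ATAC", v, 0.5, False, False) for i, v in enumerate(y)])
        r, _ = linkage.expression_mark_correlation(de, ch, "ATAC")
        expect = np.sum((x - x.mean()) * (y - y.mean())) / (
            np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
        )
        assert r == pytest.approx(expect, abs=1e-12)

    def test_independent_vectors_rarely_correlated(self):
        rng = np.random.default_rng(51)
        hits = 0
        for _ in range(100):
            x, y = rng.normal(size=1000), rng.normal(size=1000)
            r = np.corrcoef(x, y)[0, 1]
            hits += abs(r) < 0.1
        assert hits >= 95

    def test_zero_variance_rejected(self):
        de = _de([(f"g{i}", 1.0, 0.5, 0.5, "not_significant") for i in range(5)])
        ch = _changes([(f"g{i}", "ATAC", float(i), 0.5, False, False) for i in range(5)])
        with pytest.raises(ValueError, match="zero variance"):
            linkage.expression_mark_correlation(de, ch, "ATAC")
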