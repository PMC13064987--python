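"""Consensus TE calling: support rules, merging, windowing, uniqueness."""

import numpy as np
import pandas as pd
import pytest

from teregulon import te_consensus as tc

from conftest import make_calls


def make_status(statuses, te_id="rte1"):
    return pd.DataFrame([
        {"te_id": te_id, "sample_id": f"s{i + 1}", "chrom": "chr1",
         "start": 100, "end": 600, "family": "roo", "status": st}
        for i, st in enumerate(statuses)
    ])


class TestReferenceConsensus:
    @pytest.mark.parametrize("statuses,retained", [
        (("present", "present", "present"), True),
        (("present", "polymorphic", "present"), True),
        (("polymorphic", "polymorphic", "polymorphic"), True),
        (("present", "absent", "present"), False),
        (("absent", "absent", "absent"), False),
    ])
    def test_all_samples_rule(self, statuses, retained):
        out = tc.consolidate_reference_tes(make_status(statuses), ["s1", "s2", "s3"])
        assert (len(out) == 1) == retained
        if retained:
            assert out.iloc[0]["te_type"] == "reference"
            assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (100, 600)

    def test_missing_status_excludes_with_warning(self, caplog):
        status = make_status(("present", "present"))
        with caplog.at_level("WARNING"):
            out = tc.consolidate_reference_tes(status, ["s1", "s2", "s3"])
        assert len(out) == 0
        assert "no status" in caplog.text

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="unknown sample"):
            tc.consolidate_reference_tes(make_status(("present",)), ["sX"])


class TestNonReferenceConsensus:
    def test_cross_caller_merge_within_distance(self):
        a = make_calls("A", [("s1", "chr1", 1000, 1050, "roo"),
                             ("s2", "chr1", 1000, 1050, "roo")])
        b = make_calls("B", [("s1", "chr1", 1060, 1100, "roo"),
                             ("s3", "chr1", 1060, 1100, "roo")])
        out = tc.consolidate_nonreference_tes(a, b)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["start"], row["end"]) == (1000, 1100)
        assert tc.parse_support(row["support"]) == {"A": 2, "B": 2}

    def test_family_mismatch_never_merges(self):
        a = make_calls("A", [("s1", "chr1", 1000, 1050, "roo"),
                             ("s2", "chr1", 1000, 1050, "roo")])
        b = make_calls("B", [("s1", "chr1", 1000, 1050, "jockey"),
                             ("s2", "chr1", 1000, 1050, "jockey")])
        assert len(tc.consolidate_nonreference_tes(a, b)) == 0

    def test_min_sample_support_required_from_both_callers(self):
        a = make_calls("A", [("s1", "chr1", 1000, 1050, "roo"),
                             ("s2", "chr1", 1000, 1050, "roo")])
        b = make_calls("B", [("s1", "chr1", 1000, 1050, "roo")])
        assert len(tc.consolidate_nonreference_tes(a, b)) == 0
        b2 = make_calls("B", [("s1", "chr1", 1000, 1050, "roo"),
                              ("s3", "chr1", 1010, 1060, "roo")])
        assert len(tc.consolidate_nonreference_tes(a, b2)) == 1

    def test_gap_beyond_merge_distance_not_merged(self):
        a = make_calls("A", [("s1", "chr1", 1000, 1050, "roo"),
                             ("s2", "chr1", 1000, 1050, "roo")])
        b = make_calls("B", [("s1", "chr1", 1076, 1120, "roo"),
                             ("s2", "chr1", 1076, 1120, "roo")])
        assert len(tc.consolidate_nonreference_tes(a, b)) == 0
        b_edge = make_calls("B", [("s1", "chr1", 1075, 1120, "roo"),
                                  ("s2", "chr1", 1075, 1120, "roo")])
        assert len(tc.consolidate_nonreference_tes(a, b_edge)) == 1

    def test_family_comparison_case_folds(self):
        a = make_calls("A", [("s1", "chr1", 1000, 1050, "Roo"),
                             ("s2", "chr1", 1000, 1050, "roo ")])
        b = make_calls("B", [("s1", "chr1", 1000, 1050, "ROO"),
                             ("s2", "chr1", 1000, 1050, "roo")])
        assert len(tc.consolidate_nonreference_tes(a, b)) == 1

    def test_negative_length_interval_rejected(self):
        a = make_calls("A", [("s1", "chr1", 1050, 1050, "roo")])
        b = make_calls("B", [("s1", "chr1", 1000, 1050, "roo")])
        with pytest.raises(ValueError, match="non-positive length"):
            tc.consolidate_nonreference_tes(a, b)

    def test_off_annotation_chromosome_flagged_not_dropped(self):
        a = make_calls("A", [("s1", "chrU", 1000, 1050, "roo"),
                             ("s2", "chrU", 1000, 1050, "roo")])
        b = make_calls("B", [("s1", "chrU", 1000, 1050, "roo"),
                             ("s2", "chrU", 1000, 1050, "roo")])
        out = tc.consolidate_nonreference_tes(a, b, known_chroms={"chr1"})
        assert len(out) == 1 and bool(out.iloc[0]["off_annotation"])

    def test_permutation_invariance_and_idempotence(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(60):
            start = int(rng.integers(0, 50_000))
            rows.append((f"s{rng.integers(1, 4)}", "chr1", start,
                         start + int(rng.integers(20, 200)),
                         str(rng.choice(["roo", "jockey"]))))
        a = make_calls("A", rows)
        b = make_calls("B", [(s, c, st + 5, en + 5, f) for s, c, st, en, f in rows])
        base = tc.consolidate_nonreference_tes(a, b)
        for seed in range(3):
            perm = np.random.default_rng(seed).permutation(len(a))
            shuffled = tc.consolidate_nonreference_tes(
                a.iloc[perm].reset_index(drop=True),
                b.iloc[perm].reset_index(drop=True),
            )
            pd.testing.assert_frame_equal(base, shuffled)

    def test_within_caller_merge_monotone_in_distance(self):
        # larger merge distance can only coalesce more calls per caller
        rng = np.random.default_rng(3)
        rows = []
        for i in range(80):
            start = int(rng.integers(0, 20_000))
            rows.append((f"s{rng.integers(1, 4)}", "chr1", start,
                         start + int(rng.integers(20, 120)), "roo"))
        calls = make_calls("A", rows)
        sizes = [len(tc._merge_caller_calls(calls, d))
                 for d in (0, 10, 25, 100, 1000)]
        assert sizes == sorted(sizes, reverse=True)

    def test_lowering_min_samples_never_shrinks_consensus(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(80):
            start = int(rng.integers(0, 20_000))
            rows.append((f"s{rng.integers(1, 4)}", "chr1", start,
                         start + int(rng.integers(20, 120)), "roo"))
        a = make_calls("A", rows)
        b = make_calls("B", [(s, c, st + 8, en + 8, f) for s, c, st, en, f in rows])
        by_min = [len(tc.consolidate_nonreference_tes(a, b, min_samples=m))
                  for m in (3, 2, 1)]
        assert by_min == sorted(by_min)

    def test_consensus_intervals_exhaustively_merged(self):
        out_rows = []
        rng = np.random.default_rng(11)
        rows = [(f"s{1 + i % 3}", "chr1", int(p), int(p) + 40, "roo")
                for i, p in enumerate(rng.integers(0, 5_000, size=50))]
        a = make_calls("A", rows)
        b = make_calls("B", rows)
        out = tc.consolidate_nonreference_tes(a, b)
        out = out.sort_values("start").reset_index(drop=True)
        gaps = out["start"].iloc[1:].to_numpy() - out["end"].iloc[:-1].to_numpy()
        assert (gaps > 25).all()


class TestWindowAnnotation:
    def test_upstream_link_plus_strand(self, genes_df):
        tes = pd.DataFrame([{"te_id": "t1", "population": "p", "te_type": "non_reference",
                             "chrom": "chr1", "start": 9_400, "end": 9_500,
                             "family": "roo", "support": "", "off_annotation": False}])
        links = tc.annotate_te_gene_links(tes, genes_df)
        row = links[links["gene_id"] == "gA"].iloc[0]
        assert row["relative_position"] == "upstream" and row["distance"] == 500

    def test_outside_window_not_linked(self, genes_df):
        tes = pd.DataFrame([{"te_id": "t1", "population": "p", "te_type": "non_reference",
                             "chrom": "chr1", "start": 8_400, "end": 8_500,
                             "family": "roo", "support": "", "off_annotation": False}])
        assert len(tc.annotate_te_gene_links(tes, genes_df)) == 0

    def test_exactly_window_distance_is_linked(self, genes_df):
        tes = pd.DataFrame([{"te_id": "t1", "population": "p", "te_type": "non_reference",
                             "chrom": "chr1", "start": 8_900, "end": 9_000,
                             "family": "roo", "support": "", "off_annotation": False}])
        links = tc.annotate_te_gene_links(tes, genes_df, window=1000)
        assert list(links["distance"]) == [1000]

    def test_minus_strand_three_prime_overlap_is_ds_ovlp(self, genes_df):
        # gB is minus strand on [30000, 33000): its 3' boundary is the left end
        tes = pd.DataFrame([{"te_id": "t1", "population": "p", "te_type": "non_reference",
                             "chrom": "chr1", "start": 29_900, "end": 30_100,
                             "family": "roo", "support": "", "off_annotation": False}])
        links = tc.annotate_te_gene_links(tes, genes_df)
        row = links[links["gene_id"] == "gB"].iloc[0]
        assert row["relative_position"] == "ds_ovlp" and row["distance"] == 0

    def test_containment_is_genic(self, genes_df):
        tes = pd.DataFrame([{"te_id": "t1", "population": "p", "te_type": "non_reference",
                             "chrom": "chr1", "start": 10_500, "end": 10_800,
                             "family": "roo", "support": "", "off_annotation": False}])
        assert tc.annotate_te_gene_links(tes, genes_df).iloc[0]["relative_position"] == "genic"

    def test_equidistant_te_links_both_genes(self):
        genes = pd.DataFrame({
            "gene_id": ["gL", "gR"], "chrom": ["chr1", "chr1"],
            "start": [1_000, 3_000], "end": [1_500, 3_500], "strand": ["+", "+"],
        })
        tes = pd.DataFrame([{"te_id": "t1", "population": "p", "te_type": "non_reference",
                             "chrom": "chr1", "start": 2_200, "end": 2_300,
                             "family": "roo", "support": "", "off_annotation": False}])
        links = tc.annotate_te_gene_links(tes, genes, window=1000)
        assert sorted(links["gene_id"]) == ["gL", "gR"]

    def test_matches_bruteforce_all_pairs_scan(self):
        # equivalence with an independent all-pairs distance computation
        rng = np.random.default_rng(123)
        for _ in range(10):
            genes = pd.DataFrame({
                "gene_id": [f"g{i}" for i in range(30)],
                "chrom": rng.choice(["chr1", "chr2"], size=30),
                "start": (s := rng.integers(0, 40_000, size=30)),
                "end": s + rng.integers(200, 3_000, size=30),
                "strand": rng.choice(["+", "-"], size=30),
            })
            tes = pd.DataFrame({
                "te_id": [f"t{i}" for i in range(40)],
                "population": "p", "te_type": "non_reference",
                "chrom": rng.choice(["chr1", "chr2"], size=40),
                "start": (ts := rng.integers(0, 40_000, size=40)),
                "end": ts + rng.integers(50, 2_000, size=40),
                "family": "roo", "support": "", "off_annotation": False,
            })
            got = tc.annotate_te_gene_links(tes, genes, window=1000)
            got_set = set(zip(got["te_id"], got["gene_id"], got["distance"]))
            expected = set()
            for te in tes.itertuples():
                for g in genes.itertuples():
                    if te.chrom != g.chrom:
                        continue
                    if te.end <= g.start:
                        gap = g.start - te.end
                    elif te.start >= g.end:
                        gap = te.start - g.end
                    else:
                        gap = 0
                    if gap <= 1000:
                        expected.add((te.te_id, g.gene_id, gap))
            assert got_set == expected


class TestPopulationUnique:
    def _te(self, te_id, start, end, family="roo", chrom="chr1"):
        return {"te_id": te_id, "population": "p", "te_type": "non_reference",
                "chrom": chrom, "start": start, "end": end, "family": family,
                "support": "", "off_annotation": False}

    def test_exact_match_not_unique(self):
        t1 = pd.DataFrame([self._te("a", 100, 200)])
        t2 = pd.DataFrame([self._te("b", 100, 200)])
        o1, o2 = tc.label_population_unique(t1, t2)
        assert not o1.iloc[0]["population_unique"]
        assert not o2.iloc[0]["population_unique"]

    def test_no_counterpart_is_unique(self):
        t1 = pd.DataFrame([self._te("a", 100, 200)])
        t2 = pd.DataFrame([self._te("b", 10_000, 10_100)])
        o1, o2 = tc.label_population_unique(t1, t2)
        assert o1.iloc[0]["population_unique"] and o2.iloc[0]["population_unique"]

    def test_within_match_distance_is_shared(self):
        t1 = pd.DataFrame([self._te("a", 100, 200)])
        t2 = pd.DataFrame([self._te("b", 220, 320)])  # 20 bp gap
        o1, o2 = tc.label_population_unique(t1, t2, match_distance=25)
        assert not o1.iloc[0]["population_unique"]
        assert not o2.iloc[0]["population_unique"]

    def test_family_mismatch_is_unique(self):
        t1 = pd.DataFrame([self._te("a", 100, 200, family="roo")])
        t2 = pd.DataFrame([self._te("b", 100, 200, family="jockey")])
        o1, o2 = tc.label_population_unique(t1, t2)
        assert o1.iloc[0]["population_unique"] and o2.iloc[0]["population_unique"]
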