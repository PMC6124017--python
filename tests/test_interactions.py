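import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import hypergeom

from chromage.genome_io import FragmentMap, GenomeError
from chromage.interactions import (
    InteractionSet,
    assign_fragment_states,
    call_rewiring,
    classify_ends,
    fragment_active,
    fragment_state,
    pir_enrichment,
    rewiring_by_gene_category,
    rewiring_status,
    virtual_4c,
)

STATES = ["polycomb", "bivalent", "active_promoter", "active_regulatory",
          "insulator", "background"]


def fragmap(n=10, size=1_000, baited=(0,)):
    df = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * size,
        "end": (np.arange(n) + 1) * size,
        "frag_id": [f"f{i}" for i in range(n)],
        "baited": [i in baited for i in range(n)],
    })
    return FragmentMap(df)


def iset(rows, fm=None, bait_genes=None):
    fm = fm or fragmap(baited=(0, 1))
    table = pd.DataFrame(rows, columns=["bait_id", "other_id", "score_young",
                                        "score_aged", "distance"])
    return InteractionSet(table, fm, bait_genes=bait_genes or {})


class TestClassifyEnds:
    def test_both_baited_is_promoter_promoter(self):
        s = iset([("f0", "f1", 6.0, 6.0, 1_000)])
        assert classify_ends(s).tolist() == ["promoter:promoter"]

    def test_one_baited_is_promoter_pir(self):
        s = iset([("f0", "f5", 6.0, 6.0, 5_000)])
        assert classify_ends(s).tolist() == ["promoter:PIR"]

    def test_unbaited_bait_end_rejected(self):
        with pytest.raises(GenomeError, match="baited"):
            iset([("f5", "f6", 6.0, 6.0, 1_000)])


class TestRewiring:
    @pytest.mark.parametrize("sy,sa,expect", [
        (7.2, 2.0, "lost"),
        (4.9, 5.1, "stable-significant"),  # delta 0.2 < 2
        (2.0, 7.2, "gained"),
        (6.0, 8.0, "stable-significant"),
        (1.0, 2.0, "never-significant"),
        (5.0, 0.0, "lost"),  # boundary: threshold and delta exactly met
        (0.0, 5.0, "gained"),
        (7.0, 4.99, "lost"),  # delta 2.01, only young significant
        (6.9, 4.99, "stable-significant"),  # delta 1.91 < 2
    ])
    def test_rule_examples(self, sy, sa, expect):
        assert rewiring_status(sy, sa) == expect

    def test_grid_matches_exhaustive_rule_and_antisymmetry(self):
        grid = np.arange(0, 10.5, 0.5)
        for sy, sa in itertools.product(grid, grid):
            got = rewiring_status(sy, sa)
            # independent exhaustive evaluation of the stated rule
            sig_y, sig_a = sy >= 5, sa >= 5
            if sig_y and sig_a:
                expect = "stable-significant"
            elif sig_a and not sig_y and sa - sy >= 2:
                expect = "gained"
            elif sig_y and not sig_a and sy - sa >= 2:
                expect = "lost"
            elif sig_y or sig_a:
                expect = "stable-significant"
            else:
                expect = "never-significant"
            assert got == expect
            # swapping ages swaps gained <-> lost
            swapped = rewiring_status(sa, sy)
            swap = {"gained": "lost", "lost": "gained"}
            assert swapped == swap.get(got, got)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(60)
        rows = [("f0", f"f{i % 8 + 2}", float(sy), float(sa), 1_000.0)
                for i, (sy, sa) in enumerate(zip(rng.uniform(0, 10, 50),
                                                 rng.uniform(0, 10, 50)))]
        s = iset(rows)
        calls = call_rewiring(s)
        for _, r in calls.iterrows():
            assert r["status"] == rewiring_status(r["score_young"], r["score_aged"])

    def test_partition_property(self):
        rng = np.random.default_rng(61)
        rows = [("f0", f"f{i % 8 + 2}", float(sy), float(sa), 1_000.0)
                for i, (sy, sa) in enumerate(zip(rng.uniform(0, 10, 30),
                                                 rng.uniform(0, 10, 30)))]
        calls = call_rewiring(iset(rows))
        assert calls["status"].isin(["stable-significant", "gained", "lost",
                                     "never-significant"]).all()

    def test_missing_score_treated_as_zero_with_warning(self):
        fm = fragmap(baited=(0,))
        table = pd.DataFrame([("f0", "f3", np.nan, 7.0, 3_000.0)],
                             columns=["bait_id", "other_id", "score_young",
                                      "score_aged", "distance"])
        with pytest.warns(UserWarning, match="missing"):
            s = InteractionSet(table, fm)
        assert call_rewiring(s)["status"].iloc[0] == "gained"


def reference_fragment_state(s):
    """Hand-coded truth table for the six-way priority rules."""
    ap = "active_promoter" in s
    pc = "polycomb" in s
    bv = "bivalent" in s
    ar = "active_regulatory" in s
    ins = "insulator" in s
    if ap and not (pc or bv):
        return "active_promoter"
    if pc and not (ap or bv):
        return "polycomb"
    if bv or (ap and pc):
        return "bivalent"
    if ar:
        return "active_regulatory"
    if ins:
        return "insulator"
    return "background"


class TestFragmentState:
    def test_totality_and_truth_table_on_all_64_subsets(self):
        for r in range(7):
            for combo in itertools.combinations(STATES, r):
                s = set(combo)
                got = fragment_state(s)
                assert got in STATES
                assert got == reference_fragment_state(s)

    @pytest.mark.parametrize("present,expect", [
        ({"active_promoter", "polycomb"}, "bivalent"),
        ({"insulator", "background"}, "insulator"),
        ({"active_regulatory"}, "active_regulatory"),
        ({"active_promoter"}, "active_promoter"),
        ({"background"}, "background"),
    ])
    def test_priority_rule_examples(self, present, expect):
        assert fragment_state(present) == expect

    def test_active_flag_rules(self):
        assert fragment_active("active_regulatory")
        assert not fragment_active("active_regulatory", h3k27me3_peak=True)
        assert not fragment_active("bivalent", h3k4me3_peak=True)
        assert not fragment_active("polycomb", h3k27ac_peak=True)
        assert fragment_active("background", h3k4me3_peak=True)
        assert not fragment_active("background")

    def test_assign_fragment_states_from_segmentation(self):
        from chromage.chromstate import Segmentation

        fm = fragmap(n=4, size=1_000, baited=(0,))
        n_bins = 20
        bins = pd.DataFrame({"chrom": "chr1", "start": np.arange(n_bins) * 200,
                             "end": (np.arange(n_bins) + 1) * 200})
        labels = np.array(["background"] * n_bins, dtype=object)
        labels[0:5] = "active_promoter"   # fragment 0
        labels[5:8] = "polycomb"          # fragment 1 overlaps pc+bg
        labels[10:12] = "bivalent"        # fragment 2
        seg = Segmentation(bins, np.zeros(n_bins, int), labels)
        out = assign_fragment_states(fm, seg)
        assert out.loc["f0", "state"] == "active_promoter"
        assert out.loc["f1", "state"] == "polycomb"
        assert out.loc["f2", "state"] == "bivalent"
        assert out.loc["f3", "state"] == "background"


class TestVirtual4C:
    def ditags(self, rows):
        return pd.DataFrame(rows, columns=["frag_i", "frag_j", "count"])

    def test_no_ditags_touching_bait(self):
        fm = fragmap(baited=(0,))
        prof = virtual_4c(self.ditags([("f3", "f4", 5)]), "f0", fm, k=5)
        assert (prof["count"] == 0).all()

    def test_window_arithmetic(self):
        fm = fragmap(n=10, baited=(0,))
        prof = virtual_4c(self.ditags([("f0", "f7", 1)]), "f0", fm, k=5)
        assert prof["count"].tolist() == [0.0, 1.0]

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(62)
        fm = fragmap(n=23, baited=(3,))
        rows = [(f"f{a}", f"f{b}", int(c)) for a, b, c in
                zip(rng.integers(0, 23, 60), rng.integers(0, 23, 60),
                    rng.integers(1, 9, 60))]
        prof = virtual_4c(self.ditags(rows), "f3", fm, k=5)
        expect = np.zeros(len(prof))
        for a, b, c in rows:
            ia, ib = int(a[1:]), int(b[1:])
            if ia == 3 and ib != 3:
                expect[ib // 5] += c
            elif ib == 3 and ia != 3:
                expect[ia // 5] += c
        assert prof["count"].tolist() == expect.tolist()

    def test_unbaited_anchor_warns_but_runs(self):
        fm = fragmap(baited=(0,))
        with pytest.warns(UserWarning, match="not baited"):
            virtual_4c(self.ditags([("f5", "f2", 2)]), "f5", fm, k=5)


class TestPirEnrichment:
    def make_set(self, rng, n_frags=400, n_pirs=60):
        size = 2_000
        df = pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n_frags) * size,
            "end": (np.arange(n_frags) + 1) * size,
            "frag_id": [f"f{i}" for i in range(n_frags)],
            "baited": [i % 40 == 0 for i in range(n_frags)],
        })
        fm = FragmentMap(df)
        rows = []
        baits = [f"f{i}" for i in range(0, n_frags, 40)]
        used = set()
        while len(rows) < n_pirs:
            b = rng.choice(baits)
            off = int(rng.integers(1, 30)) * (1 if rng.random() < 0.5 else -1)
            o = int(b[1:]) + off
            if 0 <= o < n_frags and not df["baited"].iloc[o] and (b, o) not in used:
                used.add((b, o))
                rows.append((b, f"f{o}", 6.0, 6.0, abs(off) * size))
        return fm, iset(rows, fm=fm)

    def test_feature_covering_everything_gives_ratio_one(self):
        rng = np.random.default_rng(63)
        fm, s = self.make_set(rng)
        everything = pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                   "end": [800_000]})
        res = pir_enrichment(s, {"x": everything}, n_draws=20, seed=1)
        assert res["ratio"].iloc[0] == pytest.approx(1.0)
        assert res["draw_ci_low"].iloc[0] == res["draw_ci_high"].iloc[0]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(64)
        fm, s = self.make_set(rng)
        feats = pd.DataFrame({"chrom": "chr1",
                              "start": np.arange(0, 800_000, 9_000)})
        feats["end"] = feats["start"] + 100
        r1 = pir_enrichment(s, {"x": feats}, n_draws=30, seed=7)
        r2 = pir_enrichment(s, {"x": feats}, n_draws=30, seed=7)
        pd.testing.assert_frame_equal(r1, r2)

    def test_expected_scales_with_feature_density(self):
        rng = np.random.default_rng(65)
        fm, s = self.make_set(rng)
        sparse = pd.DataFrame({"chrom": "chr1",
                               "start": np.arange(0, 800_000, 20_000)})
        sparse["end"] = sparse["start"] + 200
        dense = pd.DataFrame({"chrom": "chr1",
                              "start": np.arange(0, 800_000, 10_000)})
        dense["end"] = dense["start"] + 200
        r_sparse = pir_enrichment(s, {"x": sparse}, n_draws=40, seed=2)
        r_dense = pir_enrichment(s, {"x": dense}, n_draws=40, seed=2)
        ratio = r_dense["expected"].iloc[0] / r_sparse["expected"].iloc[0]
        assert ratio == pytest.approx(2.0, rel=0.35)


class TestGeneCategoryStats:
    def build(self, statuses_by_cat):
        """One interaction per entry; bait f0 genes split across categories."""
        fm = fragmap(n=40, baited=(0, 1, 2))
        rows, bait_genes = [], {"f0": ["gU"], "f1": ["gN"], "f2": ["gD"]}
        other = 3
        for bait, cat in (("f0", "up"), ("f1", "unchanged"), ("f2", "down")):
            for st in statuses_by_cat[cat]:
                sy, sa = {"lost": (7.0, 2.0), "gained": (2.0, 7.0),
                          "stable-significant": (6.0, 6.0)}[st]
                rows.append((bait, f"f{other}", sy, sa, 1_000.0))
                other += 1
        s = iset(rows, fm=fm, bait_genes=bait_genes)
        deg = pd.DataFrame({"log2FC": [2.0, 0.0, -2.0],
                            "padj": [0.001, 0.9, 0.001]},
                           index=["gU", "gN", "gD"])
        return s, deg

    def test_all_stable_gives_fisher_p_one(self):
        s, deg = self.build({"up": ["stable-significant"] * 4,
                             "unchanged": ["stable-significant"] * 4,
                             "down": ["stable-significant"] * 4})
        res = rewiring_by_gene_category(call_rewiring(s), s, deg)
        assert (res["proportions"]["rewired"] == 0).all()
        assert (res["fisher"]["p"] == 1.0).all()

    def test_fisher_matches_hypergeometric_closed_form(self):
        # up: 3 rewired / 1 stable; down: 1 rewired / 3 stable
        s, deg = self.build({"up": ["lost"] * 3 + ["stable-significant"],
                             "unchanged": [],
                             "down": ["lost"] + ["stable-significant"] * 3})
        res = rewiring_by_gene_category(call_rewiring(s), s, deg)
        row = res["fisher"].set_index(["cat_a", "cat_b"]).loc[("up", "down")]
        # two-sided Fisher p for [[3,1],[1,3]] by hypergeometric enumeration
        p_obs = hypergeom.pmf(3, 8, 4, 4)
        p_exact = sum(hypergeom.pmf(k, 8, 4, 4) for k in range(5)
                      if hypergeom.pmf(k, 8, 4, 4) <= p_obs + 1e-12)
        assert row["p"] == pytest.approx(p_exact, abs=1e-10)
        assert p_exact == pytest.approx(0.485714285714, abs=1e-9)

    def test_score_log_ratio_uses_pseudocount(self):
        s, deg = self.build({"up": ["stable-significant"] * 2,
                             "unchanged": ["stable-significant"] * 2,
                             "down": ["stable-significant"] * 2})
        res = rewiring_by_gene_category(call_rewiring(s), s, deg)
        per = res["score_change"]["per_interaction"]
        assert np.allclose(per["score_log2fc"],
                           np.log2((per["score_aged"] + 0.5)
                                   / (per["score_young"] + 0.5)))

    def test_active_contact_changes_counted(self):
        s, deg = self.build({"up": ["gained"] * 3,
                             "unchanged": ["stable-significant"] * 3,
                             "down": ["lost"] * 3})
        frag_states = pd.DataFrame(
            {"state": "active_regulatory", "active": True},
            index=pd.Index([f"f{i}" for i in range(40)], name="frag_id"))
        res = rewiring_by_gene_category(call_rewiring(s), s, deg,
                                        fragment_states=frag_states)
        pg = res["active_contacts"]["per_gene"].set_index("gene_id")
        assert pg.loc["gU", "delta"] == 3   # gained 3 active contacts
        assert pg.loc["gD", "delta"] == -3  # lost 3
        assert pg.loc["gN", "delta"] == 0
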