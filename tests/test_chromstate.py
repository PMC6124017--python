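import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from chromage import genome_io
from chromage.chromstate import (
    BernoulliHMM,
    Segmentation,
    binarize,
    default_collapse_mapping,
    dominant_state,
    fit_hmm,
    genome_bins,
    occupancy_change_clusters,
    segment,
    state_coverage,
    tss_overlap,
    COLLAPSED_STATES,
)


def sample_hmm(rng, emission, transmat, T, start=None):
    K, M = emission.shape
    start = np.full(K, 1 / K) if start is None else start
    path = np.empty(T, dtype=int)
    path[0] = rng.choice(K, p=start)
    for t in range(1, T):
        path[t] = rng.choice(K, p=transmat[path[t - 1]])
    X = (rng.random((T, M)) < emission[path]).astype(np.uint8)
    return X, path


def log_forward_backward(X, emission, transmat, startprob):
    """Independent log-space forward-backward (logsumexp recursions)."""
    T = len(X)
    K = len(startprob)
    logB = np.array([
        [np.sum(X[t] * np.log(emission[k]) + (1 - X[t]) * np.log(1 - emission[k]))
         for k in range(K)] for t in range(T)])
    logA = np.log(transmat)
    la = np.empty((T, K))
    with np.errstate(divide="ignore"):
        la[0] = np.log(startprob) + logB[0]
    for t in range(1, T):
        la[t] = logB[t] + logsumexp(la[t - 1][:, None] + logA, axis=0)
    lb = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        lb[t] = logsumexp(logA + logB[t + 1] + lb[t + 1], axis=1)
    post = la + lb
    post -= logsumexp(post, axis=1, keepdims=True)
    return np.exp(post), logsumexp(la[-1])


class TestBinarize:
    def test_empty_peaks_give_zero_column(self, toy_genome):
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        bt = binarize({"ATAC": empty}, toy_genome, 200)
        assert not bt.matrix.any()

    def test_peak_spans_expected_bins(self, toy_genome):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [400], "end": [1000]})
        bt = binarize({"ATAC": peaks}, toy_genome, 200)
        chr1 = bt.bins["chrom"] == "chr1"
        set_bins = np.flatnonzero(bt.matrix[chr1.to_numpy(), 0])
        assert set_bins.tolist() == [2, 3, 4]

    def test_matches_per_bin_overlap_oracle(self, toy_genome):
        rng = np.random.default_rng(20)
        starts = np.sort(rng.choice(np.arange(0, 40_000, 600), 25, replace=False))
        peaks = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + rng.integers(50, 550, 25)})
        bt = binarize({"m": peaks}, toy_genome, 200)
        bins = bt.bins
        expect = np.zeros(len(bins), dtype=bool)
        for i, (_, b) in enumerate(bins.iterrows()):
            for _, p in peaks.iterrows():
                if (b["chrom"] == p["chrom"]
                        and max(b["start"], p["start"]) < min(b["end"], p["end"])):
                    expect[i] = True
        assert np.array_equal(bt.matrix[:, 0].astype(bool), expect)


class TestBernoulliHMM:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(21)
        X = (rng.random((500, 3)) < [0.2, 0.7, 0.5]).astype(np.uint8)
        m = BernoulliHMM(n_states=1, random_state=0).fit(X)
        assert np.allclose(m.emission_[0], X.mean(axis=0), atol=1e-9)
        assert np.allclose(m.transmat_, [[1.0]])

    def test_two_state_recovery(self):
        rng = np.random.default_rng(22)
        em = np.array([[0.9] * 5, [0.1] * 5])
        A = np.array([[0.95, 0.05], [0.05, 0.95]])
        X, _ = sample_hmm(rng, em, A, 20_000)
        m = BernoulliHMM(n_states=2, n_restarts=3, random_state=1).fit(X)
        err = min(np.abs(m.emission_ - em).max(),
                  np.abs(m.emission_[::-1] - em).max())
        assert err <= 0.05

    def test_loglik_trace_nondecreasing(self):
        rng = np.random.default_rng(23)
        X = (rng.random((2_000, 4)) < 0.3).astype(np.uint8)
        m = BernoulliHMM(n_states=3, random_state=2).fit(X)
        diffs = np.diff(m.loglik_trace_)
        assert (diffs >= -1e-8 * np.abs(m.loglik_trace_[:-1])).all()

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(24)
        em = np.array([[0.8, 0.2, 0.5], [0.1, 0.9, 0.3]])
        A = np.array([[0.9, 0.1], [0.2, 0.8]])
        X, _ = sample_hmm(rng, em, A, 1_000)
        m = BernoulliHMM(n_states=2, random_state=3).fit(X)
        post = m.predict_proba(X)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_posterior_argmax_matches_log_space_oracle(self):
        rng = np.random.default_rng(25)
        em = np.array([[0.85, 0.15, 0.6], [0.2, 0.8, 0.1], [0.5, 0.5, 0.9]])
        A = np.array([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        X, _ = sample_hmm(rng, em, A, 1_000)
        m = BernoulliHMM(n_states=3, random_state=4)
        m.fit(X)
        post = m.predict_proba(X)
        oracle_post, oracle_ll = log_forward_backward(
            X, m.emission_, m.transmat_, m.startprob_)
        assert np.allclose(post, oracle_post, atol=1e-8)
        assert m.score(X) == pytest.approx(oracle_ll, abs=1e-6)
        assert np.array_equal(m.predict(X), oracle_post.argmax(axis=1))

    def test_score_matches_hmmlearn_categorical(self):
        """Cross-check the likelihood against hmmlearn on the 2^M encoding."""
        from hmmlearn.hmm import CategoricalHMM

        rng = np.random.default_rng(26)
        em = np.array([[0.8, 0.3], [0.2, 0.7]])
        A = np.array([[0.9, 0.1], [0.3, 0.7]])
        X, _ = sample_hmm(rng, em, A, 500)
        m = BernoulliHMM(n_states=2, random_state=5).fit(X)
        # per-state categorical over the 4 mark combinations
        bits = ((np.arange(4)[:, None] >> np.arange(2)) & 1)
        emission_cat = np.exp(bits @ np.log(m.emission_).T
                              + (1 - bits) @ np.log(1 - m.emission_).T).T
        h = CategoricalHMM(n_components=2)
        h.startprob_ = m.startprob_
        h.transmat_ = m.transmat_
        h.emissionprob_ = emission_cat
        symbols = (X @ (1 << np.arange(2))).reshape(-1, 1)
        assert m.score(X) == pytest.approx(h.score(symbols), abs=1e-6)

    def test_viterbi_on_unambiguous_data(self):
        em = np.array([[0.999, 0.001], [0.001, 0.999]])
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        rng = np.random.default_rng(27)
        X, path = sample_hmm(rng, em, A, 500)
        m = BernoulliHMM(n_states=2, random_state=6).fit(X)
        vit = m.predict(X, decode="viterbi")
        mapd = m.predict(X, decode="map")
        # relabel to best match
        if (vit == path).mean() < 0.5:
            vit = 1 - vit
        if (mapd == path).mean() < 0.5:
            mapd = 1 - mapd
        assert (vit == path).mean() > 0.99
        assert (mapd == path).mean() > 0.99

    def test_sequence_lengths_break_transitions(self):
        rng = np.random.default_rng(28)
        X = (rng.random((400, 2)) < 0.4).astype(np.uint8)
        m = BernoulliHMM(n_states=2, random_state=7).fit(X, lengths=[200, 200])
        p_joint = m.predict_proba(X, lengths=[200, 200])
        p_separate = np.vstack([m.predict_proba(X[:200]), m.predict_proba(X[200:])])
        assert np.allclose(p_joint, p_separate, atol=1e-12)

    def test_identical_bins_warn(self):
        X = np.ones((100, 2), dtype=np.uint8)
        with pytest.warns(UserWarning, match="unidentifiable"):
            BernoulliHMM(n_states=2, n_iter=5, random_state=8).fit(X)


def make_segmentation(labels, bin_size=200, chrom="chr1"):
    n = len(labels)
    bins = pd.DataFrame({"chrom": chrom, "start": np.arange(n) * bin_size,
                         "end": (np.arange(n) + 1) * bin_size})
    return Segmentation(bins, np.zeros(n, dtype=int), np.asarray(labels, dtype=object))


class TestDominantState:
    def region(self, start, end):
        return {"chrom": "chr1", "start": start, "end": end}

    def test_max_coverage_wins(self):
        labels = ["active_promoter"] * 15 + ["polycomb"] * 10
        st, cov = dominant_state(make_segmentation(labels), self.region(0, 5_000))
        assert st == "active_promoter"
        assert cov["active_promoter"] == 3_000 and cov["polycomb"] == 2_000

    def test_background_loses_to_any_state(self):
        labels = ["background"] * 24 + ["polycomb"]
        st, cov = dominant_state(make_segmentation(labels), self.region(0, 5_000))
        assert st == "polycomb"
        assert cov["background"] == 4_800 and cov["polycomb"] == 200

    def test_pure_background(self):
        st, _ = dominant_state(make_segmentation(["background"] * 25),
                               self.region(0, 5_000))
        assert st == "background"

    def test_coverage_sums_to_region_length(self):
        rng = np.random.default_rng(29)
        labels = rng.choice(COLLAPSED_STATES, size=50)
        for start, end in [(0, 10_000), (150, 7_430), (1_000, 1_001)]:
            _, cov = dominant_state(make_segmentation(list(labels)),
                                    self.region(start, end))
            assert cov.sum() == end - start

    def test_tie_broken_by_priority(self):
        labels = ["insulator"] * 10 + ["polycomb"] * 10
        st, _ = dominant_state(make_segmentation(labels), self.region(0, 4_000))
        assert st == "polycomb"


class TestSegmentAndCollapse:
    def test_one_state_model_labels_everything(self, toy_genome):
        rng = np.random.default_rng(30)
        bins = genome_bins(toy_genome, 200)
        mat = (rng.random((len(bins), 2)) < 0.3).astype(np.uint8)
        from chromage.chromstate import BinaryTracks
        bt = BinaryTracks(bins, mat, ["ATAC", "H3K4me3"])
        m = BernoulliHMM(n_states=1, random_state=0).fit(mat)
        seg = segment(m, bt, {0: "background"})
        assert (seg.collapsed == "background").all()

    def test_incomplete_collapse_mapping_rejected(self, toy_genome):
        rng = np.random.default_rng(31)
        bins = genome_bins(toy_genome, 200)
        mat = (rng.random((len(bins), 2)) < 0.3).astype(np.uint8)
        from chromage.chromstate import BinaryTracks
        bt = BinaryTracks(bins, mat, ["ATAC", "H3K4me3"])
        m = BernoulliHMM(n_states=2, n_iter=5, random_state=1).fit(mat)
        with pytest.raises(ValueError, match="collapse"):
            segment(m, bt, {0: "background"})

    def test_default_collapse_mapping_keys_on_emissions(self):
        marks = ["ATAC", "H3K4me3", "H3K27ac", "H3K27me3", "CTCF"]
        emission = np.array([
            [0.9, 0.9, 0.5, 0.05, 0.1],   # active promoter
            [0.3, 0.8, 0.1, 0.8, 0.05],   # bivalent
            [0.1, 0.05, 0.05, 0.9, 0.05],  # polycomb
            [0.8, 0.1, 0.8, 0.05, 0.1],   # active regulatory
            [0.5, 0.05, 0.05, 0.05, 0.9],  # insulator
            [0.02, 0.02, 0.02, 0.02, 0.02],  # background
        ])
        mapping = default_collapse_mapping(emission, marks)
        assert [mapping[i] for i in range(6)] == [
            "active_promoter", "bivalent", "polycomb", "active_regulatory",
            "insulator", "background"]


class TestOccupancyChange:
    def promoters(self, n, chrom="chr1"):
        return pd.DataFrame({"chrom": chrom,
                             "start": np.arange(n) * 5_000,
                             "end": np.arange(n) * 5_000 + 5_000,
                             "gene_id": [f"g{i}" for i in range(n)]})

    def test_identical_segmentations_select_nothing(self):
        labels = ["active_promoter"] * 250
        seg = make_segmentation(labels)
        res = occupancy_change_clusters(seg, seg, self.promoters(10), k=2)
        assert len(res["selected"]) == 0
        assert (res["delta"].to_numpy() == 0).all()

    def test_full_window_flip_delta(self):
        young = make_segmentation(["active_promoter"] * 250)
        labels = ["active_promoter"] * 250
        labels[0:25] = ["polycomb"] * 25  # first promoter window flips entirely
        aged = make_segmentation(labels)
        res = occupancy_change_clusters(young, aged, self.promoters(10),
                                        top_frac=0.1, k=1)
        assert res["delta"].loc["g0", "polycomb"] == 5_000
        assert res["delta"].loc["g0", "active_promoter"] == -5_000
        assert list(res["selected"]) == ["g0"]

    def test_planted_patterns_recovered_as_pure_clusters(self):
        from sklearn.metrics import adjusted_rand_score

        n_prom = 60
        young_labels = ["background"] * (n_prom * 25)
        aged_labels = list(young_labels)
        truth = []
        patterns = [("active_promoter", "polycomb"),
                    ("active_promoter", "bivalent"),
                    ("polycomb", "active_regulatory")]
        for i in range(n_prom):
            frm, to = patterns[i % 3]
            truth.append(i % 3)
            young_labels[i * 25: (i + 1) * 25] = [frm] * 25
            aged_labels[i * 25: (i + 1) * 25] = [to] * 25
        young = make_segmentation(young_labels)
        aged = make_segmentation(aged_labels)
        res = occupancy_change_clusters(young, aged, self.promoters(n_prom),
                                        top_frac=0.5, k=3)
        labels = res["labels"].reindex([f"g{i}" for i in range(n_prom)])
        assert adjusted_rand_score(truth, labels) == 1.0


class TestTssOverlap:
    def genes(self):
        return pd.DataFrame({"chrom": ["chr1"], "start": [10_000], "end": [15_000],
                             "gene_id": ["g"], "score": [0.0], "strand": ["+"]})

    def test_element_touching_radius_true(self):
        el = pd.DataFrame({"chrom": ["chr1"], "start": [11_000], "end": [11_100]})
        assert tss_overlap(el, self.genes(), 1_000).tolist() == [True]

    def test_element_beyond_radius_false(self):
        el = pd.DataFrame({"chrom": ["chr1"], "start": [11_501], "end": [11_600]})
        assert tss_overlap(el, self.genes(), 1_000).tolist() == [False]

    def test_matches_brute_force_distance_scan(self):
        rng = np.random.default_rng(32)
        genes = pd.DataFrame({"chrom": "chr1",
                              "start": rng.integers(0, 90_000, 20)})
        genes["end"] = genes["start"] + 2_000
        genes["gene_id"] = [f"g{i}" for i in range(20)]
        genes["score"] = 0.0
        genes["strand"] = rng.choice(["+", "-"], 20)
        genes = genome_io.add_tss(genes)
        els = pd.DataFrame({"chrom": "chr1", "start": rng.integers(0, 95_000, 50)})
        els["end"] = els["start"] + rng.integers(1, 500, 50)
        got = tss_overlap(els, genes, 1_000)
        for i, (_, e) in enumerate(els.iterrows()):
            near = any(e["start"] <= t + 1_000 and e["end"] > t - 1_000
                       for t in genes["tss"])
            assert got[i] == near
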