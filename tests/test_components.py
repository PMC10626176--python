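"""Component predictors: naive prior, homology vote, LR, network vote."""

import io

import numpy as np
import pytest

from goranker import (
    AnnotationSet,
    ConfigError,
    Hit,
    HitTable,
    ValidationError,
    fit_lr,
    fit_naive,
    predict_blast_knn,
    predict_lr,
    predict_naive,
    predict_net_knn,
)
from goranker.components import LrModel, Network, read_hit_table, read_network
from goranker.exceptions import FitError
from goranker.features import EmbeddingMatrix

from _oracles import blast_vote_oracle


class TestNaive:
    def test_prior_is_relative_frequency(self):
        ann = AnnotationSet(
            {f"P{i}": ({"r", "t"} if i < 3 else {"r"}) for i in range(10)}
        )
        priors = fit_naive(ann)
        assert priors["t"] == pytest.approx(0.3)
        assert priors["r"] == pytest.approx(1.0)  # root carried by everyone

    def test_empty_training_set_rejected(self):
        with pytest.raises(FitError):
            fit_naive(AnnotationSet())

    def test_rows_identical_across_queries(self):
        priors = {"a": 0.4, "b": 0.1}
        m = predict_naive(priors, ["Q1", "Q2", "Q3"])
        assert m.row("Q1") == m.row("Q2") == m.row("Q3") == priors

    def test_priors_match_counting_oracle(self):
        rng = np.random.default_rng(4)
        terms = [f"t{j}" for j in range(8)]
        ann = AnnotationSet({
            f"P{i}": {terms[j] for j in rng.choice(8, size=3, replace=False)}
            for i in range(25)
        })
        priors = fit_naive(ann)
        for t in terms:
            explicit = sum(t in ts for ts in ann.by_protein.values()) / 25
            assert priors.get(t, 0.0) == pytest.approx(explicit)


class TestBlastKnn:
    train = AnnotationSet({"S1": {"A", "B"}, "S2": {"A"}, "S3": {"C"}})

    def test_single_hit_transfers_all_terms_at_one(self):
        hits = HitTable.from_hits([Hit("Q", "S1", 0.8, 80.0)])
        m = predict_blast_knn(hits, self.train)
        assert m.row("Q") == {"A": 1.0, "B": 1.0}

    def test_weighted_vote(self):
        hits = HitTable.from_hits(
            [Hit("Q", "S1", 0.8, 60.0), Hit("Q", "S3", 0.5, 40.0)]
        )
        m = predict_blast_knn(hits, self.train)
        assert m.get("Q", "B") == pytest.approx(0.6)
        assert m.get("Q", "A") == pytest.approx(0.6)
        assert m.get("Q", "C") == pytest.approx(0.4)

    def test_self_hits_and_unannotated_subjects_ignored(self):
        hits = HitTable.from_hits(
            [Hit("Q", "Q", 1.0, 500.0), Hit("Q", "S9", 0.9, 300.0),
             Hit("Q", "S2", 0.7, 50.0)]
        )
        m = predict_blast_knn(hits, self.train)
        assert m.row("Q") == {"A": 1.0}

    def test_query_with_no_retained_hits_absent(self):
        hits = HitTable.from_hits([Hit("Q", "S9", 0.9, 300.0)])
        assert not predict_blast_knn(hits, self.train)

    def test_top_k_truncates_by_bitscore(self):
        hits = HitTable.from_hits(
            [Hit("Q", "S1", 0.8, 90.0), Hit("Q", "S3", 0.5, 10.0)]
        )
        m = predict_blast_knn(hits, self.train, top_k=1)
        assert m.row("Q") == {"A": 1.0, "B": 1.0}

    def test_invalid_top_k_rejected(self):
        with pytest.raises(ConfigError):
            predict_blast_knn(HitTable({}), self.train, top_k=0)

    def test_matches_loop_oracle_on_seeded_fixture(self):
        rng = np.random.default_rng(9)
        terms = [f"t{j}" for j in range(6)]
        train = AnnotationSet({
            f"S{i}": {terms[j] for j in rng.choice(6, size=2, replace=False)}
            for i in range(8)
        })
        raw = [
            Hit("Q", f"S{i}", 0.5, float(rng.integers(20, 200)))
            for i in rng.choice(8, size=5, replace=False)
        ]
        m = predict_blast_knn(HitTable.from_hits(raw), train)
        oracle = blast_vote_oracle(
            [(h.query, h.subject, h.bitscore) for h in raw], train.by_protein
        )
        assert m.row("Q") == pytest.approx(oracle["Q"])

    def test_scores_are_convex_combination_weights(self):
        rng = np.random.default_rng(10)
        train = AnnotationSet({f"S{i}": {"shared", f"t{i}"} for i in range(5)})
        hits = HitTable.from_hits(
            [Hit("Q", f"S{i}", 0.5, float(rng.integers(10, 100))) for i in range(5)]
        )
        m = predict_blast_knn(hits, train)
        assert m.get("Q", "shared") == pytest.approx(1.0)
        assert all(s <= 1.0 + 1e-12 for _, _, s in m.items())

    def test_reader_parses_outfmt6(self):
        buf = io.StringIO("Q1\tS1\t85.3\t100\t10\t2\t1\t100\t1\t100\t1e-30\t212.0\n")
        table = read_hit_table(buf)
        (hit,) = table.by_query["Q1"]
        assert hit.identity == pytest.approx(0.853)
        assert hit.bitscore == pytest.approx(212.0)


class TestLogisticRegression:
    def test_separable_term_orders_held_out_scores(self):
        rng = np.random.default_rng(1)
        n = 40
        X = rng.normal(size=(n, 3))
        labels = X[:, 0] > 0
        X[:, 0] += np.where(labels, 2.0, -2.0)
        train = AnnotationSet(
            {f"P{i}": ({"t"} if labels[i] else {"u"}) for i in range(n)}
        )
        emb = EmbeddingMatrix([f"P{i}" for i in range(n)], X)
        model = fit_lr(emb, train, min_train_count=5)
        heldout = EmbeddingMatrix(
            ["POS", "NEG"], np.array([[3.0, 0, 0], [-3.0, 0, 0]])
        )
        scores = predict_lr(model, heldout)
        assert scores.get("POS", "t") > scores.get("NEG", "t")

    def test_rare_terms_are_not_modelled(self):
        rng = np.random.default_rng(2)
        train = AnnotationSet(
            {f"P{i}": ({"rare"} if i == 0 else {"common"}) for i in range(20)}
        )
        emb = EmbeddingMatrix([f"P{i}" for i in range(20)], rng.normal(size=(20, 4)))
        model = fit_lr(emb, train, min_train_count=5)
        assert "rare" not in model.terms

    def test_term_without_negatives_skipped(self, caplog):
        train = AnnotationSet({f"P{i}": {"everywhere"} for i in range(12)})
        emb = EmbeddingMatrix(
            [f"P{i}" for i in range(12)], np.random.default_rng(0).normal(size=(12, 3))
        )
        with caplog.at_level("WARNING"):
            model = fit_lr(emb, train, min_train_count=5)
        assert model.terms == []

    def test_zero_weights_give_one_half(self):
        model = LrModel(
            terms=["t"], weights=np.zeros((1, 3)), intercepts=np.zeros(1),
            n_features=3, min_train_count=1,
        )
        emb = EmbeddingMatrix(["P1"], np.array([[1.0, 2.0, 3.0]]))
        assert predict_lr(model, emb).get("P1", "t") == pytest.approx(0.5)

    def test_large_negative_intercept_floors_to_absent(self):
        model = LrModel(
            terms=["t"], weights=np.zeros((1, 2)), intercepts=np.array([-30.0]),
            n_features=2, min_train_count=1,
        )
        emb = EmbeddingMatrix(["P1"], np.zeros((1, 2)))
        assert not predict_lr(model, emb)

    def test_scores_equal_hand_computed_logistic(self):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(2, 4))
        b = rng.normal(size=2)
        X = rng.normal(size=(3, 4))
        model = LrModel(
            terms=["t1", "t2"], weights=W, intercepts=b, n_features=4,
            min_train_count=1,
        )
        emb = EmbeddingMatrix(["P0", "P1", "P2"], X)
        m = predict_lr(model, emb, floor=0.0)
        for i in range(3):
            for j, t in enumerate(["t1", "t2"]):
                expected = 1.0 / (1.0 + np.exp(-(X[i] @ W[j] + b[j])))
                assert m.get(f"P{i}", t) == pytest.approx(expected, abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        model = LrModel(
            terms=["t"], weights=np.zeros((1, 3)), intercepts=np.zeros(1),
            n_features=3, min_train_count=1,
        )
        emb = EmbeddingMatrix(["P1"], np.zeros((1, 5)))
        with pytest.raises(ValidationError):
            predict_lr(model, emb)


class TestNetKnn:
    train = AnnotationSet({"S1": {"A"}, "S2": {"B"}})

    def test_single_neighbor_transfers_at_one(self):
        net = Network.from_edge_list([("Q", "S1", 0.9)])
        m = predict_net_knn(net, self.train, queries=["Q"])
        assert m.row("Q") == {"A": 1.0}

    def test_weighted_vote(self):
        net = Network.from_edge_list([("Q", "S1", 0.6), ("Q", "S2", 0.4)])
        m = predict_net_knn(net, self.train, queries=["Q"])
        assert m.get("Q", "A") == pytest.approx(0.6)
        assert m.get("Q", "B") == pytest.approx(0.4)

    def test_query_without_annotated_neighbors_absent(self):
        net = Network.from_edge_list([("Q", "X", 0.8)])
        assert not predict_net_knn(net, self.train, queries=["Q"])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValidationError):
            Network.from_edge_list([("Q", "S1", -0.1)])

    def test_matches_loop_oracle_on_seeded_graph(self):
        rng = np.random.default_rng(12)
        terms = [f"t{j}" for j in range(5)]
        train = AnnotationSet({
            f"S{i}": {terms[j] for j in rng.choice(5, size=2, replace=False)}
            for i in range(6)
        })
        edges = [("Q", f"S{i}", float(rng.uniform(0.1, 1.0))) for i in range(6)]
        m = predict_net_knn(Network.from_edge_list(edges), train, queries=["Q"])
        denom = sum(w for _, _, w in edges)
        for t in terms:
            expected = sum(
                w for _, s, w in edges if t in train.by_protein[s]
            ) / denom
            assert m.get("Q", t) == pytest.approx(expected)

    def test_reader_scales_string_style_weights(self):
        buf = io.StringIO("A\tB\t900\nB\tC\t150\n")
        net = read_network(buf, scale=1000)
        assert net.neighbors("A")["B"] == pytest.approx(0.9)
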