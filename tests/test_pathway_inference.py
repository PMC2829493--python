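import pytest

from cheops.operon_stats import adjacency_matrix  # noqa: F401  (module pairing)
from cheops.pathway_inference import (
    MODELS,
    PI,
    build_cooccurrence,
    count_pi_occurrences,
    predict_corpus,
    predict_pathways,
)
from cheops.synthetic_data import SyntheticSpec, generate_corpus, truth_operons

from conftest import make_operon


def _edges(prediction, pi_type=None):
    return sorted(
        (pi.pi_type, pi.scope, pi.source_operon, pi.target_operon)
        for pi in prediction.pis
        if pi_type is None or pi.pi_type == pi_type
    )


@pytest.fixture(scope="module")
def synthetic_operons():
    genes, truth = generate_corpus(SyntheticSpec(n_species=25, seed=5))
    return truth_operons(genes, truth)


class TestCooccurrence:
    def test_counts_species_not_operon_pairs(self):
        ops = []
        for sp in ("s1", "s2", "s3"):
            ops.append(make_operon(sp, f"{sp}_o1", "ABWY"))
            ops.append(make_operon(sp, f"{sp}_o2", "R", start=500_000))
        table = build_cooccurrence(ops)
        assert table.count("ABWY", "R") == 3
        assert table.count("R", "ABWY") == 3  # symmetric lookup

    def test_single_operon_species_contributes_nothing_off_diagonal(self):
        table = build_cooccurrence([make_operon("s1", "o1", "ABRWY")])
        assert table.count("ABRWY", "Y") == 0
        assert table.count("ABRWY", "ABRWY") == 0

    def test_diagonal_requires_two_operons_of_the_type(self):
        ops = [
            make_operon("s1", "o1", "Y"),
            make_operon("s1", "o2", "Y", start=500_000),
        ]
        assert build_cooccurrence(ops).count("Y", "Y") == 1


class TestPredictPathways:
    def test_single_complete_operon_gives_only_within_pis(self, ecoli_like):
        cooc = build_cooccurrence(ecoli_like)
        for model in MODELS:
            pred = predict_pathways(ecoli_like, model, cooc)
            assert _edges(pred) == [
                ("A~B", "within", "ec_op1", "ec_op1"),
                ("A~R", "within", "ec_op1", "ec_op1"),
                ("A~W", "within", "ec_op1", "ec_op1"),
                ("A~Y", "within", "ec_op1", "ec_op1"),
            ]

    def test_single_chea_reaches_across_to_missing_r(self):
        ops = [
            make_operon("pa", "clusterI", "ABWY"),
            make_operon("pa", "clusterV", "R", start=900_000),
        ]
        pred = predict_pathways(ops, "ABRWY", build_cooccurrence(ops))
        assert ("A~R", "across", "clusterI", "clusterV") in _edges(pred)

    def test_isolated_y_distinguishes_the_y_variant_models(
        self, two_complete_plus_isolated_y
    ):
        ops = two_complete_plus_isolated_y
        cooc = build_cooccurrence(ops)
        base = predict_pathways(ops, "ABRWY", cooc)
        prime = predict_pathways(ops, "ABRWY+Y'", cooc)
        plus = predict_pathways(ops, "ABRWY+Y", cooc)
        iso_edges = lambda p: {
            (pi.source_operon, pi.target_operon)
            for pi in p.pis
            if pi.pi_type == "A~Y" and pi.target_operon == "isoY"
        }
        assert iso_edges(base) == set()
        assert iso_edges(prime) == {("cheOp2", "isoY"), ("cheOp3", "isoY")}
        assert iso_edges(plus) == {("cheOp2", "isoY"), ("cheOp3", "isoY")}
        # under +Y every (CheA operon, CheY-bearing operon) pair is wired
        ay_pairs = {
            (pi.source_operon, pi.target_operon)
            for pi in plus.pis
            if pi.pi_type == "A~Y"
        }
        assert ay_pairs == {
            (a, y)
            for a in ("cheOp2", "cheOp3")
            for y in ("cheOp2", "cheOp3", "isoY")
        }

    def test_exactly_complementary_operon_preferred(self):
        ops = [
            make_operon("sp", "srcA", "ABW"),
            make_operon("sp", "srcA2", "ABRWY", start=600_000),
            make_operon("sp", "exact", "RY", start=1_200_000),
            make_operon("sp", "surplus", "RWY", start=1_800_000),
        ]
        pred = predict_pathways(ops, "ABRWY", build_cooccurrence(ops))
        across = {
            pi.target_operon
            for pi in pred.pis
            if pi.source_operon == "srcA" and pi.scope == "across"
        }
        # the deficit {R, Y} is completed from the exactly complementary
        # operon, not from the one carrying a surplus cheW
        assert across == {"exact"}

    def test_missing_required_type_is_an_error(self):
        ops = [make_operon("sp", "o1", "ABRW")]
        with pytest.raises(ValueError, match="lacks required che type Y"):
            predict_pathways(ops, "ABRWY", build_cooccurrence(ops))

    def test_unknown_model_rejected(self, ecoli_like):
        with pytest.raises(ValueError, match="unknown model"):
            predict_pathways(ecoli_like, "XYZ", build_cooccurrence(ecoli_like))

    def test_predictions_are_deterministic(self, synthetic_operons):
        cooc = build_cooccurrence(synthetic_operons)
        for model in MODELS:
            a = predict_corpus(synthetic_operons, model, cooc)
            b = predict_corpus(synthetic_operons, model, cooc)
            assert [p.pis for p in a] == [p.pis for p in b]

    def test_variant_monotonicity_on_synthetic_corpus(self, synthetic_operons):
        cooc = build_cooccurrence(synthetic_operons)
        base = predict_corpus(synthetic_operons, "ABRWY", cooc)
        prime = predict_corpus(synthetic_operons, "ABRWY+Y'", cooc)
        plus = predict_corpus(synthetic_operons, "ABRWY+Y", cooc)

        def strip(pred):
            return {(pi.pi_type, pi.source_operon, pi.target_operon) for pi in pred.pis}

        for pb, pp, pl in zip(base, prime, plus):
            assert strip(pb) <= strip(pp) <= strip(pl)

    def test_plus_y_wires_every_a_to_every_y_operon(self, synthetic_operons):
        cooc = build_cooccurrence(synthetic_operons)
        for model in ("ABRW+Y", "ABRWY+Y"):
            for pred in predict_corpus(synthetic_operons, model, cooc):
                ops = [
                    op for op in synthetic_operons
                    if op.species_id == pred.species_id
                ]
                a_ops = {op.operon_id for op in ops if "A" in op.compressed}
                y_ops = {op.operon_id for op in ops if "Y" in op.compressed}
                ay = {
                    (pi.source_operon, pi.target_operon)
                    for pi in pred.pis
                    if pi.pi_type == "A~Y"
                }
                assert {(a, y) for a in a_ops for y in y_ops} <= ay

    def test_every_chea_pathway_is_complete(self, synthetic_operons):
        cooc = build_cooccurrence(synthetic_operons)
        for pred in predict_corpus(synthetic_operons, "ABRWY", cooc):
            ops = {
                op.operon_id: op
                for op in synthetic_operons
                if op.species_id == pred.species_id
            }
            for a_id in (oid for oid, op in ops.items() if "A" in op.compressed):
                covered = set(ops[a_id].compressed)
                for pi in pred.pis:
                    if pi.source_operon == a_id:
                        covered.add(pi.pi_type[-1])
                assert covered >= set("ABRWY")


class TestOccurrenceCounting:
    def test_aww_operon_registers_one_within_aw(self):
        ops = [make_operon("sp", "o1", "AWWBRY")]
        pred = predict_pathways(ops, "ABRWY", build_cooccurrence(ops))
        table = count_pi_occurrences([pred])
        assert table.loc[("A~W", "within"), "occurrence"] == 1

    def test_single_operon_corpus_has_no_across_occurrences(self, ecoli_like):
        preds = predict_corpus(ecoli_like * 1, "ABRWY")
        table = count_pi_occurrences(preds)
        assert table.xs("across", level="scope")["occurrence"].sum() == 0

    def test_relative_occurrences_sum_to_one(self, synthetic_operons):
        preds = predict_corpus(synthetic_operons, "ABRWY")
        assert count_pi_occurrences(preds)["relative"].sum() == pytest.approx(1.0)

    def test_within_aw_matches_operon_content_count(self, synthetic_operons):
        preds = predict_corpus(synthetic_operons, "ABRWY")
        table = count_pi_occurrences(preds)
        expected = sum(
            1 for op in synthetic_operons if {"A", "W"} <= op.compressed
        )
        assert table.loc[("A~W", "within"), "occurrence"] == expected

    def test_mixed_models_rejected(self, ecoli_like):
        cooc = build_cooccurrence(ecoli_like)
        preds = [
            predict_pathways(ecoli_like, "ABRWY", cooc),
            predict_pathways(ecoli_like, "ABRWY+Y", cooc),
        ]
        with pytest.raises(ValueError, match="mixed models"):
            count_pi_occurrences(preds)


def test_pi_scope_consistency_enforced():
    with pytest.raises(ValueError, match="scope"):
        PI("A~W", "across", "op1", "op1")
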