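import math
from dataclasses import replace

import numpy as np
import pytest

from nrpred.cascade import (
    ConfusionQuadrants,
    build_report,
    feature_ablation,
    grid_search,
    independent_test,
    jackknife,
    level1_label,
    load_model,
    mcc,
    predict_two_level,
    predict_two_level_batch,
    save_model,
    train_cascade,
    two_level_jackknife,
)
from nrpred.errors import LeakageError, ParameterError
from nrpred.fknn import FknnParams, ReferenceSet
from nrpred.simulate import FixtureSpec, generate_fixture


@pytest.mark.parametrize(
    "q, expected",
    [
        (ConfusionQuadrants(10, 0, 10, 0), 1.0),
        (ConfusionQuadrants(0, 10, 0, 10), -1.0),
        (ConfusionQuadrants(5, 5, 5, 5), 0.0),
        (ConfusionQuadrants(0, 0, 10, 0), 0.0),  # degenerate marginal
    ],
)
def test_mcc_reference_points(q, expected):
    assert mcc(q) == pytest.approx(expected)


def test_mcc_against_hand_oracle_random_tables():
    rng = np.random.default_rng(12)
    for _ in range(50):
        tp, fp, tn, fn = (int(v) for v in rng.integers(0, 40, size=4))
        q = ConfusionQuadrants(tp, fp, tn, fn)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        expected = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
        assert mcc(q) == pytest.approx(expected, abs=1e-12)
        assert -1.0 <= mcc(q) <= 1.0


def test_report_quadrants_partition_samples():
    true = np.array([0, 0, 1, 1, 2, 2])
    pred = np.array([0, 1, 1, 1, 0, 2])
    report = build_report(true, pred, ["A", "B", "C"])
    for c in "ABC":
        assert report.quadrants[c].total == 6
    assert report.overall_accuracy == pytest.approx(4 / 6)
    assert report.per_class_accuracy["B"] == pytest.approx(1.0)


def test_jackknife_identical_vectors():
    X = np.array([[1.0, 2.0], [1.0, 2.0]])
    same = ReferenceSet(X, ["A", "A"], classes=["A", "B"])
    assert jackknife(same, FknnParams(K=1)).overall_accuracy == 1.0
    diff = ReferenceSet(X, ["A", "B"])
    assert jackknife(diff, FknnParams(K=1)).overall_accuracy == 0.0


def test_jackknife_separable_fixture_is_perfect(separable_reference):
    report = jackknife(separable_reference, FknnParams(K=3, m=2.0))
    assert report.overall_accuracy == 1.0
    assert all(v == 1.0 for v in report.per_class_mcc.values())


def test_jackknife_rejects_k_too_large():
    ref = ReferenceSet(np.zeros((3, 2)), ["A", "B", "A"])
    with pytest.raises(ParameterError):
        jackknife(ref, FknnParams(K=3))


def test_jackknife_invariant_under_reference_permutation(separable_reference):
    rng = np.random.default_rng(8)
    perm = rng.permutation(separable_reference.n)
    shuffled = ReferenceSet(
        separable_reference.X[perm],
        [separable_reference.labels[i] for i in perm],
    )
    a = jackknife(separable_reference, FknnParams(K=4, m=1.6)).overall_accuracy
    b = jackknife(shuffled, FknnParams(K=4, m=1.6)).overall_accuracy
    assert a == b


def test_grid_search_singleton_and_consistency(separable_reference):
    single = grid_search(separable_reference, [2], [1.5])
    assert single.best == (2, 1.5)
    expected = jackknife(separable_reference, FknnParams(K=2, m=1.5)).overall_accuracy
    assert single.grid[(2, 1.5)] == pytest.approx(expected)


def test_grid_search_tie_resolution(separable_reference):
    # the fixture is perfectly separable, so many grid points reach 1.0;
    # the tie must resolve to the smallest K, then the smallest m
    result = grid_search(separable_reference, [5, 1, 3], [2.0, 1.5])
    assert result.best_accuracy == 1.0
    assert result.best == (1, 1.5)


def test_grid_search_rejects_bad_grids(separable_reference):
    with pytest.raises(ParameterError):
        grid_search(separable_reference, [], [2.0])
    with pytest.raises(ParameterError):
        grid_search(separable_reference, [1], [1.0])


# --- the two-level cascade ---------------------------------------------------


@pytest.fixture(scope="module")
def cascade_model(fixture_records, scales):
    return train_cascade(fixture_records, scales=scales)


def test_level1_label_mapping():
    assert level1_label("NR3") == "NR"
    assert level1_label("NONNR") == "NONNR"
    with pytest.raises(ParameterError):
        level1_label("weird")


def test_level2_reference_is_the_nr_subset(cascade_model, fixture_records):
    n_nr = sum(1 for r in fixture_records if r.label != "NONNR")
    assert cascade_model.level2.n == n_nr
    assert set(cascade_model.level2.labels) == {f"NR{i}" for i in range(1, 8)}


def test_zero_distance_queries_route_through_levels(cascade_model, fixture_records):
    nr1 = next(r for r in fixture_records if r.label == "NR1")
    res = predict_two_level(cascade_model, nr1)
    assert (res.level1_label, res.level2_label) == ("NR", "NR1")
    non = next(r for r in fixture_records if r.label == "NONNR")
    res = predict_two_level(cascade_model, non)
    assert res.level1_label == "NONNR"
    assert res.level2_label is None and res.level2_membership is None


def test_batch_prediction_skips_failing_records(cascade_model, fixture_records):
    bad = replace(fixture_records[0], identifier="BAD", sequence="ACDEF")
    results = predict_two_level_batch(cascade_model, [fixture_records[0], bad])
    assert [r.identifier for r in results] == [fixture_records[0].identifier]


def test_two_level_jackknife_routes_separable_fixture(fixture_records, scales):
    report = two_level_jackknife(fixture_records, scales=scales)
    assert report.overall_accuracy >= 0.95
    assert set(report.classes) == {f"NR{i}" for i in range(1, 8)} | {"NONNR"}


def test_independent_test_refuses_leakage(cascade_model, fixture_records):
    with pytest.raises(LeakageError, match=fixture_records[0].identifier):
        independent_test(cascade_model, [fixture_records[0]], level=1)
    renamed = replace(fixture_records[0], identifier="FRESH")
    with pytest.raises(LeakageError, match="FRESH"):
        independent_test(cascade_model, [renamed], level=1)


def test_independent_test_near_identity(cascade_model, fixture_records, scales):
    # disjoint copies: one substituted residue per sequence
    test = []
    for rec in fixture_records:
        seq = ("C" if rec.sequence[0] != "C" else "D") + rec.sequence[1:]
        test.append(replace(rec, identifier="T_" + rec.identifier, sequence=seq))
    rep1 = independent_test(cascade_model, test, level=1)
    assert rep1.overall_accuracy >= 0.95
    rep2 = independent_test(cascade_model, [t for t in test if t.label != "NONNR"], level=2)
    assert rep2.overall_accuracy >= 0.95


def test_independent_test_reports_missing_class_na(cascade_model, fixture_records):
    test = [
        replace(r, identifier="T_" + r.identifier, sequence=r.sequence[1:] + "W")
        for r in fixture_records
        if r.label not in ("NONNR", "NR6")
    ]
    report = independent_test(cascade_model, test, level=2)
    assert "NR6" in report.not_applicable
    assert report.per_class_accuracy["NR6"] is None


def test_feature_ablation_modes(fixture_records, scales):
    nr = [r for r in fixture_records if r.label != "NONNR"]
    table = feature_ablation(
        nr, ["AAC", "AAC+DC(0)", "ALL"], K_values=[1, 3], m_values=[2.0], scales=scales
    )
    assert list(table["mode"]) == ["AAC", "AAC+DC(0)", "ALL"]
    assert list(table["n_features"]) == [20, 420, 881]
    assert table.loc[table["mode"] == "ALL", "accuracy"].item() == 1.0
    with pytest.raises(ParameterError):
        feature_ablation(nr, ["AAC+DC(2)"], [1], [2.0], scales=scales)


def test_model_round_trip(tmp_path, cascade_model, fixture_records):
    path = tmp_path / "model.npz"
    save_model(cascade_model, path)
    loaded = load_model(path)
    assert loaded.params1 == cascade_model.params1
    assert loaded.weights == cascade_model.weights
    assert np.allclose(loaded.level1.X, cascade_model.level1.X)
    query = fixture_records[3]
    assert predict_two_level(loaded, query) == predict_two_level(cascade_model, query)


def test_cascade_accuracy_degrades_with_noise(scales):
    levels = [0.01, 0.08, 0.2, 0.35, 0.5]
    accs = [
        two_level_jackknife(
            generate_fixture(FixtureSpec(seed=5, mutation_rate=r, per_class=10)),
            scales=scales,
        ).overall_accuracy
        for r in levels
    ]
    assert all(a >= b for a, b in zip(accs, accs[1:]))
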