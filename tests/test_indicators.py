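"""Column inversion, delta aggregation and the dual-inversion significance rule."""

import numpy as np
import pytest

from lithicnet import (
    ClassScheme,
    NetworkParameters,
    aggregate_deltas,
    cross_class_overlap,
    indicator_sets,
    indicator_summary,
    invert_column,
    network_deltas,
    presence_counts,
    significance_call,
    train_ensemble,
)
from lithicnet.indicators import (
    ADDITION,
    CONTRA,
    IND,
    NS,
    REMOVAL,
    IndicatorCall,
    compute_delta_records,
    condition_counts,
    extract_indicator_calls,
)
from lithicnet.mlp import init_network, rescale_inputs


# ---------------------------------------------------------------- inversion

def test_double_inversion_is_identity(toy_matrix):
    twice = invert_column(invert_column(toy_matrix, "T2"), "T2")
    np.testing.assert_array_equal(twice.presence, toy_matrix.presence)


def test_inversion_touches_only_its_column(toy_matrix):
    inv = invert_column(toy_matrix, "T3")
    j = toy_matrix.technologies.index("T3")
    np.testing.assert_array_equal(inv.presence[:, j], 1 - toy_matrix.presence[:, j])
    others = [k for k in range(4) if k != j]
    np.testing.assert_array_equal(inv.presence[:, others], toy_matrix.presence[:, others])


def test_inverting_full_column_empties_it(toy_matrix):
    toy_matrix.presence[:, 0] = 1
    inv = invert_column(toy_matrix, "T1")
    assert inv.presence[:, 0].sum() == 0


def test_unknown_technology_rejected(toy_matrix):
    with pytest.raises(Exception, match="Handaxe"):
        invert_column(toy_matrix, "Handaxe")


# ------------------------------------------------------------------- deltas

def test_network_insensitive_to_technology_has_zero_deltas(toy_matrix, rng):
    params = init_network(4, 3, "softmax", rng, n_out=3)
    j = toy_matrix.technologies.index("T2")
    params.W1[:, j] = 0.0
    deltas, _ = network_deltas(params, toy_matrix, "T2")
    np.testing.assert_allclose(deltas, 0.0, atol=1e-12)


def test_three_way_deltas_sum_to_zero(toy_matrix, rng):
    """Softmax probabilities sum to one before and after inversion, so the
    per-assemblage class deltas must sum to zero."""
    params = init_network(4, 3, "softmax", rng, n_out=3)
    deltas, removal_mask = network_deltas(params, toy_matrix, "T1")
    np.testing.assert_allclose(deltas.sum(axis=1), 0.0, atol=1e-12)
    np.testing.assert_array_equal(removal_mask, toy_matrix.presence[:, 0].astype(bool))


def test_two_way_deltas_are_antisymmetric(toy_matrix, rng):
    params = init_network(4, 3, "sigmoid", rng, n_out=1)
    deltas, _ = network_deltas(params, toy_matrix, "T1")
    np.testing.assert_allclose(deltas[:, 0], -deltas[:, 1], atol=1e-15)


def test_single_hidden_unit_delta_matches_closed_form():
    """A hand-built net with one hidden unit reading only T1: the delta for
    inverting T1 is sigmoid(w2·tanh(w1·x1') + b2) − sigmoid(w2·tanh(w1·x1))."""
    w1, w2, b2 = 0.9, 1.4, -0.2
    params = NetworkParameters(
        np.array([[w1, 0.0]]), np.zeros(1), np.array([[w2]]), np.array([b2]), "sigmoid"
    )
    from lithicnet.assemblages import TechnologyMatrix

    m = TechnologyMatrix(["a", "b"], ["T1", "T2"], np.array([[1, 0], [0, 1]]),
                         ["LSA", "MIS5 MSA"])
    deltas, removal_mask = network_deltas(params, m, "T1")

    def f(x1):
        return 1.0 / (1.0 + np.exp(-(w2 * np.tanh(w1 * x1) + b2)))

    np.testing.assert_allclose(deltas[0, 0], f(-1) - f(+1), atol=1e-12)  # removal
    np.testing.assert_allclose(deltas[1, 0], f(+1) - f(-1), atol=1e-12)  # addition
    np.testing.assert_array_equal(removal_mask, [True, False])


# -------------------------------------------------------------- aggregation

def test_aggregate_degenerate_distribution():
    rec = aggregate_deltas(np.full(50, 0.123), "T1", "LSA", REMOVAL, n=7)
    assert rec.ci_low == rec.median == rec.ci_high == pytest.approx(0.123)
    assert rec.ci_low <= rec.median <= rec.ci_high


def test_aggregate_symmetric_distribution_straddles_zero(rng):
    vals = rng.normal(0.0, 0.1, size=500)
    rec = aggregate_deltas(vals, "T1", "LSA", ADDITION, n=20)
    assert rec.ci_low < 0 < rec.ci_high
    assert not rec.ci_excludes_zero()


def test_aggregate_matches_manual_percentiles():
    """Five per-network medians: the 2.5/50/97.5 percentiles with linear
    interpolation are −0.27, 0.1 and 0.38 (hand-computed)."""
    vals = np.array([-0.3, -0.1, 0.1, 0.2, 0.4])
    rec = aggregate_deltas(vals, "T1", "LSA", REMOVAL, n=4)
    assert rec.median == pytest.approx(0.1)
    assert rec.ci_low == pytest.approx(-0.3 + 0.025 * 4 * 0.2)   # −0.28
    assert rec.ci_high == pytest.approx(0.2 + (0.975 - 0.75) * 4 * 0.2)  # 0.38
    assert rec.n == 4


def test_aggregate_empty_condition_not_estimable():
    rec = aggregate_deltas(np.array([]), "T1", "LSA", REMOVAL, n=0)
    assert not rec.estimable
    assert not rec.ci_excludes_zero()


def test_per_network_median_aggregation_manual_case(rng):
    """Five hand-set 'networks' × four assemblages: per-network medians over
    the applicable assemblages, then percentiles over those medians."""
    from lithicnet.assemblages import TechnologyMatrix
    from lithicnet.ensemble import EnsembleResult, Partition
    from lithicnet.training import TrainedNetwork

    # build a deterministic 2-assemblage removal condition via a tiny matrix
    m = TechnologyMatrix(
        ["a", "b", "c", "d"], ["T1", "T2"],
        np.array([[1, 0], [1, 1], [0, 1], [0, 0]]),
        ["LSA", "LSA", "MIS3&4 MSA", "MIS5 MSA"],
    )
    scheme = ClassScheme.three_way()
    nets = []
    rng_local = np.random.default_rng(0)
    for _ in range(5):
        params = init_network(2, 2, "softmax", rng_local, n_out=3)
        nets.append(TrainedNetwork(params, Partition(np.arange(4), np.array([], dtype=int)),
                                   0.0, 0.0, 1.0))
    X = rescale_inputs(m.presence)
    from lithicnet.mlp import class_probabilities

    tensor = np.stack([class_probabilities(n.params, X) for n in nets])
    ens = EnsembleResult(scheme, nets, tensor, np.full(5, 0.2),
                         tensor.mean(axis=0), ["LSA"] * 4,
                         np.zeros(4), ["LSA", "LSA", "MIS3&4 MSA", "MIS5 MSA"])
    records = compute_delta_records(ens, m)

    # manual recomputation for T1 / LSA / removal (assemblages a and b)
    X_inv = rescale_inputs(invert_column(m, "T1").presence)
    manual = []
    for n in nets:
        d = class_probabilities(n.params, X_inv) - class_probabilities(n.params, X)
        manual.append(np.median(d[[0, 1], 0]))
    rec = records[("T1", "LSA", REMOVAL)]
    np.testing.assert_allclose(np.sort(rec.per_network_medians), np.sort(manual), atol=1e-15)
    lo, med, hi = np.percentile(manual, [2.5, 50, 97.5])
    assert rec.median == pytest.approx(med) and rec.ci_low == pytest.approx(lo)
    assert rec.n == 2


# ------------------------------------------------------------- significance

def _rec(tech, cls, cond, lo, med, hi, n):
    from lithicnet.indicators import DeltaRecord

    return DeltaRecord(tech, cls, cond, np.array([med]), med, lo, hi, n)


def test_published_backed_pieces_row_is_significant_indicator():
    """Backed Pieces for LSA: removal (−0.365, −0.236, −0.074, n=53) and
    addition (0.107, 0.247, 0.339, n=39) → IND."""
    removal = _rec("Backed Pieces", "LSA", REMOVAL, -0.365, -0.236, -0.074, 53)
    addition = _rec("Backed Pieces", "LSA", ADDITION, 0.107, 0.247, 0.339, 39)
    call = significance_call(removal, addition)
    assert call.status == IND


def test_small_sample_blocks_significance_regardless_of_cis():
    """A removal condition with n=6 (the Levallois Blade case) can never be
    significant, however clean its intervals."""
    removal = _rec("Levallois Blade Tech", "LSA", REMOVAL, -0.4, -0.3, -0.2, 6)
    addition = _rec("Levallois Blade Tech", "LSA", ADDITION, 0.2, 0.3, 0.4, 86)
    call = significance_call(removal, addition)
    assert call.status == NS
    assert not call.reasons["removal_n_ok"]


def test_same_sign_medians_not_significant():
    removal = _rec("T", "LSA", REMOVAL, 0.1, 0.2, 0.3, 40)
    addition = _rec("T", "LSA", ADDITION, 0.1, 0.2, 0.3, 52)
    assert significance_call(removal, addition).status == NS


def test_ci_through_zero_not_significant():
    removal = _rec("T", "LSA", REMOVAL, -0.3, -0.2, 0.05, 40)
    addition = _rec("T", "LSA", ADDITION, 0.1, 0.2, 0.3, 52)
    call = significance_call(removal, addition)
    assert call.status == NS
    assert not call.reasons["removal_ci_excludes_zero"]


def test_contra_indicator_sign_pattern():
    removal = _rec("Core Tool", "LSA", REMOVAL, 0.009, 0.086, 0.191, 23)
    addition = _rec("Core Tool", "LSA", ADDITION, -0.311, -0.180, -0.048, 69)
    assert significance_call(removal, addition).status == CONTRA


# ----------------------------------------------------------- summary tables

def test_summary_empty_when_all_ns(scheme3):
    calls = {
        ("T1", c): IndicatorCall("T1", c, NS) for c in scheme3.classes
    }
    df = indicator_summary(calls, scheme3)
    assert df.empty


def test_summary_layout(scheme3):
    calls = {}
    for c in scheme3.classes:
        calls[("Backed Pieces", c)] = IndicatorCall("Backed Pieces", c, NS)
        calls[("Core Tool", c)] = IndicatorCall("Core Tool", c, NS)
    calls[("Backed Pieces", "LSA")] = IndicatorCall("Backed Pieces", "LSA", IND)
    calls[("Core Tool", "MIS5 MSA")] = IndicatorCall("Core Tool", "MIS5 MSA", IND)
    calls[("Core Tool", "LSA")] = IndicatorCall("Core Tool", "LSA", CONTRA)
    df = indicator_summary(calls, scheme3)
    assert list(df.index) == ["Backed Pieces", "Core Tool"]
    assert df.loc["Backed Pieces", "LSA"] == IND
    assert df.loc["Core Tool", "LSA"] == CONTRA
    assert df.loc["Core Tool", "MIS3&4 MSA"] == ""


def test_two_way_contra_joins_other_class_indicator_set(scheme2):
    calls = {
        ("Backed Pieces", "LSA"): IndicatorCall("Backed Pieces", "LSA", IND),
        ("Core Tool", "LSA"): IndicatorCall("Core Tool", "LSA", CONTRA),
        ("Backed Pieces", "MSA"): IndicatorCall("Backed Pieces", "MSA", CONTRA),
        ("Core Tool", "MSA"): IndicatorCall("Core Tool", "MSA", IND),
    }
    sets = indicator_sets(calls, scheme2)
    assert sets["LSA"] == {"Backed Pieces"}
    assert sets["MSA"] == {"Core Tool"}


# ------------------------------------------------------------------ overlap

def test_overlap_hand_fixture(scheme3):
    from lithicnet.assemblages import TechnologyMatrix

    m = TechnologyMatrix(
        ["a", "b", "c", "d"], ["T1", "T2", "T3"],
        np.array([[1, 1, 1], [1, 0, 0], [0, 1, 1], [0, 0, 0]]),
        ["LSA", "LSA", "MIS3&4 MSA", "MIS5 MSA"],
    )
    sets = {"LSA": {"T1"}, "MIS3&4 MSA": {"T2"}, "MIS5 MSA": {"T3"}}
    out = cross_class_overlap(m, sets)
    # a: all three; b: one; c: two; d: none
    assert float(out["multi_class"]) == pytest.approx(2 / 4)
    assert float(out["all_classes"]) == pytest.approx(1 / 4)


def test_overlap_empty_sets_zero(toy_matrix):
    out = cross_class_overlap(toy_matrix, {"LSA": set(), "MSA": set()})
    assert float(out["multi_class"]) == 0.0
    assert float(out["both_classes"]) == 0.0


# -------------------------------------------------- pipeline-level invariants

def test_condition_counts_match_prevalence_and_partition_92(surrogate, scheme3, trained_ensemble3):
    """Removal n equals the presence count for every technology, and the two
    conditions partition the 92 assemblages."""
    records = compute_delta_records(trained_ensemble3, surrogate)
    counts = presence_counts(surrogate)
    for tech in surrogate.technologies:
        rem = records[(tech, "LSA", REMOVAL)]
        add = records[(tech, "LSA", ADDITION)]
        assert rem.n == counts[tech]
        assert rem.n + add.n == 92
    cc = condition_counts(surrogate)
    assert (cc["n_removal"] + cc["n_addition"] == 92).all()


def test_class_medians_sum_to_zero_across_classes(surrogate, scheme3, trained_ensemble3):
    """Three-way softmax deltas sum to zero exactly per assemblage, so the
    per-class ensemble medians per condition nearly cancel wherever the delta
    distributions are roughly symmetric — i.e. for technologies without a
    strong class association. (For strongly class-linked technologies the
    median is a nonlinear summary of a skewed distribution and cancellation
    is only loose, as in the published indicator tables.)"""
    records = compute_delta_records(trained_ensemble3, surrogate)
    for tech in ("Borer", "Notch", "Platform Core", "Centripetal Tech"):
        for cond in (REMOVAL, ADDITION):
            total = sum(records[(tech, c, cond)].median for c in scheme3.classes)
            assert abs(total) < 0.02, (tech, cond, total)
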