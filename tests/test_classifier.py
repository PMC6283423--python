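"""Positive-unlabeled naive Bayes: likelihoods, scoring, prior, validation."""

import math

import numpy as np
import pandas as pd
import pytest

from uorfcatalog.classifier import (
    NaiveBayesModel,
    fit,
    loo_validate,
    ms_evidence_flags,
    peptide_features,
    peptide_score,
    score_all,
    select_prior,
)
from uorfcatalog.features import DiscretizationScheme, discretize_features


def one_feature_scheme(n_bins=2, name="f"):
    return DiscretizationScheme(cuts={name: [0.5 * (i + 1) for i in range(n_bins - 1)]})


def test_fit_unsmoothed_frequencies():
    """8 of 10 positives in bin 1 with k=0 gives p(bin1|pos) = 0.8."""
    binned = pd.DataFrame({"f": [1.0] * 8 + [0.0] * 2 + [0.0] * 5 + [1.0] * 5})
    mask = np.array([True] * 10 + [False] * 10)
    model = fit(binned, mask, one_feature_scheme(), smoothing=0.0, prior=0.5)
    assert model.likelihood_pos["f"][1] == pytest.approx(0.8)
    assert model.likelihood_unl["f"][0] == pytest.approx(0.5)


def test_fit_add_one_smoothing_unseen_bin():
    """A bin unseen among 10 positives with k=1 and 2 bins gets 1/12."""
    binned = pd.DataFrame({"f": [1.0] * 10 + [0.0] * 5 + [1.0] * 5})
    mask = np.array([True] * 10 + [False] * 10)
    model = fit(binned, mask, one_feature_scheme(), smoothing=1.0, prior=0.5)
    assert model.likelihood_pos["f"][0] == pytest.approx(1 / 12)
    model.validate()


def test_fit_identical_features_identical_tables():
    binned = pd.DataFrame({"a": [0.0, 1.0, 1.0, 0.0], "b": [0.0, 1.0, 1.0, 0.0]})
    mask = np.array([True, True, False, False])
    scheme = DiscretizationScheme(cuts={"a": [0.5], "b": [0.5]})
    model = fit(binned, mask, scheme)
    assert np.allclose(model.likelihood_pos["a"], model.likelihood_pos["b"])


def test_fit_empty_positive_set_fatal():
    binned = pd.DataFrame({"f": [0.0, 1.0]})
    with pytest.raises(ValueError, match="positive"):
        fit(binned, np.array([False, False]), one_feature_scheme())


def hand_model(prior=0.5):
    scheme = DiscretizationScheme(cuts={"f1": [0.5], "f2": [0.5]})
    return NaiveBayesModel(
        prior,
        {"f1": np.array([0.8, 0.2]), "f2": np.array([0.9, 0.1])},
        {"f1": np.array([0.4, 0.6]), "f2": np.array([0.3, 0.7])},
        0.0,
        scheme,
    )


def test_score_two_feature_hand_computation():
    """p_pos/p_neg = 0.5*0.8*0.9 / (0.5*0.4*0.3) = 6, so score = ln 6."""
    scores = score_all(hand_model(), pd.DataFrame({"f1": [0.0], "f2": [0.0]}))
    assert scores[0].score == pytest.approx(math.log(6))
    assert scores[0].label is True


def test_score_prior_only_and_tie_break():
    """Uniform likelihoods leave only the prior; at P_pos = 0.5 the score is
    exactly 0 and the strict > rule labels negative."""
    scheme = DiscretizationScheme(cuts={"f": [0.5]})
    uniform = NaiveBayesModel(
        0.5, {"f": np.array([0.5, 0.5])}, {"f": np.array([0.5, 0.5])}, 0.0, scheme
    )
    s = score_all(uniform, pd.DataFrame({"f": [1.0]}))[0]
    assert s.score == pytest.approx(0.0) and s.label is False
    biased = NaiveBayesModel(
        0.61, {"f": np.array([0.5, 0.5])}, {"f": np.array([0.5, 0.5])}, 0.0, scheme
    )
    s = score_all(biased, pd.DataFrame({"f": [1.0]}))[0]
    assert s.score == pytest.approx(math.log(0.61 / 0.39))


def test_uninformative_feature_contributes_nothing():
    model = hand_model()
    base = score_all(model, pd.DataFrame({"f1": [0.0], "f2": [0.0]}))[0].score
    model3 = NaiveBayesModel(
        0.5,
        {**model.likelihood_pos, "f3": np.array([0.6, 0.4])},
        {**model.likelihood_unl, "f3": np.array([0.6, 0.4])},
        0.0,
        DiscretizationScheme(cuts={"f1": [0.5], "f2": [0.5], "f3": [0.5]}),
    )
    got = score_all(model3, pd.DataFrame({"f1": [0.0], "f2": [0.0], "f3": [1.0]}))
    assert got[0].score == pytest.approx(base)


def test_feature_order_permutation_invariance():
    frame = pd.DataFrame({"f1": [0.0, 1.0], "f2": [1.0, 0.0]})
    a = [s.score for s in score_all(hand_model(), frame)]
    b = [s.score for s in score_all(hand_model(), frame[["f2", "f1"]])]
    assert a == pytest.approx(b)


def test_missing_value_skips_feature():
    frame = pd.DataFrame({"f1": [0.0], "f2": [np.nan]})
    s = score_all(hand_model(), frame)[0]
    assert s.score == pytest.approx(math.log(0.8 / 0.4))


def test_select_prior_separable_plateau():
    """A perfectly separating feature gives an F1=1 plateau; the smallest
    plateau prior is returned."""
    binned = pd.DataFrame({"f": [1.0] * 20 + [0.0] * 80})
    mask = np.array([True] * 20 + [False] * 80)
    scheme = one_feature_scheme()
    prior, table = select_prior(binned, mask, scheme, smoothing=0.0)
    assert table["f1"].max() == pytest.approx(1.0)
    plateau = table.loc[table["f1"] >= 1.0 - 1e-12, "prior"]
    assert prior == pytest.approx(plateau.min())


def test_select_prior_uninformative_goes_all_positive():
    """With a constant feature the classifier is prior-driven; F1 is maximized
    by the all-positive regime (F1 = 2P/(P+n) with P positives of n), so the
    chosen prior sits at the smallest grid value tipping every score > 0."""
    binned = pd.DataFrame({"f": [0.0] * 100})
    mask = np.array([True] * 25 + [False] * 75)
    scheme = DiscretizationScheme(cuts={"f": []})
    prior, table = select_prior(binned, mask, scheme, smoothing=1.0)
    expected_f1 = 2 * 25 / (25 + 100)
    assert table["f1"].max() == pytest.approx(expected_f1)
    assert prior == pytest.approx(0.51)  # first grid point with log-odds > 0


# ---------------------------------------------------------------------------
# peptide score
# ---------------------------------------------------------------------------

def test_peptide_features_hand_values():
    frame = peptide_features(["MKT"])
    row = frame.iloc[0]
    assert row["length"] == 3
    assert row["freq_M"] == row["freq_K"] == row["freq_T"] == pytest.approx(1 / 3)
    assert row["freq_A"] == 0


def test_ms_evidence_exact_match_excluding_cds():
    flags = ms_evidence_flags(
        uorf_peptides=["MKTLLW", "MAAA"],
        evidence_peptides=["KTLL", "AAA"],
        cds_peptides=["XXAAAXX"],  # AAA also maps to a CDS -> unusable
    )
    assert flags == [True, False]


def test_identical_peptides_identical_scores():
    seqs = {"u1": "ATGAAAACATAA", "u2": "ATGAAAACATAA", "u3": "ATGTGGTGGTAA"}
    scores = {p.key: p.probability for p in peptide_score(seqs, {"u1"})}
    assert scores["u1"] == pytest.approx(scores["u2"])
    assert 0 < scores["u3"] < 1


# ---------------------------------------------------------------------------
# leave-one-experiment-out validation
# ---------------------------------------------------------------------------

def test_loo_perfect_feature_gives_auc_one(rng):
    """Scores that rank every held-out positive above all negatives give
    AUC exactly 1 in each fold (each active uORF detected by exactly one
    experiment, so the evaluation negatives are pure inactives)."""
    n = 402
    active = np.arange(n) < 81
    feature = np.where(active, 5.0, 0.0)  # cleanly separable
    assignment = np.arange(n) % 3
    detections = pd.DataFrame(
        {f"e{i}": active & (assignment == i) for i in range(3)}
    )
    report = loo_validate(pd.DataFrame({"x": feature}), detections)
    assert len(report.folds) == 3
    assert all(f.auc == 1.0 for f in report.folds)


def test_loo_random_scores_auc_half(rng):
    n = 1000
    detections = pd.DataFrame(
        {f"e{i}": rng.random(n) < 0.2 for i in range(3)}
    )
    features = pd.DataFrame({"noise": rng.normal(size=n)})
    report = loo_validate(features, detections)
    assert report.mean_auc == pytest.approx(0.5, abs=0.05)


def test_loo_requires_three_experiments(rng):
    detections = pd.DataFrame({"e1": [True, False], "e2": [False, True]})
    with pytest.raises(ValueError):
        loo_validate(pd.DataFrame({"x": [0.0, 1.0]}), detections)
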