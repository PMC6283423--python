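"""Feature extraction rules, MDLP discretization, and KS prioritization."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uorfcatalog.features import (
    FeatureContext,
    compute_features,
    default_feature_catalog,
    discretize_features,
    ks_rank,
    mdlp_cut_points,
)
from uorfcatalog.synthetic_data import simulate_catalog
from uorfcatalog.uorf_scan import scan_transcript
from conftest import make_single_exon

SEQ = "ATGAAATAGC" + "ATGGATTAA"


@pytest.fixture()
def context_and_record():
    model = make_single_exon(SEQ, cds_start=11)
    rec = scan_transcript(model, SEQ)[0]  # ATG@1, stop TAG@7-9
    ctx = FeatureContext(
        models={"t1": model},
        sequences={"t1": SEQ},
        conservation={("c", 1): 1.0, ("c", 2): 2.0, ("c", 3): 3.0},
        expression={"t1": 5.0},
        uorfs_per_transcript={"t1": 1},
    )
    return ctx, rec


def test_feature_rules_hand_values(context_and_record):
    ctx, rec = context_and_record
    frame = compute_features([rec], ctx)
    row = frame.iloc[0]
    assert row["dist_to_cds"] == 2  # stop end at 9, CDS start at 11
    assert row["internal_starts"] == 1  # ATA at position 6 of ATGAAATAG
    assert row["gc_content"] == pytest.approx(2 / 9)
    assert row["uorf_length"] == 9
    assert row["utr5_length"] == 10
    assert row["dist_from_cap"] == 0
    assert row["cons_start"] == pytest.approx(2.0)  # mean of 1,2,3
    assert math.isnan(row["cons_stop"])  # no track over the stop codon
    assert row["start_codon"] == "ATG"
    assert row["expression"] == 5.0


def test_missing_tracks_yield_nan():
    model = make_single_exon(SEQ, cds_start=11)
    rec = scan_transcript(model, SEQ)[0]
    ctx = FeatureContext(models={"t1": model}, sequences={"t1": SEQ})
    row = compute_features([rec], ctx).iloc[0]
    assert math.isnan(row["cons_start"]) and math.isnan(row["expression"])


# ---------------------------------------------------------------------------
# MDLP
# ---------------------------------------------------------------------------

def _entropy(labels):
    n = len(labels)
    return -sum((c / n) * math.log2(c / n) for c in Counter(labels).values())


def oracle_mdlp(values, labels):
    """Exhaustive-search discretization oracle: at each recursion step try
    every candidate cut, take the information-gain maximum (smallest cut on
    ties) and accept it by direct evaluation of the Fayyad-Irani criterion."""
    pairs = sorted(zip(values, labels))

    def recurse(pairs):
        n = len(pairs)
        labs = [l for _, l in pairs]
        if n < 2 or len(set(labs)) < 2:
            return []
        best = None
        for i in range(1, n):
            if pairs[i][0] == pairs[i - 1][0]:
                continue
            l1 = [l for _, l in pairs[:i]]
            l2 = [l for _, l in pairs[i:]]
            gain = _entropy(labs) - (len(l1) * _entropy(l1)
                                     + len(l2) * _entropy(l2)) / n
            if best is None or gain > best[0] + 1e-12:
                best = (gain, i, l1, l2)
        if best is None:
            return []
        gain, i, l1, l2 = best
        k, k1, k2 = len(set(labs)), len(set(l1)), len(set(l2))
        delta = math.log2(3**k - 2) - (
            k * _entropy(labs) - k1 * _entropy(l1) - k2 * _entropy(l2)
        )
        if gain <= (math.log2(n - 1) + delta) / n:
            return []
        cut = (pairs[i - 1][0] + pairs[i][0]) / 2
        return recurse(pairs[:i]) + [cut] + recurse(pairs[i:])

    return sorted(recurse(pairs))


def test_mdlp_single_clean_cut():
    """Two well-separated label blocks get exactly one cut between them."""
    cuts = mdlp_cut_points([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert len(cuts) == 1 and 3 < cuts[0] < 10


def test_mdlp_degenerate_inputs():
    assert mdlp_cut_points([1, 2, 3, 4], [0, 0, 0, 0]) == []  # uniform labels
    assert mdlp_cut_points([5, 5, 5, 5], [0, 1, 0, 1]) == []  # constant feature
    # interleaved labels: no cut survives the MDL acceptance test
    assert mdlp_cut_points([1, 2, 3, 4, 5, 6], [0, 1, 0, 1, 0, 1]) == []


def test_mdlp_matches_exhaustive_oracle():
    rng = np.random.default_rng(42)
    for _ in range(60):
        n = int(rng.integers(2, 31))
        values = rng.integers(0, 10, n).astype(float)
        labels = rng.integers(0, 2, n)
        assert mdlp_cut_points(values, labels) == pytest.approx(
            oracle_mdlp(values.tolist(), labels.tolist())
        )


def test_mdlp_deterministic():
    rng = np.random.default_rng(1)
    values = rng.normal(size=200)
    labels = (values + rng.normal(scale=0.5, size=200) > 0).astype(int)
    assert mdlp_cut_points(values, labels) == mdlp_cut_points(values, labels)


def test_discretization_reduces_class_entropy():
    """Weighted class entropy over bins never exceeds the single-bin entropy
    of the training labels."""
    rng = np.random.default_rng(5)
    values = np.concatenate([rng.normal(0, 1, 150), rng.normal(2, 1, 150)])
    labels = np.arange(300) >= 150
    frame = pd.DataFrame({"x": values})
    scheme = discretize_features(frame, labels)
    binned = scheme.apply(frame)["x"].to_numpy(int)
    total = _entropy(labels.tolist())
    weighted = 0.0
    for b in np.unique(binned):
        sub = labels[binned == b].tolist()
        weighted += len(sub) / len(labels) * _entropy(sub)
    assert weighted <= total + 1e-12


def test_categorical_features_bypass_mdlp():
    frame = pd.DataFrame({"codon": ["ATG", "CTG", "ATG", "ACG"]})
    scheme = discretize_features(frame, np.array([1, 0, 1, 0], bool))
    assert scheme.categories["codon"] == ["ACG", "ATG", "CTG"]
    binned = scheme.apply(pd.DataFrame({"codon": ["CTG", "TTG"]}))
    assert binned["codon"].iloc[0] == 2 and math.isnan(binned["codon"].iloc[1])


# ---------------------------------------------------------------------------
# KS ranking
# ---------------------------------------------------------------------------

def test_ks_hand_values():
    pos = [1.0, 2.0, 3.0]
    frame = pd.DataFrame({"same": pos + pos, "disjoint": pos + [10.0, 11.0, 12.0],
                          "shifted": pos + [2.0, 3.0, 4.0]})
    mask = np.array([True] * 3 + [False] * 3)
    table = ks_rank(frame, mask).set_index("feature")
    assert table.loc["same", "ks"] == 0
    assert table.loc["disjoint", "ks"] == 1
    assert table.loc["shifted", "ks"] == pytest.approx(1 / 3)
    assert sorted(table["rank"]) == [1, 2, 3]


_values = st.floats(-50, 50).filter(lambda v: v == 0 or abs(v) > 1e-3)


@settings(max_examples=30, deadline=None)
@given(st.lists(_values, min_size=3, max_size=20, unique=True),
       st.lists(_values, min_size=3, max_size=20, unique=True))
def test_ks_invariant_under_monotone_transform(pos, unl):
    frame = pd.DataFrame({"x": pos + unl})
    mask = np.array([True] * len(pos) + [False] * len(unl))
    base = ks_rank(frame, mask)["ks"].iloc[0]
    transformed = ks_rank(np.exp(frame / 25.0), mask)["ks"].iloc[0]
    assert transformed == pytest.approx(base)


def test_shifted_features_rank_high_on_synthetic_catalog():
    """With the generator's defaults (conserved starts, shorter CDS distance
    for active uORFs) those two features land in the KS top 5."""
    sim = simulate_catalog(seed=2)
    pos = sim.detections.sum(axis=1) >= 2
    table = ks_rank(sim.features, pos.to_numpy())
    top5 = set(table.head(5)["feature"])
    assert {"cons_start", "dist_to_cds"} <= top5
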