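"""Per-uORF attributes, MDLP entropy discretization, and KS feature ranking.

Attributes cover position/length (distance to the CDS, 5'UTR length, uORF
length), conservation at the start/stop codons, expression, and sequence
signatures (GC content, internal near-cognate starts, start-codon identity,
start context). Continuous attributes are discretized by recursive
entropy-minimizing binary splitting with the Fayyad-Irani minimum description
length acceptance criterion, and ranked by the two-sample Kolmogorov-Smirnov
statistic between positive and unlabeled uORFs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import TranscriptModel
from .uorf_scan import NEAR_COGNATE_STARTS, UorfRecord

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class FeatureDef:
    """One attribute: a name, a category, and a deterministic extraction rule.

    ``extract(record, context)`` returns a float (or a category label for
    categorical features) or NaN/None when the rule's inputs are missing.
    """

    name: str
    category: str  # position/length | conservation | expression | sequence
    kind: str  # continuous | categorical
    extract: Callable


@dataclass
class FeatureContext:
    """Shared inputs for feature extraction on one catalog."""

    models: dict[str, TranscriptModel]
    sequences: dict[str, str]
    conservation: dict[tuple[str, int], float] | None = None
    expression: dict[str, float] | None = None
    uorfs_per_transcript: dict[str, int] | None = None


def _seq(rec: UorfRecord, ctx: FeatureContext) -> str:
    return ctx.sequences[rec.transcript_id][rec.t_start - 1 : rec.t_stop_end]


def _codon_conservation(rec: UorfRecord, ctx: FeatureContext, t_first: int) -> float:
    if ctx.conservation is None:
        return math.nan
    model = ctx.models[rec.transcript_id]
    vals = []
    for t in range(t_first, t_first + 3):
        contig, g = model.transcript_to_genome(t)
        v = ctx.conservation.get((contig, g))
        if v is not None:
            vals.append(v)
    return float(np.mean(vals)) if vals else math.nan


def distance_to_cds(rec: UorfRecord, ctx: FeatureContext) -> float:
    """Distance (nt) from the uORF stop-codon end to the CDS start."""
    return float(ctx.models[rec.transcript_id].cds_start - rec.t_stop_end)


def internal_start_count(rec: UorfRecord, ctx: FeatureContext) -> float:
    """Near-cognate/ATG 3-mers inside the uORF, any frame, after position 1."""
    seq = _seq(rec, ctx)
    starts = frozenset(NEAR_COGNATE_STARTS)
    return float(
        sum(1 for i in range(1, len(seq) - 2) if seq[i : i + 3] in starts)
    )


def start_context_score(rec: UorfRecord, ctx: FeatureContext) -> float:
    """Kozak-like context: purine at -3 (+2) and G at +4 (+1) of the start."""
    full = ctx.sequences[rec.transcript_id]
    score = 0.0
    if rec.t_start >= 4 and full[rec.t_start - 4] in "AG":
        score += 2.0
    if rec.t_start + 3 <= len(full) and full[rec.t_start + 2] == "G":
        score += 1.0
    return score


def default_feature_catalog() -> list[FeatureDef]:
    """The attributes named in the main analysis, as an extensible list."""
    return [
        FeatureDef("cons_start", "conservation", CONTINUOUS,
                   lambda r, c: _codon_conservation(r, c, r.t_start)),
        FeatureDef("cons_stop", "conservation", CONTINUOUS,
                   lambda r, c: _codon_conservation(r, c, r.t_stop_end - 2)),
        FeatureDef("dist_to_cds", "position/length", CONTINUOUS, distance_to_cds),
        FeatureDef("dist_from_cap", "position/length", CONTINUOUS,
                   lambda r, c: float(r.t_start - 1)),
        FeatureDef("utr5_length", "position/length", CONTINUOUS,
                   lambda r, c: float(c.models[r.transcript_id].utr5_length)),
        FeatureDef("uorf_length", "position/length", CONTINUOUS,
                   lambda r, c: float(r.length)),
        FeatureDef("internal_starts", "sequence", CONTINUOUS, internal_start_count),
        FeatureDef("gc_content", "sequence", CONTINUOUS,
                   lambda r, c: sum(b in "GC" for b in _seq(r, c)) / r.length),
        FeatureDef("start_codon", "sequence", CATEGORICAL,
                   lambda r, c: r.start_codon),
        FeatureDef("start_context", "sequence", CONTINUOUS, start_context_score),
        FeatureDef("n_uorfs_on_transcript", "position/length", CONTINUOUS,
                   lambda r, c: float((c.uorfs_per_transcript or {})
                                      .get(r.transcript_id, math.nan))),
        FeatureDef("expression", "expression", CONTINUOUS,
                   lambda r, c: float((c.expression or {})
                                      .get(r.transcript_id, math.nan))),
    ]


def compute_features(
    records: list[UorfRecord],
    context: FeatureContext,
    catalog: list[FeatureDef] | None = None,
) -> pd.DataFrame:
    """Evaluate every feature rule on every uORF; missing values become NaN."""
    catalog = catalog or default_feature_catalog()
    names = [f.name for f in catalog]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in catalog")
    data = {}
    for fdef in catalog:
        col = [fdef.extract(rec, context) for rec in records]
        data[fdef.name] = col if fdef.kind == CATEGORICAL else np.asarray(col, float)
    frame = pd.DataFrame(data)
    frame.index = pd.Index([rec.key for rec in records], name="uorf_key", tupleize_cols=False)
    return frame


# ---------------------------------------------------------------------------
# MDLP discretization (Fayyad & Irani recursive entropy minimization)
# ---------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _best_cut(values: np.ndarray, labels: np.ndarray):
    """Best binary cut of a sorted value/label pair by class-information gain.

    Returns (cut, gain, ent_parent, k, k1, k2, ent1, ent2) or None when no
    candidate cut exists. Candidate cuts are midpoints between adjacent
    distinct values; ties on gain break toward the smallest cut.
    """
    n = len(values)
    classes, y = np.unique(labels, return_inverse=True)
    k = len(classes)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    left = np.cumsum(onehot, axis=0)  # counts for splits after index i
    total = left[-1]
    ent_parent = _entropy(total)
    boundaries = np.nonzero(values[1:] != values[:-1])[0]  # split after index i
    if len(boundaries) == 0:
        return None
    best = None
    for i in boundaries:
        c1 = left[i]
        c2 = total - c1
        n1, n2 = i + 1, n - i - 1
        ent1, ent2 = _entropy(c1), _entropy(c2)
        gain = ent_parent - (n1 * ent1 + n2 * ent2) / n
        cut = (values[i] + values[i + 1]) / 2.0
        if best is None or gain > best[1] + 1e-12:
            k1 = int((c1 > 0).sum())
            k2 = int((c2 > 0).sum())
            best = (cut, gain, ent_parent, k, k1, k2, ent1, ent2)
    return best


def mdl_accepts(n, gain, ent_parent, k, k1, k2, ent1, ent2) -> bool:
    """Fayyad-Irani MDL acceptance test for a binary split of n examples."""
    delta = math.log2(3**k - 2) - (k * ent_parent - k1 * ent1 - k2 * ent2)
    return gain > (math.log2(n - 1) + delta) / n


def mdlp_cut_points(values, labels) -> list[float]:
    """Recursive MDLP discretization; returns sorted accepted cut points.

    Finite values only; requires at least 2 observations (fewer, or a
    constant feature, or uniform labels, gives no cuts).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    order = np.argsort(values, kind="stable")
    values, labels = values[order], labels[order]
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        v, y = values[lo:hi], labels[lo:hi]
        if hi - lo < 2 or len(np.unique(y)) < 2:
            return
        best = _best_cut(v, y)
        if best is None:
            return
        cut, gain, ent_parent, k, k1, k2, ent1, ent2 = best
        if not mdl_accepts(hi - lo, gain, ent_parent, k, k1, k2, ent1, ent2):
            return
        cuts.append(cut)
        mid = lo + int(np.searchsorted(v, cut, side="right"))
        recurse(lo, mid)
        recurse(mid, hi)

    recurse(0, len(values))
    return sorted(cuts)


@dataclass
class DiscretizationScheme:
    """Per-feature cut points (continuous) or category lists (categorical)."""

    cuts: dict[str, list[float]] = field(default_factory=dict)
    categories: dict[str, list] = field(default_factory=dict)
    fallback: set[str] = field(default_factory=set)

    def n_bins(self, name: str) -> int:
        if name in self.categories:
            return len(self.categories[name])
        return len(self.cuts[name]) + 1

    def apply(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Map feature values to integer bins; missing values stay NaN.

        Continuous values map by cut points (np.digitize); categories unseen
        in training map to NaN.
        """
        out = {}
        for name in frame.columns:
            if name in self.categories:
                cat_index = {c: i for i, c in enumerate(self.categories[name])}
                out[name] = np.array(
                    [cat_index.get(v, np.nan) for v in frame[name]], float
                )
            else:
                vals = np.asarray(frame[name], float)
                binned = np.digitize(vals, self.cuts[name]).astype(float)
                binned[~np.isfinite(vals)] = np.nan
                out[name] = binned
        return pd.DataFrame(out, index=frame.index)


def discretize_features(
    frame: pd.DataFrame,
    positive_mask: np.ndarray,
    feature_kinds: dict[str, str] | None = None,
) -> DiscretizationScheme:
    """Fit an MDLP scheme per feature against the positive/unlabeled split.

    Categorical features (object dtype, or listed in ``feature_kinds``)
    bypass MDLP: each observed category is a bin. Continuous features with no
    accepted cut fall back to a single bin and are flagged.
    """
    feature_kinds = feature_kinds or {}
    scheme = DiscretizationScheme()
    labels = np.asarray(positive_mask, bool).astype(int)
    for name in frame.columns:
        kind = feature_kinds.get(
            name, CATEGORICAL if frame[name].dtype == object else CONTINUOUS
        )
        if kind == CATEGORICAL:
            scheme.categories[name] = sorted(pd.unique(frame[name].dropna()))
            continue
        vals = np.asarray(frame[name], float)
        ok = np.isfinite(vals)
        cuts = mdlp_cut_points(vals[ok], labels[ok]) if ok.sum() >= 2 else []
        scheme.cuts[name] = cuts
        if not cuts:
            scheme.fallback.add(name)
    return scheme


# ---------------------------------------------------------------------------
# KS feature prioritization
# ---------------------------------------------------------------------------

def ks_rank(frame: pd.DataFrame, positive_mask: np.ndarray) -> pd.DataFrame:
    """Rank features by the two-sample KS statistic (positive vs unlabeled).

    A greater statistic means greater power to distinguish the sets.
    Categorical features and features with an all-missing group get KS NaN
    and rank last, flagged. Ranks are 1..N, descending by statistic.
    """
    mask = np.asarray(positive_mask, bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both the positive and the unlabeled group must be non-empty")
    rows = []
    for name in frame.columns:
        if frame[name].dtype == object:
            rows.append((name, math.nan, math.nan, True))
            continue
        pos = np.asarray(frame[name][mask], float)
        unl = np.asarray(frame[name][~mask], float)
        pos, unl = pos[np.isfinite(pos)], unl[np.isfinite(unl)]
        if len(pos) == 0 or len(unl) == 0:
            rows.append((name, math.nan, math.nan, True))
            continue
        res = stats.ks_2samp(pos, unl)
        rows.append((name, float(res.statistic), float(res.pvalue), False))
    out = pd.DataFrame(rows, columns=["feature", "ks", "pvalue", "flagged"])
    out = out.sort_values(
        by=["ks", "feature"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
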