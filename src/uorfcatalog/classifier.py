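"""Positive-unlabeled Naive-Bayes classification of uORFs.

The model scores each uORF by comparing P_pos * prod_i p(A_i | pos) against
P_neg * prod_i p(A_i | unl), where the likelihoods are smoothed empirical bin
frequencies of the discretized attributes in the positive (2-voted) and
unlabeled training sets, and P_pos + P_neg = 1. The reported score is the
natural log odds log(p_pos / p_neg), with 0 as the positive/negative
threshold. The prior P_pos is chosen by F1 maximization on a grid; the
operating point used for the published genome-scale catalog was 0.61.

Feature independence is certainly violated in practice; naive Bayes is used
for its robustness as a ranking score, not as a calibrated posterior.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve

from .annotation_io import translate_orf
from .features import DiscretizationScheme, discretize_features

logger = logging.getLogger(__name__)

#: F1-maximizing prior at the published genome-scale operating point.
DEFAULT_PRIOR = 0.61

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class NaiveBayesModel:
    prior: float
    likelihood_pos: dict[str, np.ndarray]
    likelihood_unl: dict[str, np.ndarray]
    smoothing: float
    scheme: DiscretizationScheme
    n_clamped: int = 0

    @property
    def prior_neg(self) -> float:
        return 1.0 - self.prior

    def feature_names(self) -> list[str]:
        return list(self.likelihood_pos)

    def validate(self, tol: float = 1e-9) -> None:
        """Check the probability invariants of a fitted model."""
        assert abs(self.prior + self.prior_neg - 1.0) <= tol
        for name in self.likelihood_pos:
            for table in (self.likelihood_pos[name], self.likelihood_unl[name]):
                if abs(table.sum() - 1.0) > tol:
                    raise AssertionError(f"likelihoods of {name} do not normalize")
                if (table <= 0).any():
                    raise AssertionError(f"non-positive likelihood in {name}")


@dataclass
class UorfScore:
    key: object
    p_pos: float
    p_neg: float
    score: float

    @property
    def label(self) -> bool:
        """Positive iff score strictly exceeds 0."""
        return self.score > 0


def _bin_frequencies(binned: np.ndarray, n_bins: int, k: float) -> np.ndarray:
    ok = np.isfinite(binned)
    counts = np.bincount(binned[ok].astype(int), minlength=n_bins).astype(float)
    return (counts + k) / (counts.sum() + k * n_bins)


def fit(
    binned: pd.DataFrame,
    positive_mask: np.ndarray,
    scheme: DiscretizationScheme,
    smoothing: float = 1.0,
    prior: float = DEFAULT_PRIOR,
) -> NaiveBayesModel:
    """Fit per-attribute bin likelihoods for the positive and unlabeled sets.

    ``binned`` holds integer bin indices (NaN = missing). Likelihoods are
    add-k smoothed empirical frequencies; k defaults to 1 so every bin keeps
    positive mass.
    """
    mask = np.asarray(positive_mask, bool)
    if mask.sum() == 0:
        raise ValueError("empty positive set")
    if (~mask).sum() == 0:
        raise ValueError("empty unlabeled set")
    lik_pos, lik_unl = {}, {}
    for name in binned.columns:
        n_bins = scheme.n_bins(name)
        col = np.asarray(binned[name], float)
        lik_pos[name] = _bin_frequencies(col[mask], n_bins, smoothing)
        lik_unl[name] = _bin_frequencies(col[~mask], n_bins, smoothing)
    model = NaiveBayesModel(prior, lik_pos, lik_unl, smoothing, scheme)
    if smoothing > 0:
        model.validate()
    return model


def log_likelihood_ratios(model: NaiveBayesModel, binned: pd.DataFrame) -> np.ndarray:
    """Sum of per-feature log(p(A_i|pos)/p(A_i|unl)); missing features skip.

    Bin indices outside the training range (a value past the outermost cut
    cannot occur, but unseen categories can) are clamped to the nearest bin
    and counted on the model.
    """
    total = np.zeros(len(binned))
    for name in model.feature_names():
        col = np.asarray(binned[name], float)
        ok = np.isfinite(col)
        idx = col[ok].astype(int)
        n_bins = len(model.likelihood_pos[name])
        clamped = np.clip(idx, 0, n_bins - 1)
        model.n_clamped += int((clamped != idx).sum())
        with np.errstate(divide="ignore"):  # k=0 fits may hold zero mass
            contrib = np.log(model.likelihood_pos[name][clamped]) - np.log(
                model.likelihood_unl[name][clamped]
            )
        total[ok] += contrib
    return total


def score_all(model: NaiveBayesModel, binned: pd.DataFrame) -> list[UorfScore]:
    """Score every row as the natural-log odds of being an active uORF."""
    llr = log_likelihood_ratios(model, binned)
    log_prior = math.log(model.prior) - math.log(model.prior_neg)
    scores = llr + log_prior
    out = []
    for key, s in zip(binned.index, scores):
        # p_pos/p_neg on the probability scale, normalized for readability
        p_pos = 1.0 / (1.0 + math.exp(-s))
        out.append(UorfScore(key=key, p_pos=p_pos, p_neg=1.0 - p_pos, score=float(s)))
    return out


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def select_prior(
    binned: pd.DataFrame,
    positive_mask: np.ndarray,
    scheme: DiscretizationScheme,
    grid: np.ndarray | None = None,
    smoothing: float = 1.0,
) -> tuple[float, pd.DataFrame]:
    """Choose the prior P_pos maximizing F1 on the training partition.

    Truth positives are the (2-voted) positives, truth negatives the
    unlabeled examples. Ties break toward the smallest prior. If no grid
    value achieves F1 > 0, a warning is logged and 0.5 returned.
    """
    if grid is None:
        grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
    mask = np.asarray(positive_mask, bool)
    model = fit(binned, mask, scheme, smoothing, prior=0.5)
    llr = log_likelihood_ratios(model, binned)
    rows = []
    best_prior, best_f1 = None, -1.0
    for p in grid:
        predicted = llr + (math.log(p) - math.log1p(-p)) > 0
        tp = int((predicted & mask).sum())
        fp = int((predicted & ~mask).sum())
        fn = int((~predicted & mask).sum())
        f1 = _f1(tp, fp, fn)
        rows.append((float(p), f1))
        if f1 > best_f1 + 1e-12:
            best_prior, best_f1 = float(p), f1
    if best_f1 <= 0:
        logger.warning("F1 is zero across the whole prior grid; defaulting to 0.5")
        best_prior = 0.5
    return best_prior, pd.DataFrame(rows, columns=["prior", "f1"])


# ---------------------------------------------------------------------------
# Peptide feature score
# ---------------------------------------------------------------------------

def peptide_features(
    peptides: list[str], ms_flags: list[bool] | None = None
) -> pd.DataFrame:
    """Peptide length, the 20 amino-acid frequencies, and the MS flag."""
    if ms_flags is None:
        ms_flags = [False] * len(peptides)
    rows = []
    for pep, ms in zip(peptides, ms_flags):
        n = len(pep)
        row = {"length": float(n)}
        for aa in AA_ALPHABET:
            row[f"freq_{aa}"] = pep.count(aa) / n if n else 0.0
        row["ms_evidence"] = float(bool(ms))
        rows.append(row)
    return pd.DataFrame(rows)


def ms_evidence_flags(
    uorf_peptides: list[str], evidence_peptides: list[str],
    cds_peptides: list[str] | None = None,
) -> list[bool]:
    """Exact-substring mass-spectrometry evidence per uORF peptide.

    A uORF carries MS evidence iff some supplied MS peptide is an exact
    substring of its in-frame translation and does not also occur in any CDS
    translation (frame fidelity and CDS exclusion by construction of the
    translated sequences).
    """
    cds_peptides = cds_peptides or []
    usable = [
        p for p in evidence_peptides
        if p and not any(p in cds for cds in cds_peptides)
    ]
    return [any(p in pep for p in usable) for pep in uorf_peptides]


@dataclass
class PeptideScore:
    key: object
    probability: float


def peptide_score(
    uorf_sequences: dict[object, str],
    positive_keys: set,
    ms_peptides: list[str] | None = None,
    cds_peptides: list[str] | None = None,
    smoothing: float = 1.0,
) -> list[PeptideScore]:
    """Score uORF peptides with the same PU naive-Bayes machinery.

    ``uorf_sequences`` maps uORF key -> nucleotide sequence (start through
    stop). The peptide probability is reported separately and never folded
    into the main uORF score. Zero-length peptides are excluded.
    """
    keys, peps = [], []
    for key, nt in uorf_sequences.items():
        aa = translate_orf(nt)
        if aa:
            keys.append(key)
            peps.append(aa)
    if not keys:
        return []
    flags = ms_evidence_flags(peps, ms_peptides or [], cds_peptides)
    frame = peptide_features(peps, flags)
    mask = np.array([k in positive_keys for k in keys])
    scheme = discretize_features(frame, mask)
    binned = scheme.apply(frame)
    model = fit(binned, mask, scheme, smoothing, prior=0.5)
    scored = score_all(model, binned)
    return [PeptideScore(key=k, probability=s.p_pos) for k, s in zip(keys, scored)]


# ---------------------------------------------------------------------------
# Leave-one-experiment-out validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationFold:
    held_out: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_eval_pos: int


@dataclass
class ValidationReport:
    folds: list[ValidationFold] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean([f.auc for f in self.folds]))


def loo_validate(
    features: pd.DataFrame,
    detections: pd.DataFrame,
    positives_mode: str = "either",
    smoothing: float = 1.0,
) -> ValidationReport:
    """Serial leave-one-experiment-out cross-validation.

    For each held-out experiment the model trains on positives defined from
    the remaining experiments (``either``: detected in >=1 of them;
    ``both``: detected in all), with the held-out experiment's detections
    returned to the unlabeled pool. It is then asked to retrieve the held-out
    detections from among the non-training examples; performance is the ROC
    AUC of that retrieval. Folds with no held-out positives are skipped with
    a warning.
    """
    if detections.shape[1] < 3:
        raise ValueError("leave-one-out validation needs at least 3 experiments")
    if positives_mode not in ("either", "both"):
        raise ValueError(f"unknown positives_mode {positives_mode!r}")
    report = ValidationReport()
    for held in detections.columns:
        train_cols = [c for c in detections.columns if c != held]
        det = detections[train_cols].to_numpy(bool)
        train_pos = det.any(axis=1) if positives_mode == "either" else det.all(axis=1)
        eval_mask = ~train_pos
        truth = detections[held].to_numpy(bool)[eval_mask]
        if truth.sum() == 0:
            logger.warning("fold %s skipped: no held-out positives", held)
            continue
        scheme = discretize_features(features, train_pos)
        binned = scheme.apply(features)
        model = fit(binned, train_pos, scheme, smoothing, prior=0.5)
        llr = log_likelihood_ratios(model, binned)[eval_mask]
        fpr, tpr, _ = roc_curve(truth, llr)
        report.folds.append(
            ValidationFold(
                held_out=str(held), fpr=fpr, tpr=tpr,
                auc=float(auc(fpr, tpr)), n_eval_pos=int(truth.sum()),
            )
        )
    return report


def prediction_yield_report(counts: dict[str, tuple[int, int]]) -> dict[str, float]:
    """Percent classified positive per partition from (positive, total) pairs.

    E.g. {"two_voted": (590, 768)} -> {"two_voted": 76.8...}.
    """
    out = {}
    for name, (k, n) in counts.items():
        if n <= 0:
            raise ValueError(f"empty partition {name}")
        out[name] = 100.0 * k / n
    return out
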