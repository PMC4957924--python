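"""Sequence-based scoring of candidate phosphotyrosine windows.

Three complementary scores over 11-mer pY windows, mirroring the standard
toolbox for phosphosite motif analysis:

1. **Logo score** — sum of sequence-logo heights ``f(i,j) * R_j`` over the 10
   flanking positions, where ``R_j`` is the column information content in
   bits (optionally with the small-sample correction ``e_n = 19/(2 ln2 n)``).
2. **PSSM score** — a position-specific scoring matrix over a 21-symbol
   alphabet (20 amino acids plus blank) built from a positive alignment of
   known dephosphorylation sites, a negative alignment of unannotated
   tyrosine windows, and the pooled total alignment.  The default combining
   formula is a per-position log-odds with total-matrix pseudocount; the
   formula is pluggable and its identifier is carried in all outputs.
3. **Classifier score** — a specificity-calibrated linear classifier on
   one-hot position encoding plus amino-acid composition, thresholded on
   held-out negatives so that at most ``1 - target_specificity`` of them
   pass.

A candidate enters the consensus set iff it ranks within the top fraction
``q`` under all three scores simultaneously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .sequence_library import AA20, BLANK, FLANK, PeptideWindow

ALPHABET21 = AA20 + BLANK
#: flanking positions, N- to C-terminal, centre (position 0) excluded
POSITIONS = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)
N_POSITIONS = len(POSITIONS)

_AA_INDEX = {a: i for i, a in enumerate(AA20)}
_SYM_INDEX = {a: i for i, a in enumerate(ALPHABET21)}

#: identifier of the default PSSM combining formula, recorded in outputs
PSSM_FORMULA_ID = "log-odds-total-pseudocount-v1"

__all__ = [
    "ALPHABET21",
    "POSITIONS",
    "PSSM_FORMULA_ID",
    "LogoMatrix",
    "FrequencyMatrices",
    "SiteClassifier",
    "CandidateRecord",
    "ScoringError",
    "build_logo",
    "logo_score",
    "build_pssm",
    "pssm_score",
    "log_odds_term",
    "encode_windows",
    "train_classifier",
    "classifier_score",
    "classifier_pass",
    "rank_descending",
    "consensus",
    "records_to_frame",
    "read_external_scores",
]


class ScoringError(ValueError):
    """Invalid input to a scoring operation."""


def _flanks(window: PeptideWindow | str) -> str:
    seq = str(window)
    return seq[:FLANK] + seq[FLANK + 1 :]


# ---------------------------------------------------------------------------
# Method 1: information-content (sequence-logo) score


@dataclass
class LogoMatrix:
    """Per-symbol logo heights (bits), 20 amino acids x 10 flanking positions.

    ``heights[i, j] = f(i, j) * R_j`` with ``R_j`` the information content of
    column ``j``.  Blanks do not contribute to column frequencies and score 0.
    """

    heights: np.ndarray
    n_sequences: int
    small_sample_correction: bool

    def column_information(self) -> np.ndarray:
        """R_j per column (the column sums of the height matrix)."""
        return self.heights.sum(axis=0)


def build_logo(
    positives: Sequence[PeptideWindow], correction: bool = True
) -> LogoMatrix:
    """Build the logo-height matrix from the positive alignment.

    For each flanking column j: ``H_j = -sum_i f(i,j) log2 f(i,j)`` over the
    20 amino acids (blanks excluded from the column counts),
    ``R_j = log2(20) - (H_j + e_n)`` clamped at 0, with
    ``e_n = 19 / (2 ln2 n_j)`` when the small-sample correction is on
    (``n_j`` = non-blank observations in the column).
    """
    if not positives:
        raise ScoringError("build_logo requires at least one positive window")
    counts = np.zeros((20, N_POSITIONS))
    for w in positives:
        for j, sym in enumerate(_flanks(w)):
            if sym == BLANK:
                continue
            counts[_AA_INDEX[sym], j] += 1
    heights = np.zeros_like(counts)
    for j in range(N_POSITIONS):
        n_j = counts[:, j].sum()
        if n_j == 0:
            continue
        f = counts[:, j] / n_j
        nz = f > 0
        entropy = -np.sum(f[nz] * np.log2(f[nz]))
        e_n = 19.0 / (2.0 * math.log(2.0) * n_j) if correction else 0.0
        r_j = max(0.0, math.log2(20.0) - (entropy + e_n))
        heights[:, j] = f * r_j
    return LogoMatrix(
        heights=heights,
        n_sequences=len(positives),
        small_sample_correction=correction,
    )


def logo_score(window: PeptideWindow | str, logo: LogoMatrix) -> float:
    """Sum of logo heights of the window's residues over the 10 flanking positions."""
    total = 0.0
    for j, sym in enumerate(_flanks(window)):
        if sym == BLANK:
            continue
        if sym not in _AA_INDEX:
            raise ScoringError(f"cannot score symbol {sym!r}")
        total += logo.heights[_AA_INDEX[sym], j]
    return float(total)


# ---------------------------------------------------------------------------
# Method 2: PSSM score


@dataclass
class FrequencyMatrices:
    """Positive / negative / total relative-frequency matrices (21 x 10).

    Rows follow :data:`ALPHABET21` (blank last); every column of every matrix
    sums to 1.  ``total`` is built from the pooled multiset of both
    alignments.
    """

    positive: np.ndarray
    negative: np.ndarray
    total: np.ndarray
    n_positive: int = 0
    n_negative: int = 0


def _frequency_matrix(windows: Sequence[PeptideWindow]) -> np.ndarray:
    counts = np.zeros((21, N_POSITIONS))
    for w in windows:
        for j, sym in enumerate(_flanks(w)):
            counts[_SYM_INDEX[sym], j] += 1
    return counts / counts.sum(axis=0, keepdims=True)


def build_pssm(
    positives: Sequence[PeptideWindow], negatives: Sequence[PeptideWindow]
) -> FrequencyMatrices:
    """Build the positive, negative and pooled-total frequency matrices."""
    if not positives or not negatives:
        raise ScoringError("build_pssm requires non-empty positive and negative sets")
    return FrequencyMatrices(
        positive=_frequency_matrix(positives),
        negative=_frequency_matrix(negatives),
        total=_frequency_matrix(list(positives) + list(negatives)),
        n_positive=len(positives),
        n_negative=len(negatives),
    )


def log_odds_term(fp: float, fn: float, ft: float, alpha: float) -> float:
    """Default per-position PSSM term: ``log2((fp + a*ft) / (fn + a*ft))``.

    A symbol absent from all data (``ft == 0``) contributes 0.
    """
    if ft == 0.0:
        return 0.0
    return math.log2((fp + alpha * ft) / (fn + alpha * ft))


def pssm_score(
    window: PeptideWindow | str,
    matrices: FrequencyMatrices,
    alpha: float = 0.05,
    term: Callable[[float, float, float, float], float] = log_odds_term,
) -> float:
    """PSSM score: sum of per-position terms over the 10 flanking positions."""
    if alpha <= 0:
        raise ScoringError("pseudoweight alpha must be > 0")
    total = 0.0
    for j, sym in enumerate(_flanks(window)):
        i = _SYM_INDEX.get(sym)
        if i is None:
            raise ScoringError(f"cannot score symbol {sym!r}")
        total += term(
            matrices.positive[i, j], matrices.negative[i, j], matrices.total[i, j], alpha
        )
    return float(total)


# ---------------------------------------------------------------------------
# Method 3: specificity-calibrated classifier


@dataclass
class SiteClassifier:
    """A linear site classifier with a specificity-calibrated threshold.

    The score is the linear decision value; ``pass`` means score >= threshold,
    with the threshold chosen on held-out calibration negatives so that at
    most ``1 - target_specificity`` of them pass.
    """

    model: LogisticRegression
    threshold: float
    target_specificity: float
    feature_spec: str
    seed: int
    calibration: dict = field(default_factory=dict)


MIN_CLASS_SIZE = 20


def encode_windows(windows: Sequence[PeptideWindow | str]) -> np.ndarray:
    """One-hot (21 symbols x 10 positions) + composition (21) feature matrix."""
    X = np.zeros((len(windows), 21 * N_POSITIONS + 21))
    for r, w in enumerate(windows):
        for j, sym in enumerate(_flanks(w)):
            i = _SYM_INDEX.get(sym)
            if i is None:
                raise ScoringError(f"cannot encode symbol {sym!r}")
            X[r, j * 21 + i] = 1.0
            X[r, 21 * N_POSITIONS + i] += 1.0 / N_POSITIONS
    return X


def calibrate_threshold(negative_scores: np.ndarray, specificity: float) -> float:
    """Threshold such that at most ``1 - specificity`` of the scores pass (>=).

    With ``n`` sorted scores the threshold is the order statistic at index
    ``ceil(specificity * n)`` (0-based); if that falls past the end, the
    threshold sits just above the maximum and nothing passes.
    """
    s = np.sort(np.asarray(negative_scores, dtype=float))
    k = math.ceil(specificity * len(s))
    if k >= len(s):
        return float(s[-1]) + 1e-9
    return float(s[k])


def train_classifier(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    target_specificity: float = 0.95,
    seed: int = 0,
) -> SiteClassifier:
    """Train the linear site classifier and calibrate its threshold.

    Negatives are split (shuffled by ``seed``) into a training half and a
    calibration half; the threshold is the order statistic of the calibration
    scores at the target specificity.  Deterministic given the seed.
    """
    if len(positives) < MIN_CLASS_SIZE or len(negatives) < MIN_CLASS_SIZE:
        raise ScoringError(
            f"each class needs at least {MIN_CLASS_SIZE} windows "
            f"(got {len(positives)} positive, {len(negatives)} negative)"
        )
    if not 0.0 < target_specificity < 1.0:
        raise ScoringError("target_specificity must be in (0, 1)")
    rng = np.random.default_rng(seed)
    neg = list(negatives)
    order = rng.permutation(len(neg))
    n_train = len(neg) // 2
    neg_train = [neg[i] for i in order[:n_train]]
    neg_calib = [neg[i] for i in order[n_train:]]

    X = np.vstack([encode_windows(list(positives)), encode_windows(neg_train)])
    y = np.concatenate([np.ones(len(positives)), np.zeros(len(neg_train))])
    model = LogisticRegression(max_iter=2000, C=1.0)
    model.fit(X, y)

    calib_scores = model.decision_function(encode_windows(neg_calib))
    threshold = calibrate_threshold(calib_scores, target_specificity)
    pos_scores = model.decision_function(encode_windows(list(positives)))
    return SiteClassifier(
        model=model,
        threshold=threshold,
        target_specificity=target_specificity,
        feature_spec="onehot21x10+composition21",
        seed=seed,
        calibration={
            "n_positive": len(positives),
            "n_negative_train": len(neg_train),
            "n_negative_calibration": len(neg_calib),
            "calibration_pass_rate": float(np.mean(calib_scores >= threshold)),
            "training_sensitivity": float(np.mean(pos_scores >= threshold)),
        },
    )


def classifier_score(
    window: PeptideWindow | str | Sequence[PeptideWindow | str],
    clf: SiteClassifier,
) -> float | np.ndarray:
    """Continuous decision score; batch input returns an array."""
    if isinstance(window, (PeptideWindow, str)):
        return float(clf.model.decision_function(encode_windows([window]))[0])
    return clf.model.decision_function(encode_windows(list(window)))


def classifier_pass(window: PeptideWindow | str, clf: SiteClassifier) -> bool:
    return classifier_score(window, clf) >= clf.threshold


# ---------------------------------------------------------------------------
# Consensus


@dataclass
class CandidateRecord:
    """A peptide window with its three scores, ranks and consensus flag."""

    window: PeptideWindow
    score_logo: float | None = None
    score_pssm: float | None = None
    score_clf: float | None = None
    rank_logo: int | None = None
    rank_pssm: int | None = None
    rank_clf: int | None = None
    in_consensus: bool = False

    @property
    def peptide(self) -> str:
        return self.window.sequence


def rank_descending(scores: Sequence[float], peptides: Sequence[str]) -> list[int]:
    """Ranks 1..N, best score first; ties broken by lexicographic peptide order."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], peptides[i]))
    ranks = [0] * len(scores)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


def consensus(records: Sequence[CandidateRecord], q: float) -> list[CandidateRecord]:
    """Flag records ranking within the top fraction ``q`` under all three methods.

    Ranks are recomputed in place (descending score, lexicographic peptide
    tie-break); ``in_consensus`` is set iff ``rank <= ceil(q * N)`` for every
    method.  Returns the same record objects.
    """
    if not 0.0 < q <= 1.0:
        raise ScoringError("q must be in (0, 1]")
    records = list(records)
    peptides = [r.peptide for r in records]
    for attr_score, attr_rank in (
        ("score_logo", "rank_logo"),
        ("score_pssm", "rank_pssm"),
        ("score_clf", "rank_clf"),
    ):
        scores = [getattr(r, attr_score) for r in records]
        if any(s is None for s in scores):
            raise ScoringError(f"{attr_score} missing on some records")
        for r, rank in zip(records, rank_descending(scores, peptides)):
            setattr(r, attr_rank, rank)
    cutoff = math.ceil(q * len(records))
    for r in records:
        r.in_consensus = (
            r.rank_logo <= cutoff and r.rank_pssm <= cutoff and r.rank_clf <= cutoff
        )
    return records


def records_to_frame(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide": [r.peptide for r in records],
            "score_logo": [r.score_logo for r in records],
            "score_pssm": [r.score_pssm for r in records],
            "score_clf": [r.score_clf for r in records],
            "rank_logo": [r.rank_logo for r in records],
            "rank_pssm": [r.rank_pssm for r in records],
            "rank_clf": [r.rank_clf for r in records],
            "in_consensus": [r.in_consensus for r in records],
            "sources": [
                ",".join(f"{pid}:{pos}" for pid, pos, _ in sorted(r.window.sources))
                for r in records
            ],
            "genes": [
                ",".join(sorted({g for _, _, g in r.window.sources if g}))
                for r in records
            ],
        }
    )


def read_external_scores(path) -> dict[str, float]:
    """Adapter for externally produced per-peptide score files (``peptide \\t score``).

    Lets scores from an external site predictor replace the built-in
    classifier while keeping the consensus machinery unchanged.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", names=["peptide", "score"])
    if len(frame) and str(frame.iloc[0]["peptide"]) == "peptide":
        frame = frame.iloc[1:]
    return {str(r.peptide): float(r.score) for r in frame.itertuples(index=False)}
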