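"""Locus-level methylation-state prediction from sequence ("genomic code").

Consensus fragments are discretized into high (>80% in all samples)
and low (<20%) methylation classes, balanced train/test sets are
drawn, and a linear support-vector classifier on overlapping k-mer
frequency features (the primal form of a spectrum kernel) is grid
searched over C in {0.01, 0.1, 1, 10} and k in 1..10 by
cross-validated ROC-AUC. Trained models transfer across species
without retraining, yielding a train x test AUC matrix; species whose
mean off-diagonal AUC as a test species falls below 0.45 are flagged
"inverted" (their sequence-methylation relationship runs opposite to
the rest). Differential feature weights and tripled-3-mer (9-mer
repeat) frequencies probe what drives the inversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .methylome_metrics import _fragment_means
from .reffree_core import MethylationCallSet

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)
DEFAULT_K_GRID = tuple(range(1, 11))


@dataclass
class LabeledFragmentSet:
    """Fragments labeled high/low by their across-sample methylation."""

    frame: pd.DataFrame  # columns: fragment, sequence, label
    species: str = "species"

    def sequences(self, label: Optional[str] = None) -> List[str]:
        df = self.frame if label is None else self.frame[self.frame["label"] == label]
        return list(df["sequence"])


def discretize_fragments(
    callset: MethylationCallSet,
    sequences: Mapping[str, str],
    rule: str = "strict",
    min_mean_coverage: float = 10.0,
    low_thresh: float = 0.2,
    high_thresh: float = 0.8,
    species: str = "species",
) -> LabeledFragmentSet:
    """Label fragments high/low from per-sample fragment means.

    strict rule: low iff every sample mean < 0.2 and high iff every
    sample mean > 0.8; lenient: low iff any sample mean < 0.2 (high
    unchanged). Fragments need mean coverage strictly above
    ``min_mean_coverage`` reads; everything else stays unlabeled.
    """
    fm = _fragment_means(callset.counts)
    rows = []
    for frag, sub in fm.groupby("fragment"):
        if frag not in sequences:
            continue
        if sub["mean_reads"].mean() <= min_mean_coverage:
            continue
        means = sub["mean_ratio"].to_numpy()
        if rule == "strict":
            is_low = bool(np.all(means < low_thresh))
        elif rule == "lenient":
            is_low = bool(np.any(means < low_thresh))
        else:
            raise ValueError(f"unknown rule {rule!r}")
        is_high = bool(np.all(means > high_thresh))
        if is_high and not is_low:
            rows.append((frag, sequences[frag], "high"))
        elif is_low and not is_high:
            rows.append((frag, sequences[frag], "low"))
    if not rows:
        raise ValueError("zero labeled fragments; consider the lenient rule")
    return LabeledFragmentSet(pd.DataFrame(rows, columns=["fragment", "sequence", "label"]), species=species)


def make_balanced_sets(
    labeled: LabeledFragmentSet,
    set_size: int = 2000,
    seed: int = 0,
) -> Tuple[LabeledFragmentSet, LabeledFragmentSet]:
    """Disjoint class-balanced train and test sets of ``set_size`` each.

    Each set holds set_size/2 fragments per class; when the limiting
    class has fewer than set_size total, both classes shrink to keep
    the sets balanced (the limiting class is split evenly between
    train and test).
    """
    rng = np.random.default_rng(seed)
    df = labeled.frame
    idx_by_class = {lab: df.index[df["label"] == lab].to_numpy() for lab in ("high", "low")}
    n_min = min(len(v) for v in idx_by_class.values())
    if n_min < 2:
        raise ValueError("limiting class has fewer than 2 fragments")
    per_class_per_set = min(set_size // 2, n_min // 2)
    train_idx, test_idx = [], []
    for lab, idx in idx_by_class.items():
        chosen = rng.permutation(idx)[: 2 * per_class_per_set]
        train_idx.extend(chosen[:per_class_per_set])
        test_idx.extend(chosen[per_class_per_set:])
    train = LabeledFragmentSet(df.loc[train_idx].reset_index(drop=True), labeled.species)
    test = LabeledFragmentSet(df.loc[test_idx].reset_index(drop=True), labeled.species)
    return train, test


# ---------------------------------------------------------------------------
# k-mer features (sparse, hashed vocabulary)
# ---------------------------------------------------------------------------

def _kmer_count_matrix(seqs: Sequence[str], k: int, vocab: Optional[Dict[str, int]] = None) -> Tuple[sparse.csr_matrix, Dict[str, int]]:
    """Sparse overlapping-k-mer frequency matrix; rows sum to 1.

    With a fixed ``vocab`` (scoring against a trained model), unseen
    k-mers are dropped; otherwise the vocabulary is built from the data.
    Sequences shorter than k yield all-zero rows.
    """
    grow = vocab is None
    if grow:
        vocab = {}
    data, indices, indptr = [], [], [0]
    for s in seqs:
        s = s.upper()
        counts: Dict[int, int] = {}
        n = 0
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            if any(c not in "ACGT" for c in w):
                continue
            j = vocab.get(w)
            if j is None:
                if not grow:
                    n += 1
                    continue
                j = len(vocab)
                vocab[w] = j
            counts[j] = counts.get(j, 0) + 1
            n += 1
        for j, c in counts.items():
            indices.append(j)
            data.append(c / n)
        indptr.append(len(indices))
    X = sparse.csr_matrix((data, indices, indptr), shape=(len(seqs), max(len(vocab), 1)))
    return X, vocab


@dataclass
class CodeModel:
    """A trained linear k-mer classifier; score > 0 predicts 'high'."""

    species_trained: str
    k: int
    C: float
    weights: Dict[str, float]
    intercept: float
    cv_auc: float

    def score(self, seqs: Sequence[str]) -> np.ndarray:
        vocab = {m: i for i, m in enumerate(self.weights)}
        X, _ = _kmer_count_matrix(seqs, self.k, vocab)
        w = np.array(list(self.weights.values()))
        return X @ w + self.intercept

    def sign_flipped(self) -> "CodeModel":
        return CodeModel(self.species_trained + "_flipped", self.k, self.C,
                         {m: -w for m, w in self.weights.items()}, -self.intercept, self.cv_auc)


def evaluate_auc(scores: np.ndarray, labels: Sequence[str]) -> float:
    """ROC-AUC by the rank statistic with midrank tie handling.

    Equals the Mann-Whitney U statistic divided by n_high * n_low, so
    a sign-flipped score vector gives exactly 1 - AUC.
    """
    y = np.asarray([1 if l == "high" else 0 for l in labels])
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("test set must contain both classes")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _cv_auc(seqs: List[str], y: np.ndarray, k: int, C: float, folds: int, seed: int) -> float:
    X, vocab = _kmer_count_matrix(seqs, k)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        clf = LinearSVC(C=C, loss="hinge", max_iter=20000, random_state=seed)
        clf.fit(X[tr], y[tr])
        s = X[te] @ clf.coef_.ravel() + clf.intercept_[0]
        aucs.append(evaluate_auc(s, ["high" if v else "low" for v in y[te]]))
    return float(np.mean(aucs))


def train_code_model(
    train: LabeledFragmentSet,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    folds: int = 10,
    seed: int = 0,
) -> CodeModel:
    """Grid-search (k, C) by mean cross-validated AUC; refit on all data.

    Ties go to the smaller k, then the smaller C (parsimony). Weights
    are on normalized k-mer frequencies without further scaling, so
    they read directly as per-k-mer effect sizes.
    """
    seqs = list(train.frame["sequence"])
    y = (train.frame["label"] == "high").to_numpy(int)
    best = None
    for k in sorted(k_grid):
        for C in sorted(C_grid):
            auc = _cv_auc(seqs, y, k, C, folds, seed)
            if best is None or auc > best[0] + 1e-12:
                best = (auc, k, C)
    cv_auc, k, C = best
    X, vocab = _kmer_count_matrix(seqs, k)
    clf = LinearSVC(C=C, loss="hinge", max_iter=20000, random_state=seed)
    clf.fit(X, y)
    inv_vocab = {i: m for m, i in vocab.items()}
    w = clf.coef_.ravel()
    weights = {inv_vocab[i]: float(w[i]) for i in range(len(inv_vocab))}
    return CodeModel(train.species, k, C, weights, float(clf.intercept_[0]), cv_auc)


# ---------------------------------------------------------------------------
# Cross-species transfer
# ---------------------------------------------------------------------------

@dataclass
class CrossPredictionMatrix:
    auc: pd.DataFrame  # train species x test species
    mean_off_diagonal: pd.Series  # per test species
    inverted: List[str]


def cross_species_matrix(
    models: Mapping[str, CodeModel],
    test_sets: Mapping[str, LabeledFragmentSet],
    inversion_threshold: float = 0.45,
) -> CrossPredictionMatrix:
    """AUC of every model on every species' held-out test set.

    Features are recomputed per test species at each model's k. The
    per-species summary is the mean off-diagonal AUC of its test
    column; species strictly below ``inversion_threshold`` are flagged
    inverted.
    """
    species = sorted(set(models) | set(test_sets))
    mat = pd.DataFrame(np.nan, index=species, columns=species)
    for tr in species:
        model = models.get(tr)
        if model is None:
            continue
        for te in species:
            ts = test_sets.get(te)
            if ts is None:
                continue
            scores = model.score(list(ts.frame["sequence"]))
            mat.loc[tr, te] = evaluate_auc(scores, list(ts.frame["label"]))
    off = {}
    for te in species:
        col = mat[te].drop(index=te).dropna()
        off[te] = float(col.mean()) if len(col) else np.nan
    mean_off = pd.Series(off)
    inverted = detect_inverted(mean_off, inversion_threshold)
    return CrossPredictionMatrix(auc=mat, mean_off_diagonal=mean_off, inverted=inverted)


def detect_inverted(mean_off_diagonal: pd.Series, threshold: float = 0.45) -> List[str]:
    """Species with mean off-diagonal test AUC strictly below threshold."""
    if len(mean_off_diagonal) < 3:
        raise ValueError("need at least 3 species")
    return sorted(mean_off_diagonal.index[mean_off_diagonal < threshold])


# ---------------------------------------------------------------------------
# Differential weights and 9-mer repeats
# ---------------------------------------------------------------------------

def model_weight_table(models: Mapping[str, CodeModel], kmers: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Species x k-mer weight table (missing k-mers filled with 0)."""
    if kmers is None:
        kmers = sorted({m for mod in models.values() for m in mod.weights})
    return pd.DataFrame({sp: {m: mod.weights.get(m, 0.0) for m in kmers}
                         for sp, mod in models.items()}).T


def differential_feature_weights(
    models: Mapping[str, CodeModel],
    focal: Sequence[str],
    group: Sequence[str],
    top_n: int = 10,
) -> pd.DataFrame:
    """Top differential k-mer weights between a focal set and a group.

    Per k-mer, a two-sided rank-sum test of focal-species weights
    against group-species weights; reports the ``top_n`` smallest
    p-values with group-mean weights split by sign (for logo
    rendering).
    """
    if len(group) < 3:
        raise ValueError("comparison group needs at least 3 species")
    W = model_weight_table(models)
    rows = []
    for m in W.columns:
        a = W.loc[list(focal), m].to_numpy()
        b = W.loc[list(group), m].to_numpy()
        if np.all(a == b[: len(a)]) and len(a) == len(b):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        gm = float(b.mean())
        rows.append({"kmer": m, "p": p, "focal_mean": float(a.mean()),
                     "group_mean": gm,
                     "group_mean_pos": max(gm, 0.0), "group_mean_neg": min(gm, 0.0)})
    df = pd.DataFrame(rows).sort_values(["p", "kmer"]).reset_index(drop=True)
    return df.head(top_n)


def ninemer_frequency(seqs: Sequence[str], ninemer: str) -> float:
    """Occurrences of the 9-mer per sequence position (pooled)."""
    total_pos = sum(max(0, len(s) - len(ninemer) + 1) for s in seqs)
    if total_pos == 0:
        return 0.0
    hits = 0
    for s in seqs:
        s = s.upper()
        i = s.find(ninemer)
        while i != -1:
            hits += 1
            i = s.find(ninemer, i + 1)
    return hits / total_pos


def ninemer_repeat_analysis(
    labeled_sets: Mapping[str, LabeledFragmentSet],
    threemer: str,
    cross_auc: Optional[pd.Series] = None,
) -> Tuple[pd.Series, Optional[float]]:
    """Per-species high-vs-low frequency difference of the tripled 3-mer.

    The 9-mer is the 3-mer repeated three times (e.g. ACG ->
    ACGACGACG). Returns the per-species difference freq(9-mer | high) -
    freq(9-mer | low), and its Pearson correlation with ``cross_auc``
    (e.g. each species' AUC under an inverted-trained model) when
    provided.
    """
    ninemer = threemer * 3
    diffs = {}
    for sp, ls in labeled_sets.items():
        high = ls.sequences("high")
        low = ls.sequences("low")
        if not high and not low:
            warnings.warn(f"species {sp} has no labeled fragments")
            continue
        diffs[sp] = ninemer_frequency(high, ninemer) - ninemer_frequency(low, ninemer)
    series = pd.Series(diffs, dtype=float)
    r = None
    if cross_auc is not None:
        common = series.index.intersection(cross_auc.index)
        if len(common) >= 3 and series.loc[common].std() > 0 and cross_auc.loc[common].std() > 0:
            r = float(stats.pearsonr(series.loc[common], cross_auc.loc[common])[0])
    return series, r
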