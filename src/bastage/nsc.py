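"""Nearest-shrunken-centroid (PAM) classification with repeated-CV voting.

The classifier standardizes each class centroid against the overall
centroid,

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0)),

where s_i is the pooled within-class standard deviation of probe i,
s0 = median_i(s_i) guards against probes with tiny variance, and
m_k = sqrt(1/n_k + 1/n) (a sqrt(1/n_k - 1/n) variant is available).
Soft-thresholding d'_ik = sign(d_ik) * max(|d_ik| - delta, 0) shrinks
the class centroids toward the overall centroid and drops probes whose
d'_ik vanish in every class; a new sample x is assigned by minimizing

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k.

Cohort assignment follows a ten-times ten-fold cross-validation scheme:
each repetition draws a fresh stratified 10-fold partition of the
labelled seed samples; every seed sample receives one out-of-fold vote
per repetition, and every unlabelled (external) sample receives one vote
per repetition, the majority prediction of that repetition's ten fold
models.  A sample is assigned to the class winning at least 6 of the 10
repetition votes, and is otherwise left unclassified.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bastage.nsc")

UNCLASSIFIED = "unclassified"


class NSCError(ValueError):
    """Invalid input to the nearest-shrunken-centroid classifier."""


@dataclass(frozen=True)
class NSCModel:
    """Fitted nearest-shrunken-centroid model.

    ``d`` holds the unshrunken standardized contrasts; ``delta`` is the
    soft threshold currently applied.  The shrunken quantities are
    derived properties so re-shrinking always starts from the unshrunken
    fit.  The reconstruction identity
    ``class_centroids = overall_centroid + m_k * (s_i + s0) * d`` holds
    exactly at delta = 0.
    """

    probe_ids: tuple[str, ...]
    class_labels: tuple[str, ...]
    overall_centroid: np.ndarray          # (p,)
    class_centroids: np.ndarray           # (p, K), unshrunken
    pooled_sd: np.ndarray                 # (p,)
    s0: float
    m_k: np.ndarray                       # (K,)
    d: np.ndarray                         # (p, K), unshrunken
    priors: np.ndarray                    # (K,)
    n_k: np.ndarray                       # (K,)
    delta: float = 0.0

    @property
    def shrunken_d(self) -> np.ndarray:
        return np.sign(self.d) * np.maximum(np.abs(self.d) - self.delta, 0.0)

    @property
    def shrunken_centroids(self) -> np.ndarray:
        scale = (self.pooled_sd + self.s0)[:, None] * self.m_k[None, :]
        return self.overall_centroid[:, None] + scale * self.shrunken_d

    @property
    def surviving_probes(self) -> np.ndarray:
        """Boolean mask of probes with a nonzero shrunken contrast in any class."""
        return np.any(self.shrunken_d != 0.0, axis=1)

    def to_json(self) -> str:
        payload = {
            "probe_ids": list(self.probe_ids),
            "class_labels": list(self.class_labels),
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "m_k": self.m_k.tolist(),
            "d": self.d.tolist(),
            "priors": self.priors.tolist(),
            "n_k": self.n_k.tolist(),
            "delta": self.delta,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "NSCModel":
        obj = json.loads(text)
        return cls(
            probe_ids=tuple(obj["probe_ids"]),
            class_labels=tuple(obj["class_labels"]),
            overall_centroid=np.asarray(obj["overall_centroid"], dtype=float),
            class_centroids=np.asarray(obj["class_centroids"], dtype=float),
            pooled_sd=np.asarray(obj["pooled_sd"], dtype=float),
            s0=float(obj["s0"]),
            m_k=np.asarray(obj["m_k"], dtype=float),
            d=np.asarray(obj["d"], dtype=float),
            priors=np.asarray(obj["priors"], dtype=float),
            n_k=np.asarray(obj["n_k"], dtype=float),
            delta=float(obj["delta"]),
        )


def fit_nsc(
    matrix: pd.DataFrame,
    labels: "pd.Series | Sequence[str]",
    priors: Literal["empirical", "uniform"] = "empirical",
    m_variant: Literal["plus", "minus"] = "plus",
) -> NSCModel:
    """Fit an unshrunken (delta = 0) nearest-shrunken-centroid model.

    Parameters
    ----------
    matrix
        Expression restricted to the signature probes, probes x samples.
    labels
        Class label per sample (aligned to ``matrix.columns``).
    priors
        ``empirical`` uses class proportions n_k / n; ``uniform`` uses 1/K.
    m_variant
        ``plus``: m_k = sqrt(1/n_k + 1/n) (default); ``minus``: the
        variance-exact sqrt(1/n_k - 1/n) form.
    """
    if isinstance(labels, pd.Series):
        labels = labels.reindex(matrix.columns)
        if labels.isna().any():
            missing = list(labels.index[labels.isna()])
            raise NSCError(f"labels missing for samples: {missing}")
        y = labels.to_numpy()
    else:
        y = np.asarray(list(labels))
        if y.size != matrix.shape[1]:
            raise NSCError(
                f"got {y.size} labels for {matrix.shape[1]} samples"
            )
    X = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise NSCError("expression matrix contains non-finite values")

    classes = tuple(sorted(set(map(str, y))))
    if len(classes) < 2:
        raise NSCError(f"need >=2 classes, got {classes}")
    n = X.shape[1]
    K = len(classes)
    n_k = np.array([np.sum(y == c) for c in classes], dtype=float)
    if np.any(n_k < 2):
        bad = [c for c, nk in zip(classes, n_k) if nk < 2]
        raise NSCError(f"classes absent or singleton: {bad}")

    overall = X.mean(axis=1)
    centroids = np.column_stack([X[:, y == c].mean(axis=1) for c in classes])
    # pooled within-class variance: s_i^2 = (1/(n-K)) sum_k sum_{j in C_k} (x_ij - xbar_ik)^2
    ss = np.zeros(X.shape[0])
    for k, c in enumerate(classes):
        resid = X[:, y == c] - centroids[:, k][:, None]
        ss += np.sum(resid ** 2, axis=1)
    pooled_sd = np.sqrt(ss / (n - K))
    s0 = float(np.median(pooled_sd))
    if np.all(pooled_sd + s0 == 0.0):
        raise NSCError("all probes have zero pooled variance; cannot standardize")

    if m_variant == "plus":
        m_k = np.sqrt(1.0 / n_k + 1.0 / n)
    elif m_variant == "minus":
        m_k = np.sqrt(1.0 / n_k - 1.0 / n)
    else:
        raise NSCError(f"unknown m_variant {m_variant!r}")

    scale = (pooled_sd + s0)[:, None] * m_k[None, :]
    d = (centroids - overall[:, None]) / scale

    if priors == "empirical":
        pi = n_k / n
    elif priors == "uniform":
        pi = np.full(K, 1.0 / K)
    else:
        raise NSCError(f"unknown priors {priors!r}")

    return NSCModel(
        probe_ids=tuple(map(str, matrix.index)),
        class_labels=classes,
        overall_centroid=overall,
        class_centroids=centroids,
        pooled_sd=pooled_sd,
        s0=s0,
        m_k=m_k,
        d=d,
        priors=pi,
        n_k=n_k,
        delta=0.0,
    )


def shrink(model: NSCModel, delta: float) -> NSCModel:
    """Apply soft-threshold shrinkage delta to a fitted model."""
    if delta < 0:
        raise NSCError(f"delta must be nonnegative, got {delta}")
    return dataclasses.replace(model, delta=float(delta))


def _discriminants(model: NSCModel, X: np.ndarray) -> np.ndarray:
    """delta_k(x) for each sample (columns of X); shape (n_samples, K)."""
    centroids = model.shrunken_centroids           # (p, K)
    denom = (model.pooled_sd + model.s0) ** 2       # (p,)
    diff = X.T[:, :, None] - centroids[None, :, :]  # (n, p, K); X arrives (p, n)
    scores = np.sum(diff ** 2 / denom[None, :, None], axis=1)
    return scores - 2.0 * np.log(model.priors)[None, :]


def predict_nsc(
    model: NSCModel, sample: Sequence[float]
) -> tuple[str, np.ndarray, np.ndarray]:
    """Classify one sample vector aligned to the model's probe order.

    Returns (label, class probabilities, discriminant scores).  The
    probabilities p_k = exp(-delta_k/2) / sum_l exp(-delta_l/2) are
    computed after subtracting the minimum discriminant for stability.
    Exact ties are broken by the fixed class order with a logged warning.
    """
    x = np.asarray(sample, dtype=float)
    if x.shape != (len(model.probe_ids),):
        raise NSCError(
            f"sample length {x.shape} does not match model probes "
            f"({len(model.probe_ids)})"
        )
    if not np.all(np.isfinite(x)):
        raise NSCError("sample contains non-finite values")
    scores = _discriminants(model, x[:, None])[0]
    shifted = scores - scores.min()
    weights = np.exp(-shifted / 2.0)
    probs = weights / weights.sum()
    k = int(np.argmin(scores))
    if np.sum(scores == scores.min()) > 1:
        logger.warning(
            "discriminant tie; breaking by class order -> %s",
            model.class_labels[k],
        )
    return model.class_labels[k], probs, scores


def predict_matrix(model: NSCModel, matrix: pd.DataFrame) -> pd.Series:
    """Classify every column of a probes x samples matrix (vectorized)."""
    missing = [p for p in model.probe_ids if p not in matrix.index]
    if missing:
        raise NSCError(f"matrix missing model probes: {missing[:5]}...")
    X = matrix.loc[list(model.probe_ids)].to_numpy(dtype=float)
    scores = _discriminants(model, X)
    idx = np.argmin(scores, axis=1)
    return pd.Series(
        [model.class_labels[k] for k in idx], index=matrix.columns, name="prediction"
    )


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Round-robin stratified fold assignment after within-class shuffling.

    Sample positions are dealt class by class into folds so every fold
    receives a near-balanced share of each class even when folds hold
    only one or two samples.
    """
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    start = 0
    for c in sorted(set(y)):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(idx.size)]
        for j, i in enumerate(idx):
            folds[(start + j) % n_folds].append(int(i))
        start += idx.size  # stagger classes so small folds mix classes
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def select_delta(
    matrix: pd.DataFrame,
    labels: pd.Series,
    delta_grid: Sequence[float],
    folds: int = 10,
    seed: int = 0,
    priors: Literal["empirical", "uniform"] = "empirical",
    m_variant: Literal["plus", "minus"] = "plus",
) -> tuple[float, pd.Series]:
    """Choose the shrinkage threshold by stratified k-fold cross-validation.

    Returns the largest delta achieving the minimum CV error (preferring
    sparser models on ties) and the full error curve indexed by delta.
    """
    grid = sorted(float(d) for d in delta_grid)
    if not grid:
        raise NSCError("empty delta grid")
    if any(d < 0 for d in grid):
        raise NSCError("delta grid must be nonnegative")
    labels = labels.reindex(matrix.columns)
    y = labels.to_numpy()
    n = y.size
    if folds > n:
        raise NSCError(f"folds ({folds}) exceed sample count ({n})")
    rng = np.random.default_rng(seed)
    # canonical sample order inside classes keeps folds invariant to input order
    order = np.argsort(matrix.columns.to_numpy())
    fold_idx = _stratified_folds(y[order], folds, rng)
    fold_idx = [order[f] for f in fold_idx]

    errors = np.zeros(len(grid))
    for held_out in fold_idx:
        if held_out.size == 0:
            continue
        train_mask = np.ones(n, dtype=bool)
        train_mask[held_out] = False
        train_cols = matrix.columns[train_mask]
        base = fit_nsc(matrix[train_cols], labels[train_cols], priors, m_variant)
        test = matrix[matrix.columns[held_out]]
        truth = y[held_out]
        for gi, delta in enumerate(grid):
            preds = predict_matrix(shrink(base, delta), test)
            errors[gi] += np.sum(preds.to_numpy() != truth)
    curve = pd.Series(errors / n, index=pd.Index(grid, name="delta"), name="cv_error")
    best = curve.min()
    chosen = max(d for d, e in curve.items() if e == best)
    return float(chosen), curve


@dataclass(frozen=True)
class VoteTable:
    """Per-sample class votes across CV repetitions and final assignment.

    ``table`` is indexed by sample ID with one ``vote_<r>`` column per
    repetition (the string label, or empty string for an abstention),
    per-class vote counts, ``n_abstentions``, ``assignment`` and ``role``
    (``train`` for out-of-fold voting on labelled samples, ``external``
    for unlabelled samples classified by repetition-majority).
    """

    table: pd.DataFrame
    class_labels: tuple[str, ...]
    repetitions: int
    vote_threshold: int

    @property
    def assignments(self) -> pd.Series:
        return self.table["assignment"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="sample_id")


def _tally(
    votes: list[str | None],
    class_labels: tuple[str, ...],
    vote_threshold: int,
) -> tuple[dict[str, int], int, str]:
    counts = {c: sum(v == c for v in votes) for c in class_labels}
    n_abstain = sum(v is None for v in votes)
    assignment = UNCLASSIFIED
    for c in class_labels:
        if counts[c] >= vote_threshold:
            assignment = c
            break
    return counts, n_abstain, assignment


def repeated_cv_classify(
    train_matrix: pd.DataFrame,
    train_labels: pd.Series,
    external_matrix: pd.DataFrame | None = None,
    repetitions: int = 10,
    folds: int = 10,
    seed: int = 0,
    delta: float = 0.0,
    priors: Literal["empirical", "uniform"] = "empirical",
    m_variant: Literal["plus", "minus"] = "plus",
    vote_threshold: int = 6,
    external_mode: Literal["fold_majority", "full_model"] = "fold_majority",
) -> VoteTable:
    """Ten-times ten-fold CV with majority-vote class assignment.

    Each repetition draws a fresh stratified fold partition of the
    labelled samples.  Labelled samples are voted on out-of-fold (the
    model fit on the other folds predicts the held-out fold); external
    samples receive, per repetition, either the majority prediction of
    that repetition's fold models (``fold_majority``, default; a tied
    fold-model majority abstains) or the prediction of a single model
    refit on all labelled samples (``full_model``).  Final assignment
    requires at least ``vote_threshold`` of ``repetitions`` votes for
    one class; otherwise the sample is unclassified.
    """
    if not 1 <= vote_threshold <= repetitions:
        raise NSCError(
            f"vote_threshold must be in 1..{repetitions}, got {vote_threshold}"
        )
    train_labels = train_labels.reindex(train_matrix.columns)
    if train_labels.isna().any():
        missing = list(train_labels.index[train_labels.isna()])
        raise NSCError(f"labels missing for samples: {missing}")
    y = train_labels.to_numpy()
    n = y.size
    if folds > n:
        raise NSCError(f"folds ({folds}) exceed training sample count ({n})")
    class_labels = tuple(sorted(set(map(str, y))))
    if len(class_labels) < 2:
        raise NSCError("training set must contain both classes")
    if external_matrix is not None and external_matrix.shape[1] == 0:
        external_matrix = None
    if external_matrix is not None:
        overlap = set(external_matrix.columns) & set(train_matrix.columns)
        if overlap:
            raise NSCError(f"external samples overlap training set: {sorted(overlap)}")

    seeds = np.random.SeedSequence(seed).spawn(repetitions)
    train_votes: dict[str, list[str | None]] = {
        str(s): [] for s in train_matrix.columns
    }
    ext_ids = list(map(str, external_matrix.columns)) if external_matrix is not None else []
    ext_votes: dict[str, list[str | None]] = {s: [] for s in ext_ids}

    order = np.argsort(train_matrix.columns.to_numpy())
    for rep_seed in seeds:
        rng = np.random.default_rng(rep_seed)
        fold_idx = [order[f] for f in _stratified_folds(y[order], folds, rng)]
        rep_ext_preds: dict[str, list[str]] = {s: [] for s in ext_ids}
        rep_train_pred: dict[str, str] = {}
        for held_out in fold_idx:
            if held_out.size == 0:
                continue
            train_mask = np.ones(n, dtype=bool)
            train_mask[held_out] = False
            cols = train_matrix.columns[train_mask]
            model = shrink(
                fit_nsc(train_matrix[cols], train_labels[cols], priors, m_variant),
                delta,
            )
            oof = predict_matrix(model, train_matrix[train_matrix.columns[held_out]])
            for sid, pred in oof.items():
                rep_train_pred[str(sid)] = pred
            if external_matrix is not None and external_mode == "fold_majority":
                ext_pred = predict_matrix(model, external_matrix)
                for sid, pred in ext_pred.items():
                    rep_ext_preds[str(sid)].append(pred)
        for sid in train_votes:
            train_votes[sid].append(rep_train_pred.get(sid))
        if external_matrix is not None:
            if external_mode == "full_model":
                full = shrink(
                    fit_nsc(train_matrix, train_labels, priors, m_variant), delta
                )
                ext_pred = predict_matrix(full, external_matrix)
                for sid, pred in ext_pred.items():
                    ext_votes[str(sid)].append(pred)
            else:
                for sid, preds in rep_ext_preds.items():
                    counts = {c: preds.count(c) for c in class_labels}
                    top = max(counts.values())
                    winners = [c for c, k in counts.items() if k == top]
                    ext_votes[sid].append(winners[0] if len(winners) == 1 else None)

    rows = []
    for sid, votes in list(train_votes.items()) + list(ext_votes.items()):
        counts, n_abstain, assignment = _tally(votes, class_labels, vote_threshold)
        row: dict[str, object] = {
            f"vote_{r + 1}": ("" if v is None else v) for r, v in enumerate(votes)
        }
        for c in class_labels:
            row[f"n_{c}_votes"] = counts[c]
        row["n_abstentions"] = n_abstain
        row["assignment"] = assignment
        row["role"] = "train" if sid in train_votes else "external"
        rows.append(pd.Series(row, name=sid))
    table = pd.DataFrame(rows)
    table.index.name = "sample_id"
    return VoteTable(
        table=table,
        class_labels=class_labels,
        repetitions=repetitions,
        vote_threshold=vote_threshold,
    )
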