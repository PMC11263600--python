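"""Target–decoy FDR control for the two moieties of a glycopeptide.

Peptide q-values come from a Percolator-style semi-supervised re-scoring:
starting from the peptide score, a linear max-margin classifier (C = 1) is
re-trained for a fixed number of rounds on confident targets (q <= 0.01)
versus decoys over the features [peptide score, peptide coverage, Cor'_P],
and the final decision values are converted to q-values by decoy counting
with monotonization.

Glycan q-values use plain decoy counting on the glycan score (optionally
smoothing the decoy tail with a fitted Gamma survival function); glycan
compositions of 3 or fewer residues yield too few peptide+Y ions for the
estimate to be meaningful and are flagged undefined.

The joint FDR combines the two by inclusion–exclusion; an undefined glycan
FDR propagates the peptide FDR with the flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _stats
from sklearn.svm import LinearSVC

__all__ = [
    "qvalues_from_scores",
    "peptide_fdr",
    "glycan_fdr",
    "joint_fdr",
    "GLYCAN_SIZE_EXCLUSION",
]

GLYCAN_SIZE_EXCLUSION = 3


def qvalues_from_scores(
    scores: np.ndarray, is_decoy: np.ndarray, pseudocount: int = 0
) -> np.ndarray:
    """Decoy-counting q-values, monotone non-increasing in score.

    q(s) = (#decoys >= s + pseudocount) / max(#targets >= s, 1), capped at 1,
    then monotonized from the best score downward.  The default is the
    classical counting estimate (no pseudocount); pass ``pseudocount=1``
    for the conservative Percolator-style variant.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    n = scores.size
    q = np.empty(n)
    n_decoy = 0
    n_target = 0
    raw = np.empty(n)
    for rank, i in enumerate(order):
        if is_decoy[i]:
            n_decoy += 1
        else:
            n_target += 1
        raw[rank] = min((n_decoy + pseudocount) / max(n_target, 1), 1.0)
    running = np.minimum.accumulate(raw[::-1])[::-1]
    q[order] = running
    return q


def peptide_fdr(
    features: np.ndarray,
    is_decoy: np.ndarray,
    n_iterations: int = 3,
    train_q: float = 0.01,
    C: float = 1.0,
    min_decoys: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Semi-supervised peptide q-values.

    ``features`` is (n, k) with the raw peptide score in column 0; decoys
    are the negative class.  Falls back to score-only counting when decoys
    are too few or when re-scoring degrades the initial direction.
    """
    features = np.asarray(features, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    scores = features[:, 0].copy()
    q = qvalues_from_scores(scores, is_decoy)
    if int(is_decoy.sum()) < min_decoys or (~is_decoy).sum() == 0:
        warnings.warn("too few decoys for semi-supervised re-scoring; using score-only q-values")
        return q
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (features - mu) / sd
    best_q = q
    best_pass = int(((q <= train_q) & ~is_decoy).sum())
    for _ in range(n_iterations):
        positives = (best_q <= train_q) & ~is_decoy
        if positives.sum() < 5:
            break
        X = np.vstack([Z[positives], Z[is_decoy]])
        y = np.concatenate([np.ones(int(positives.sum())), np.zeros(int(is_decoy.sum()))])
        clf = LinearSVC(C=C, random_state=seed, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        new_scores = clf.decision_function(Z)
        new_q = qvalues_from_scores(new_scores, is_decoy)
        n_pass = int(((new_q <= train_q) & ~is_decoy).sum())
        if n_pass >= best_pass:
            best_q, best_pass = new_q, n_pass
    return best_q


def glycan_fdr(
    scores: np.ndarray,
    is_decoy: np.ndarray,
    glycan_sizes: Optional[np.ndarray] = None,
    gamma_tail: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """(q-values, defined flags) for the glycan moiety.

    Sizes <= 3 residues are flagged undefined (q set to NaN); the optional
    Gamma tail fit smooths the decoy survival function at high scores.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    defined = np.ones(scores.size, dtype=bool)
    if glycan_sizes is not None:
        defined = np.asarray(glycan_sizes) > GLYCAN_SIZE_EXCLUSION
    if is_decoy.sum() == 0:
        warnings.warn(
            "too few decoy glycan matches to estimate the glycan FDR accurately"
        )
        n_targets = int((~is_decoy).sum())
        q = np.full(scores.size, 1.0 / (n_targets + 1))
    elif gamma_tail and is_decoy.sum() >= 10:
        d = scores[is_decoy]
        d = d[d > 0]
        if d.size >= 10:
            shape, loc, scale = _stats.gamma.fit(d, floc=0.0)
            n_d, n_t = int(is_decoy.sum()), max(int((~is_decoy).sum()), 1)
            q = np.empty(scores.size)
            for i, s in enumerate(scores):
                exp_decoys = n_d * float(_stats.gamma.sf(s, shape, loc=loc, scale=scale))
                n_better = int((scores[~is_decoy] >= s).sum())
                q[i] = min((exp_decoys + 1) / max(n_better, 1), 1.0)
            order = np.argsort(-scores, kind="stable")
            q[order] = np.minimum.accumulate(q[order])
        else:
            q = qvalues_from_scores(scores, is_decoy)
    else:
        q = qvalues_from_scores(scores, is_decoy)
    q = q.astype(float)
    q[~defined] = np.nan
    return q, defined


def joint_fdr(
    fdr_p: np.ndarray | float,
    fdr_g: np.ndarray | float,
    glycan_defined: Optional[np.ndarray] = None,
) -> np.ndarray | float:
    """Inclusion–exclusion combination; undefined glycan FDR propagates the
    peptide FDR alone."""
    p = np.asarray(fdr_p, dtype=float)
    g = np.asarray(fdr_g, dtype=float)
    out = p + g - p * g
    if glycan_defined is not None:
        defined = np.asarray(glycan_defined, dtype=bool)
        out = np.where(defined, out, p)
    else:
        out = np.where(np.isnan(g), p, out)
    if np.isscalar(fdr_p) and np.isscalar(fdr_g):
        return float(out)
    return out
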