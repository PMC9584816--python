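"""Within-dataset batch detection by classifier-entropy sample merging.

Samples that a held-out classifier cannot tell apart (normalized out-of-bag
prediction entropy >= threshold) are merged iteratively; the surviving
groups are the batches.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)


def normalized_entropy(oob: np.ndarray) -> float:
    """Mean per-row Shannon entropy of class probabilities, scaled by
    log(n_columns) so the result lies in [0, 1]. A single column is defined
    as 1.0 (indistinguishable by construction)."""
    oob = np.asarray(oob, dtype=float)
    if oob.ndim != 2:
        raise ValueError("oob must be 2-D (cells x groups)")
    if oob.shape[1] < 2:
        return 1.0
    if not np.allclose(oob.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("oob rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(oob > 0, oob * np.log(oob), 0.0)
    h = -terms.sum(axis=1)
    return float(h.mean() / np.log(oob.shape[1]))


def sample_dissimilarity(oob: pd.DataFrame, sample_of_cell) -> pd.DataFrame:
    """1 - Spearman rho between per-sample mean oob probability profiles.

    ``oob`` columns are the current groups; rows align with
    ``sample_of_cell``. Constant profiles give distance 1 with a warning.
    """
    sample_of_cell = np.asarray(sample_of_cell)
    profiles = oob.groupby(sample_of_cell).mean()
    samples = list(profiles.index)
    n = len(samples)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = profiles.iloc[i].to_numpy(), profiles.iloc[j].to_numpy()
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                warnings.warn(
                    f"constant oob profile for {samples[i]} or {samples[j]}; distance set to 1",
                    stacklevel=2,
                )
                d = 1.0
            else:
                rho = scipy.stats.spearmanr(a, b).statistic
                d = 1.0 - rho
            dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=samples, columns=samples)


class RandomForestOob:
    """Default classifier: random forest with out-of-bag class probabilities."""

    def __init__(self, n_estimators: int = 100, seed: int = 0):
        self.n_estimators = n_estimators
        self.seed = seed

    def __call__(self, X: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        classes = sorted(set(y))
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")
        rf = RandomForestClassifier(
            n_estimators=self.n_estimators,
            oob_score=True,
            random_state=self.seed,
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-tree oob coverage warnings
            rf.fit(X, y)
        prob = rf.oob_decision_function_
        # cells never left out-of-bag have all-nan rows -> uniform
        bad = ~np.isfinite(prob).all(axis=1)
        prob[bad] = 1.0 / prob.shape[1]
        # renormalize against float drift
        prob = prob / prob.sum(axis=1, keepdims=True)
        cols = list(rf.classes_)
        return pd.DataFrame(prob, columns=cols)[classes]


def detect_batches(
    embedding: np.ndarray,
    sample_ids,
    classifier=None,
    threshold: float = 0.9,
    seed: int = 0,
    gate: str = "pair",
) -> tuple[dict, list]:
    """Iteratively merge samples the classifier cannot separate.

    Loop: train on current groups, rank group pairs by oob-profile
    dissimilarity, tentatively merge the closest pair, retrain on the cells
    of just those two groups, and accept the merge if their normalized oob
    entropy >= ``threshold`` (``gate="pair"``; ``gate="global"`` instead
    gates on the entropy over all groups). Rejected pairs are marked
    unmergeable; the loop ends when none remain.

    Returns ``(sample_id -> batch_id, merge trace)``.
    """
    if gate not in {"pair", "global"}:
        raise ValueError("gate must be 'pair' or 'global'")
    sample_ids = np.asarray(sample_ids, dtype=object)
    embedding = np.asarray(embedding, dtype=float)
    if len(sample_ids) != embedding.shape[0]:
        raise ValueError("sample_ids length does not match embedding rows")
    if classifier is None:
        classifier = RandomForestOob(seed=seed)

    samples = sorted(set(sample_ids))
    if len(samples) < 2:
        return {s: "B1" for s in samples}, []

    group_of = {s: s for s in samples}  # sample -> group key
    members: dict = {s: [s] for s in samples}
    unmergeable: set = set()
    trace: list = []

    def group_labels():
        return np.array([group_of[s] for s in sample_ids], dtype=object)

    while len(members) > 1:
        y = group_labels()
        oob = classifier(embedding, y)
        dist = sample_dissimilarity(oob, y)
        pairs = []
        keys = sorted(members)
        for i, a in enumerate(keys):
            for b in keys[i + 1 :]:
                if frozenset((a, b)) not in unmergeable:
                    pairs.append((float(dist.loc[a, b]), a, b))
        if not pairs:
            break
        pairs.sort()
        _, a, b = pairs[0]
        mask = (y == a) | (y == b)
        pair_oob = classifier(embedding[mask], y[mask])
        h_pair = normalized_entropy(pair_oob.to_numpy())
        h_global = normalized_entropy(oob.to_numpy())
        h = h_pair if gate == "pair" else h_global
        accepted = h >= threshold
        trace.append(
            {
                "pair": [a, b],
                "distance": pairs[0][0],
                "entropy_pair": h_pair,
                "entropy_global": h_global,
                "accepted": bool(accepted),
            }
        )
        if accepted:
            new_key = min(a, b)
            members[new_key] = sorted(members.pop(a) + members.pop(b))
            for s in members[new_key]:
                group_of[s] = new_key
            unmergeable = {p for p in unmergeable if a not in p and b not in p}
            logger.info("merged %s + %s (entropy %.3f)", a, b, h)
        else:
            unmergeable.add(frozenset((a, b)))

    final_groups = sorted(members)
    batch_of_group = {g: f"B{i + 1}" for i, g in enumerate(final_groups)}
    assignment = {s: batch_of_group[group_of[s]] for s in samples}
    return assignment, trace
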