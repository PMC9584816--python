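"""Query embedding into a reference latent space and similarity-weighted
k-NN label propagation with per-cell probability scores."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from atlasforge.data_model import GeneMatrix

logger = logging.getLogger(__name__)


def embed_query(reference_model: dict, query_gm: GeneMatrix) -> np.ndarray:
    """Project query lognorm onto the reference PCA loadings.

    Genes are matched by id; reference features missing from the query are
    zero-filled (after centering/scaling with the reference parameters) with
    a warning. Any embedder honoring the shared-space contract may replace
    this.
    """
    if query_gm.lognorm is None:
        raise ValueError("query lognorm layer required")
    ref_genes = reference_model["genes"]
    q_lookup = {g: i for i, g in enumerate(query_gm.gene_ids)}
    present = [g for g in ref_genes if g in q_lookup]
    if not present:
        raise ValueError("no overlap between query genes and reference features")
    missing_frac = 1.0 - len(present) / len(ref_genes)
    if missing_frac > 0:
        warnings.warn(
            f"query misses {missing_frac:.1%} of reference features; zero-filling",
            stacklevel=2,
        )
    X = np.zeros((query_gm.n_cells, len(ref_genes)))
    for j, g in enumerate(ref_genes):
        if g in q_lookup:
            X[:, j] = np.asarray(
                query_gm.lognorm[:, q_lookup[g]].todense()
            ).ravel()
            X[:, j] = (X[:, j] - reference_model["mean"][j]) / reference_model["sd"][j]
    # missing features stay at 0 (the reference mean after standardization)
    return X @ reference_model["loadings"]


def cosine_sim_from_dist(d) -> np.ndarray:
    """sim = 1 - d^2 / 2 for Euclidean distances between L2-normalized
    vectors (exactly the cosine), clipped at 0 for weighting."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    return np.maximum(1.0 - d**2 / 2.0, 0.0)


def _l2_normalize(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def propagate_labels(
    query_latent: np.ndarray,
    reference_latent: np.ndarray,
    reference_labels,
    k: int = 25,
) -> pd.DataFrame:
    """Similarity-weighted k-NN label vote.

    Rows are L2-normalized; p(label) = sum of neighbor similarities carrying
    that label / total neighbor similarity. Ties in the argmax go to the
    single nearest neighbor's label; all-zero similarity falls back to a
    uniform vote over neighbor labels (with a warning).

    Returns a DataFrame with ``predicted_label``, ``probability`` and one
    ``p_<label>`` column per reference label.
    """
    reference_labels = np.asarray(reference_labels, dtype=object)
    reference_latent = np.asarray(reference_latent, dtype=float)
    query_latent = np.asarray(query_latent, dtype=float)
    if k > reference_latent.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {reference_latent.shape[0]}")
    ref_n = _l2_normalize(reference_latent)
    qry_n = _l2_normalize(query_latent)
    nn = NearestNeighbors(n_neighbors=k).fit(ref_n)
    dist, idx = nn.kneighbors(qry_n)
    sims = cosine_sim_from_dist(dist)
    labels_sorted = sorted(set(reference_labels))
    label_pos = {lab: j for j, lab in enumerate(labels_sorted)}
    n_q = qry_n.shape[0]
    probs = np.zeros((n_q, len(labels_sorted)))
    warned = False
    for i in range(n_q):
        neigh_labels = reference_labels[idx[i]]
        s = sims[i]
        total = s.sum()
        if total <= 0:
            if not warned:
                warnings.warn(
                    "all-zero neighbor similarities; uniform vote", stacklevel=2
                )
                warned = True
            s = np.ones_like(s)
            total = s.sum()
        for lab, w in zip(neigh_labels, s):
            probs[i, label_pos[lab]] += w
        probs[i] /= probs[i].sum()
    pred = []
    for i in range(n_q):
        row = probs[i]
        best = row.max()
        tied = [labels_sorted[j] for j in np.flatnonzero(row == best)]
        if len(tied) > 1:
            pred.append(reference_labels[idx[i, 0]])  # nearest neighbor breaks ties
        else:
            pred.append(tied[0])
    out = pd.DataFrame(probs, columns=[f"p_{lab}" for lab in labels_sorted])
    out.insert(0, "predicted_label", pred)
    out.insert(1, "probability", probs.max(axis=1))
    return out
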