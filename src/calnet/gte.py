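"""Effective-connectivity inference with Generalized Transfer Entropy.

Plug-in transfer entropy in bits on binary spike trains, Markov order ``k``
(default 2) with instant feedback: the conditioning set of GTE(i -> j)
contains j's k-frame past, i's k-frame past, and i's same-frame state at the
predicted frame.  Probabilities are raw state counts over all frames
(0 log 0 = 0 convention, no bias correction).

Edge significance uses the joint score distribution of the row and column of
the pair: an edge i -> j is significant when G[i, j] exceeds the mean + 2 SD
of all scores into j and all scores out of i.  Inference is refused on
recordings with 25 or fewer active neurons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EffectiveNetwork",
    "InferenceRefused",
    "compute_gte_scores",
    "threshold_network",
    "infer_effective_network",
    "MIN_ACTIVE_NEURONS",
]

MIN_ACTIVE_NEURONS = 25  # inference requires strictly more active neurons


class InferenceRefused(RuntimeError):
    """Raised when a recording has too few active neurons for inference."""

    def __init__(self, n_active: int):
        self.n_active = n_active
        super().__init__(
            f"network inference refused: {n_active} active neurons "
            f"(> {MIN_ACTIVE_NEURONS} required)"
        )


@dataclass
class EffectiveNetwork:
    scores: np.ndarray  # GTE(i -> j) in bits, diagonal zero
    adjacency: np.ndarray  # bool, significant edges
    markov_order: int = 2
    instant_feedback: bool = True
    neuron_ids: np.ndarray | None = None  # ROI ids of the analyzed neurons
    thresholds: np.ndarray | None = None  # per-pair mean + n_sd * SD null level

    @property
    def n_nodes(self) -> int:
        return self.scores.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())


def _entropy_from_counts(counts: np.ndarray, axis=None) -> np.ndarray:
    n = counts.sum(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / n
        h = -np.where(counts > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return h.sum(axis=axis)


def compute_gte_scores(
    raster: np.ndarray,
    k: int = 2,
    instant_feedback: bool = True,
    enforce_min_active: bool = True,
) -> np.ndarray:
    """Pairwise plug-in GTE score matrix (bits) on a binary raster.

    Rows are neurons; set ``enforce_min_active=False`` to run on small test
    rasters (oracles, toy examples).
    """
    raster = np.atleast_2d(np.asarray(raster)).astype(np.int64)
    n, T = raster.shape
    if enforce_min_active and n <= MIN_ACTIVE_NEURONS:
        raise InferenceRefused(n)
    if T < k + 2:
        raise ValueError("raster too short for the requested Markov order")

    # time range: t = k-1 .. T-2 (k-frame past and one future frame defined)
    ts = np.arange(k - 1, T - 1)
    m = ts.size
    # k-bit past code per neuron: bit b = x[t - b]
    past = np.zeros((n, m), dtype=np.int64)
    for b in range(k):
        past |= raster[:, ts - b] << b
    nxt = raster[:, ts + 1]

    n_past = 1 << k
    inst_states = 2 if instant_feedback else 1
    n_states = 2 * n_past * n_past * inst_states

    scores = np.zeros((n, n))
    for j in range(n):
        base = nxt[j] + (past[j] << 1)  # j_next (bit 0) + j_past (k bits)
        # conditional entropy terms that depend only on j
        c_jp_jn = np.bincount(base, minlength=2 * n_past).astype(np.float64)
        codes = base[None, :] + (past << (1 + k))
        if instant_feedback:
            codes = codes + (nxt << (1 + 2 * k))
        offsets = (np.arange(n) * n_states)[:, None]
        flat = (codes + offsets).ravel()
        counts = np.bincount(flat, minlength=n * n_states).reshape(n, n_states)
        # axes: (i_inst, i_past, j_past, j_next) after reshape
        c = counts.reshape(n, inst_states, n_past, n_past, 2)
        # H(j_next, j_past) and H(j_past) are pair-independent
        h_jn_jp = _entropy_from_counts(c_jp_jn)
        h_jp = _entropy_from_counts(c_jp_jn.reshape(n_past, 2).sum(axis=1))
        # H(full) and H(cond) per source neuron
        h_full = _entropy_from_counts(c.reshape(n, -1), axis=1)
        h_cond = _entropy_from_counts(c.sum(axis=4).reshape(n, -1), axis=1)
        # TE = H(j_next | j_past) - H(j_next | cond)
        scores[:, j] = (h_jn_jp - h_jp) - (h_full - h_cond)
    np.fill_diagonal(scores, 0.0)
    # clip tiny negative values from floating cancellation
    np.clip(scores, 0.0, None, out=scores)
    return scores


def threshold_network(
    scores: np.ndarray,
    n_sd: float = 2.0,
    markov_order: int = 2,
    instant_feedback: bool = True,
    neuron_ids: np.ndarray | None = None,
) -> EffectiveNetwork:
    """Binarize scores with the joint row/column significance rule.

    The null set for i -> j is the concatenation of column j (all inputs to
    j, x != j) and row i (all outputs of i, y != i); the edge is significant
    when G[i, j] strictly exceeds mean + ``n_sd`` SD of that set.
    """
    G = np.asarray(scores, dtype=np.float64)
    n = G.shape[0]
    if n < 2:
        return EffectiveNetwork(G, np.zeros_like(G, dtype=bool),
                                markov_order, instant_feedback, neuron_ids)
    off_diag = ~np.eye(n, dtype=bool)
    col_sum = np.where(off_diag, G, 0.0).sum(axis=0)
    col_sq = np.where(off_diag, G**2, 0.0).sum(axis=0)
    row_sum = np.where(off_diag, G, 0.0).sum(axis=1)
    row_sq = np.where(off_diag, G**2, 0.0).sum(axis=1)
    m = 2.0 * (n - 1)
    mean = (row_sum[:, None] + col_sum[None, :]) / m
    var = (row_sq[:, None] + col_sq[None, :]) / m - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    thresholds = mean + n_sd * sd
    adjacency = (G > thresholds) & off_diag
    return EffectiveNetwork(G, adjacency, markov_order, instant_feedback,
                            neuron_ids, thresholds)


def infer_effective_network(
    raster: np.ndarray,
    k: int = 2,
    instant_feedback: bool = True,
    n_sd: float = 2.0,
    neuron_ids: np.ndarray | None = None,
) -> EffectiveNetwork:
    """Scores + significance thresholding in one call (>=26 active rows)."""
    scores = compute_gte_scores(raster, k=k, instant_feedback=instant_feedback)
    return threshold_network(
        scores, n_sd=n_sd, markov_order=k,
        instant_feedback=instant_feedback, neuron_ids=neuron_ids,
    )
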