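"""Analytical SC->FC model: shortest-path-length, search-information, ED.

The analytical model treats the weighted structural connectome as a
communication substrate.  Edge weights w are converted to lengths (1/w by
default: stronger connections are shorter, hence preferentially used), and
two communication predictors are computed for every region pair:

* SPL -- weighted shortest-path length (Dijkstra).
* SI  -- search information: -log2 of the probability that a random walker,
  stepping with probability proportional to edge weight, follows the shortest
  path.  High SI means the shortest path is "hidden" in the local topology.
  An optional memory variant forbids the walker from immediately stepping
  back along the edge it just traversed.  SI is symmetrized as the mean of
  the two directions.

Per subject, band and SC weighting, the observed FC edge vector is regressed
(OLS with intercept) on [SPL, SI, ED]; the fitted values are the predicted FC
and the Pearson correlation between observed and fitted edges (equal to the
multiple correlation R by the OLS identity) is the accuracy score.

Shortest-path ties are broken deterministically by choosing, at every step,
the smallest-index next node that still lies on an optimal path; this yields
the lexicographically smallest optimal node sequence, which matters because
SI depends on the chosen path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path
from sklearn.base import BaseEstimator, RegressorMixin

from .core import (
    ConnectivityMatrix,
    ConnectomeError,
    Parcellation,
    matrix_from_edges,
    upper_triangle,
)

LENGTH_TRANSFORMS = ("inv", "neglog")


class DisconnectedGraphError(ConnectomeError):
    """The SC graph is disconnected, so SPL/SI are undefined for some pair."""


class IsolatedNodeError(ConnectomeError):
    """A node has zero strength; the walker's transition row is undefined."""


class ConstantResponseError(ConnectomeError):
    """The observed FC edge vector is constant; correlation is undefined."""


def to_lengths(weights: np.ndarray, transform: str = "inv") -> np.ndarray:
    """Convert an edge-weight matrix to an edge-length matrix.

    ``inv``: L = 1/w (absent edges, w == 0, become +inf).  ``neglog``:
    L = -log(w), which requires all present weights in (0, 1) — normalize
    the SC first.
    """
    w = np.asarray(weights, dtype=float)
    if transform not in LENGTH_TRANSFORMS:
        raise ValueError(f"length transform must be one of {LENGTH_TRANSFORMS}")
    with np.errstate(divide="ignore"):
        if transform == "inv":
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
        else:
            present = w > 0
            if np.any(w[present] >= 1.0):
                raise ConnectomeError(
                    "neglog length transform requires weights in (0, 1); "
                    "normalize the SC matrix first"
                )
            lengths = np.where(present, -np.log(np.where(present, w, 1.0)), np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_paths(lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs weighted shortest paths with deterministic tie-breaking.

    Returns ``(spl, next_hop)`` where ``spl[i, j]`` is the minimal total
    length (+inf for disconnected pairs) and ``next_hop[i, j]`` is the next
    node after ``i`` on the lexicographically smallest optimal path to ``j``
    (-1 where undefined, j for i == j).

    Following ``next_hop`` greedily reconstructs the full path: at each step
    the smallest-index neighbour that still lies on some optimal path is
    chosen, which produces the lexicographically smallest optimal node
    sequence.
    """
    L = np.asarray(lengths, dtype=float)
    n = L.shape[0]
    graph = np.where(np.isfinite(L), L, 0.0)
    np.fill_diagonal(graph, 0.0)
    D = _csgraph_shortest_path(graph, method="D", directed=False)

    finite_edge = np.isfinite(L) & ~np.eye(n, dtype=bool)
    # on_path[u, v, t]: edge (u, v) starts an optimal u->t path
    with np.errstate(invalid="ignore"):
        on_path = np.isclose(
            L[:, :, None] + D[None, :, :], D[:, None, :], rtol=1e-9, atol=1e-12
        )
    on_path &= finite_edge[:, :, None]
    on_path &= np.isfinite(D)[None, :, :]

    any_hop = on_path.any(axis=1)
    next_hop = np.where(any_hop, on_path.argmax(axis=1), -1)
    np.fill_diagonal(next_hop, 0)
    next_hop[np.arange(n), np.arange(n)] = np.arange(n)
    return D, next_hop


def path_between(next_hop: np.ndarray, source: int, target: int) -> list[int]:
    """Node sequence of the stored shortest path from source to target."""
    if source == target:
        return [source]
    path = [source]
    cur = source
    for _ in range(next_hop.shape[0]):
        nxt = int(next_hop[cur, target])
        if nxt < 0:
            raise DisconnectedGraphError(f"no path from {source} to {target}")
        path.append(nxt)
        cur = nxt
        if cur == target:
            return path
    raise ConnectomeError("next-hop table contains a cycle")


def transition_matrix(weights: np.ndarray) -> np.ndarray:
    """Row-stochastic random-walk transition matrix P(i,j) = w(i,j)/s(i)."""
    w = np.asarray(weights, dtype=float)
    strength = w.sum(axis=1)
    if np.any(strength <= 0):
        isolated = np.flatnonzero(strength <= 0).tolist()
        raise IsolatedNodeError(f"nodes with zero strength: {isolated}")
    return w / strength[:, None]


def search_information(
    weights: np.ndarray, next_hop: np.ndarray, memory: bool = False
) -> np.ndarray:
    """Symmetrized search information (bits) along the stored shortest paths.

    Without memory the step probability is w(u, v)/s(u).  With memory every
    step after the first renormalizes by excluding the edge just traversed:
    w(u, v) / (s(u) - w(u, prev)).  The directed values are symmetrized as
    (SI(s->t) + SI(t->s)) / 2; the diagonal is 0.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    strength = w.sum(axis=1)
    if np.any(strength <= 0):
        raise IsolatedNodeError("isolated node: transition probabilities undefined")
    if np.any(next_hop < 0):
        raise DisconnectedGraphError("graph is disconnected; SI undefined")

    targets = np.broadcast_to(np.arange(n)[None, :], (n, n))
    cur = np.broadcast_to(np.arange(n)[:, None], (n, n)).copy()
    prev = np.full((n, n), -1, dtype=int)
    neg_log2_prob = np.zeros((n, n))
    active = cur != targets
    for _ in range(n):
        if not active.any():
            break
        c = cur[active]
        t = targets[active]
        nxt = next_hop[c, t]
        denom = strength[c]
        if memory:
            p = prev[active]
            has_prev = p >= 0
            denom = denom - np.where(has_prev, w[c, np.where(has_prev, p, 0)], 0.0)
        step_prob = w[c, nxt] / denom
        neg_log2_prob[active] -= np.log2(step_prob)
        prev[active] = c
        cur[active] = nxt
        active = cur != targets
    si = (neg_log2_prob + neg_log2_prob.T) / 2.0
    np.fill_diagonal(si, 0.0)
    return si


@dataclass
class PredictorSet:
    """Per-edge SPL, SI and ED vectors in canonical edge ordering."""

    spl: np.ndarray
    si: np.ndarray
    ed: np.ndarray
    source_weight: str | None = None

    def design(self) -> np.ndarray:
        """Edge-by-predictor matrix [SPL, SI, ED] (no intercept column)."""
        return np.column_stack([self.spl, self.si, self.ed])


def build_predictors(
    sc: ConnectivityMatrix,
    ed: ConnectivityMatrix,
    si_memory: bool = False,
    length_transform: str = "inv",
) -> PredictorSet:
    """Assemble the upper-triangle SPL, symmetrized SI and ED predictors."""
    lengths = to_lengths(sc.values, transform=length_transform)
    spl, next_hop = shortest_paths(lengths)
    if not np.all(np.isfinite(spl)):
        raise DisconnectedGraphError(
            "SC graph is disconnected; increase the synthetic density or "
            "check the input matrix"
        )
    si = search_information(sc.values, next_hop, memory=si_memory)
    return PredictorSet(
        spl=upper_triangle(spl),
        si=upper_triangle(si),
        ed=upper_triangle(ed.values),
        source_weight=sc.variant,
    )


class AnalyticalFCModel(BaseEstimator, RegressorMixin):
    """Per-subject OLS of observed FC edges on [SPL, SI, ED].

    Scikit-learn style estimator: ``fit(X, y)`` takes the edge-by-predictor
    design (``PredictorSet.design()`` or any (m, p) array) and the observed
    FC edge vector; fitted values are the predicted FC edges.

    Parameters
    ----------
    si_memory : bool
        Use the memory variant of search information in
        :meth:`predictors_from_matrices`.
    length_transform : str
        'inv' (1/w) or 'neglog' (-log w on normalized weights).
    zscore_predictors : bool
        Z-score predictor columns before fitting.  Affine, so it changes the
        coefficients but not the fitted values or the accuracy r.

    Attributes
    ----------
    coef_ : (p,) slope coefficients.
    intercept_ : float.
    fitted_ : predicted FC edge vector for the training edges.
    r_ : Pearson correlation between observed and fitted edges (>= 0).
    """

    def __init__(
        self,
        si_memory: bool = False,
        length_transform: str = "inv",
        zscore_predictors: bool = False,
    ):
        self.si_memory = si_memory
        self.length_transform = length_transform
        self.zscore_predictors = zscore_predictors

    def predictors_from_matrices(
        self, sc: ConnectivityMatrix, ed: ConnectivityMatrix
    ) -> PredictorSet:
        return build_predictors(
            sc, ed, si_memory=self.si_memory, length_transform=self.length_transform
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError(f"design {X.shape} incompatible with response {y.shape}")
        if X.shape[0] < 5:
            raise ValueError("need at least 5 edges to fit the analytical model")
        if np.ptp(y) == 0:
            raise ConstantResponseError("observed FC edges are constant")
        if self.zscore_predictors:
            sd = X.std(axis=0, ddof=0)
            X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        design = np.column_stack([np.ones(X.shape[0]), X])
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            warnings.warn(
                "collinear predictors: coefficients from minimum-norm "
                "pseudo-inverse solution",
                stacklevel=2,
            )
        fitted = design @ beta
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        self.fitted_ = fitted
        self.r_ = self._pearson(y, fitted)
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _pearson(observed: np.ndarray, fitted: np.ndarray) -> float:
        if np.ptp(fitted) == 0:
            return 0.0
        return float(np.corrcoef(observed, fitted)[0, 1])

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.zscore_predictors:
            sd = X.std(axis=0, ddof=0)
            X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        return self.intercept_ + X @ self.coef_


def fit_fc(pred: PredictorSet, ofc: ConnectivityMatrix, **model_kwargs):
    """Fit the analytical regression for one subject/band/weight.

    Returns the fitted :class:`AnalyticalFCModel` (with ``fitted_`` holding
    the predicted FC edges and ``r_`` the accuracy).
    """
    model = AnalyticalFCModel(**model_kwargs)
    return model.fit(pred.design(), ofc.edges())


def predict_subject(
    cohort,
    subject_id: str,
    weight: str,
    band: str,
    si_memory: bool = False,
    length_transform: str = "inv",
    predictors: PredictorSet | None = None,
) -> tuple[ConnectivityMatrix, dict]:
    """Predict one subject's FC in one band from one SC weighting.

    Returns the predicted FC matrix and a correlation record dict with keys
    subject, model, band, weight, r, beta0..beta3.
    """
    try:
        sc = cohort.get(subject_id, "SC", weight)
        ed = cohort.get(subject_id, "ED", None)
        ofc = cohort.get(subject_id, "FC", band)
    except KeyError as exc:
        raise ConnectomeError(
            f"subject {subject_id!r} is missing matrix {exc}"
        ) from exc
    if predictors is None:
        predictors = build_predictors(
            sc, ed, si_memory=si_memory, length_transform=length_transform
        )
    model = AnalyticalFCModel(
        si_memory=si_memory, length_transform=length_transform
    ).fit(predictors.design(), ofc.edges())
    pfc = ConnectivityMatrix(
        values=matrix_from_edges(model.fitted_, cohort.parcellation.n),
        kind="FC",
        variant=band,
        parcellation=cohort.parcellation,
    )
    record = {
        "subject": subject_id,
        "model": "analytical",
        "band": band,
        "weight": weight,
        "r": model.r_,
        "beta0": model.intercept_,
        "beta1": model.coef_[0],
        "beta2": model.coef_[1],
        "beta3": model.coef_[2],
    }
    return pfc, record


def predict_cohort(
    cohort,
    weights=None,
    bands=None,
    si_memory: bool = False,
    length_transform: str = "inv",
    subjects=None,
):
    """Correlation records for every (subject, band, weight) combination.

    Predictors are computed once per (subject, weight) and reused across
    bands.  Returns a pandas DataFrame.
    """
    import pandas as pd

    from .core import FC_BANDS, SC_VARIANTS

    weights = list(weights) if weights is not None else list(SC_VARIANTS)
    bands = list(bands) if bands is not None else list(FC_BANDS)
    subject_ids = subjects if subjects is not None else [s.id for s in cohort.subjects]
    records = []
    for sid in subject_ids:
        ed = cohort.get(sid, "ED", None)
        for weight in weights:
            sc = cohort.get(sid, "SC", weight)
            pred = build_predictors(
                sc, ed, si_memory=si_memory, length_transform=length_transform
            )
            for band in bands:
                _, rec = predict_subject(
                    cohort, sid, weight, band,
                    si_memory=si_memory,
                    length_transform=length_transform,
                    predictors=pred,
                )
                records.append(rec)
    return pd.DataFrame.from_records(records)
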