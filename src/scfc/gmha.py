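"""Graph multi-head-attention autoencoder (GMHA-AE) for SC -> FC mapping.

The encoder runs GAT-style additive attention over the structural graph: the
SC matrix is the weighted adjacency (plus self-loops), and each node carries
ED-derived statistics (mean, SD and minimum of its distances to the other
regions) concatenated with SC node attributes (strength and degree, and
optionally the node's full SC row).  Per head h the unnormalized score for
an edge (i, j) is

    e_ij = LeakyReLU(a_h^T [W_h x_i || W_h x_j]) + u_h * log(1 + w_ij)

with w_ii = 0 for the self-loop term, softmax-normalized over the
neighbourhood; the learned edge-weight term u_h lets SC strength modulate
attention.  Hidden layers concatenate heads, the final layer averages them,
producing an n x d_z latent representation per subject.  The decoder scores
every region pair symmetrically with an MLP on [z_i . z_j || |z_i - z_j|]
and reconstructs the FC edge vector.  The objective is edge-wise MSE against
the max-normalized observed FC plus gamma times the squared L2 norm of all
parameters (gamma = 0.01 by default).

Evaluation follows a participant-level 5-fold cross-validation: each fold's
held-out subjects are scored exactly once by a model that never saw them;
subjects outside the cohort (e.g. patients) are scored by averaging the five
fold models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import (
    ConnectivityMatrix,
    ConnectomeError,
    matrix_from_edges,
    upper_triangle,
)
from .nn import Adam, Tensor, concat

NODE_FEATURE_NAMES = ("ed_mean", "ed_sd", "ed_min", "sc_strength", "sc_degree")


class LeakageError(ConnectomeError):
    """A subject appears both in training and in external prediction."""


class TrainingDivergedError(ConnectomeError):
    """The training loss became non-finite."""


def build_node_features(
    ed: ConnectivityMatrix, sc: ConnectivityMatrix, include_sc_row: bool = True
) -> np.ndarray:
    """Per-node feature matrix, z-scored across nodes.

    Columns, in order: mean ED to all other nodes, sample SD of those n-1
    distances (divisor n-2), minimum ED (nearest anatomical neighbour), SC
    node strength, SC node degree.  With ``include_sc_row`` the node's
    max-normalized SC row is appended (F = 5 + n); the row columns are
    indexed by node position, which makes the model more expressive over a
    fixed parcellation at the cost of exact relabeling equivariance (the
    five intrinsic features keep it).
    """
    n = ed.parcellation.n
    if n < 3:
        raise ConnectomeError("node features need at least 3 regions")
    off = ~np.eye(n, dtype=bool)
    dists = ed.values[off].reshape(n, n - 1)
    w = sc.values
    scale = np.abs(w).max()
    w_norm = w / scale if scale > 0 else w
    feats = np.column_stack(
        [
            dists.mean(axis=1),
            dists.std(axis=1, ddof=1),
            dists.min(axis=1),
            w.sum(axis=1),
            (w > 0).sum(axis=1).astype(float),
        ]
    )
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=0)
    # a column is constant (z-score 0) when its spread is at rounding level
    tiny = 1e-12 * np.maximum(1.0, np.abs(mu))
    feats = np.where(sd > tiny, (feats - mu) / np.where(sd > tiny, sd, 1.0), 0.0)
    if include_sc_row:
        feats = np.hstack([feats, w_norm])
    return feats


def subject_graph(cohort, subject_id: str, weight: str, include_sc_row: bool = True):
    """(node features, max-normalized adjacency) for one subject."""
    sc = cohort.get(subject_id, "SC", weight)
    ed = cohort.get(subject_id, "ED", None)
    X = build_node_features(ed, sc, include_sc_row=include_sc_row)
    scale = np.abs(sc.values).max()
    A = sc.values / scale if scale > 0 else sc.values
    return X, A


def normalized_fc_edges(ofc: ConnectivityMatrix) -> np.ndarray:
    """Max-normalized observed FC edge vector (the reconstruction target)."""
    edges = ofc.edges()
    scale = np.abs(edges).max()
    return edges / scale if scale > 0 else edges


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------


@dataclass
class FoldSplit:
    """Participant-level k-fold partition with per-fold train/val splits."""

    folds: list[list[str]]
    train: list[list[str]]
    validation: list[list[str]]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def development(self, fold: int) -> list[str]:
        return self.train[fold] + self.validation[fold]


def make_folds(subject_ids, k: int = 5, seed: int = 0,
               val_fraction: float = 0.25) -> FoldSplit:
    """Deterministic participant-level k-fold split.

    Each fold's complement (the development set) is further split 75/25
    into training and validation subjects for parameter fitting and
    hyperparameter selection.
    """
    ids = [s.id if hasattr(s, "id") else str(s) for s in subject_ids]
    if k > len(ids):
        raise ConnectomeError(f"cannot make {k} folds from {len(ids)} subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = [sorted(np.array(ids)[part]) for part in np.array_split(order, k)]
    train, validation = [], []
    for i in range(k):
        dev = [sid for j in range(k) if j != i for sid in folds[j]]
        dev_order = rng.permutation(len(dev))
        n_val = max(1, int(round(val_fraction * len(dev))))
        val_idx = set(dev_order[:n_val].tolist())
        validation.append(sorted(dev[j] for j in range(len(dev)) if j in val_idx))
        train.append(sorted(dev[j] for j in range(len(dev)) if j not in val_idx))
    return FoldSplit(folds=folds, train=train, validation=validation, seed=seed)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, shape)


class GmhaAutoencoder(BaseEstimator):
    """Graph multi-head-attention autoencoder, scikit-learn style.

    ``fit(graphs, targets)`` trains one model on a list of subject graphs
    (``(node_features, adjacency)`` tuples) against FC edge-vector targets;
    ``predict(graphs)`` returns predicted edge vectors.  Cohort-level
    cross-validated training lives in :func:`train_crossval`.

    Parameters mirror the training protocol: 2 attention layers, 4 heads,
    hidden width 64 (split across heads), latent dimension 32, Adam with
    learning rate 1e-3, 200 epochs, batches of 32 subject graphs, L2
    regularization weight ``gamma`` = 0.01, LeakyReLU slope 0.2.
    """

    def __init__(
        self,
        layers: int = 2,
        heads: int = 4,
        hidden_dim: int = 64,
        latent_dim: int = 32,
        decoder_hidden: int = 64,
        learning_rate: float = 1e-3,
        epochs: int = 200,
        batch_size: int = 32,
        gamma: float = 0.01,
        leaky_slope: float = 0.2,
        seed: int = 0,
    ):
        self.layers = layers
        self.heads = heads
        self.hidden_dim = hidden_dim
        self.latent_dim = latent_dim
        self.decoder_hidden = decoder_hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.gamma = gamma
        self.leaky_slope = leaky_slope
        self.seed = seed

    # -- parameters --------------------------------------------------------

    def _init_params(self, n_features: int, rng,
                     target_mean: float = 0.5,
                     target_sd: float = 0.25) -> dict:
        if self.hidden_dim % self.heads:
            raise ConnectomeError("hidden_dim must be divisible by heads")
        per_head = self.hidden_dim // self.heads
        params = {}
        f_in = n_features
        for layer in range(self.layers):
            last = layer == self.layers - 1
            f_out = self.latent_dim if last else per_head
            for h in range(self.heads):
                params[f"W{layer}_{h}"] = Tensor(_glorot(rng, (f_in, f_out)), True)
                params[f"a1_{layer}_{h}"] = Tensor(
                    _glorot(rng, (f_out, 1)), True)
                params[f"a2_{layer}_{h}"] = Tensor(
                    _glorot(rng, (f_out, 1)), True)
                params[f"u{layer}_{h}"] = Tensor(np.zeros((1, 1)), True)
            f_in = f_out if last else per_head * self.heads
        params["D1"] = Tensor(_glorot(rng, (2 * self.latent_dim, self.decoder_hidden)), True)
        params["b1"] = Tensor(np.zeros((1, self.decoder_hidden)), True)
        # output layer initialized to the training targets' location and
        # spread: convergence then does not depend on where the normalized
        # FC distribution happens to sit inside [0, 1]
        params["D2"] = Tensor(
            _glorot(rng, (self.decoder_hidden, 1)) * (target_sd / 0.25), True
        )
        params["b2"] = Tensor(np.full((1, 1), target_mean), True)
        return params

    # -- forward -----------------------------------------------------------

    def _attention_layer(self, X: Tensor, adj: np.ndarray, layer: int,
                         params: dict) -> Tensor:
        """One multi-head attention layer over the SC graph."""
        n = adj.shape[0]
        mask = (adj > 0) | np.eye(n, dtype=bool)
        edge_term = np.log1p(adj)  # w_ii = 0 for the self-loop term
        last = layer == self.layers - 1
        heads_out = []
        for h in range(self.heads):
            H = X @ params[f"W{layer}_{h}"]
            s1 = H @ params[f"a1_{layer}_{h}"]
            s2 = H @ params[f"a2_{layer}_{h}"]
            scores = (s1 + s2.T).leaky_relu(self.leaky_slope) + (
                params[f"u{layer}_{h}"] * edge_term
            )
            alpha = scores.masked_softmax(mask, axis=1)
            heads_out.append((alpha @ H).elu())
        if last:
            out = heads_out[0]
            for t in heads_out[1:]:
                out = out + t
            return out * (1.0 / self.heads)
        return concat(heads_out, axis=1)

    def _encode(self, X: np.ndarray, adj: np.ndarray, params: dict) -> Tensor:
        out = Tensor(X)
        for layer in range(self.layers):
            out = self._attention_layer(out, adj, layer, params)
        return out

    def _decode(self, Z: Tensor, n: int, params: dict) -> Tensor:
        # standardize each latent dimension across nodes: keeps the pair
        # features well-scaled whatever the attention output magnitude,
        # without breaking symmetry in (i, j)
        mu = Z.mean(axis=0, keepdims=True)
        centered = Z - mu
        var = (centered**2).mean(axis=0, keepdims=True)
        Z = centered * ((var + 1e-8) ** -0.5)
        iu, ju = np.triu_indices(n, k=1)
        zi, zj = Z[iu], Z[ju]
        pair = concat([zi * zj, (zi - zj).abs()], axis=1)
        hidden = (pair @ params["D1"] + params["b1"]).elu()
        return hidden @ params["D2"] + params["b2"]

    def _forward(self, X: np.ndarray, adj: np.ndarray, params: dict) -> Tensor:
        Z = self._encode(X, adj, params)
        return self._decode(Z, adj.shape[0], params)

    def _reg(self, params: dict) -> Tensor:
        reg = None
        for p in params.values():
            term = (p**2).sum()
            reg = term if reg is None else reg + term
        return reg

    # -- training ----------------------------------------------------------

    def fit(self, graphs, targets, validation=None):
        """Train on subject graphs against normalized FC edge targets.

        ``validation``: optional ``(graphs, targets)`` pair whose MSE is
        logged per epoch (never used for gradient updates).
        """
        graphs = list(graphs)
        targets = [np.asarray(t, float).reshape(-1, 1) for t in targets]
        rng = np.random.default_rng(self.seed)
        flat = np.concatenate([t.ravel() for t in targets])
        params = self._init_params(
            graphs[0][0].shape[1], rng,
            target_mean=float(flat.mean()),
            target_sd=float(flat.std()) or 0.25,
        )
        opt = Adam(list(params.values()), lr=self.learning_rate)
        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(len(graphs))
            epoch_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                batch = order[start:start + self.batch_size]
                opt.zero_grad()
                loss = None
                for idx in batch:
                    X, A = graphs[idx]
                    pred = self._forward(X, A, params)
                    mse = ((pred - targets[idx]) ** 2).mean()
                    loss = mse if loss is None else loss + mse
                loss = loss * (1.0 / len(batch)) + self.gamma * self._reg(params)
                if not np.isfinite(loss.data):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}"
                    )
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(batch)
            entry = {"epoch": epoch, "train_loss": epoch_loss / len(graphs)}
            if validation is not None:
                entry["val_mse"] = self._eval_mse(validation[0], validation[1], params)
            history.append(entry)
        self.params_ = params
        self.history_ = history
        self.n_features_in_ = graphs[0][0].shape[1]
        return self

    def objective(self, graphs, targets) -> float:
        """Full training objective: mean edge MSE + gamma * ||theta||^2."""
        mse = self._eval_mse(
            graphs, [np.asarray(t).ravel() for t in targets], self.params_
        )
        reg = float(self._reg(self.params_).data)
        return mse + self.gamma * reg

    def _eval_mse(self, graphs, targets, params) -> float:
        total = 0.0
        for (X, A), t in zip(graphs, targets):
            pred = self._forward(X, A, params).data.ravel()
            total += float(np.mean((pred - np.asarray(t).ravel()) ** 2))
        return total / len(graphs)

    # -- inference ---------------------------------------------------------

    def predict(self, graphs) -> list[np.ndarray]:
        """Predicted FC edge vectors, one per subject graph."""
        return [
            self._forward(X, A, self.params_).data.ravel() for X, A in graphs
        ]

    def encode(self, X: np.ndarray, adj: np.ndarray) -> np.ndarray:
        """Latent n x d_z representation for one subject graph."""
        return self._encode(X, adj, self.params_).data

    def reconstruction_mse(self, graphs, targets) -> float:
        return self._eval_mse(
            graphs, [np.asarray(t).ravel() for t in targets], self.params_
        )


# ---------------------------------------------------------------------------
# cohort-level cross-validated training
# ---------------------------------------------------------------------------


@dataclass
class CrossValResult:
    """Fold models plus out-of-fold predictions for one (band, weight)."""

    band: str
    weight: str
    include_sc_row: bool
    fold_split: FoldSplit
    models: list[GmhaAutoencoder]
    records: pd.DataFrame
    chosen_params: list[dict] = field(default_factory=list)

    @property
    def trained_ids(self) -> set:
        return {sid for fold in self.fold_split.folds for sid in fold}


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def train_crossval(
    cohort,
    band: str,
    weight: str,
    k: int = 5,
    seed: int = 0,
    grid: dict | None = None,
    include_sc_row: bool = True,
    subjects=None,
    **estimator_kwargs,
) -> CrossValResult:
    """Participant-level k-fold training for one (band, weight) condition.

    For each fold, candidate hyperparameter combinations from ``grid``
    (lists keyed by estimator parameter names; ``None`` means the defaults
    only) are trained on the fold's training subjects and ranked by
    validation MSE; the winner is retrained on the full development set and
    scores the held-out subjects exactly once.  Every random draw derives
    from ``seed``.
    """
    ids = [s.id for s in (subjects or cohort.subjects)]
    split = make_folds(ids, k=k, seed=seed)
    graphs = {
        sid: subject_graph(cohort, sid, weight, include_sc_row=include_sc_row)
        for sid in ids
    }
    targets = {
        sid: normalized_fc_edges(cohort.get(sid, "FC", band)) for sid in ids
    }
    grid_items = sorted((grid or {}).items())
    combos = [
        dict(zip([k_ for k_, _ in grid_items], values))
        for values in product(*[v for _, v in grid_items])
    ] or [{}]

    models, records, chosen = [], [], []
    for fold in range(split.k):
        tr, va, te = split.train[fold], split.validation[fold], split.folds[fold]
        best = None
        for combo in combos:
            if len(combos) > 1:
                kwargs = {**estimator_kwargs, **combo}
                cand = GmhaAutoencoder(seed=seed + 1000 * fold, **kwargs)
                cand.fit(
                    [graphs[s] for s in tr], [targets[s] for s in tr],
                    validation=([graphs[s] for s in va], [targets[s] for s in va]),
                )
                val = cand.history_[-1]["val_mse"]
            else:
                combo, val = combos[0], 0.0
            if best is None or val < best[1]:
                best = (combo, val)
        chosen.append(best[0])
        kwargs = {**estimator_kwargs, **best[0]}
        model = GmhaAutoencoder(seed=seed + 1000 * fold, **kwargs)
        dev = tr + va
        model.fit(
            [graphs[s] for s in dev], [targets[s] for s in dev],
            validation=([graphs[s] for s in va], [targets[s] for s in va]),
        )
        models.append(model)
        preds = model.predict([graphs[s] for s in te])
        for sid, pred in zip(te, preds):
            records.append(
                {
                    "subject": sid,
                    "model": "gmha",
                    "band": band,
                    "weight": weight,
                    "fold": fold,
                    "r": _pearson(targets[sid], pred),
                }
            )
    return CrossValResult(
        band=band,
        weight=weight,
        include_sc_row=include_sc_row,
        fold_split=split,
        models=models,
        records=pd.DataFrame.from_records(records),
        chosen_params=chosen,
    )


def predict_external(
    result: CrossValResult, cohort, subject_ids, allow_seen: bool = False
) -> tuple[dict, pd.DataFrame]:
    """Score subjects outside the training cohort (e.g. patients).

    Predictions are averaged over the k fold models.  Scoring a subject that
    appeared in any training fold raises :class:`LeakageError` unless
    ``allow_seen`` is set.
    """
    seen = result.trained_ids & set(subject_ids)
    if seen and not allow_seen:
        raise LeakageError(
            f"subjects {sorted(seen)} were used in training; pass "
            "allow_seen=True to override"
        )
    records, pfcs = [], {}
    n = cohort.parcellation.n
    for sid in subject_ids:
        X, A = subject_graph(
            cohort, sid, result.weight, include_sc_row=result.include_sc_row
        )
        preds = [m.predict([(X, A)])[0] for m in result.models]
        pred = np.mean(preds, axis=0)
        target = normalized_fc_edges(cohort.get(sid, "FC", result.band))
        pfcs[sid] = ConnectivityMatrix(
            values=matrix_from_edges(pred, n),
            kind="FC",
            variant=result.band,
            parcellation=cohort.parcellation,
        )
        records.append(
            {
                "subject": sid,
                "model": "gmha",
                "band": result.band,
                "weight": result.weight,
                "fold": -1,
                "r": _pearson(target, pred),
            }
        )
    return pfcs, pd.DataFrame.from_records(records)


def export_latent(result: CrossValResult, cohort, subject_ids=None) -> pd.DataFrame:
    """Flat table of latent node coordinates plus per-subject error 1 - r.

    Each subject is encoded by the model of the fold that held it out (or
    the first fold model for unseen subjects), so latents are never produced
    by a model trained on that subject.
    """
    ids = subject_ids or [s.id for s in cohort.subjects]
    fold_of = {
        sid: f for f, fold in enumerate(result.fold_split.folds) for sid in fold
    }
    rows = []
    for sid in ids:
        X, A = subject_graph(
            cohort, sid, result.weight, include_sc_row=result.include_sc_row
        )
        model = result.models[fold_of.get(sid, 0)]
        Z = model.encode(X, A)
        pred = model.predict([(X, A)])[0]
        target = normalized_fc_edges(cohort.get(sid, "FC", result.band))
        err = 1.0 - _pearson(target, pred)
        for node in range(Z.shape[0]):
            row = {"subject": sid, "node": node, "prediction_error": err}
            row.update({f"z{d}": Z[node, d] for d in range(Z.shape[1])})
            rows.append(row)
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_crossval(result: CrossValResult, directory) -> None:
    """Write a reloadable checkpoint directory for a cross-validated run."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "band": result.band,
        "weight": result.weight,
        "include_sc_row": result.include_sc_row,
        "seed": result.fold_split.seed,
        "folds": result.fold_split.folds,
        "train": result.fold_split.train,
        "validation": result.fold_split.validation,
        "estimator_params": [m.get_params() for m in result.models],
    }
    (directory / "config.json").write_text(json.dumps(meta, indent=1))
    result.records.to_csv(directory / "oof_records.csv", index=False)
    for f, model in enumerate(result.models):
        np.savez(
            directory / f"fold{f}_params.npz",
            **{k: v.data for k, v in model.params_.items()},
        )
        pd.DataFrame(model.history_).to_csv(
            directory / f"fold{f}_loss.csv", index=False
        )


def load_crossval(directory) -> CrossValResult:
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    split = FoldSplit(
        folds=meta["folds"],
        train=meta["train"],
        validation=meta["validation"],
        seed=meta["seed"],
    )
    models = []
    for f, params in enumerate(meta["estimator_params"]):
        model = GmhaAutoencoder(**params)
        archive = np.load(directory / f"fold{f}_params.npz")
        model.params_ = {k: Tensor(archive[k], True) for k in archive.files}
        model.history_ = pd.read_csv(
            directory / f"fold{f}_loss.csv"
        ).to_dict("records")
        models.append(model)
    return CrossValResult(
        band=meta["band"],
        weight=meta["weight"],
        include_sc_row=meta["include_sc_row"],
        fold_split=split,
        models=models,
        records=pd.read_csv(directory / "oof_records.csv"),
    )
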