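"""Functional and effective connectivity between oscillatory elements.

*Functional connectivity* (FC) is the plain Pearson correlation matrix of
the 48 elements across trials.  *Effective connectivity* (EC) is directed
and model-based: each element is predicted from the other 47 (optionally
plus the two behavior variables) with the random-intercept model, and the
averaged regression coefficients form a target-by-source weight matrix.
Both are bootstrap-averaged: 50 subsamples of 75% of the trials drawn
without replacement (stratified by subject so every random intercept stays
identifiable), with the held-out 25% used to cross-validate each target's
predictive performance (Pearson r).

All columns are z-scored per subsample with training statistics, so the
stored weights are per-SD (standardized) coefficients, comparable across
elements and invariant to common rescaling of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .elements import element_columns
from .io import validate_table
from .mixedlm import GramLMM

__all__ = [
    "ECMatrix",
    "FCMatrix",
    "compute_fc",
    "fit_ec",
    "cross_train",
    "ec_similarity",
]

BEHAVIOR_NODES = ("error", "duration")


@dataclass
class ECMatrix:
    """Directed weighted adjacency over element (and behavior) nodes.

    ``weights[t, s]`` is the averaged coefficient of source node ``s`` in
    the model predicting target node ``t`` (target row, source column);
    the diagonal is structurally zero.
    """

    nodes: list[str]
    weights: np.ndarray
    n_bootstrap: int = 0
    provenance: str = "pooled"
    performance: np.ndarray | None = None  # per-target cross-validated r

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.nodes)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square over nodes")
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite EC weights")
        if np.abs(np.diag(self.weights)).max(initial=0.0) > 0:
            raise ValueError("EC diagonal must be zero")

    @property
    def abs_weights(self) -> np.ndarray:
        return np.abs(self.weights)

    def off_diagonal(self) -> np.ndarray:
        """Flattened off-diagonal weights in row-major order."""
        n = len(self.nodes)
        mask = ~np.eye(n, dtype=bool)
        return self.weights[mask]

    def element_submatrix(self) -> "ECMatrix":
        """Restrict to the 48 element nodes (drop behavior nodes)."""
        keep = [i for i, n in enumerate(self.nodes) if n not in BEHAVIOR_NODES]
        idx = np.ix_(keep, keep)
        return ECMatrix(
            nodes=[self.nodes[i] for i in keep],
            weights=self.weights[idx],
            n_bootstrap=self.n_bootstrap,
            provenance=self.provenance,
            performance=None if self.performance is None else self.performance[keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.nodes, columns=self.nodes)

    def to_csv(self, path) -> None:
        # orientation: rows = target, columns = source
        df = self.to_dataframe()
        df.index.name = "target\\source"
        df.to_csv(path)

    def to_edge_list(self, path=None) -> pd.DataFrame:
        rows = []
        for t, tn in enumerate(self.nodes):
            for s, sn in enumerate(self.nodes):
                if t == s:
                    continue
                w = self.weights[t, s]
                rows.append((sn, tn, w, abs(w), self.provenance))
        df = pd.DataFrame(rows, columns=["source", "target", "weight", "abs_weight", "provenance"])
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for t, tn in enumerate(self.nodes):
            for s, sn in enumerate(self.nodes):
                if t != s and self.weights[t, s] != 0:
                    g.add_edge(sn, tn, weight=float(self.weights[t, s]))
        return g


@dataclass
class FCMatrix:
    """Bootstrap-averaged symmetric Pearson correlation matrix."""

    nodes: list[str]
    weights: np.ndarray
    n_bootstrap: int = 0
    provenance: str = "pooled"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.nodes, columns=self.nodes)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)


def _stratified_split(subject_ids: np.ndarray, frac: float, rng: np.random.Generator):
    """75/25-style split without replacement, per subject."""
    train = []
    for s in np.unique(subject_ids):
        idx = np.flatnonzero(subject_ids == s)
        if frac >= 1.0:
            train.append(idx)
            continue
        n_train = max(int(round(frac * idx.size)), 1)
        n_train = min(n_train, idx.size - 1) if idx.size > 1 else idx.size
        train.append(rng.choice(idx, size=n_train, replace=False))
    train = np.sort(np.concatenate(train))
    test = np.setdiff1d(np.arange(subject_ids.size), train)
    return train, test


def compute_fc(
    table: pd.DataFrame,
    n_boot: int = 50,
    frac: float = 0.75,
    seed: int = 0,
) -> FCMatrix:
    """Bootstrap-averaged element correlation matrix.

    Each of ``n_boot`` replicas correlates the 48 elements on a random
    ``frac`` subsample (without replacement, stratified by subject); the
    replicas are averaged.  A constant element column is rejected by name.
    """
    validate_table(table, require_behavior=False)
    cols = element_columns()
    X = table[cols].to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = cols[int(np.argmax(sd == 0))]
        raise ValueError(f"element {bad!r} is constant; correlation undefined")
    subs = table["subject"].to_numpy()
    rng = np.random.default_rng(seed)
    acc = np.zeros((len(cols), len(cols)))
    for _ in range(n_boot):
        tr, _ = _stratified_split(subs, frac, rng)
        if tr.size < 3:
            raise ValueError("fewer than 3 trials per resample")
        sub = X[tr]
        if (sub.std(axis=0) == 0).any():
            bad = cols[int(np.argmax(sub.std(axis=0) == 0))]
            raise ValueError(f"element {bad!r} is constant in a resample")
        acc += np.corrcoef(sub, rowvar=False)
    w = acc / n_boot
    np.fill_diagonal(w, 1.0)
    return FCMatrix(nodes=list(cols), weights=w, n_bootstrap=n_boot)


def _node_columns(include_behavior: bool) -> list[str]:
    cols = element_columns()
    return cols + list(BEHAVIOR_NODES) if include_behavior else cols


def _fit_targets(
    M_train: np.ndarray,
    subs_train: np.ndarray,
    M_test: np.ndarray,
    subs_test: np.ndarray,
    reml: bool,
):
    """Fit each column of M on all others; return (coef matrix, per-target r).

    Columns are z-scored with training statistics before fitting, so
    coefficients are standardized.  Held-out performance is the Pearson r
    between predicted and actual (standardized) target values.
    """
    mean = M_train.mean(axis=0)
    sd = M_train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z_train = (M_train - mean) / sd
    Z_test = (M_test - mean) / sd if M_test.size else M_test
    n_nodes = M_train.shape[1]
    engine = GramLMM(Z_train, subs_train)
    W = np.zeros((n_nodes, n_nodes))
    perf = np.full(n_nodes, np.nan)
    for t in range(n_nodes):
        didx = np.array([j for j in range(n_nodes) if j != t])
        res = engine.fit(y_index=t, design_indices=didx, reml=reml)
        W[t, didx] = res["beta1"]
        if M_test.size:
            u = np.array([res["u"].get(s, 0.0) for s in subs_test])
            yhat = res["beta0"] + Z_test[:, didx] @ res["beta1"] + u
            y = Z_test[:, t]
            if np.std(yhat) > 0 and np.std(y) > 0:
                perf[t] = stats.pearsonr(y, yhat)[0]
            else:
                perf[t] = 0.0
    return W, perf


def fit_ec(
    table: pd.DataFrame,
    include_behavior: bool = False,
    n_boot: int = 50,
    frac: float = 0.75,
    seed: int = 0,
    reml: bool = True,
    provenance: str | None = None,
) -> ECMatrix:
    """Estimate the effective-connectivity matrix by element-wise prediction.

    For each bootstrap replica (``frac`` of trials, stratified by subject)
    every node is regressed on all other nodes with the random-intercept
    model; coefficients are averaged over replicas and the held-out
    fraction gives the per-target cross-validated Pearson r (stored in
    ``performance``, averaged over replicas).
    """
    require_behavior = bool(include_behavior)
    validate_table(table, require_behavior=require_behavior)
    nodes = _node_columns(include_behavior)
    M = table[nodes].to_numpy(dtype=float)
    subs = table["subject"].to_numpy()
    rng = np.random.default_rng(seed)
    W = np.zeros((len(nodes), len(nodes)))
    perf = np.zeros(len(nodes))
    for _ in range(n_boot):
        tr, te = _stratified_split(subs, frac, rng)
        Wb, pb = _fit_targets(M[tr], subs[tr], M[te], subs[te], reml)
        W += Wb
        perf += np.nan_to_num(pb)
    W /= n_boot
    perf /= n_boot
    np.fill_diagonal(W, 0.0)
    if provenance is None:
        cats = table["category"].unique()
        provenance = cats[0] if len(cats) == 1 else "pooled"
    return ECMatrix(
        nodes=nodes,
        weights=W,
        n_bootstrap=n_boot,
        provenance=provenance,
        performance=perf,
    )


def cross_train(
    table: pd.DataFrame,
    n_boot: int = 10,
    frac: float = 0.75,
    seed: int = 0,
    reml: bool = True,
    categories: list[str] | None = None,
) -> pd.DataFrame:
    """Cross-training generalization matrix between trial categories.

    Entry (A, B): element-prediction models are fitted on a 75% training
    subsample of category A and evaluated on the held-out 25% of category
    B; the value is the Pearson r between actual and predicted element
    values averaged over the 48 targets and over ``n_boot`` resamples.
    The diagonal reduces to each category's own cross-validated EC
    performance.
    """
    validate_table(table, require_behavior=False)
    if categories is None:
        categories = list(pd.unique(table["category"]))
    if len(categories) < 2:
        raise ValueError("cross-training needs at least 2 categories")
    for c in categories:
        if (table["category"] == c).sum() < 8:
            raise ValueError(f"category {c!r} absent or too small for a 75/25 split")
    cols = element_columns()
    rng = np.random.default_rng(seed)
    out = np.zeros((len(categories), len(categories)))
    sub_tabs = {c: table[table["category"] == c].reset_index(drop=True) for c in categories}
    for _ in range(n_boot):
        splits = {}
        for c in categories:
            t = sub_tabs[c]
            subs = t["subject"].to_numpy()
            tr, te = _stratified_split(subs, frac, rng)
            splits[c] = (t, tr, te)
        for ia, a in enumerate(categories):
            ta, tra, _ = splits[a]
            M_train = ta.loc[tra, cols].to_numpy(dtype=float)
            subs_train = ta.loc[tra, "subject"].to_numpy()
            mean = M_train.mean(axis=0)
            sd = np.where(M_train.std(axis=0) > 0, M_train.std(axis=0), 1.0)
            engine = GramLMM((M_train - mean) / sd, subs_train)
            fits = []
            for t in range(len(cols)):
                didx = np.array([j for j in range(len(cols)) if j != t])
                fits.append((didx, engine.fit(y_index=t, design_indices=didx, reml=reml)))
            for ib, b in enumerate(categories):
                tb, _, teb = splits[b]
                M_test = tb.loc[teb, cols].to_numpy(dtype=float)
                subs_test = tb.loc[teb, "subject"].to_numpy()
                Z_test = (M_test - mean) / sd
                rs = []
                for t, (didx, res) in enumerate(fits):
                    u = np.array([res["u"].get(s, 0.0) for s in subs_test])
                    yhat = res["beta0"] + Z_test[:, didx] @ res["beta1"] + u
                    y = Z_test[:, t]
                    if np.std(yhat) > 0 and np.std(y) > 0:
                        rs.append(stats.pearsonr(y, yhat)[0])
                out[ia, ib] += float(np.mean(rs)) if rs else 0.0
    out /= n_boot
    return pd.DataFrame(out, index=categories, columns=categories)


def ec_similarity(ecA: ECMatrix, ecB: ECMatrix) -> float:
    """Pearson correlation of the two flattened off-diagonal weight vectors."""
    if list(ecA.nodes) != list(ecB.nodes):
        raise ValueError("EC matrices have different node sets or ordering")
    a = ecA.off_diagonal()
    b = ecB.off_diagonal()
    return float(stats.pearsonr(a, b)[0])
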