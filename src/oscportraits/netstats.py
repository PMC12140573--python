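"""Graph-level characterization of effective-connectivity networks.

Weighted homophily asks what fraction of total connection weight joins
nodes sharing a label — the same region (spatial), the same frequency band
(spectral) or the same movement phase (temporal):

    H_axis = sum of |w| over same-label ordered pairs / sum of all |w|.

Each axis is tested against a null in which that axis' labels are permuted
across nodes while the wiring (and the other two label axes) stays fixed.
All computations use |w|: the homophily ratios are ratios of weight sums
and would be ill-behaved under sign cancellation.  Strong links are the
entries above the 97th percentile of the pooled absolute off-diagonal
weight distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ec import BEHAVIOR_NODES, ECMatrix
from .elements import ElementIndex

__all__ = [
    "HomophilyTriplet",
    "NullDistribution",
    "NodeStrengths",
    "strong_links",
    "homophily",
    "homophily_null",
    "delta_homophily",
    "node_strengths",
    "homophily_report",
]

AXES = ("spatial", "spectral", "temporal")
_AXIS_ATTR = {"spatial": "region", "spectral": "band", "temporal": "epoch"}


@dataclass(frozen=True)
class HomophilyTriplet:
    """Fractions of total |weight| on same-region/band/epoch links."""

    spatial: float
    spectral: float
    temporal: float

    def __post_init__(self) -> None:
        for axis in AXES:
            v = getattr(self, axis)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"homophily ratio {axis}={v} outside [0, 1]")

    def as_percent(self) -> tuple[float, float, float]:
        return (100 * self.spatial, 100 * self.spectral, 100 * self.temporal)


@dataclass
class NullDistribution:
    statistic: str
    n_shuffles: int
    values: np.ndarray
    seed: int
    observed: float
    p_value: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_shuffles:
            raise ValueError("values length must equal n_shuffles")


@dataclass(frozen=True)
class NodeStrengths:
    node: str
    in_strength: float
    out_strength: float
    in_count: int
    out_count: int


def _element_labels_of(ec: ECMatrix, axis: str) -> np.ndarray:
    attr = _AXIS_ATTR[axis]
    labels = []
    for n in ec.nodes:
        if n in BEHAVIOR_NODES:
            raise ValueError("behavior nodes must be excluded before homophily")
        labels.append(getattr(ElementIndex.from_name(n), attr))
    return np.asarray(labels)


def strong_links(
    ec: ECMatrix, percentile: float = 97.0, pool: list[ECMatrix] | None = None
) -> np.ndarray:
    """Boolean mask of links strictly above the pooled percentile threshold.

    The threshold is the given percentile of |weights| pooled over the
    off-diagonals of all matrices in ``pool`` (default: just ``ec``), as
    when one common threshold serves all per-category networks.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be inside (0, 100)")
    if not pool:
        pool = [ec]
    pooled = np.concatenate([np.abs(m.off_diagonal()) for m in pool])
    threshold = np.percentile(pooled, percentile)
    mask = ec.abs_weights > threshold
    np.fill_diagonal(mask, False)
    return mask


def _homophily_from(absw: np.ndarray, labels_by_axis: dict[str, np.ndarray]) -> HomophilyTriplet:
    off = ~np.eye(absw.shape[0], dtype=bool)
    total = absw[off].sum()
    if total <= 0:
        raise ValueError("zero total weight; homophily undefined")
    vals = {}
    for axis, labels in labels_by_axis.items():
        same = labels[:, None] == labels[None, :]
        vals[axis] = float(absw[same & off].sum() / total)
    return HomophilyTriplet(**vals)


def homophily(ec: ECMatrix) -> HomophilyTriplet:
    """Spatial/spectral/temporal homophily of an element-node network."""
    ec = ec.element_submatrix()
    labels = {axis: _element_labels_of(ec, axis) for axis in AXES}
    return _homophily_from(ec.abs_weights, labels)


def homophily_null(
    ec: ECMatrix,
    label_axis: str,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Label-permutation null for one homophily axis.

    The chosen axis' labels are permuted across nodes (weights and the
    other label axes untouched) and the homophily recomputed each time;
    the empirical p-value is (1 + #{null >= observed}) / (1 + n_shuffles).
    """
    if label_axis not in AXES:
        raise ValueError(f"label_axis must be one of {AXES}, got {label_axis!r}")
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be at least 100")
    ec = ec.element_submatrix()
    absw = ec.abs_weights
    labels = {axis: _element_labels_of(ec, axis) for axis in AXES}
    observed = getattr(_homophily_from(absw, labels), label_axis)
    rng = np.random.default_rng(seed)
    base = labels[label_axis]
    null = np.empty(n_shuffles)
    off = ~np.eye(absw.shape[0], dtype=bool)
    total = absw[off].sum()
    for i in range(n_shuffles):
        perm = rng.permutation(base)
        same = perm[:, None] == perm[None, :]
        null[i] = absw[same & off].sum() / total
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_shuffles)
    return NullDistribution(
        statistic=f"H_{label_axis}",
        n_shuffles=n_shuffles,
        values=null,
        seed=seed,
        observed=float(observed),
        p_value=float(p),
    )


def delta_homophily(
    h_category: HomophilyTriplet, h_pooled: HomophilyTriplet
) -> tuple[float, float, float]:
    """Percent change of each homophily axis relative to the pooled network."""
    out = []
    for axis in AXES:
        pooled = getattr(h_pooled, axis)
        if pooled <= 0:
            raise ValueError(f"pooled homophily on axis {axis!r} is zero")
        out.append(100.0 * (getattr(h_category, axis) - pooled) / pooled)
    return tuple(out)


def node_strengths(
    ec: ECMatrix,
    node: str,
    mask: np.ndarray | None = None,
    percentile: float = 97.0,
    pool: list[ECMatrix] | None = None,
) -> NodeStrengths:
    """Incoming/outgoing |weight| sums and strong-link counts for one node.

    In-strength sums the node's row (the sources that predict it);
    out-strength sums its column (the targets it helps predict).  Counts
    are over the strong-links mask, computed here from ``percentile`` and
    ``pool`` when not supplied.
    """
    if node not in ec.nodes:
        raise ValueError(f"unknown node {node!r}")
    i = ec.nodes.index(node)
    absw = ec.abs_weights
    if mask is None:
        mask = strong_links(ec, percentile=percentile, pool=pool)
    return NodeStrengths(
        node=node,
        in_strength=float(absw[i, :].sum()),
        out_strength=float(absw[:, i].sum()),
        in_count=int(mask[i, :].sum()),
        out_count=int(mask[:, i].sum()),
    )


def homophily_report(
    ec_by_category: dict[str, ECMatrix],
    ec_pooled: ECMatrix,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy per-category homophily table: observed, null mean, p, delta-H%."""
    h_pooled = homophily(ec_pooled)
    rows = []
    for cat, ec in ec_by_category.items():
        h = homophily(ec)
        dh = delta_homophily(h, h_pooled)
        for axis, d in zip(AXES, dh):
            null = homophily_null(ec, axis, n_shuffles=n_shuffles, seed=seed)
            rows.append(
                {
                    "category": cat,
                    "axis": axis,
                    "observed": getattr(h, axis),
                    "null_mean": float(null.values.mean()),
                    "p_value": null.p_value,
                    "delta_pct": d,
                }
            )
    return pd.DataFrame(rows)
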