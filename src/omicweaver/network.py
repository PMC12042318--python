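"""Mutual-information networks with ARACNE pruning and key-driver analysis.

The default MI estimator is Gaussian-rank: each feature is mapped to normal
scores (rank-based inverse normal transform), Pearson correlation is computed
on the scores, and MI = -1/2 ln(1 - r^2) nats.  This is exact for Gaussian
copulas and invariant under strictly monotone marginal transforms.  An
equal-frequency binning plug-in estimator is available behind a config key.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, ValidationError
from .diffexpr import bh_adjust

MI_CAP = 5.0  # nats; caps the r -> 1 divergence


def _rank_int(X: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform per row, ties averaged."""
    n = X.shape[1]
    ranks = stats.rankdata(X, axis=1)
    return stats.norm.ppf(ranks / (n + 1.0))


def mutual_information_matrix(
    m: ExpressionMatrix, estimator: str = "gaussian_rank", n_bins: int | None = None,
) -> pd.DataFrame:
    """Symmetric pairwise MI (nats) between features; diagonal is zero."""
    if m.n_samples < 10:
        raise ValidationError("need >= 10 samples for MI estimation")
    X = m.values
    if np.isnan(X).any():
        X = np.where(np.isnan(X), np.nanmean(X, axis=1, keepdims=True), X)
    constant = X.std(axis=1) == 0
    if estimator == "gaussian_rank":
        Z = _rank_int(X)
        Z[constant] = 0.0
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(Z)
        r = np.where(np.isfinite(r), r, 0.0)
        r2 = np.clip(r**2, 0.0, 1.0 - 1e-12)
        mi = -0.5 * np.log1p(-r2)
        mi = np.minimum(mi, MI_CAP)
    elif estimator == "binning":
        if n_bins is None:
            n_bins = max(2, int(np.floor(np.sqrt(m.n_samples / 5.0))) + 1)
        G, n = X.shape
        # equal-frequency bin labels per feature
        labels = np.empty((G, n), dtype=np.int64)
        for g in range(G):
            labels[g] = pd.qcut(stats.rankdata(X[g], method="average"),
                                n_bins, labels=False, duplicates="drop")
        mi = np.zeros((G, G))
        for i in range(G):
            for j in range(i + 1, G):
                joint = np.zeros((n_bins, n_bins))
                np.add.at(joint, (labels[i], labels[j]), 1.0)
                joint /= n
                pi = joint.sum(axis=1, keepdims=True)
                pj = joint.sum(axis=0, keepdims=True)
                with np.errstate(divide="ignore", invalid="ignore"):
                    term = joint * np.log(joint / (pi * pj))
                mi[i, j] = mi[j, i] = np.nansum(term)
        mi = np.minimum(np.clip(mi, 0.0, None), MI_CAP)
    else:
        raise ValidationError(f"unknown MI estimator {estimator!r}")
    mi[constant, :] = 0.0
    mi[:, constant] = 0.0
    np.fill_diagonal(mi, 0.0)
    return pd.DataFrame(mi, index=m.feature_ids, columns=m.feature_ids)


@dataclasses.dataclass
class MINetwork:
    """Dense MI matrix plus the edge set surviving DPI pruning."""

    nodes: list[str]
    mi: pd.DataFrame
    edges: set[tuple[str, str]]          # canonical (min, max) node pairs
    epsilon: float

    def neighbors(self) -> dict[str, set[str]]:
        nb: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            nb[u].add(v)
            nb[v].add(u)
        return nb


def aracne_prune(mi: pd.DataFrame, epsilon: float = 0.0,
                 mi_threshold: float = 0.0) -> MINetwork:
    """Data-processing-inequality pruning of a dense MI matrix.

    For every triple (i, j, k) the edge (i, j) is marked for removal when
    MI_ij < min(MI_ik, MI_kj) - epsilon; all marks are evaluated against the
    original matrix and applied after the full pass, so the result is
    independent of node order.  Edges with MI <= mi_threshold are dropped
    outright.
    """
    M = mi.to_numpy(float)
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValidationError("MI matrix must be symmetric")
    nodes = list(mi.index)
    G = len(nodes)
    keep = M > mi_threshold
    np.fill_diagonal(keep, False)
    removed = np.zeros_like(keep)
    # vectorized over k: edge (i,j) dies if any k has both legs stronger
    for k in range(G):
        col = M[:, k]
        # min of the two legs through k, for every (i, j)
        legs = np.minimum.outer(col, col)
        mark = (M < legs - epsilon) & keep
        mark[:, k] = False
        mark[k, :] = False
        removed |= mark
    final = keep & ~removed
    edges = {tuple(sorted((nodes[i], nodes[j])))
             for i in range(G) for j in range(i + 1, G) if final[i, j]}
    return MINetwork(nodes, mi, edges, epsilon)


def module_local_network(net: MINetwork, members: list[str]) -> MINetwork:
    """Subgraph induced by a module's members plus their direct neighbors."""
    nb = net.neighbors()
    keep = set(members) & set(net.nodes)
    for v in list(keep):
        keep |= nb.get(v, set())
    nodes = [v for v in net.nodes if v in keep]
    edges = {(u, v) for u, v in net.edges if u in keep and v in keep}
    return MINetwork(nodes, net.mi.loc[nodes, nodes], edges, net.epsilon)


def key_driver_analysis(
    net: MINetwork, signature: set[str], h: int = 2, fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of a signature within each node's h-hop neighborhood.

    Background is the full node set of the network.  Key drivers are the
    nodes with neighborhood FDR < ``fdr_threshold``, ranked by odds ratio
    then p-value.
    """
    sig = set(signature) & set(net.nodes)
    if not sig:
        raise ValidationError("signature shares no nodes with the network")
    nb = net.neighbors()
    U = len(net.nodes)
    S = len(sig)
    rows = []
    for v in net.nodes:
        frontier = {v}
        reach: set[str] = set()
        for _ in range(h):
            nxt = set()
            for u in frontier:
                nxt |= nb[u]
            nxt -= reach | {v}
            if not nxt:
                break
            reach |= nxt
            frontier = nxt
        nsize = len(reach)
        k = len(reach & sig)
        if nsize == 0:
            rows.append(dict(node=v, neighborhood=0, overlap=0,
                             odds_ratio=np.nan, p=np.nan))
            continue
        p = stats.hypergeom.sf(k - 1, U, S, nsize)
        cells = (k, nsize - k, S - k, U - nsize - S + k)
        if 0 in cells:
            a, b, c, d = (c + 0.5 for c in cells)
        else:
            a, b, c, d = cells
        rows.append(dict(node=v, neighborhood=nsize, overlap=k,
                         odds_ratio=(a * d) / (b * c), p=p))
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["is_key_driver"] = table["fdr"] < fdr_threshold
    table = table.sort_values(["is_key_driver", "odds_ratio", "p"],
                              ascending=[False, False, True], kind="mergesort")
    return table.reset_index(drop=True)
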