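"""Over-representation and enrichment statistics.

One Fisher 2x2 engine backs every categorical enrichment in the pipeline
(modules vs cell types, modules vs trait gene lists, miRNA targets vs DEPs,
module preservation); on top sit the cell-type specificity index (pSI) and a
preranked GSEA with a gene-label permutation null.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, GeneSetCollection, ValidationError
from .coexpression import GREY, ModuleSet
from .diffexpr import bh_adjust


def fisher_test_greater(k: int, query: int, setsize: int, universe: int) -> tuple[float, float]:
    """One-sided (greater) Fisher p and Haldane-corrected odds ratio.

    2x2 table: (in query & set, in query only, in set only, in neither).
    """
    p = float(stats.hypergeom.sf(k - 1, universe, query, setsize))
    cells = (k, query - k, setsize - k, universe - query - setsize + k)
    if min(cells) < 0:
        raise ValidationError("inconsistent 2x2 table")
    if 0 in cells:
        a, b, c, d = (c + 0.5 for c in cells)
    else:
        a, b, c, d = cells
    return p, (a * d) / (b * c)


def fisher_overrepresentation(
    query: set[str], sets: GeneSetCollection, universe: set[str], query_name: str = "query",
) -> pd.DataFrame:
    """One-sided Fisher over-representation of ``query`` in each gene set."""
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = set(query) & universe
    rows = []
    for name, members in sets.items():
        s = set(members) & universe
        k = len(query & s)
        p, orr = fisher_test_greater(k, len(query), len(s), len(universe))
        rows.append(dict(query=query_name, set=name, universe=len(universe),
                         query_size=len(query), set_size=len(s), overlap=k,
                         odds_ratio=orr, p=p))
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# cell-type specificity index


@dataclasses.dataclass
class SpecificityProfile:
    si: pd.DataFrame    # genes x cell types, average rank (1 = most specific)
    psi: pd.DataFrame   # genes x cell types, permutation p
    n_permutations: int


def _si_matrix(means: np.ndarray) -> np.ndarray:
    """Average rank of each gene's log-ratio against every other cell type.

    Rank 1 = largest mean_t - mean_u, i.e. most specific to type t.
    """
    G, T = means.shape
    si = np.zeros((G, T))
    for t in range(T):
        ranks = np.zeros(G)
        for u in range(T):
            if u == t:
                continue
            diff = means[:, t] - means[:, u]
            ranks += stats.rankdata(-diff, method="average")
        si[:, t] = ranks / (T - 1)
    return si


def specificity_index_psi(
    cell_means: ExpressionMatrix, B: int = 1000, seed: int = 0,
    pseudocount: float = 1e-6,
) -> SpecificityProfile:
    """Specificity index and its permutation p-value per gene and cell type.

    ``cell_means`` holds log-scale mean expression (genes x cell types).  The
    null shuffles each gene's values across cell types independently; the
    permuted SI values are pooled per type across genes and permutations into
    one empirical null, so pSI is strictly monotone in SI within a type and
    has resolution 1/(B x n_genes) rather than the 1/n_types floor a per-gene
    comparison would impose.
    """
    if cell_means.n_samples < 2:
        raise ValidationError("need at least 2 cell types")
    if B < 100:
        warnings.warn("B < 100 permutations gives coarse pSI resolution")
    M = cell_means.values + pseudocount
    G, T = M.shape
    si_obs = _si_matrix(M)
    rng = np.random.default_rng(seed)
    # pooled permutation null per cell type
    null_sorted = [[] for _ in range(T)]
    for _ in range(B):
        keys = rng.random((G, T))
        perm = np.take_along_axis(M, np.argsort(keys, axis=1), axis=1)
        si_perm = _si_matrix(perm)
        for t in range(T):
            null_sorted[t].append(si_perm[:, t])
    psi = np.empty((G, T))
    for t in range(T):
        pool = np.sort(np.concatenate(null_sorted[t]))
        # count of permuted SI <= observed, +1 correction
        counts = np.searchsorted(pool, si_obs[:, t], side="right")
        psi[:, t] = (1.0 + counts) / (pool.size + 1.0)
    idx, cols = cell_means.feature_ids, cell_means.sample_ids
    return SpecificityProfile(pd.DataFrame(si_obs, index=idx, columns=cols),
                              pd.DataFrame(psi, index=idx, columns=cols), B)


def celltype_module_enrichment(
    mods: ModuleSet, prof: SpecificityProfile, psi_threshold: float = 0.05,
    id_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of each module in each cell type's pSI gene set.

    ``id_map`` (profile gene id -> module feature id) bridges namespaces when
    the profile is gene-level and modules are protein-level; identity by
    default.  Universe = features present in both the modules and the profile.
    """
    if id_map is None:
        id_map = {g: g for g in prof.psi.index}
    mapped = {g: f for g, f in id_map.items()
              if g in prof.psi.index and f in mods.assignment}
    universe = set(mapped.values())
    if not universe:
        raise ValidationError("no features shared between modules and profile")
    rows = []
    for ct in prof.psi.columns:
        hits = {mapped[g] for g in mapped if prof.psi.at[g, ct] <= psi_threshold}
        for mod in sorted({c for c in mods.assignment.values() if c != GREY}):
            members = set(mods.members(mod)) & universe
            k = len(members & hits)
            if not hits:
                rows.append(dict(query=mod, set=ct, universe=len(universe),
                                 query_size=len(members), set_size=0, overlap=0,
                                 odds_ratio=np.nan, p=1.0))
                continue
            p, orr = fisher_test_greater(k, len(members), len(hits), len(universe))
            rows.append(dict(query=mod, set=ct, universe=len(universe),
                             query_size=len(members), set_size=len(hits),
                             overlap=k, odds_ratio=orr, p=p))
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# preranked GSEA


@dataclasses.dataclass
class GseaResult:
    table: pd.DataFrame                   # per set: ES, NES, p, fdr, n_hits
    leading_edge: dict[str, list[str]]


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, N: int) -> np.ndarray:
    """Enrichment score for hit positions (sorted ascending along axis -1).

    ``pos``: (..., nh) 0-based positions in the ranked list; ``weights``:
    matching |score|^p values.  Returns the signed maximal deviation of the
    running sum.
    """
    nh = pos.shape[-1]
    miss = 1.0 / (N - nh)
    w = weights / np.clip(weights.sum(axis=-1, keepdims=True), 1e-300, None)
    cumw = np.cumsum(w, axis=-1)
    i = np.arange(1, nh + 1)
    after = cumw - (pos + 1 - (i - 1) - 1) * miss          # just after hit i
    before = np.concatenate(
        [np.zeros((*pos.shape[:-1], 1)), cumw[..., :-1]], axis=-1
    ) - (pos - (i - 1)) * miss                              # just before hit i
    hi = after.max(axis=-1)
    lo = before.min(axis=-1)
    return np.where(hi >= -lo, hi, lo)


def gsea_preranked(
    ranked: pd.Series, sets: GeneSetCollection, weight: float = 1.0,
    B: int = 1000, seed: int = 0, min_size: int = 3,
) -> GseaResult:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked``: feature -> signed score.  Ties are broken deterministically by
    feature id.  For each set the p-value compares |ES| against same-sign
    permutation scores, and NES divides ES by the mean same-sign |ES_perm|.
    Sets overlapping the ranking by fewer than ``min_size`` features are
    skipped and flagged.
    """
    if not np.isfinite(ranked.to_numpy(float)).all():
        raise ValidationError("scores must be finite")
    order = sorted(ranked.index, key=lambda f: (-ranked[f], f))
    scores = ranked[order].to_numpy(float)
    N = len(order)
    pos_of = {f: i for i, f in enumerate(order)}
    absw = np.abs(scores) ** weight
    rng = np.random.default_rng(seed)
    rows, leading = [], {}
    for name, members in sets.items():
        hit_pos = np.sort([pos_of[f] for f in members if f in pos_of])
        nh = len(hit_pos)
        if nh < min_size or nh >= N:
            rows.append(dict(set=name, n_hits=nh, ES=np.nan, NES=np.nan,
                             p=np.nan, skipped=True))
            continue
        es = float(_es_from_positions(hit_pos[None, :], absw[hit_pos][None, :], N)[0])
        perm_pos = np.sort(
            np.array([rng.choice(N, nh, replace=False) for _ in range(B)]), axis=1
        )
        es_perm = _es_from_positions(perm_pos, absw[perm_pos], N)
        same = es_perm >= 0 if es >= 0 else es_perm < 0
        n_same = int(same.sum())
        p = (1.0 + float((np.abs(es_perm[same]) >= abs(es)).sum())) / (n_same + 1.0)
        denom = np.abs(es_perm[same]).mean() if n_same else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        rows.append(dict(set=name, n_hits=nh, ES=es, NES=nes, p=p, skipped=False))
        # leading edge: hits at or before the running-sum extremum
        if es >= 0:
            w = absw[hit_pos] / absw[hit_pos].sum()
            running_after = np.cumsum(w) - (hit_pos + 1 - np.arange(1, nh + 1)) / (N - nh)
            peak = int(np.argmax(running_after))
            leading[name] = [order[q] for q in hit_pos[: peak + 1]]
        else:
            leading[name] = [order[q] for q in hit_pos]
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return GseaResult(table, leading)


# ---------------------------------------------------------------------------
# trait-list (TWAS-style) module enrichment


def twas_module_enrichment(
    mods: ModuleSet,
    trait_lists: dict[str, list[str]],
    id_map: dict[str, str],
    top_n: int = 200,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of each trait's top genes in each protein module.

    ``id_map`` maps gene id -> protein id.  Default universe = genes mappable
    to measured proteins; per trait the query is the top ``top_n`` genes of
    its ranked list intersected with the universe; module sets are the mapped
    genes of each module's proteins.  Nominal p < 0.05 is flagged significant
    (the convention for these lists); BH FDR is reported alongside.
    """
    if top_n <= 0:
        raise ValidationError("top_n must be positive")
    mapped = {g: p for g, p in id_map.items() if p in mods.assignment}
    if universe is None:
        universe = set(mapped)
    prot2gene = {p: g for g, p in mapped.items()}
    module_sets = {}
    for mod in sorted({c for c in mods.assignment.values() if c != GREY}):
        genes = [prot2gene[p] for p in mods.members(mod) if p in prot2gene]
        genes = [g for g in genes if g in universe]
        if genes:
            module_sets[mod] = genes
    frames = []
    for trait, ranked in trait_lists.items():
        if len(ranked) < top_n:
            warnings.warn(f"trait {trait!r} list shorter than top_n; using all {len(ranked)}")
        query = set(ranked[:top_n]) & universe
        t = fisher_overrepresentation(query, GeneSetCollection(module_sets),
                                      universe, query_name=trait)
        frames.append(t)
    table = pd.concat(frames, ignore_index=True)
    table["significant"] = table["p"] < 0.05
    return table
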