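"""Signed weighted co-expression modules.

The construction follows the standard weighted-network recipe: Pearson
correlation -> signed soft-threshold adjacency a_ij = ((1+r)/2)^beta ->
topological overlap matrix -> average-linkage clustering of 1-TOM -> static
height cut -> eigengene-based merging of near-duplicate modules.  Module
labels are deterministic color names ordered by module size.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_core import ExpressionMatrix, SampleTable, ValidationError
from .diffexpr import bh_adjust

# conventional module palette, assigned largest-module-first
COLOR_SEQUENCE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta",
)
GREY = "grey"


@dataclasses.dataclass
class CoexpressionParams:
    """Network construction settings; soft power defaults are per region."""

    beta: float | None = None            # None -> pick by scale-free fit
    region_beta: dict | None = None      # {"DLPFC": 6, "sgPFC": 4}
    candidate_powers: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16, 18, 20)
    scale_free_target: float = 0.8
    merge_cut_height: float = 0.1
    min_module_size: int = 20
    # tree cut: clusters are harvested at ascending fractions of the maximum
    # merge height and kept when internally cohesive; weak modules only
    # separate from the noise floor near the root, strong ones far below it
    cut_height_fracs: tuple = (0.88, 0.90, 0.92, 0.94, 0.95, 0.96, 0.97, 0.98)
    cohesion_min: float = 0.2       # median within-cluster Pearson r to accept
    max_missing_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.region_beta is None:
            self.region_beta = {"DLPFC": 6.0, "sgPFC": 4.0}
        if not (0.0 < self.merge_cut_height < 1.0):
            raise ValidationError("merge_cut_height must lie in (0, 1)")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be >= 2")
        if self.beta is not None and self.beta < 1:
            raise ValidationError("soft power must be >= 1")

    def beta_for(self, region: str | None) -> float | None:
        if self.beta is not None:
            return self.beta
        if region is not None and region in self.region_beta:
            return float(self.region_beta[region])
        return None


@dataclasses.dataclass
class ModuleSet:
    """Feature->module assignment plus eigengenes and kME."""

    assignment: dict[str, str]           # feature -> color label ("grey" = unassigned)
    eigengenes: pd.DataFrame             # modules x samples, unit norm per module
    kme: pd.DataFrame                    # features x modules
    params: CoexpressionParams
    cohort: str = ""                     # e.g. "PTSD/DLPFC"

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.index]

    def members(self, module: str) -> list[str]:
        return [f for f, m in self.assignment.items() if m == module]


def pairwise_correlation(m: ExpressionMatrix) -> np.ndarray:
    """Feature-feature Pearson correlation, pairwise-complete when missing."""
    X = m.values
    if not np.isnan(X).any():
        with np.errstate(invalid="ignore"):
            return np.corrcoef(X)
    df = pd.DataFrame(X.T)
    return df.corr(min_periods=3).to_numpy()


def signed_adjacency(cor: np.ndarray, beta: float) -> np.ndarray:
    """a_ij = ((1 + r_ij)/2)^beta with zero diagonal."""
    cor = np.asarray(cor, float)
    a = ((1.0 + np.clip(cor, -1.0, 1.0)) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: shared-neighbor weight relative to the sparser node.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), diagonal 1.
    """
    adj = np.asarray(adj, float)
    if not np.allclose(adj, adj.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # includes u = i or j terms, which are zero off the diagonal path
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def pick_soft_threshold(
    m: ExpressionMatrix,
    powers: tuple = CoexpressionParams.candidate_powers,
    target: float = 0.8,
    default: float = 6.0,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, float]:
    """Scale-free topology scan: smallest power whose fit index reaches target.

    Fit index = R^2 of log10 frequency vs log10 mean connectivity over
    equal-width connectivity bins, negated when the slope is positive
    (scale-free networks have a falling degree distribution); falls back to
    ``default`` when no candidate reaches the target.
    """
    if m.n_features < 20:
        raise ValidationError("need >= 20 features for the soft-threshold scan")
    cor = pairwise_correlation(m)
    if np.isnan(cor).all():
        raise ValidationError("correlation undefined (constant features?)")
    rows = []
    chosen = None
    for b in powers:
        a = signed_adjacency(cor, b)
        k = np.nansum(a, axis=1)
        k = k[k > 0]
        if k.size < n_bins:
            rows.append(dict(power=b, fit=np.nan, slope=np.nan, mean_k=np.nan))
            continue
        qs = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
        idx = np.clip(np.searchsorted(qs, k, side="right") - 1, 0, n_bins - 1)
        freq = np.bincount(idx, minlength=n_bins).astype(float)
        mean_k = np.array([k[idx == i].mean() if (idx == i).any() else np.nan
                           for i in range(n_bins)])
        ok = (freq > 0) & np.isfinite(mean_k) & (mean_k > 0)
        if ok.sum() < 3:
            rows.append(dict(power=b, fit=np.nan, slope=np.nan, mean_k=float(np.mean(k))))
            continue
        x, y = np.log10(mean_k[ok]), np.log10(freq[ok])
        slope, _, r, _, _ = stats.linregress(x, y)
        fit = r**2 * (-np.sign(slope))
        rows.append(dict(power=b, fit=fit, slope=slope, mean_k=float(np.mean(k))))
        if chosen is None and fit >= target:
            chosen = float(b)
    table = pd.DataFrame(rows)
    return table, (chosen if chosen is not None else float(default))


def _color_labels(clusters: list[list[str]]) -> dict[str, str]:
    """Deterministic labels: largest module gets the first palette color."""
    order = sorted(range(len(clusters)), key=lambda i: (-len(clusters[i]), clusters[i][0]))
    labels = {}
    for rank, i in enumerate(order):
        color = COLOR_SEQUENCE[rank] if rank < len(COLOR_SEQUENCE) else f"module{rank}"
        for f in clusters[i]:
            labels[f] = color
    return labels


def module_eigengenes(
    m: ExpressionMatrix, assignment: dict[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First singular vector per module (on z-scored members) plus kME table.

    Eigengenes are unit-norm and sign-aligned so the mean member correlation
    is positive.  kME is the Pearson correlation of every feature with every
    eigengene; features constant across samples get missing kME.
    """
    modules = sorted({c for c in assignment.values() if c != GREY})
    if not modules:
        raise ValidationError("no non-grey modules")
    X = m.values
    fidx = {f: i for i, f in enumerate(m.feature_ids)}
    me_rows = {}
    for mod in modules:
        members = [f for f in m.feature_ids if assignment.get(f) == mod]
        sub = X[[fidx[f] for f in members]]
        mu = np.nanmean(sub, axis=1, keepdims=True)
        sd = np.nanstd(sub, axis=1, ddof=1, keepdims=True)
        keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
        z = (sub[keep] - mu[keep]) / sd[keep]
        z = np.where(np.isnan(z), 0.0, z)  # missing cells contribute nothing
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        # sign convention: mean correlation with members > 0
        cors = [np.corrcoef(row, me)[0, 1] for row in z]
        if np.nanmean(cors) < 0:
            me = -me
        me_rows[mod] = me / np.linalg.norm(me)
    eigengenes = pd.DataFrame(me_rows, index=m.sample_ids).T

    # kME: feature x module correlations
    sd = np.nanstd(X, axis=1, ddof=1)
    kme = np.full((m.n_features, len(modules)), np.nan)
    mu = np.nanmean(X, axis=1, keepdims=True)
    Z = (X - mu) / np.where(sd[:, None] > 0, sd[:, None], np.nan)
    has_nan = np.isnan(Z).any()
    ME = eigengenes.to_numpy()
    MEz = (ME - ME.mean(axis=1, keepdims=True)) / ME.std(axis=1, ddof=1, keepdims=True)
    if not has_nan:
        kme = (Z @ MEz.T) / (m.n_samples - 1)
    else:
        for i in range(m.n_features):
            row = Z[i]
            ok = np.isfinite(row)
            if ok.sum() >= 3:
                for j in range(len(modules)):
                    r = np.corrcoef(row[ok], ME[j, ok])[0, 1]
                    kme[i, j] = r
    kme_df = pd.DataFrame(kme, index=m.feature_ids, columns=modules)
    return eigengenes, kme_df


def detect_modules(
    m: ExpressionMatrix,
    params: CoexpressionParams | None = None,
    region: str | None = None,
    cohort: str = "",
) -> ModuleSet:
    """Full module construction: adjacency -> TOM -> tree cut -> eigengene merge.

    Deterministic given the matrix and parameters.  Features with more than
    ``max_missing_frac`` missing values are excluded from the network and left
    grey.
    """
    params = params or CoexpressionParams()
    usable = list(m.feature_ids)
    if m.missing_mask is not None and m.missing_mask.any():
        frac = m.missing_mask.mean(axis=1)
        usable = [f for f, fr in zip(m.feature_ids, frac) if fr <= params.max_missing_frac]
    work = m.subset_features(usable)
    assignment = {f: GREY for f in m.feature_ids}
    if work.n_features < params.min_module_size:
        return ModuleSet(assignment, pd.DataFrame(columns=m.sample_ids),
                         pd.DataFrame(index=m.feature_ids), params, cohort)

    beta = params.beta_for(region)
    if beta is None:
        _, beta = pick_soft_threshold(work, params.candidate_powers,
                                      params.scale_free_target)
    cor = pairwise_correlation(work)
    cor = np.where(np.isfinite(cor), cor, 0.0)
    # drop features with undefined self-correlation (constant profiles)
    sd_ok = np.nanstd(work.values, axis=1) > 0
    adj = signed_adjacency(cor, beta)
    adj[~sd_ok, :] = 0.0
    adj[:, ~sd_ok] = 0.0
    tom = tom_similarity(adj)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    link = hierarchy.average(squareform(diss, checks=False))
    hmax = link[:, 2].max()
    assigned = np.zeros(work.n_features, bool)
    clusters: list[list[str]] = []
    for frac in params.cut_height_fracs:
        flat = hierarchy.fcluster(link, t=float(frac * hmax), criterion="distance")
        for cid in np.unique(flat):
            idx = np.where((flat == cid) & ~assigned)[0]
            if len(idx) < params.min_module_size:
                continue
            # cohesion check on (a deterministic subset of) the candidate
            sub = idx[:300]
            block = cor[np.ix_(sub, sub)]
            med = float(np.median(block[np.triu_indices(len(sub), 1)]))
            if med >= params.cohesion_min:
                clusters.append([work.feature_ids[i] for i in idx])
                assigned[idx] = True
    if not clusters:
        return ModuleSet(assignment, pd.DataFrame(columns=m.sample_ids),
                         pd.DataFrame(index=m.feature_ids), params, cohort)

    # eigengene merge: average-linkage on 1 - cor(ME), cut at merge height
    provisional = {f: f"c{ci}" for ci, cl in enumerate(clusters) for f in cl}
    for f in work.feature_ids:
        provisional.setdefault(f, GREY)
    while True:
        me, _ = module_eigengenes(work, provisional)
        if len(me) < 2:
            break
        cor_me = np.corrcoef(me.to_numpy())
        d_me = 1.0 - cor_me
        np.fill_diagonal(d_me, 0.0)
        d_me = np.clip((d_me + d_me.T) / 2.0, 0.0, None)
        link_me = hierarchy.average(squareform(d_me, checks=False))
        groups = hierarchy.fcluster(link_me, t=params.merge_cut_height, criterion="distance")
        if len(np.unique(groups)) == len(me):
            break
        mapping = {}
        for gid in np.unique(groups):
            mods = [me.index[i] for i in np.where(groups == gid)[0]]
            tgt = mods[0]
            for mod in mods:
                mapping[mod] = tgt
        provisional = {f: mapping.get(c, GREY) for f, c in provisional.items()}

    final_clusters = {}
    for f, c in provisional.items():
        if c != GREY:
            final_clusters.setdefault(c, []).append(f)
    labels = _color_labels(list(final_clusters.values()))
    for f, color in labels.items():
        assignment[f] = color
    me, kme = module_eigengenes(work, {f: assignment[f] for f in work.feature_ids})
    kme = kme.reindex(m.feature_ids)
    return ModuleSet(assignment, me, kme, params, cohort)


def module_trait_correlation(
    mods: ModuleSet, s: SampleTable, traits: list[str] | None = None,
    case: str | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each (encoded) trait.

    Encoding: dx CON=0/case=1, sex F=0/M=1, ancestry one-hot, continuous as-is.
    BH correction spans the full module x trait grid.
    """
    if traits is None:
        traits = ["dx", "age", "pmi", "sex", "ancestry", "rin"]
    df = s.frame.set_index("sample_id").loc[list(mods.eigengenes.columns)]
    encoded: dict[str, np.ndarray] = {}
    for t in traits:
        if t == "dx":
            if case is None:
                lv = [x for x in df["dx"].unique() if x != "CON"]
                case_lv = lv[0] if lv else "PTSD"
            else:
                case_lv = case
            encoded["dx"] = (df["dx"] == case_lv).to_numpy(float)
        elif t == "sex":
            encoded["sex"] = (df["sex"] == "M").to_numpy(float)
        elif t == "ancestry":
            for lv in sorted(df["ancestry"].unique())[1:]:
                encoded[f"ancestry_{lv}"] = (df["ancestry"] == lv).to_numpy(float)
        else:
            encoded[t] = df[t].to_numpy(float)
    rows = []
    for mod in mods.eigengenes.index:
        me = mods.eigengenes.loc[mod].to_numpy(float)
        for name, x in encoded.items():
            if np.std(x) == 0 or np.std(me) == 0:
                rows.append(dict(module=mod, trait=name, r=np.nan, p=np.nan))
                continue
            r, p = stats.pearsonr(me, x)
            rows.append(dict(module=mod, trait=name, r=r, p=p))
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table


def module_overlap_preservation(a: ModuleSet, b: ModuleSet) -> pd.DataFrame:
    """Cross-tabulate two module sets feature-by-feature with Fisher tests.

    For each (module in a, module in b) pair: one-sided (greater) Fisher p of
    the 2x2 membership table over the shared universe, odds ratio with a 0.5
    Haldane correction on zero cells, BH across all pairs; preserved iff
    FDR < 0.05.
    """
    universe = sorted(set(a.assignment) & set(b.assignment))
    if not universe:
        raise ValidationError("module sets share no features")
    rows = []
    mods_a = sorted({c for c in a.assignment.values() if c != GREY})
    mods_b = sorted({c for c in b.assignment.values() if c != GREY})
    U = len(universe)
    for ma in mods_a:
        in_a = {f for f in universe if a.assignment[f] == ma}
        for mb in mods_b:
            in_b = {f for f in universe if b.assignment[f] == mb}
            k = len(in_a & in_b)
            qa, qb = len(in_a), len(in_b)
            p = stats.hypergeom.sf(k - 1, U, qa, qb)
            cells = (k, qa - k, qb - k, U - qa - qb + k)
            if 0 in cells:
                k2, b2, c2, d2 = (c + 0.5 for c in cells)
            else:
                k2, b2, c2, d2 = cells
            rows.append(dict(module_a=ma, module_b=mb, universe=U,
                             size_a=qa, size_b=qb, overlap=k,
                             odds_ratio=(k2 * d2) / (b2 * c2), p=p))
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["preserved"] = table["fdr"] < 0.05
    return table
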