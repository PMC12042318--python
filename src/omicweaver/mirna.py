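"""miRNA-protein integration.

Builds the matched-sample protein-miRNA correlation graph (protein log10
intensity vs miRNA log2 FPKM, Pearson, nominal p < 0.05 edges), then asks
which miRNAs' connected proteins are enriched for differential proteins or
for co-expression module membership, cross-references predicted-target
tables, and fits the grouped RNA-vs-protein fold-change regression that
separates miRNA-targeted proteins from the rest.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ExpressionMatrix, SampleTable, TargetTable, ValidationError
from .coexpression import GREY, ModuleSet
from .diffexpr import bh_adjust
from .enrichment import fisher_test_greater


def mirna_fpkm(
    counts: ExpressionMatrix,
    lengths: dict[str, int],
    min_mean: float = 0.5,
) -> ExpressionMatrix:
    """Filter by mean raw count > ``min_mean`` and convert to log2(FPKM + 1).

    FPKM_gj = counts_gj * 1e9 / (length_g * total_counts_j), with the library
    totals taken over the retained features.  Features lacking a length are
    dropped with a warning.
    """
    if counts.modality != "mirna_counts":
        raise ValidationError("mirna_fpkm expects mirna_counts")
    means = counts.values.mean(axis=1)
    keep = [f for f, mu in zip(counts.feature_ids, means) if mu > min_mean]
    missing_len = [f for f in keep if f not in lengths]
    if missing_len:
        import warnings

        warnings.warn(f"{len(missing_len)} miRNAs lack lengths and were dropped")
        keep = [f for f in keep if f in lengths]
    if not keep:
        raise ValidationError("no miRNAs pass the expression filter")
    sub = counts.subset_features(keep)
    L = np.array([lengths[f] for f in keep], float)
    if (L <= 0).any():
        raise ValidationError("miRNA lengths must be positive")
    totals = sub.values.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("sample with zero library size")
    fpkm = sub.values * 1e9 / (L[:, None] * totals[None, :])
    return ExpressionMatrix(keep, list(sub.sample_ids), np.log2(fpkm + 1.0), "mirna_log2fpkm")


def match_multiomic_samples(
    prot: ExpressionMatrix,
    mirna: ExpressionMatrix,
    s: SampleTable,
    case: str,
    region: str,
) -> list[str]:
    """Samples measured in both modalities, restricted to CON+case in a region."""
    df = s.frame
    cohort = df[(df["region"] == region) & (df["dx"].isin(["CON", case]))]
    matched = [sid for sid in cohort["sample_id"]
               if sid in set(prot.sample_ids) and sid in set(mirna.sample_ids)]
    if len(matched) < 3:
        raise ValidationError(
            f"only {len(matched)} matched samples for CON+{case} in {region}"
        )
    return matched


@dataclasses.dataclass
class ConnectionGraph:
    """miRNA-protein correlation edges with per-node tested-universe bookkeeping."""

    edges: pd.DataFrame      # mirna_id, protein_id, r, p, significant, n
    cohort: str              # e.g. "PTSD/DLPFC"
    tested_proteins: dict[str, set[str]]   # mirna -> proteins tested against it

    def significant_partners(self, mirna_id: str) -> set[str]:
        e = self.edges
        sel = e[(e["mirna_id"] == mirna_id) & e["significant"]]
        return set(sel["protein_id"])


def correlate_protein_mirna(
    prot: ExpressionMatrix,
    mirna_log2fpkm: ExpressionMatrix,
    samples: list[str] | None = None,
    cohort: str = "",
    p_threshold: float = 0.05,
    min_n: int = 3,
    adjust: np.ndarray | None = None,
) -> ConnectionGraph:
    """Pearson correlation of every (protein, miRNA) pair on matched samples.

    Missing protein entries are excluded pairwise; pairs with fewer than
    ``min_n`` complete observations or a constant vector are untested.
    Significance is the nominal two-sided p < ``p_threshold``, per the edge
    convention (inference happens at the enrichment layer, not per edge).

    ``adjust`` (n_samples x k covariate matrix, e.g. the dx indicator) turns
    the edges into partial correlations: both sides are residualized on the
    covariates first and the t-test degrees of freedom drop by k.  Useful to
    separate direct miRNA-protein coupling from shared diagnosis effects.
    """
    if samples is None:
        samples = [s for s in prot.sample_ids if s in set(mirna_log2fpkm.sample_ids)]
    if len(samples) < min_n:
        raise ValidationError("fewer than 3 matched samples")
    P = prot.subset_samples(samples).values            # (Gp, n)
    M = mirna_log2fpkm.subset_samples(samples).values  # (Gm, n)
    n = len(samples)
    df_loss = 0
    if adjust is not None:
        Z = np.column_stack([np.ones(n), np.asarray(adjust, float)])
        df_loss = Z.shape[1] - 1
        H = Z @ np.linalg.pinv(Z)
        if np.isnan(P).any():
            P = np.where(np.isnan(P), np.nanmean(P, axis=1, keepdims=True), P)
        P = P - P @ H.T
        M = M - M @ H.T
    has_nan = np.isnan(P).any()

    def corr_block(P: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Pc = P - P.mean(axis=1, keepdims=True)
        Mc = M - M.mean(axis=1, keepdims=True)
        Pn = np.sqrt((Pc**2).sum(axis=1))
        Mn = np.sqrt((Mc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Pc @ Mc.T) / np.outer(Pn, Mn)
        counts = np.full(r.shape, n)
        return r, counts

    if not has_nan:
        r, counts = corr_block(P, M)
    else:
        Gp, Gm = P.shape[0], M.shape[0]
        r = np.full((Gp, Gm), np.nan)
        counts = np.zeros((Gp, Gm), int)
        for i in range(Gp):
            ok = ~np.isnan(P[i])
            if ok.sum() < min_n:
                continue
            x = P[i, ok]
            if x.std() == 0:
                continue
            sub = M[:, ok]
            xc = x - x.mean()
            mc = sub - sub.mean(axis=1, keepdims=True)
            denom = np.sqrt((xc**2).sum()) * np.sqrt((mc**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r[i] = (mc @ xc) / denom
            counts[i] = ok.sum()

    r = np.clip(r, -1.0, 1.0)
    dof = counts - 2 - df_loss
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(dof / np.clip(1.0 - r**2, 1e-300, None))
        pval = 2.0 * stats.t.sf(np.abs(t), np.clip(dof, 1, None))
    tested = np.isfinite(r) & (counts >= min_n) & (dof >= 1)

    prot_ids = np.array(prot.feature_ids)
    mir_ids = np.array(mirna_log2fpkm.feature_ids)
    ii, jj = np.where(tested)
    edges = pd.DataFrame(
        {
            "mirna_id": mir_ids[jj],
            "protein_id": prot_ids[ii],
            "r": r[ii, jj],
            "p": pval[ii, jj],
            "n": counts[ii, jj],
        }
    )
    edges["significant"] = edges["p"] < p_threshold
    # share one set object across miRNAs tested against the full protein panel
    full = set(prot_ids)
    all_tested = tested.all(axis=0)
    tested_map = {
        mid: (full if all_tested[j] else set(prot_ids[tested[:, j]]))
        for j, mid in enumerate(mir_ids)
    }
    return ConnectionGraph(edges, cohort, tested_map)


def mirna_dep_enrichment(
    g: ConnectionGraph,
    dep_flags: dict[str, bool],
    mirna_de: pd.DataFrame | None = None,
    sign_by: str = "log2fc",
) -> pd.DataFrame:
    """Per-miRNA Fisher enrichment of DEPs among its connected proteins.

    Universe = proteins tested against the miRNA; query = its significantly
    connected proteins; set = DEPs (nominal disease p < 0.05 upstream).  The
    display sign of -log10 p follows the miRNA's disease log2FC when a miRNA
    DE table is supplied (``sign_by='log2fc'``) or the mean edge correlation
    (``sign_by='mean_r'``).
    """
    de_lookup = {}
    if mirna_de is not None:
        de_lookup = dict(zip(mirna_de["feature_id"], mirna_de["log2fc"]))
    sig_edges = g.edges[g.edges["significant"]]
    by_mirna = {mid: grp for mid, grp in sig_edges.groupby("mirna_id", sort=False)}
    dep_set = {p for p, flag in dep_flags.items() if flag}
    rows = []
    for mid, universe in sorted(g.tested_proteins.items()):
        e = by_mirna.get(mid)
        connected = (set(e["protein_id"]) if e is not None else set()) & universe
        deps = dep_set & universe
        mean_r = float(e["r"].mean()) if e is not None and len(e) else np.nan
        if not connected:
            rows.append(dict(mirna_id=mid, universe=len(universe), query_size=0,
                             set_size=len(deps), overlap=0, odds_ratio=np.nan,
                             p=1.0, mean_r=mean_r, sign=0.0))
            continue
        k = len(connected & deps)
        p, orr = fisher_test_greater(k, len(connected), len(deps), len(universe))
        if sign_by == "mean_r":
            sign = float(np.sign(mean_r)) if np.isfinite(mean_r) else 0.0
        else:
            sign = float(np.sign(de_lookup.get(mid, 0.0)))
        rows.append(dict(mirna_id=mid, universe=len(universe), query_size=len(connected),
                         set_size=len(deps), overlap=k, odds_ratio=orr, p=p,
                         mean_r=mean_r, sign=sign))
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p"] < 0.05
    table["signed_logp"] = table["sign"] * -np.log10(np.clip(table["p"], 1e-300, 1.0))
    return table


def mirna_module_enrichment(g: ConnectionGraph, mods: ModuleSet) -> pd.DataFrame:
    """Per (miRNA, module) Fisher enrichment of module membership among the
    miRNA's significantly connected proteins; universe = proteins tested
    against that miRNA.  Mean edge correlation over the significant edges
    landing in the module is reported for sign interpretation."""
    modules = sorted({c for c in mods.assignment.values() if c != GREY})
    sig_edges = g.edges[g.edges["significant"]]
    by_mirna = {mid: grp for mid, grp in sig_edges.groupby("mirna_id", sort=False)}
    member_sets = {mod: set(mods.members(mod)) for mod in modules}
    rows = []
    for mid, universe in sorted(g.tested_proteins.items()):
        e = by_mirna.get(mid)
        if e is None:
            e = sig_edges.iloc[:0]
        connected = set(e["protein_id"]) & universe
        r_by_prot = dict(zip(e["protein_id"], e["r"]))
        for mod in modules:
            members = member_sets[mod] & universe
            if not members:
                continue
            k = len(connected & members)
            in_mod_r = [r_by_prot[p] for p in (connected & members)]
            mean_r = float(np.mean(in_mod_r)) if in_mod_r else np.nan
            if not connected:
                rows.append(dict(mirna_id=mid, module=mod, universe=len(universe),
                                 query_size=0, set_size=len(members), overlap=0,
                                 odds_ratio=np.nan, p=1.0, mean_module_r=mean_r))
                continue
            p, orr = fisher_test_greater(k, len(connected), len(members), len(universe))
            rows.append(dict(mirna_id=mid, module=mod, universe=len(universe),
                             query_size=len(connected), set_size=len(members),
                             overlap=k, odds_ratio=orr, p=p, mean_module_r=mean_r))
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p"] < 0.05
    return table


def annotate_predicted_targets(g: ConnectionGraph, targets: TargetTable) -> ConnectionGraph:
    """Flag edges present in a predicted-target table, per source."""
    edges = g.edges.copy()
    tdf = targets.frame
    edge_idx = pd.MultiIndex.from_arrays([edges["mirna_id"], edges["protein_id"]])
    for source in sorted(tdf["source"].unique()):
        sel = tdf[tdf["source"] == source]
        pair_idx = pd.MultiIndex.from_arrays([sel["mirna_id"], sel["target_id"]])
        edges[f"predicted_{source}"] = edge_idx.isin(pair_idx)
    pred_cols = [c for c in edges.columns if c.startswith("predicted_")]
    edges["predicted"] = edges[pred_cols].any(axis=1) if pred_cols else False
    return ConnectionGraph(edges, g.cohort, g.tested_proteins)


def grouped_fc_regression(
    pairs: pd.DataFrame,  # columns: feature_id, rna_log2fc, protein_log2fc
    group: dict[str, bool],  # feature_id -> miRNA-associated?
) -> pd.DataFrame:
    """Per-group OLS of protein log2FC on RNA log2FC.

    Groups: proteins with at least one significant miRNA connection vs the
    rest.  Groups with < 3 pairs or degenerate variance are flagged undefined.
    """
    out = []
    labels = {True: "mirna_associated", False: "not_associated"}
    for flag, name in labels.items():
        sel = pairs[[group.get(f, False) == flag for f in pairs["feature_id"]]]
        x = sel["rna_log2fc"].to_numpy(float)
        y = sel["protein_log2fc"].to_numpy(float)
        if len(sel) < 3 or np.std(x) == 0 or np.std(y) == 0:
            out.append(dict(group=name, n=len(sel), slope=np.nan,
                            intercept=np.nan, r=np.nan, defined=False))
            continue
        fit = stats.linregress(x, y)
        out.append(dict(group=name, n=len(sel), slope=fit.slope,
                        intercept=fit.intercept, r=fit.rvalue, defined=True))
    return pd.DataFrame(out)
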