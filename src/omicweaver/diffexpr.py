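"""Differential abundance testing.

Two engines share one result schema:

* a moderated linear model for protein log-intensities — per-feature OLS with
  empirical-Bayes shrinkage of residual variances toward a common prior
  (scaled-F moment matching via digamma/trigamma inversion), giving a
  moderated t with d0 + d_g degrees of freedom;
* a negative-binomial Wald test for RNA / miRNA counts — per-feature NB GLM
  (log link, log size-factor offset) fit by batched IRLS, with a per-feature
  moment dispersion estimate refined by one-dimensional maximum likelihood.

Plus Benjamini-Hochberg adjustment, rank-rank hypergeometric overlap maps and
RNA-protein concordance summaries.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_core import COUNT_MODALITIES, ExpressionMatrix, SampleTable, ValidationError

LOG2_PER_LOG10 = np.log2(10.0)

# modality-specific covariate defaults, mirroring region-stratified models:
# proteins adjust for age/ancestry/sex; transcripts add PMI, age^2, RIN, RIN^2;
# miRNAs adjust for age, RIN, sex.
PROTEIN_COVARIATES = ("age", "ancestry", "sex")
RNA_COVARIATES = ("pmi", "sex", "ancestry", "age", "age2", "rin", "rin2")
MIRNA_COVARIATES = ("age", "rin", "sex")


@dataclasses.dataclass
class DesignSpec:
    """Two-group contrast (CON vs one case level) with additive covariates."""

    case: str  # "PTSD" or "MDD"
    covariates: tuple[str, ...] = PROTEIN_COVARIATES
    region: str | None = None

    def build(self, s: SampleTable) -> tuple[np.ndarray, list[str]]:
        """Model matrix with intercept; dx column is the tested coefficient."""
        df = s.frame
        levels = set(df["dx"])
        if levels != {"CON", self.case}:
            raise ValidationError(
                f"design needs exactly CON and {self.case} samples, got {sorted(levels)}"
            )
        cols: list[np.ndarray] = [np.ones(len(df))]
        names = ["intercept"]
        cols.append((df["dx"] == self.case).to_numpy(float))
        names.append("dx")
        for c in self.covariates:
            if c == "age2":
                cols.append(df["age"].to_numpy(float) ** 2)
                names.append("age2")
            elif c == "rin2":
                cols.append(df["rin"].to_numpy(float) ** 2)
                names.append("rin2")
            elif c in ("sex", "ancestry"):
                col = df[c].astype(str)
                ref = col.value_counts().idxmax()  # reference = most frequent level
                for lv in sorted(set(col) - {ref}):
                    cols.append((col == lv).to_numpy(float))
                    names.append(f"{c}_{lv}")
            else:
                if c not in df.columns:
                    raise ValidationError(f"covariate {c!r} not in sample table")
                cols.append(df[c].to_numpy(float))
                names.append(c)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # name the offending columns for the error message
            bad = []
            for j in range(X.shape[1]):
                keep = [k for k in range(X.shape[1]) if k != j]
                if np.linalg.matrix_rank(X[:, keep]) == np.linalg.matrix_rank(X):
                    bad.append(names[j])
            raise ValidationError(f"rank-deficient design; collinear columns: {bad}")
        return X, names


@dataclasses.dataclass
class EBayesPrior:
    d0: float      # prior degrees of freedom, may be +inf
    s0_sq: float   # prior residual variance

    def __post_init__(self) -> None:
        if not (self.d0 > 0 and self.s0_sq > 0):
            raise ValidationError("EBayes prior requires d0 > 0 and s0_sq > 0")


# ---------------------------------------------------------------------------
# BH adjustment


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; NaN entries are ignored and propagate."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = ps.size
    if m == 0:
        return out
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[ok] = adj
    return out


# ---------------------------------------------------------------------------
# size factors


def median_ratio_size_factors(counts: ExpressionMatrix) -> np.ndarray:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    s_j = median over all-positive features g of K_gj / geomean_g(K_g.).
    """
    if counts.modality not in COUNT_MODALITIES:
        raise ValidationError("size factors require a count modality")
    K = counts.values
    allpos = (K > 0).all(axis=1)
    if not allpos.any():
        raise ValidationError(
            "no feature is positive in every sample; median-ratio size factors "
            "need a pseudo-reference — filter or supply factors externally"
        )
    ref = np.exp(np.log(K[allpos]).mean(axis=1))
    ratios = K[allpos] / ref[:, None]
    s = np.median(ratios, axis=0)
    return s / np.exp(np.log(s).mean())


# ---------------------------------------------------------------------------
# empirical-Bayes moderated linear model


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_fdist(s2: np.ndarray, df: np.ndarray) -> EBayesPrior:
    """Moment-match log residual variances against a scaled F distribution.

    Returns the prior (d0, s0^2); d0 = +inf when the observed spread of
    log-variances is no wider than sampling noise alone explains.
    """
    ok = np.isfinite(s2) & (df > 0)
    s2 = np.clip(s2[ok], 1e-300, None)
    df = df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    if n < 2:
        return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(emean)))
    evar = np.sum((e - emean) ** 2) / (n - 1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0, s0_sq = np.inf, np.exp(emean)
    return EBayesPrior(d0=float(d0), s0_sq=float(s0_sq))


def fit_moderated_linear_model(
    m: ExpressionMatrix,
    s: SampleTable,
    d: DesignSpec,
    d0_override: float | None = None,
) -> tuple[pd.DataFrame, EBayesPrior]:
    """Per-protein OLS with empirical-Bayes variance moderation.

    Features are fit on complete cases; features with fewer complete cases
    than rank(X)+1 are flagged untested (NaN statistics).  Coefficients are
    estimated on the stored log10-intensity scale and reported as log2 fold
    changes (x log2(10)).  ``d0_override`` pins the prior df (0 recovers the
    ordinary OLS t; +inf the s0-based z).
    """
    X, names = d.build(s)
    n, p = X.shape
    Y = m.values
    G = Y.shape[0]
    j_dx = names.index("dx")

    beta = np.full(G, np.nan)
    se_unsc = np.full(G, np.nan)  # sqrt(v_gj): unscaled SE of the dx coefficient
    s2 = np.full(G, np.nan)
    dfree = np.zeros(G)
    has_nan = np.isnan(Y).any()

    if not has_nan:
        XtX = X.T @ X
        XtXi = np.linalg.inv(XtX)
        B = XtXi @ X.T @ Y.T  # p x G
        resid = Y.T - X @ B
        dfg = n - p
        s2[:] = (resid**2).sum(axis=0) / dfg
        dfree[:] = dfg
        beta[:] = B[j_dx]
        se_unsc[:] = np.sqrt(XtXi[j_dx, j_dx])
    else:
        for g in range(G):
            ok = ~np.isnan(Y[g])
            ng = int(ok.sum())
            if ng < p + 1:
                continue
            Xg = X[ok]
            if np.linalg.matrix_rank(Xg) < p:
                continue
            XtXi = np.linalg.inv(Xg.T @ Xg)
            b = XtXi @ Xg.T @ Y[g, ok]
            r = Y[g, ok] - Xg @ b
            dfree[g] = ng - p
            s2[g] = (r @ r) / dfree[g]
            beta[g] = b[j_dx]
            se_unsc[g] = np.sqrt(XtXi[j_dx, j_dx])

    tested = np.isfinite(beta) & (dfree > 0)
    prior = fit_fdist(s2[tested], dfree[tested])
    if d0_override is not None:
        # d0=0 is a legal limiting case (ordinary t); bypass the d0>0 check
        prior = EBayesPrior.__new__(EBayesPrior)
        prior.d0 = float(d0_override)
        prior.s0_sq = float(fit_fdist(s2[tested], dfree[tested]).s0_sq)

    d0, s0_sq = prior.d0, prior.s0_sq
    if d0 == 0.0:
        s2_post = s2.copy()
        df_total = dfree.astype(float)
    elif np.isinf(d0):
        s2_post = np.full(G, s0_sq)
        df_total = np.full(G, np.inf)
    else:
        with np.errstate(invalid="ignore"):
            s2_post = (d0 * s0_sq + dfree * s2) / (d0 + dfree)
        df_total = d0 + dfree
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / (np.sqrt(s2_post) * se_unsc)
        pval = np.where(
            np.isinf(df_total),
            2.0 * stats.norm.sf(np.abs(tstat)),
            2.0 * stats.t.sf(np.abs(tstat), np.where(df_total > 0, df_total, 1.0)),
        )
    pval = np.where(tested, pval, np.nan)
    tstat = np.where(tested, tstat, np.nan)

    table = pd.DataFrame(
        {
            "feature_id": m.feature_ids,
            "log2fc": beta * LOG2_PER_LOG10,
            "se": np.sqrt(s2_post) * se_unsc * LOG2_PER_LOG10,
            "statistic": tstat,
            "p": pval,
            "fdr": bh_adjust(pval),
            "df_total": np.where(tested, df_total, np.nan),
            "mean_expression": np.nanmean(Y, axis=1),
            "tested": tested,
        }
    )
    return table, prior


# ---------------------------------------------------------------------------
# negative-binomial Wald test


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-feature NB2 log-likelihood; alpha is (G,), Y and mu are (G, n)."""
    a = alpha[:, None]
    inv = 1.0 / a
    return (
        special.gammaln(Y + inv) - special.gammaln(inv) - special.gammaln(Y + 1.0)
        + Y * np.log(a * mu / (1.0 + a * mu)) - inv * np.log1p(a * mu)
    ).sum(axis=1)


def _irls_nb(
    Y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
    max_iter: int = 100, tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for NB GLMs with log link.

    Returns (beta (G,p), cov (G,p,p), converged (G,)).
    """
    G, n = Y.shape
    p = X.shape[1]
    # initialize from log normalized mean
    beta = np.zeros((G, p))
    beta[:, 0] = np.log(np.clip((Y / np.exp(offset)[None, :]).mean(axis=1), 1e-8, None))
    converged = np.zeros(G, bool)
    active = np.ones(G, bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        eta = beta[idx] @ X.T + offset[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[idx, None] * mu)  # IRLS weights, canonical-ish
        zresp = eta - offset[None, :] + (Y[idx] - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, w, X)
        XtWz = np.einsum("ni,gn,gn->gi", X, w, zresp)
        XtWX += 1e-10 * np.eye(p)[None, :, :]
        new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        delta = np.abs(new - beta[idx]).max(axis=1)
        beta[idx] = new
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    # covariance at the final fit
    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, w, X) + 1e-10 * np.eye(X.shape[1])[None, :, :]
    cov = np.linalg.inv(XtWX)
    return beta, cov, converged


def _refine_dispersion(
    Y: np.ndarray, mu: np.ndarray, alpha0: np.ndarray, iters: int = 40
) -> np.ndarray:
    """Golden-section ML refinement of per-feature dispersion on log scale."""
    lo = np.full(alpha0.shape, np.log(1e-8))
    hi = np.full(alpha0.shape, np.log(50.0))
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - phi * (b - a)
    d = a + phi * (b - a)
    fc = _nb_loglik(Y, mu, np.exp(c))
    fd = _nb_loglik(Y, mu, np.exp(d))
    for _ in range(iters):
        take_c = fc > fd  # keep the higher-likelihood side
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
        c = b - phi * (b - a)
        d = a + phi * (b - a)
        fc = _nb_loglik(Y, mu, np.exp(c))
        fd = _nb_loglik(Y, mu, np.exp(d))
    return np.exp((a + b) / 2.0)


def nb_wald_test(
    counts: ExpressionMatrix,
    s: SampleTable,
    d: DesignSpec,
    size_factors: np.ndarray | None = None,
    refine_ml: bool = True,
    dispersion: np.ndarray | float | None = None,
) -> pd.DataFrame:
    """Per-feature negative-binomial Wald test of the dx coefficient.

    Dispersion: method-of-moments on normalized counts, optionally refined by
    one-dimensional ML at the fitted means; then one IRLS refit.  Passing
    ``dispersion`` pins it instead (scalar or per-feature; e.g. ~0 for the
    Poisson limit).  Features whose IRLS fails to converge are flagged with
    missing p.
    """
    if counts.modality not in COUNT_MODALITIES:
        raise ValidationError("nb_wald_test requires a count modality")
    X, names = d.build(s)
    j_dx = names.index("dx")
    Y = counts.values
    G, n = Y.shape
    if size_factors is None:
        size_factors = median_ratio_size_factors(counts)
    offset = np.log(size_factors)

    norm = Y / size_factors[None, :]
    mbar = norm.mean(axis=1)
    if dispersion is not None:
        alpha = np.clip(np.broadcast_to(np.asarray(dispersion, float), (G,)).copy(),
                        1e-8, 50.0)
        refine_ml = False
    else:
        s2 = norm.var(axis=1, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha = (s2 * n / (n - 1) - mbar) / mbar**2
        alpha = np.where(np.isfinite(alpha), alpha, 1e-8)
        alpha = np.clip(alpha, 1e-8, 50.0)

    beta, cov, convg = _irls_nb(Y, X, offset, alpha)
    if refine_ml:
        mu = np.exp(np.clip(beta @ X.T + offset[None, :], -30.0, 30.0))
        alpha = _refine_dispersion(Y, mu, alpha)
        beta, cov, convg = _irls_nb(Y, X, offset, alpha)

    se = np.sqrt(cov[:, j_dx, j_dx])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta[:, j_dx] / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.where(convg, pval, np.nan)
    return pd.DataFrame(
        {
            "feature_id": counts.feature_ids,
            "log2fc": beta[:, j_dx] / np.log(2.0),
            "se": se / np.log(2.0),
            "statistic": np.where(convg, z, np.nan),
            "p": pval,
            "fdr": bh_adjust(pval),
            "df_total": np.full(G, np.inf),
            "mean_expression": mbar,
            "tested": convg,
            "dispersion": alpha,
        }
    )


# ---------------------------------------------------------------------------
# rank-rank hypergeometric overlap


@dataclasses.dataclass
class RRHOMap:
    """Signed -log10 hypergeometric overlap grid between two ranked lists."""

    grid: np.ndarray                      # (len(steps_a), len(steps_b))
    steps_a: np.ndarray
    steps_b: np.ndarray
    step: int
    score_a: pd.Series
    score_b: pd.Series
    quadrants: dict[str, tuple[slice, slice]]  # uu, dd, ud, du index blocks


def signed_rank_score(de: pd.DataFrame) -> pd.Series:
    """-log10(p) * sign(log2fc), the ranking score for RRHO."""
    p = np.clip(de["p"].to_numpy(float), 1e-300, 1.0)
    score = -np.log10(p) * np.sign(de["log2fc"].to_numpy(float))
    return pd.Series(score, index=de["feature_id"].to_numpy())


def rrho_map(a: pd.DataFrame, b: pd.DataFrame, step: int | None = None,
             cap: float = 50.0) -> RRHOMap:
    """Rank-rank hypergeometric overlap between two DE tables.

    Both lists are ranked by signed score (-log10 p, signed by fold-change
    direction), descending.  At each grid point (i, j) the map holds the
    -log10 upper-tail hypergeometric probability of the observed overlap
    between the top-i of list a and top-j of list b, signed positive in the
    concordant quadrants (uu, dd) and negative in the discordant ones.
    """
    sa = signed_rank_score(a)
    sb = signed_rank_score(b)
    common = sa.index.intersection(sb.index)
    common = common[~(sa[common].isna() | sb[common].isna())]
    N = len(common)
    if N < 10:
        raise ValidationError("need at least 10 shared features for RRHO")
    sa = sa[common].sort_values(ascending=False, kind="mergesort")
    # ranks of each feature in b's ordering
    sb_sorted = sb[common].sort_values(ascending=False, kind="mergesort")
    pos_in_b = pd.Series(np.arange(N), index=sb_sorted.index)
    b_rank_of_a = pos_in_b[sa.index].to_numpy()

    if step is None:
        step = max(1, int(np.floor(np.sqrt(N))))
    steps = np.arange(step, N + 1, step)
    # overlap counts via a cumulative membership trick:
    # member[i, j] = 1 if a-rank i item lies in b's top j
    grid = np.empty((len(steps), len(steps)))
    # indicator matrix is N x len(steps); N is a few thousand at most here
    ind = (b_rank_of_a[:, None] < steps[None, :]).astype(np.int64)
    cum = np.cumsum(ind, axis=0)
    ks = cum[steps - 1, :]  # overlap of top-i (rows) with top-j (cols)
    M = N
    for ii, i in enumerate(steps):
        grid[ii, :] = stats.hypergeom.sf(ks[ii, :] - 1, M, i, steps)
    logp = -np.log10(np.clip(grid, 10**-cap, 1.0))

    # quadrant blocks from each list's sign-change split
    na_up = int((sa > 0).sum())
    nb_up = int((sb_sorted > 0).sum())
    ia = int(np.searchsorted(steps, na_up, side="right"))
    ib = int(np.searchsorted(steps, nb_up, side="right"))
    quadrants = {
        "uu": (slice(0, ia), slice(0, ib)),
        "ud": (slice(0, ia), slice(ib, len(steps))),
        "du": (slice(ia, len(steps)), slice(0, ib)),
        "dd": (slice(ia, len(steps)), slice(ib, len(steps))),
    }
    signed = logp.copy()
    signed[quadrants["ud"]] *= -1.0
    signed[quadrants["du"]] *= -1.0
    return RRHOMap(signed, steps, steps.copy(), step, sa, sb_sorted, quadrants)


# ---------------------------------------------------------------------------
# RNA-protein concordance


def rna_protein_concordance(
    de_rna: pd.DataFrame,
    de_protein: pd.DataFrame,
    id_map: dict[str, str],
    p_thresh: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Pair log2 fold changes of features nominally significant at both levels.

    ``id_map`` maps gene id -> protein id.  Summary holds the fraction of
    sign-concordant pairs, OLS slope (protein ~ rna) and Pearson r; flagged
    undefined when no pairs survive.
    """
    rna = de_rna.set_index("feature_id")
    prot = de_protein.set_index("feature_id")
    rows = []
    for g, p in id_map.items():
        if g in rna.index and p in prot.index:
            rg, pg = rna.loc[g], prot.loc[p]
            if rg["p"] < p_thresh and pg["p"] < p_thresh:
                rows.append(
                    dict(gene_id=g, protein_id=p,
                         rna_log2fc=float(rg["log2fc"]), protein_log2fc=float(pg["log2fc"]),
                         rna_p=float(rg["p"]), protein_p=float(pg["p"]))
                )
    table = pd.DataFrame(rows, columns=["gene_id", "protein_id", "rna_log2fc",
                                        "protein_log2fc", "rna_p", "protein_p"])
    if len(table) == 0:
        return table, {"n_pairs": 0, "concordance": np.nan, "slope": np.nan,
                       "r": np.nan, "defined": False}
    x = table["rna_log2fc"].to_numpy()
    y = table["protein_log2fc"].to_numpy()
    conc = float(np.mean(np.sign(x) == np.sign(y)))
    if len(table) >= 3 and np.std(x) > 0 and np.std(y) > 0:
        slope = float(np.polyfit(x, y, 1)[0])
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        slope = r = np.nan
    return table, {"n_pairs": int(len(table)), "concordance": conc,
                   "slope": slope, "r": r, "defined": True}
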