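"""Sample and feature QC: annotation filters, count filters, mitochondrial
dominance, PCA covariate scan and per-feature variance partitioning."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import COUNT_MODALITIES, ExpressionMatrix, SampleTable, ValidationError


@dataclasses.dataclass
class ProteinAnnotation:
    frame: pd.DataFrame  # columns: feature_id, swissprot_flag, peptide_count

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("feature_id", "swissprot_flag", "peptide_count"):
            if col not in df.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        if df["feature_id"].duplicated().any():
            raise ValidationError("duplicate feature_id in annotation")
        if (df["peptide_count"] < 0).any():
            raise ValidationError("negative peptide_count")


@dataclasses.dataclass
class VarianceReport:
    """PCA / variance-partition diagnostics.

    ``fractions``: feature x (covariate..., residual) variance fractions.
    ``pc_variance``: explained-variance fraction per PC (nonincreasing).
    ``pc_assoc``: PC x covariate association p-values.
    """

    fractions: pd.DataFrame | None = None
    pc_variance: np.ndarray | None = None
    pc_assoc: pd.DataFrame | None = None
    pc_scores: pd.DataFrame | None = None


def filter_unannotated_proteins(m: ExpressionMatrix, ann: ProteinAnnotation) -> ExpressionMatrix:
    """Keep proteins registered in SwissProt with at least one supporting peptide."""
    df = ann.frame.set_index("feature_id")
    missing = [f for f in m.feature_ids if f not in df.index]
    if missing:
        raise ValidationError(f"{len(missing)} matrix features lack annotation rows")
    keep = [f for f in m.feature_ids
            if bool(df.at[f, "swissprot_flag"]) and df.at[f, "peptide_count"] >= 1]
    return m.subset_features(keep)


def filter_low_count_features(m: ExpressionMatrix, min_mean: float = 0.5) -> ExpressionMatrix:
    """Drop features whose mean raw count across all samples is < min_mean."""
    if m.modality not in COUNT_MODALITIES:
        raise ValidationError("count filter applies to count modalities only")
    means = m.values.mean(axis=1)
    keep = [f for f, mu in zip(m.feature_ids, means) if mu >= min_mean]
    return m.subset_features(keep)


def filter_mito_dominated_samples(
    m: ExpressionMatrix, mito_ids: set[str], max_frac: float = 0.5
) -> ExpressionMatrix:
    """Drop samples where mitochondrial features hold more than max_frac of counts."""
    if m.modality not in COUNT_MODALITIES:
        raise ValidationError("mito filter applies to count modalities only")
    unknown = set(mito_ids) - set(m.feature_ids)
    if unknown:
        raise ValidationError(f"mito ids absent from matrix: {sorted(unknown)[:5]}")
    if not mito_ids:
        return m
    mask = np.array([f in mito_ids for f in m.feature_ids])
    totals = m.values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, m.values[mask].sum(axis=0) / totals, 0.0)
    keep = [s for s, fr in zip(m.sample_ids, frac) if fr <= max_frac]  # strict > is dropped
    if not keep:
        raise ValidationError("mito filter removed every sample")
    return m.subset_samples(keep)


def _covariate_columns(s: SampleTable, covariates: list[str]) -> dict[str, tuple[np.ndarray, bool]]:
    """Map covariate name -> (design columns without intercept, is_categorical)."""
    out = {}
    df = s.frame
    for c in covariates:
        if c not in df.columns:
            raise ValidationError(f"covariate {c!r} not in sample table")
        col = df[c]
        if col.dtype.kind in "ifu" and c not in ("dx", "region", "sex", "ancestry"):
            out[c] = (col.to_numpy(float)[:, None], False)
        else:
            d = pd.get_dummies(col.astype(str), drop_first=True)
            out[c] = (d.to_numpy(float), True)
    return out


def pca_covariate_scan(
    m: ExpressionMatrix, s: SampleTable, n_pcs: int = 10,
    covariates: list[str] | None = None,
) -> VarianceReport:
    """PCA of the feature-standardized matrix plus per-PC covariate association.

    Missing protein entries are mean-imputed for the PCA only.  Association is
    one-way ANOVA for categorical covariates and a Pearson correlation test for
    continuous ones.
    """
    if m.n_samples < 3:
        raise ValidationError("need at least 3 samples for PCA")
    if covariates is None:
        covariates = [c for c in ("dx", "region", "sex", "ancestry", "age", "pmi", "rin")
                      if c in s.frame.columns]
    X = m.values.copy()
    mu = np.nanmean(X, axis=1, keepdims=True)
    X = np.where(np.isnan(X), mu, X)
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    X = (X[keep] - mu[keep]) / sd[keep][:, None]
    # samples x features for the SVD
    U, svals, _ = np.linalg.svd(X.T - X.T.mean(axis=0), full_matrices=False)
    k = min(n_pcs, len(svals))
    var = svals**2
    pc_variance = var[:k] / var.sum()
    scores = U[:, :k] * svals[:k]
    pc_names = [f"PC{i + 1}" for i in range(k)]
    pc_scores = pd.DataFrame(scores, index=m.sample_ids, columns=pc_names)

    assoc = pd.DataFrame(index=pc_names, columns=covariates, dtype=float)
    df = s.frame.set_index("sample_id").loc[m.sample_ids]
    for c in covariates:
        col = df[c]
        categorical = not (col.dtype.kind in "ifu" and c not in ("dx", "region", "sex", "ancestry"))
        for i, pc in enumerate(pc_names):
            y = scores[:, i]
            if categorical:
                groups = [y[(col == lv).to_numpy()] for lv in col.unique()]
                groups = [g for g in groups if len(g) >= 2]
                if len(groups) < 2:
                    p = np.nan
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        p = stats.f_oneway(*groups).pvalue
            else:
                x = col.to_numpy(float)
                p = stats.pearsonr(x, y).pvalue if np.std(x) > 0 else np.nan
            assoc.at[pc, c] = p
    return VarianceReport(pc_variance=pc_variance, pc_assoc=assoc, pc_scores=pc_scores)


def variance_fractions(
    m: ExpressionMatrix, s: SampleTable, covariates: list[str]
) -> VarianceReport:
    """Per-feature fraction of variance attributable to each covariate.

    Each covariate's share is its marginal single-covariate R^2; the residual
    is 1 - R^2 of the full additive model.  When sample correlation between
    covariates pushes the marginal shares above the full-model R^2 they are
    rescaled proportionally to sum to it, so shares plus residual always total
    at most 1.  Missing protein entries are handled per feature (complete
    cases).
    """
    cols = _covariate_columns(s, covariates)
    n = m.n_samples
    Y = m.values
    designs = {}
    for c, (Z, _) in cols.items():
        Zc = Z - Z.mean(axis=0)
        designs[c] = Zc
    Zfull = np.hstack([designs[c] for c in covariates])
    if np.linalg.matrix_rank(Zfull) < Zfull.shape[1]:
        warnings.warn("collinear covariates; marginal fractions reported as-is")

    def r2(Z: np.ndarray, y: np.ndarray) -> float:
        yc = y - y.mean()
        tss = yc @ yc
        if tss <= 0:
            return np.nan
        beta, *_ = np.linalg.lstsq(Z, yc, rcond=None)
        fit = Z @ beta
        return float(np.clip((fit @ fit) / tss, 0.0, 1.0))

    rows = []
    has_nan = np.isnan(Y).any()
    for i in range(m.n_features):
        y = Y[i]
        ok = ~np.isnan(y) if has_nan else np.ones(n, bool)
        if ok.sum() < Zfull.shape[1] + 2:
            rows.append({c: np.nan for c in covariates} | {"residual": np.nan})
            continue
        marg = {c: r2(designs[c][ok], y[ok]) for c in covariates}
        full = r2(Zfull[ok], y[ok])
        total = sum(v for v in marg.values() if np.isfinite(v))
        if total > full > 0:
            marg = {c: v * full / total for c, v in marg.items()}
        rows.append(marg | {"residual": 1.0 - full})
    frame = pd.DataFrame(rows, index=m.feature_ids)
    return VarianceReport(fractions=frame)
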