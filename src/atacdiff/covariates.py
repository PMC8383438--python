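"""Iterative PC-regression covariate selection.

The procedure mirrors how batch-aware count analyses pick adjustment
variables: regress every candidate metadata variable against the first
``n_pcs`` principal components of the normalized peak matrix; while any
candidate is Bonferroni-significant, select one (preferring technical
variables, then those explaining the most PC variance, then fewer
parameters), regress its effect out of the matrix, and recompute the PCA on
the residuals.  The loop stops when no candidate remains significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class CovariateCandidate:
    name: str
    kind: str  # "continuous" | "categorical"
    n_levels: int = 1
    is_technical: bool = False

    def __post_init__(self):
        if self.n_levels < 1 or (self.kind == "categorical" and self.n_levels < 2):
            raise ValueError(f"bad n_levels for candidate {self.name}")


@dataclass
class SelectionIteration:
    selected: str
    pvalues: pd.DataFrame  # candidates x PCs
    variance_share: pd.Series
    threshold: float


@dataclass
class SelectionTrace:
    iterations: list = field(default_factory=list)
    final_selected: list = field(default_factory=list)
    stop_reason: str = ""


def make_candidates(
    metadata: pd.DataFrame, technical: set[str] | None = None, exclude: set[str] | None = None
) -> list[CovariateCandidate]:
    """Infer candidate kinds from dtypes; object/category columns are factors."""
    technical = technical or set()
    exclude = exclude or set()
    out = []
    for col in metadata.columns:
        if col in exclude:
            continue
        ser = metadata[col]
        if ser.dtype == object or isinstance(ser.dtype, pd.CategoricalDtype) or ser.dtype == bool:
            levels = ser.astype(str).nunique()
            if levels < 2:
                continue
            out.append(CovariateCandidate(col, "categorical", levels, col in technical))
        else:
            out.append(CovariateCandidate(col, "continuous", 1, col in technical))
    return out


def _pca_scores(matrix: np.ndarray, n_pcs: int):
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    total = np.sum(s**2)
    n_pcs = min(n_pcs, len(s))
    scores = u[:, :n_pcs] * s[:n_pcs]
    share = s[:n_pcs] ** 2 / total if total > 0 else np.zeros(n_pcs)
    return scores, share


def pc_association(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    candidates: list[CovariateCandidate],
    n_pcs: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-(candidate, PC) association p-values plus PC variance shares.

    ``matrix`` is samples x peaks (log-CPM or residuals).  Continuous
    candidates use the univariate linear-regression t-test; categorical
    candidates use a one-way ANOVA F-test.  A constant candidate yields p = 1
    with a warning.
    """
    arr = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    n = arr.shape[0]
    if n <= n_pcs:
        n_pcs = n - 1
    scores, share = _pca_scores(arr, n_pcs)
    n_pcs = scores.shape[1]
    cols = [f"PC{i+1}" for i in range(n_pcs)]
    pvals = pd.DataFrame(1.0, index=[c.name for c in candidates], columns=cols)
    for cand in candidates:
        x = metadata[cand.name]
        if cand.kind == "continuous":
            xv = x.to_numpy(dtype=float)
            if np.all(xv == xv[0]):
                warnings.warn(f"candidate {cand.name} is constant; p set to 1", stacklevel=2)
                continue
            for j in range(n_pcs):
                res = stats.linregress(xv, scores[:, j])
                pvals.loc[cand.name, cols[j]] = res.pvalue
        else:
            groups_idx = x.astype(str).to_numpy()
            levels = np.unique(groups_idx)
            if len(levels) < 2:
                warnings.warn(f"candidate {cand.name} is constant; p set to 1", stacklevel=2)
                continue
            for j in range(n_pcs):
                groups = [scores[groups_idx == lv, j] for lv in levels]
                with np.errstate(invalid="ignore"):
                    _, p = stats.f_oneway(*groups)
                pvals.loc[cand.name, cols[j]] = 1.0 if np.isnan(p) else p
    return pvals, pd.Series(share, index=cols, name="variance_share")


def select_next(
    pvals: pd.DataFrame,
    variance_share: pd.Series,
    candidates: list[CovariateCandidate],
    alpha: float = 0.05,
) -> str | None:
    """Pick the next covariate among Bonferroni-significant candidates.

    Significance: min over PCs of p < alpha / (n_candidates x n_pcs).
    Ranking among significant candidates: technical first, then the largest
    variance-weighted evidence score sum_PC[-log10(p) x varshare], then fewer
    parameters, then name.
    """
    if not candidates:
        return None
    threshold = alpha / (len(candidates) * pvals.shape[1])
    ranked = []
    for cand in candidates:
        p_row = pvals.loc[cand.name]
        if p_row.min() >= threshold:
            continue
        with np.errstate(divide="ignore"):
            score = float(
                np.sum(-np.log10(np.clip(p_row.to_numpy(), 1e-300, None))
                       * variance_share.to_numpy())
            )
        ranked.append((0 if cand.is_technical else 1, -score, cand.n_levels, cand.name))
    if not ranked:
        return None
    ranked.sort()
    return ranked[0][3]


def _encode(values: pd.Series) -> np.ndarray:
    """Centered design columns for one covariate (indicator coding, no intercept)."""
    if values.dtype == object or isinstance(values.dtype, pd.CategoricalDtype) or values.dtype == bool:
        dummies = pd.get_dummies(values.astype(str), drop_first=True).to_numpy(dtype=float)
        if dummies.shape[1] == 0:
            return np.zeros((len(values), 0))
        X = dummies
    else:
        X = values.to_numpy(dtype=float)[:, None]
    return X - X.mean(axis=0, keepdims=True)


def regress_out(matrix: pd.DataFrame, values: pd.Series) -> pd.DataFrame:
    """Project one covariate out of every peak column, keeping the mean.

    Categorical variables are indicator-coded; a level with a single sample
    gets exactly-zero residuals there by construction (warned).
    """
    arr = matrix.to_numpy(dtype=float)
    Xc = _encode(values.loc[matrix.index] if isinstance(values, pd.Series) else pd.Series(values))
    if Xc.shape[1] == 0 or not np.any(Xc):
        return matrix.copy()
    if (values.dtype == object or values.dtype == bool) and (
        values.astype(str).value_counts() == 1
    ).any():
        warnings.warn("categorical level with a single sample; its residuals are 0",
                      stacklevel=2)
    beta, *_ = np.linalg.lstsq(Xc, arr, rcond=None)
    resid = arr - Xc @ beta
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def impute_missing(
    metadata: pd.DataFrame, method: str = "median"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median (continuous) / mode (categorical) imputation with cell flags."""
    if method != "median":
        raise ValueError(f"unknown imputation method {method!r}")
    out = metadata.copy()
    flags = metadata.isna()
    for col in metadata.columns:
        ser = metadata[col]
        if not ser.isna().any():
            continue
        if ser.isna().all():
            raise ValueError(f"variable {col!r} is entirely missing")
        if ser.isna().mean() >= 0.5:
            warnings.warn(f"variable {col!r} is >=50% missing", stacklevel=2)
        if ser.dtype == object or isinstance(ser.dtype, pd.CategoricalDtype):
            fill = ser.mode().sort_values().iloc[0]
        else:
            fill = ser.median()
        out[col] = ser.fillna(fill)
    return out, flags


def run_selection(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    candidates: list[CovariateCandidate],
    n_pcs: int = 10,
    alpha: float = 0.05,
    max_iter: int | None = None,
) -> SelectionTrace:
    """Full iterative loop: associate -> select -> regress out -> re-PCA."""
    trace = SelectionTrace()
    remaining = list(candidates)
    current = matrix.copy()
    max_iter = len(candidates) if max_iter is None else max_iter
    while remaining and len(trace.final_selected) < max_iter:
        pvals, share = pc_association(current, metadata, remaining, n_pcs=n_pcs)
        chosen = select_next(pvals, share, remaining, alpha=alpha)
        if chosen is None:
            trace.stop_reason = "no Bonferroni-significant candidate"
            return trace
        threshold = alpha / (len(remaining) * pvals.shape[1])
        trace.iterations.append(SelectionIteration(chosen, pvals, share, threshold))
        trace.final_selected.append(chosen)
        current = regress_out(current, metadata[chosen])
        remaining = [c for c in remaining if c.name != chosen]
    trace.stop_reason = "max_iter" if remaining else "candidates exhausted"
    return trace


class PCCovariateSelector(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping the iterative selection loop.

    ``fit(X, covariates=metadata, technical={...})`` runs the loop on X
    (n_samples x n_peaks) and stores ``selected_`` and ``trace_``;
    ``transform`` residualizes the selected covariates out of X in selection
    order.
    """

    def __init__(self, n_pcs: int = 10, alpha: float = 0.05, max_iter: int | None = None):
        self.n_pcs = n_pcs
        self.alpha = alpha
        self.max_iter = max_iter

    def fit(self, X, y=None, covariates: pd.DataFrame = None, technical: set | None = None):
        if covariates is None:
            raise ValueError("fit requires covariates= (per-sample metadata table)")
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        covariates = covariates.loc[Xdf.index] if isinstance(X, pd.DataFrame) else covariates
        cands = make_candidates(covariates, technical=technical)
        self.trace_ = run_selection(
            Xdf, covariates, cands, n_pcs=self.n_pcs, alpha=self.alpha, max_iter=self.max_iter
        )
        self.selected_ = list(self.trace_.final_selected)
        self._metadata = covariates
        return self

    def transform(self, X):
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        out = Xdf.copy()
        for name in self.selected_:
            out = regress_out(out, self._metadata[name])
        return out if isinstance(X, pd.DataFrame) else out.to_numpy()
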