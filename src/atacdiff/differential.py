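"""Negative-binomial quasi-likelihood differential accessibility testing.

The model for peak *i* in sample *j* is ``y_ij ~ NB(mu_ij, phi_i)`` with
``log mu_ij = offset_j + x_j' beta_i`` where the offset is the log effective
(TMM-normalized) library size.  Dispersions are estimated by maximizing the
Cox-Reid adjusted profile likelihood (APL) on a log-scale grid: a common
value, an abundance-dependent trend, and per-peak (tagwise) values obtained
by weighting each peak's own APL with the APL of its abundance neighbours
(empirical-Bayes shrinkage controlled by a prior df).  Testing uses
quasi-likelihood F-tests: per-peak quasi-dispersions (residual deviance /
residual df) are moderated across peaks by an F-distribution fit
(squeezeVar-style) and the deviance drop between nested designs is compared
against the moderated quasi-dispersion on an F distribution.

This is a compatible re-implementation of the standard NB-QLF scheme for
count matrices; numerical parity with any particular external package is not
claimed — calibration is established by simulation in the test-suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .intervals import drop_sex_chromosomes, intervals_from_ids
from .normalize import cpm_log, tmm_factors

LN2 = float(np.log(2.0))

# ---------------------------------------------------------------------------
# batched NB GLM


@dataclass
class GLMFit:
    beta: np.ndarray  # (G, p)
    mu: np.ndarray  # (G, n)
    deviance: np.ndarray  # (G,)
    converged: np.ndarray  # (G,) bool
    df_residual: int


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Residual deviance per peak; Poisson limit used for phi ~ 0."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-300)
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[:, None], y.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(y / mu), 0.0)
        pois = 2.0 * (ylogy - (y - mu))
        r = 1.0 / np.maximum(phi, 1e-300)
        nb = 2.0 * (ylogy - (y + r) * np.log((y + r) / (mu + r)))
    unit = np.where(phi < 1e-8, pois, nb)
    return np.maximum(unit.sum(axis=1), 0.0)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood (Poisson limit for phi ~ 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-300)
    phi_col = np.asarray(phi, dtype=float)[:, None]
    small = phi_col[:, 0] < 1e-8
    out = np.empty(y.shape[0])
    if np.any(~small):
        r = 1.0 / phi_col[~small]
        ys, ms = y[~small], mu[~small]
        out[~small] = np.sum(
            special.gammaln(ys + r)
            - special.gammaln(r)
            - special.gammaln(ys + 1.0)
            + r * np.log(r / (r + ms))
            + ys * np.log(ms / (r + ms)),
            axis=1,
        )
    if np.any(small):
        ys, ms = y[small], mu[small]
        out[small] = np.sum(ys * np.log(ms) - ms - special.gammaln(ys + 1.0), axis=1)
    return out


def fit_nb_glm_batched(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> GLMFit:
    """Fisher-scoring / IRLS fit of the NB log-link GLM for every row of Y.

    Y: (G, n) counts; X: (n, p) full-rank design; offset: (n,) log effective
    library sizes; phi: scalar or (G,) dispersions.  Convergence is a
    relative deviance change below ``tol`` (or ``max_iter`` sweeps, after
    which unconverged rows are flagged, never raised).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (Y.shape[1],))
    G, n = Y.shape
    p = X.shape[1]
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (G,)).copy()

    # initialize from a log-linear least-squares fit
    z0 = np.log(Y + 0.5) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, p)

    eta = np.clip(beta @ X.T + offset[None, :], -30.0, 30.0)
    mu = np.exp(eta)
    dev = nb_deviance(Y, mu, phi)
    active = np.ones(G, dtype=bool)
    converged = np.zeros(G, dtype=bool)
    ridge = 1e-10 * np.eye(p)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        mu_a = mu[idx]
        W = mu_a / (1.0 + phi[idx, None] * mu_a)  # Fisher weights
        resp = (eta[idx] - offset[None, :]) + (Y[idx] - mu_a) / np.maximum(mu_a, 1e-10)
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X) + ridge[None, :, :]
        XtWz = np.einsum("ni,gn->gi", X, W * resp)
        try:
            new_beta = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new_beta = np.stack(
                [np.linalg.lstsq(XtWX[g], XtWz[g], rcond=None)[0] for g in range(len(idx))]
            )
        # step-halving on deviance increase
        step = np.ones(len(idx))
        old_dev = dev[idx]
        for _half in range(6):
            cand = beta[idx] + step[:, None] * (new_beta - beta[idx])
            eta_c = np.clip(cand @ X.T + offset[None, :], -30.0, 30.0)
            mu_c = np.exp(eta_c)
            dev_c = nb_deviance(Y[idx], mu_c, phi[idx])
            worse = dev_c > old_dev * (1 + 1e-10) + 1e-10
            if not worse.any():
                break
            step[worse] *= 0.5
        beta[idx] = cand
        eta[idx] = eta_c
        mu[idx] = mu_c
        rel = np.abs(dev_c - old_dev) / (np.abs(old_dev) + 1.0)
        dev[idx] = dev_c
        done = rel < tol
        converged[idx[done]] = True
        active[idx[done]] = False

    return GLMFit(beta=beta, mu=mu, deviance=dev, converged=converged,
                  df_residual=n - p)


def fit_nb_glm(counts_row, design, offsets, phi) -> tuple[np.ndarray, float, np.ndarray]:
    """Single-peak convenience wrapper: returns (coefficients, deviance, fitted)."""
    fit = fit_nb_glm_batched(
        np.asarray(counts_row, dtype=float)[None, :], np.asarray(design), offsets,
        np.asarray([phi], dtype=float),
    )
    return fit.beta[0], float(fit.deviance[0]), fit.mu[0]


# ---------------------------------------------------------------------------
# dispersion estimation


def _cox_reid(X: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """0.5 * logdet(X' W X) per row (Cox-Reid adjustment)."""
    W = mu / (1.0 + np.asarray(phi)[:, None] * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, W, X) + 1e-10 * np.eye(X.shape[1])[None]
    sign, logdet = np.linalg.slogdet(XtWX)
    return 0.5 * logdet


def _apl_grid(Y, X, offset, phi_grid) -> np.ndarray:
    """Adjusted profile log-likelihood at every grid dispersion; (G, K)."""
    G = Y.shape[0]
    apl = np.empty((G, len(phi_grid)))
    for k, phi in enumerate(phi_grid):
        fit = fit_nb_glm_batched(Y, X, offset, np.full(G, phi))
        apl[:, k] = nb_loglik(Y, fit.mu, np.full(G, phi)) - _cox_reid(X, fit.mu, np.full(G, phi))
    return apl


def _argmax_refined(scores: np.ndarray, log_grid: np.ndarray) -> np.ndarray:
    """Per-row grid argmax with parabolic interpolation in log-dispersion."""
    scores = np.atleast_2d(scores)
    i = np.argmax(scores, axis=1)
    out = log_grid[i].astype(float)
    interior = (i > 0) & (i < len(log_grid) - 1)
    idx = np.flatnonzero(interior)
    if idx.size:
        im, i0, ip = i[idx] - 1, i[idx], i[idx] + 1
        ym = scores[idx, im]
        y0 = scores[idx, i0]
        yp = scores[idx, ip]
        denom = ym - 2 * y0 + yp
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (ym - yp) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        h = log_grid[1] - log_grid[0]
        out[idx] = log_grid[i0] + shift * h
    return out


@dataclass
class DispersionEstimates:
    common: float
    trended: np.ndarray  # (G,)
    tagwise: np.ndarray  # (G,)
    abundance: np.ndarray  # mean log2 CPM per peak
    excluded_all_zero: list = field(default_factory=list)


def estimate_dispersions(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    prior_df: float = 10.0,
    grid_range: tuple = (1e-4, 10.0),
    grid_length: int = 19,
    n_bins: int = 20,
    peak_ids=None,
) -> DispersionEstimates:
    """Common / trended / tagwise NB dispersions via gridded Cox-Reid APL.

    All-zero rows are excluded before estimation (recorded in the result and
    warned); they receive the common dispersion.  Tagwise estimates maximize
    ``APL_g + (prior_df / df_residual) * APL_neighbourhood`` so
    ``prior_df = inf`` returns exactly the trend.  All outputs are >= 1e-6.
    """
    Y = np.asarray(Y, dtype=float)
    G, n = Y.shape
    df_res = n - X.shape[1]
    if df_res < 1:
        raise ValueError("residual df < 1: design leaves no degrees of freedom")
    nonzero = Y.sum(axis=1) > 0
    excluded = (
        [peak_ids[g] for g in np.flatnonzero(~nonzero)]
        if peak_ids is not None
        else np.flatnonzero(~nonzero).tolist()
    )
    if excluded:
        warnings.warn(f"excluding {len(excluded)} all-zero peaks from dispersion estimation",
                      stacklevel=2)
    Yw = Y[nonzero]
    Gw = Yw.shape[0]

    log_grid = np.linspace(np.log(grid_range[0]), np.log(grid_range[1]), grid_length)
    phi_grid = np.exp(log_grid)
    apl = _apl_grid(Yw, X, offset, phi_grid)

    common = float(np.exp(_argmax_refined(apl.sum(axis=0)[None, :], log_grid))[0])

    lib = np.exp(np.broadcast_to(np.asarray(offset, dtype=float), (n,)))
    abundance_w = np.log2(np.maximum((Yw / lib[None, :]).mean(axis=1) * 1e6, 1e-10))

    n_bins_eff = int(np.clip(Gw // 50, 1, n_bins))
    order = np.argsort(abundance_w, kind="mergesort")
    bin_of = np.empty(Gw, dtype=int)
    bin_of[order] = np.minimum((np.arange(Gw) * n_bins_eff) // Gw, n_bins_eff - 1)
    local = np.empty_like(apl)
    for b in range(n_bins_eff):
        members = bin_of == b
        local[members] = apl[members].mean(axis=0)[None, :]

    trended_w = np.exp(_argmax_refined(local, log_grid))

    if np.isinf(prior_df):
        tag_w = trended_w.copy()
    else:
        weight = prior_df / df_res
        tag_w = np.exp(_argmax_refined(apl + weight * local, log_grid))

    trended = np.full(G, common)
    tagwise = np.full(G, common)
    abundance = np.full(G, np.nan)
    trended[nonzero] = trended_w
    tagwise[nonzero] = tag_w
    abundance[nonzero] = abundance_w
    return DispersionEstimates(
        common=max(common, 1e-6),
        trended=np.maximum(trended, 1e-6),
        tagwise=np.maximum(tagwise, 1e-6),
        abundance=abundance,
        excluded_all_zero=excluded,
    )


# ---------------------------------------------------------------------------
# quasi-likelihood F-test


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Moderate sample variances toward a common prior (F-distribution fit).

    Returns (prior df, prior variance, posterior variances).  Rows with
    non-positive s2 are excluded from the moment fit but still squeezed.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0, np.full_like(s2, np.nan)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        var_prior = float(
            np.exp(emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0))
        )
    else:
        df_prior = np.inf
        var_prior = float(np.exp(emean))
    if np.isinf(df_prior):
        var_post = np.full_like(s2, var_prior)
    else:
        var_post = (df_prior * var_prior + df * s2) / (df_prior + df)
    return df_prior, var_prior, var_post


def ql_f_test(
    Y: np.ndarray,
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    offset: np.ndarray,
    dispersion: np.ndarray,
) -> pd.DataFrame:
    """Quasi-likelihood F-test of nested NB GLM designs, per row of Y.

    Quasi-dispersions (residual deviance / residual df under the full model)
    are squeezed toward their common trend; F = (deviance drop / delta df) /
    moderated quasi-dispersion, referred to F(delta df, prior df + residual
    df).  Non-converged rows get p = 1 and are flagged.
    """
    X_full = np.asarray(X_full, dtype=float)
    X_reduced = np.asarray(X_reduced, dtype=float)
    df_diff = X_full.shape[1] - X_reduced.shape[1]
    if df_diff <= 0:
        raise ValueError("contrast is empty: reduced design is not smaller than full")
    fit_full = fit_nb_glm_batched(Y, X_full, offset, dispersion)
    fit_red = fit_nb_glm_batched(Y, X_reduced, offset, dispersion)
    df_res = fit_full.df_residual
    if df_res < 1:
        raise ValueError("no residual degrees of freedom under the full design")
    s2 = fit_full.deviance / df_res
    df_prior, var_prior, s2_post = squeeze_var(s2, df_res)
    delta = np.maximum(fit_red.deviance - fit_full.deviance, 0.0)
    F = (delta / df_diff) / np.maximum(s2_post, 1e-12)
    df2 = min(df_prior + df_res, 1e8)
    p = stats.f.sf(F, df_diff, df2)
    bad = ~(fit_full.converged & fit_red.converged)
    p = np.where(bad, 1.0, np.clip(p, np.nextafter(0, 1), 1.0))
    return pd.DataFrame(
        {
            "F": F,
            "p": p,
            "deviance_full": fit_full.deviance,
            "deviance_reduced": fit_red.deviance,
            "quasi_dispersion": s2_post,
            "converged": ~bad,
        }
    ).assign(df_prior=df_prior, df_test=df_diff, df_residual=df_res)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# comparison presets and the full contrast runner


@dataclass(frozen=True)
class DesignSpec:
    """One case-control comparison: contrast, stratum, pairing, nominal sizes."""

    name: str
    contrast: str  # "cell_type" | "disease"
    cell_fraction: str = "all"  # "all" | "neuronal" | "non_neuronal"
    sex: str = "all"  # "all" | "F" | "M"
    paired_by_donor: bool = False
    paired_donors_only: bool = True
    nominal_n: tuple = (0, 0)  # (cases, controls) in the emulated cohort


LEVEL_PRESETS = {
    "L1": DesignSpec("L1", "cell_type", "all", "all", paired_by_donor=True,
                     nominal_n=(40, 40)),
    "L2_neuronal": DesignSpec("L2_neuronal", "disease", "neuronal", "all",
                              nominal_n=(19, 21)),
    "L2_non_neuronal": DesignSpec("L2_non_neuronal", "disease", "non_neuronal", "all",
                                  nominal_n=(19, 21)),
    "L3A": DesignSpec("L3A", "disease", "non_neuronal", "F", nominal_n=(11, 11)),
    "L3B": DesignSpec("L3B", "disease", "non_neuronal", "M", nominal_n=(8, 10)),
    "L3C": DesignSpec("L3C", "disease", "neuronal", "F", nominal_n=(11, 11)),
    "L3D": DesignSpec("L3D", "disease", "neuronal", "M", nominal_n=(8, 10)),
    "L3E": DesignSpec("L3E", "disease", "non_neuronal", "F",
                      paired_donors_only=False, nominal_n=(14, 13)),
}


def select_stratum(metadata: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Samples entering a comparison under its stratum and pairing rules."""
    meta = metadata
    if design.cell_fraction != "all":
        meta = meta[meta["cell_fraction"] == design.cell_fraction]
    if design.sex != "all":
        meta = meta[meta["sex"] == design.sex]
    if design.paired_donors_only and "donor_id" in meta.columns:
        fractions = metadata.groupby("donor_id")["cell_fraction"].nunique()
        paired = set(fractions.index[fractions == 2])
        meta = meta[meta["donor_id"].isin(paired)]
    return meta


def _design_matrices(meta: pd.DataFrame, design: DesignSpec, covariates: list[str]):
    """Full/reduced design matrices; rank-deficient covariate columns pruned."""
    n = len(meta)
    cols = [np.ones(n)]
    names = ["intercept"]
    for cov in covariates:
        ser = meta[cov]
        if ser.dtype == object or isinstance(ser.dtype, pd.CategoricalDtype) or ser.dtype == bool:
            dm = pd.get_dummies(ser.astype(str), drop_first=True, prefix=cov)
            for c in dm.columns:
                cols.append(dm[c].to_numpy(dtype=float))
                names.append(c)
        else:
            v = ser.to_numpy(dtype=float)
            sd = v.std()
            cols.append((v - v.mean()) / (sd if sd > 0 else 1.0))
            names.append(cov)
    if design.paired_by_donor:
        dm = pd.get_dummies(meta["donor_id"].astype(str), drop_first=True, prefix="donor")
        for c in dm.columns:
            cols.append(dm[c].to_numpy(dtype=float))
            names.append(c)
    # greedy rank pruning of nuisance columns (keeps intercept, drops aliased)
    kept_cols, kept_names = [], []
    basis = np.empty((n, 0))
    for col, name in zip(cols, names):
        cand = np.column_stack([basis, col])
        if np.linalg.matrix_rank(cand) > basis.shape[1]:
            basis = cand
            kept_cols.append(col)
            kept_names.append(name)
        else:
            warnings.warn(f"dropping aliased design column {name!r}", stacklevel=3)
    if design.contrast == "cell_type":
        group = (meta["cell_fraction"] == "neuronal").to_numpy(dtype=float)
    else:
        group = meta["is_case"].to_numpy(dtype=float)
    X_reduced = np.column_stack(kept_cols)
    X_full = np.column_stack([X_reduced, group])
    if np.linalg.matrix_rank(X_full) <= X_reduced.shape[1]:
        raise ValueError("group indicator is confounded with the adjustment design")
    return X_full, X_reduced, kept_names + ["group"]


def run_contrast(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    design: DesignSpec | str,
    covariates: list[str] | None = None,
    min_count: int = 10,
    prior_df: float = 10.0,
    fdr_q: float = 0.05,
    dialect: str = "ucsc",
) -> pd.DataFrame:
    """Full differential run: sex-chrom exclusion -> TMM -> NB-QLF -> BH.

    ``counts`` is peaks x samples with ``chrom:start-end`` row ids.  Returns a
    table with peak coordinates, log2FC (case vs control, or neuronal vs
    non-neuronal for the cell-type contrast), mean logCPM, quasi-F, p, BH q
    and a direction label; significant means q < ``fdr_q``.
    """
    if isinstance(design, str):
        design = LEVEL_PRESETS[design]
    covariates = covariates or []
    missing = [c for c in covariates if c not in metadata.columns]
    if missing:
        raise ValueError(f"covariates not in metadata: {missing}")

    meta = select_stratum(metadata.loc[counts.columns.intersection(metadata.index)], design)
    if design.contrast == "cell_type":
        group = meta["cell_fraction"] == "neuronal"
    else:
        group = meta["is_case"].astype(bool)
    if group.sum() < 2 or (~group).sum() < 2:
        raise ValueError(
            f"{design.name}: need >=2 samples per group "
            f"(got {int(group.sum())} vs {int((~group).sum())})"
        )

    sub = drop_sex_chromosomes(counts[meta.index], dialect=dialect)
    sub = sub[sub.sum(axis=1) >= min_count]
    if sub.empty:
        raise ValueError("no peaks left after filtering")

    nf = tmm_factors(sub)
    offset = np.log(nf.effective_library_size)
    X_full, X_reduced, names = _design_matrices(meta, design, covariates)

    Y = sub.to_numpy(dtype=float)
    disp = estimate_dispersions(Y, X_full, offset, prior_df=prior_df,
                                peak_ids=list(sub.index))
    fit = fit_nb_glm_batched(Y, X_full, offset, disp.trended)
    test = ql_f_test(Y, X_full, X_reduced, offset, disp.trended)

    log2fc = fit.beta[:, -1] / LN2
    q = bh_adjust(test["p"].to_numpy())
    try:
        coords = intervals_from_ids(sub.index)
    except ValueError:  # non-genomic row ids (e.g. plain matrices): placeholder coords
        coords = pd.DataFrame(
            {"chrom": "chrUn", "start": np.arange(len(sub)), "end": np.arange(len(sub)) + 1}
        )
    mean_logcpm = np.log2(
        np.maximum(cpm_log(sub, nf).pipe(lambda d: (2.0 ** d).mean(axis=1)), 1e-10)
    )
    res = pd.DataFrame(
        {
            "peak_id": sub.index,
            "chrom": coords["chrom"].to_numpy(),
            "start": coords["start"].to_numpy(),
            "end": coords["end"].to_numpy(),
            "log2FC": log2fc,
            "mean_logCPM": np.asarray(mean_logcpm),
            "F": test["F"].to_numpy(),
            "p": test["p"].to_numpy(),
            "q": q,
            "converged": test["converged"].to_numpy(),
        }
    ).reset_index(drop=True)
    res["direction"] = np.where(
        res["log2FC"] > 0, "more_accessible_in_case", "less_accessible_in_case"
    )
    res["significant"] = res["q"] < fdr_q
    res.attrs["design"] = design
    res.attrs["covariate_columns"] = names
    res.attrs["common_dispersion"] = disp.common
    return res


class NBQLFTester(BaseEstimator):
    """sklearn-style fit-shaped wrapper around :func:`run_contrast`.

    ``fit(X, y)`` takes X = counts with samples as rows (n_samples x n_peaks,
    DataFrame indexed by sample id with peak-id columns) and y = binary group
    labels; optional ``covariates`` aligns a metadata table.  Fitted results
    land in ``results_``.
    """

    def __init__(self, min_count: int = 10, prior_df: float = 10.0, fdr_q: float = 0.05):
        self.min_count = min_count
        self.prior_df = prior_df
        self.fdr_q = fdr_q

    def fit(self, X, y, covariates: pd.DataFrame = None, covariate_names=None):
        Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        meta = pd.DataFrame(index=Xdf.index)
        meta["is_case"] = np.asarray(y, dtype=bool)
        meta["cell_fraction"] = "non_neuronal"
        meta["sex"] = "F"
        if covariates is not None:
            meta = meta.join(covariates)
        spec = DesignSpec("custom", "disease", "all", "all", paired_donors_only=False)
        self.results_ = run_contrast(
            Xdf.T, meta, spec, covariates=list(covariate_names or []),
            min_count=self.min_count, prior_df=self.prior_df, fdr_q=self.fdr_q,
        )
        return self
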