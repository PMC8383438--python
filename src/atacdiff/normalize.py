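"""Between-sample normalization by the weighted trimmed mean of M-values (TMM).

TMM estimates one scaling factor per sample relative to a reference sample:
peaks expressed in both samples contribute a log-ratio M and a log-abundance
A; the most extreme 30% of M-values and 5% of A-values (both sides) are
trimmed, and the remaining M-values are averaged with inverse asymptotic
binomial-variance weights.  Factors are rescaled so their geometric mean is 1,
and effective library sizes are library_size x factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class NormFactors:
    sample_ids: list
    library_size: np.ndarray
    tmm_factor: np.ndarray

    @property
    def effective_library_size(self) -> np.ndarray:
        return self.library_size * self.tmm_factor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "library_size": self.library_size,
                "tmm_factor": self.tmm_factor,
                "effective_library_size": self.effective_library_size,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (on log2 scale -> 2**)."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    if o.size == 0:
        return 1.0
    po, pr = o / lib_obs, r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # asymptotic variance of M (delta method on binomial proportions)
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(M), rankdata(A)
    kept = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not kept.any():
        return 1.0
    f = np.sum(M[kept] / v[kept]) / np.sum(1.0 / v[kept])
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    ref="auto",
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """TMM normalization factors for a peaks x samples count matrix.

    ``ref="auto"`` picks the sample whose upper-quartile count fraction is
    closest to the mean upper quartile.  Factors are rescaled to geometric
    mean 1.
    """
    Y = counts.to_numpy(dtype=float)
    lib = Y.sum(axis=0)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"sample {counts.columns[zero[0]]!r} has all-zero counts")
    if ref == "auto":
        f75 = np.array(
            [np.quantile(Y[:, j][Y[:, j] >= 0], 0.75) / lib[j] for j in range(Y.shape[1])]
        )
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if ref not in counts.columns:
            raise ValueError(f"reference sample {ref!r} not in matrix")
        ref_idx = int(counts.columns.get_loc(ref))
    factors = np.ones(Y.shape[1])
    for j in range(Y.shape[1]):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(Y[:, j], Y[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(list(counts.columns), lib, factors)


def cpm_log(counts: pd.DataFrame, norm: NormFactors, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts per million on effective library sizes, finite everywhere.

    The prior count is interpreted per million of effective library
    (``prior_j = prior * eff_j / 1e6``), so the result is exactly invariant
    to a common rescaling of counts and libraries:
    ``log2((y + prior_j) / (eff_j + 2 * prior_j) * 1e6)``.
    """
    missing = set(counts.columns) - set(norm.sample_ids)
    if missing:
        raise ValueError(f"normalization factors missing for samples: {sorted(missing)}")
    eff = pd.Series(norm.effective_library_size, index=norm.sample_ids)[counts.columns]
    eff = eff.to_numpy(dtype=float)
    prior_j = prior * eff / 1e6
    vals = (counts.to_numpy(dtype=float) + prior_j[None, :]) / (
        eff[None, :] + 2.0 * prior_j[None, :]
    ) * 1e6
    return pd.DataFrame(np.log2(vals), index=counts.index, columns=counts.columns)


class TMMNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: counts -> TMM-normalized log2-CPM.

    ``fit`` expects X of shape (n_samples, n_peaks) (samples as rows, the
    sklearn convention) and computes ``library_sizes_``, ``tmm_factors_`` and
    ``effective_library_sizes_``; ``transform`` returns log2-CPM on the same
    shape.
    """

    def __init__(self, ref="auto", trim_m: float = 0.30, trim_a: float = 0.05,
                 prior: float = 0.5):
        self.ref = ref
        self.trim_m = trim_m
        self.trim_a = trim_a
        self.prior = prior

    def _as_counts(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.T
        X = np.asarray(X)
        return pd.DataFrame(X.T)

    def fit(self, X, y=None):
        counts = self._as_counts(X)
        nf = tmm_factors(counts, ref=self.ref, trim_m=self.trim_m, trim_a=self.trim_a)
        self.sample_ids_ = nf.sample_ids
        self.library_sizes_ = nf.library_size
        self.tmm_factors_ = nf.tmm_factor
        self.effective_library_sizes_ = nf.effective_library_size
        self.norm_factors_ = nf
        return self

    def transform(self, X):
        counts = self._as_counts(X)
        nf = NormFactors(list(counts.columns), counts.to_numpy(dtype=float).sum(axis=0),
                         self.tmm_factors_)
        out = cpm_log(counts, nf, prior=self.prior).T
        return out if isinstance(X, pd.DataFrame) else out.to_numpy()
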