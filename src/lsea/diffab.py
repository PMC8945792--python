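"""Normalization and negative-binomial differential abundance.

Count-style modelling of MRM quantitation signals between two sample
groups:

* **median-of-ratios size factors** — for sample *j*,
  ``s_j = median_i(x_ij / geomean_i)`` over the reference lipids (those
  with strictly positive signal in every sample), where ``geomean_i`` is
  the geometric mean of lipid *i* across samples; counts divided by
  ``s_j`` are the normalized signals;
* a simplified **variance-stabilizing transform** ``log2(x + c)`` feeding
  embeddings and heatmaps;
* a **negative-binomial Wald test**: per-lipid method-of-moments
  dispersion ``alpha`` under the NB variance ``v = mu + alpha mu^2``, a
  delta-method standard error for the log2 fold change of group means,
  two-sided normal p-values, and Benjamini-Hochberg adjustment.

This is deliberately the plainest defensible NB pipeline: no
empirical-Bayes dispersion shrinkage, no fold-change shrinkage, no
outlier refitting. The estimators follow scikit-learn conventions
(``fit``/``transform`` on samples x lipids arrays, fitted attributes with
trailing underscores) so they compose with sklearn pipelines; the
module-level functions operate on lipids x samples frames, the native
orientation of quantitation tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .io import SignalMatrix

#: dispersion floor applied in the Wald variance (keeps se > 0)
ALPHA_FLOOR = 1e-8
#: pseudo-mean added to a group whose mean is zero (keeps log2fc finite)
ZERO_GROUP_PSEUDO_MEAN = 0.5

RANK_METRICS = ("wald_z", "log2fc", "signed_logp")


class NormalizationError(ValueError):
    """Size factors are undefined (empty reference set)."""


def _as_frame(m) -> pd.DataFrame:
    """Accept a SignalMatrix or a lipids x samples DataFrame."""
    if isinstance(m, SignalMatrix):
        return m.values
    return m


# ----------------------------------------------------------- size factors


class MedianOfRatiosNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios normalization in sklearn orientation.

    ``fit`` learns per-lipid geometric means from the fitted samples
    (restricted to lipids positive in every sample); ``transform``
    divides each sample (row) by its size factor, the median ratio of
    that sample's signals to the stored geometric means.

    Attributes
    ----------
    geometric_means_ : ndarray of shape (n_lipids,)
        Reference geometric means; NaN outside the reference set.
    reference_mask_ : ndarray of bool
        Lipids usable as reference (all-positive across fitted samples).
    size_factors_ : ndarray of shape (n_samples,)
        Size factors of the samples seen at fit time.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples x lipids array")
        with np.errstate(divide="ignore"):
            logs = np.where(X > 0, np.log(np.maximum(X, 1e-300)), -np.inf)
        ref = np.all(np.nan_to_num(X, nan=0.0) > 0, axis=0)
        if not ref.any():
            raise NormalizationError(
                "no lipid is positive in every sample; consider the "
                "pseudo-reference fallback (drop all-zero samples or relax "
                "the presence filter)"
            )
        geo = np.full(X.shape[1], np.nan)
        geo[ref] = np.exp(logs[:, ref].mean(axis=0))
        self.reference_mask_ = ref
        self.geometric_means_ = geo
        self.n_features_in_ = X.shape[1]
        self.size_factors_ = self._factors(X)
        return self

    def _factors(self, X: np.ndarray) -> np.ndarray:
        ratios = X[:, self.reference_mask_] / self.geometric_means_[self.reference_mask_]
        s = np.median(ratios, axis=1)
        if (s <= 0).any():
            return s
        # pin the scale (geometric mean 1) so normalization is an exact
        # fixed point: re-estimated factors come back as all ones
        return s / np.exp(np.log(s).mean())

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("lipid dimension changed between fit and transform")
        s = self._factors(X)
        if (s <= 0).any():
            raise NormalizationError("non-positive size factor; sample has "
                                     "zero median ratio over the reference set")
        return X / s[:, None]


def size_factors(m) -> pd.Series:
    """Per-sample size factors of a lipids x samples matrix."""
    df = _as_frame(m)
    norm = MedianOfRatiosNormalizer().fit(df.to_numpy().T)
    return pd.Series(norm.size_factors_, index=df.columns, name="size_factor")


def normalize(m, s: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample's column by its size factor."""
    df = _as_frame(m)
    if s is None:
        s = size_factors(df)
    if (np.asarray(s) <= 0).any():
        raise NormalizationError("size factors must be positive")
    return df.div(pd.Series(s, index=df.columns), axis=1)


class VarianceStabilizingTransform(BaseEstimator, TransformerMixin):
    """Shifted-log transform ``log2(x + pseudocount)``; stateless, monotone."""

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        return self

    def transform(self, X):
        return np.log2(np.asarray(X, dtype=float) + self.pseudocount)


def vst(m, pseudocount: float = 1.0) -> pd.DataFrame:
    df = _as_frame(m)
    out = VarianceStabilizingTransform(pseudocount).fit(df).transform(df)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


# ------------------------------------------------------------ NB Wald test


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def estimate_dispersion(counts: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Per-lipid method-of-moments NB dispersion.

    ``alpha = max(0, (pooled within-group variance - mean) / mean^2)``
    on the (normalized) counts, with the pooled variance weighted by
    within-group degrees of freedom. Zero-variance lipids get alpha 0;
    the Wald step applies the :data:`ALPHA_FLOOR`.
    """
    groups = pd.Series(groups)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("each group needs n >= 2 to estimate dispersion")
    X = counts.to_numpy(dtype=float)
    cols = pd.Index(counts.columns)
    ss = np.zeros(X.shape[0])
    dof = 0
    for lev in levels:
        idx = cols.get_indexer(groups.index[groups == lev])
        sub = X[:, idx]
        ss += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
        dof += sub.shape[1] - 1
    pooled_var = ss / dof
    mean = X.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    alpha = np.where(mean > 0, np.maximum(alpha, 0.0), 0.0)
    return pd.Series(alpha, index=counts.index, name="dispersion")


class NegativeBinomialWaldTest(BaseEstimator):
    """Two-group NB Wald differential-abundance test.

    Parameters
    ----------
    level_a, level_b : optional group labels; the fold change is
        ``level_b`` over ``level_a``. Defaults to the sorted label order.
    pseudocount : pseudo-mean added to a group whose mean is exactly zero.
    normalize : compute median-of-ratios size factors from the raw counts
        (set False when the input is already normalized).

    After ``fit(X, y)`` with X of shape (n_samples, n_lipids):

    results_ : DataFrame with base_mean, log2fc, se, wald_z, p, q and
        dispersion per lipid; lipids all-zero in both groups carry NaN p
        and are excluded from the BH family.
    size_factors_ : per-sample size factors used.
    """

    def __init__(
        self,
        level_a: str | None = None,
        level_b: str | None = None,
        pseudocount: float = ZERO_GROUP_PSEUDO_MEAN,
        normalize: bool = True,
        round_counts: bool = True,
        alpha_floor: float = ALPHA_FLOOR,
    ):
        self.level_a = level_a
        self.level_b = level_b
        self.pseudocount = pseudocount
        self.normalize = normalize
        self.round_counts = round_counts
        self.alpha_floor = alpha_floor

    def fit(self, X, y, lipid_ids=None):
        if isinstance(X, pd.DataFrame):
            lipid_ids = lipid_ids if lipid_ids is not None else list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if lipid_ids is None:
            lipid_ids = [f"f{i}" for i in range(X.shape[1])]
        y = pd.Series(np.asarray(y), name="group")
        levels = sorted(y.unique())
        if len(levels) != 2:
            raise ValueError(f"need exactly two groups, got {levels}")
        a = self.level_a if self.level_a is not None else levels[0]
        b = self.level_b if self.level_b is not None else levels[1]
        if {a, b} != set(levels):
            raise ValueError(f"levels ({a!r}, {b!r}) do not match data {levels}")
        mask_a = (y == a).to_numpy()
        mask_b = (y == b).to_numpy()
        n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
        if min(n_a, n_b) < 2:
            raise ValueError("each group needs n >= 2")

        counts = np.nan_to_num(X, nan=0.0)
        if self.round_counts:
            counts = _round_half_up(counts)
        if self.normalize:
            norm = MedianOfRatiosNormalizer().fit(counts)
            s = norm.size_factors_
        else:
            s = np.ones(X.shape[0])
        normed = counts / s[:, None]

        frame = pd.DataFrame(normed.T, index=pd.Index(lipid_ids, name="lipid"))
        disp = estimate_dispersion(
            frame, pd.Series(y.to_numpy(), index=frame.columns)
        ).to_numpy()
        alpha = np.maximum(disp, self.alpha_floor)

        mu_a = normed[mask_a].mean(axis=0)
        mu_b = normed[mask_b].mean(axis=0)
        untested = (mu_a == 0) & (mu_b == 0)
        mu_a_adj = np.where(mu_a == 0, self.pseudocount, mu_a)
        mu_b_adj = np.where(mu_b == 0, self.pseudocount, mu_b)

        log2fc = np.log2(mu_b_adj / mu_a_adj)
        v_a = mu_a_adj + alpha * mu_a_adj**2
        v_b = mu_b_adj + alpha * mu_b_adj**2
        se = (1.0 / np.log(2)) * np.sqrt(
            v_a / (n_a * mu_a_adj**2) + v_b / (n_b * mu_b_adj**2)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            z = log2fc / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        p = np.where(untested, np.nan, p)
        q = np.full_like(p, np.nan)
        tested = ~np.isnan(p)
        if tested.any():
            q[tested] = multipletests(p[tested], method="fdr_bh")[1]

        self.levels_ = (a, b)
        self.group_sizes_ = {a: n_a, b: n_b}
        self.size_factors_ = s
        self.results_ = pd.DataFrame(
            {
                "base_mean": normed.mean(axis=0),
                "log2fc": np.where(untested, np.nan, log2fc),
                "se": np.where(untested, np.nan, se),
                "wald_z": np.where(untested, np.nan, z),
                "p": p,
                "q": q,
                "dispersion": disp,
            },
            index=pd.Index(lipid_ids, name="lipid"),
        )
        return self


def wald_test(
    counts,
    groups: pd.Series,
    size_factors: pd.Series | None = None,
    level_a: str | None = None,
    level_b: str | None = None,
) -> pd.DataFrame:
    """NB Wald test on a lipids x samples matrix; log2fc is B over A.

    ``groups`` maps sample id -> label. When ``size_factors`` is omitted
    they are estimated from the counts by median of ratios.
    """
    df = _as_frame(counts)
    groups = pd.Series(groups).loc[df.columns]
    est = NegativeBinomialWaldTest(
        level_a=level_a,
        level_b=level_b,
        normalize=size_factors is None,
        round_counts=size_factors is None,
    )
    X = df.to_numpy(dtype=float).T
    if size_factors is not None:
        s = pd.Series(size_factors).loc[df.columns].to_numpy(dtype=float)
        X = _round_half_up(np.nan_to_num(X, nan=0.0)) / s[:, None]
    est.fit(X, groups.to_numpy(), lipid_ids=list(df.index))
    return est.results_


def rank_metric(
    res: pd.DataFrame, metric: str = "wald_z"
) -> pd.DataFrame:
    """Ranked (lipid, score) list for enrichment, best score first.

    Untested lipids (NaN p) are excluded; ties break lexicographically
    by lipid id so the ranking is fully deterministic.
    """
    if metric not in RANK_METRICS:
        raise ValueError(f"metric must be one of {RANK_METRICS}")
    if res.empty:
        raise ValueError("empty differential-abundance result")
    tested = res.dropna(subset=["p"])
    if metric == "wald_z":
        score = tested["wald_z"]
    elif metric == "log2fc":
        score = tested["log2fc"]
    else:
        # signed -log10 p, cautious at p == 0
        p = tested["p"].clip(lower=np.nextafter(0, 1))
        score = -np.log10(p) * np.sign(tested["log2fc"])
    out = pd.DataFrame({"lipid": tested.index, "score": score.to_numpy()})
    out = out.sort_values(
        ["score", "lipid"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
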