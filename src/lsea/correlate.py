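"""Lipid-mediator vs protein-marker correlation.

Each (lipid, protein) pair is tested with Pearson's r when both paired
vectors look Gaussian (Shapiro-Wilk on each at ``alpha_norm``) and with
Spearman's rho otherwise — the parametric/non-parametric split used for
immunoblot panels (HO-1, iNOS, Cyp1b1, Hsp70, COX2, MPO) against the
mediator matrix. Missing observations are dropped pairwise, never
imputed; p-values are BH-adjusted across the full lipid x protein grid
within a stratum. With the small per-stratum n typical of these designs
the t-approximation is weak, so an exact-style permutation p-value is
available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import SignalMatrix

MIN_PAIRS = 3


class CorrelationError(ValueError):
    pass


@dataclass
class ProteinPanel:
    """Proteins x samples grid of relative immunoblot signals."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise CorrelationError("protein signals must be non-negative")
        if self.values.index.duplicated().any():
            raise CorrelationError("duplicate protein names")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def choose_method(x, y, alpha_norm: float = 0.05) -> str:
    """'pearson' iff both vectors pass Shapiro-Wilk at ``alpha_norm``.

    Constant vectors cannot be tested for normality and fall through to
    Spearman (whose coefficient is then undefined and reported NA by the
    caller).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < MIN_PAIRS:
        raise CorrelationError(f"need paired vectors with n >= {MIN_PAIRS}")
    for v in (x, y):
        if np.ptp(v) == 0:
            return "spearman"
        if stats.shapiro(v).pvalue < alpha_norm:
            return "spearman"
    return "pearson"


def _permutation_p(x, y, observed_r, method, n_perm, rng) -> float:
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    hits = 0
    for _ in range(n_perm):
        r = corr(x, rng.permutation(y)).statistic
        if abs(r) >= abs(observed_r) - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def correlate_pair(
    x,
    y,
    alpha_norm: float = 0.05,
    permutation: bool = False,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[str, float, float, int]:
    """(method, coefficient, p, n_used) for one complete-case pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    if n < MIN_PAIRS:
        return "spearman", np.nan, np.nan, n
    method = choose_method(x, y, alpha_norm)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return method, np.nan, np.nan, n
    if method == "pearson":
        res = stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
    coef, p = float(res.statistic), float(res.pvalue)
    if permutation:
        rng = rng if rng is not None else np.random.default_rng(0)
        p = _permutation_p(x, y, coef, method, n_perm, rng)
    return method, coef, p, n


class LipidProteinCorrelation(BaseEstimator):
    """All-pairs mixed-method correlation between two aligned panels.

    ``fit(lipids_df, proteins_df)`` with both frames features x samples
    over a shared sample set; results land in ``results_`` (tidy) and
    ``matrix_`` (lipids x proteins coefficient grid, heatmap-ready).
    """

    def __init__(
        self,
        alpha_norm: float = 0.05,
        permutation: bool = False,
        n_perm: int = 1000,
        seed: int = 0,
    ):
        self.alpha_norm = alpha_norm
        self.permutation = permutation
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, X, y=None):
        lipids_df, proteins_df = X if isinstance(X, tuple) else (X, y)
        shared = [s for s in lipids_df.columns if s in set(proteins_df.columns)]
        if len(shared) < MIN_PAIRS:
            raise CorrelationError(
                f"only {len(shared)} shared samples; need >= {MIN_PAIRS}"
            )
        rows = []
        for li, lvec in lipids_df[shared].iterrows():
            for pi, pvec in proteins_df[shared].iterrows():
                rng = np.random.default_rng(self.seed)
                method, coef, p, n = correlate_pair(
                    lvec.to_numpy(),
                    pvec.to_numpy(),
                    self.alpha_norm,
                    self.permutation,
                    self.n_perm,
                    rng,
                )
                rows.append(
                    {"lipid": li, "protein": pi, "method": method,
                     "coefficient": coef, "p": p, "n_used": n}
                )
        res = pd.DataFrame(rows)
        res["q"] = np.nan
        ok = res["p"].notna()
        if ok.any():
            res.loc[ok, "q"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
        self.results_ = res
        self.matrix_ = res.pivot(index="lipid", columns="protein",
                                 values="coefficient")
        return self


def correlate_matrix(
    m: SignalMatrix,
    panel: ProteinPanel,
    stratum: dict[str, str] | None = None,
    alpha_norm: float = 0.05,
    permutation: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy per-pair correlation table within one metadata stratum.

    BH adjustment spans the full lipid x protein grid of the stratum,
    mirroring per-condition correlation heatmaps (positive and negative
    coefficients colour-coded by sign).
    """
    sub = m.select(**stratum) if stratum else m
    if sub.n_samples < MIN_PAIRS:
        raise CorrelationError(
            f"stratum {stratum!r} has {sub.n_samples} samples; "
            f"need >= {MIN_PAIRS}"
        )
    est = LipidProteinCorrelation(
        alpha_norm=alpha_norm, permutation=permutation, n_perm=n_perm, seed=seed
    ).fit((sub.values, panel.values))
    return est.results_
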