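"""Consomic-panel screening against a shared control strain.

The screen performs Dunnett's many-to-one comparison of every strain
against the host (control) strain per parameter, orders strains by
mean value, computes the Spearman rank-correlation matrix across the
six parameters, and quantifies nonadditivity: the summed phenotypic
effects of the significant single-substitution strains expressed as a
percentage of the parental difference.  An index far above 100%
indicates epistatic (nonadditive) interaction among chromosomes.

Dunnett adjusted p-values use the classical equicorrelated
multivariate-t formulation with the pooled within-group variance.  For
balanced panels (all group sizes equal) the distribution of
``max_i |T_i|`` is evaluated by Gauss-Hermite x chi quadrature; for
unbalanced panels a seeded Monte-Carlo reference distribution with the
exact correlation structure ``corr(T_i, T_j) = lambda_i lambda_j``,
``lambda_i = sqrt(n_i / (n_i + n_0))``, is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

PARAMETERS = ("BVTV", "TbN", "ConnD", "TbSp", "SMI", "TbTh")

__all__ = [
    "PARAMETERS",
    "ScreenResult",
    "CorrelationMatrix",
    "dunnett_screen",
    "order_strains",
    "spearman_matrix",
    "nonadditivity_index",
]


@dataclass(frozen=True)
class ScreenResult:
    """Per (strain, parameter) screen statistics vs the control strain.

    ``frame`` columns: parameter, strain, n, mean, se, t, p_adj,
    significant, degenerate.  The control strain appears with NaN
    statistics (no self-comparison).
    """

    control: str
    donor: str
    alpha: float
    frame: pd.DataFrame = field(compare=False)

    def means(self, parameter: str) -> pd.Series:
        sub = self.frame[self.frame["parameter"] == parameter]
        return sub.set_index("strain")["mean"]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Spearman rho and p-values for all parameter pairs."""

    rho: pd.DataFrame = field(compare=False)
    p: pd.DataFrame = field(compare=False)
    n: int = 0


# -- Dunnett machinery -------------------------------------------------


@lru_cache(maxsize=64)
def _quad_nodes(df: int, n_chi: int = 48, n_z: int = 48):
    """Quadrature nodes for E over W = S/sigma (chi_df/sqrt(df)) and
    Z0 ~ N(0,1)."""
    # chi factor via Gauss-Legendre on the probability scale
    q, wq = np.polynomial.legendre.leggauss(n_chi)
    q = 0.5 * (q + 1.0)
    wq = 0.5 * wq
    w_nodes = np.sqrt(stats.chi2.ppf(q, df) / df)
    # standard normal via Gauss-Hermite
    x, wx = np.polynomial.hermite.hermgauss(n_z)
    z_nodes = np.sqrt(2.0) * x
    wz = wx / np.sqrt(np.pi)
    return w_nodes, wq, z_nodes, wz


def dunnett_max_abs_cdf(t: np.ndarray, k: int, df: int, rho: float = 0.5) -> np.ndarray:
    """P(max_i |T_i| <= t) for k equicorrelated Dunnett statistics."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    w_nodes, wq, z_nodes, wz = _quad_nodes(df)
    sr, cr = np.sqrt(rho), np.sqrt(1.0 - rho)
    tw = t[:, None, None] * w_nodes[None, :, None]  # (nt, nw, 1)
    zu = sr * z_nodes[None, None, :]  # (1, 1, nz)
    inner = stats.norm.cdf((tw - zu) / cr) - stats.norm.cdf((-tw - zu) / cr)
    inner = np.clip(inner, 0.0, 1.0) ** k
    return np.einsum("twz,w,z->t", inner, wq, wz)


def _dunnett_p_balanced(t_abs: np.ndarray, k: int, df: int) -> np.ndarray:
    return np.clip(1.0 - dunnett_max_abs_cdf(t_abs, k, df, rho=0.5), 0.0, 1.0)


def _dunnett_p_mc(
    t_abs: np.ndarray,
    lambdas: np.ndarray,
    df: int,
    draws: int,
    seed: int,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    k = lambdas.size
    z0 = rng.standard_normal(draws)
    z = rng.standard_normal((draws, k))
    w = np.sqrt(rng.chisquare(df, draws) / df)
    t = (np.sqrt(1.0 - lambdas**2)[None, :] * z + lambdas[None, :] * z0[:, None]) / w[
        :, None
    ]
    ref = np.abs(t).max(axis=1)
    ref.sort()
    # p = P(max |T| >= observed), right-continuous empirical tail
    idx = np.searchsorted(ref, t_abs, side="left")
    return 1.0 - idx / draws


def dunnett_screen(
    table: pd.DataFrame,
    control: str = "B6",
    donor: str = "MSM",
    alpha: float = 0.05,
    parameters: tuple[str, ...] | None = None,
    mc_draws: int = 40000,
    mc_seed: int = 20130,
) -> ScreenResult:
    """Dunnett many-to-one screen of every strain against the control.

    Missing values are dropped listwise per parameter.  Groups whose
    pooled variance degenerates to zero report p = 1 with a warning
    flag.  ``alpha`` is the family-wise level used for the
    ``significant`` flags.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if control not in set(table["strain"]):
        raise ValueError(f"control strain {control!r} absent from table")
    if parameters is None:
        parameters = tuple(p for p in PARAMETERS if p in table.columns)
    strains = sorted(set(table["strain"]))
    others = [s for s in strains if s != control]
    if not others:
        raise ValueError("need at least one comparison strain")
    rows = []
    for param in parameters:
        sub = table[["strain", param]].dropna()
        grp = sub.groupby("strain")[param]
        n = grp.size()
        if n.get(control, 0) < 2:
            raise ValueError(f"control strain needs >= 2 animals for {param}")
        mean = grp.mean()
        sd = grp.std(ddof=1)
        # pooled within-group variance across all groups (classic Dunnett)
        navail = n[n >= 2]
        ss = ((navail - 1) * sd[navail.index] ** 2).sum()
        df = int((navail - 1).sum())
        s2 = ss / df if df > 0 else 0.0
        degenerate = s2 <= 0
        if degenerate:
            warnings.warn(
                f"degenerate (zero) pooled variance for {param}; p set to 1",
                stacklevel=2,
            )
        tvals = {}
        for s in others:
            if degenerate:
                tvals[s] = 0.0
            else:
                se_diff = np.sqrt(s2 * (1.0 / n[s] + 1.0 / n[control]))
                tvals[s] = (mean[s] - mean[control]) / se_diff
        t_abs = np.abs(np.array([tvals[s] for s in others]))
        k = len(others)
        if degenerate:
            p_adj = np.ones(k)
        elif n.nunique() == 1:
            p_adj = _dunnett_p_balanced(t_abs, k, df)
        else:
            lam = np.sqrt(n[others].to_numpy(float) / (n[others].to_numpy(float) + n[control]))
            p_adj = _dunnett_p_mc(t_abs, lam, df, mc_draws, mc_seed)
        for s, p in zip(others, p_adj):
            rows.append(
                {
                    "parameter": param,
                    "strain": s,
                    "n": int(n[s]),
                    "mean": mean[s],
                    "se": sd[s] / np.sqrt(n[s]),
                    "t": tvals[s],
                    "p_adj": float(p),
                    "significant": bool(p < alpha) and not degenerate,
                    "degenerate": bool(degenerate),
                }
            )
        rows.append(
            {
                "parameter": param,
                "strain": control,
                "n": int(n[control]),
                "mean": mean[control],
                "se": sd[control] / np.sqrt(n[control]),
                "t": np.nan,
                "p_adj": np.nan,
                "significant": False,
                "degenerate": bool(degenerate),
            }
        )
    frame = pd.DataFrame(rows)
    return ScreenResult(control=control, donor=donor, alpha=alpha, frame=frame)


def order_strains(result: ScreenResult, parameter: str) -> list[str]:
    """Strains sorted ascending by mean; ties broken lexicographically."""
    means = result.means(parameter)
    return sorted(means.index, key=lambda s: (means[s], s))


def spearman_matrix(
    table: pd.DataFrame,
    parameters: tuple[str, ...] = PARAMETERS,
    strain_means: bool = False,
) -> CorrelationMatrix:
    """Spearman rho and p for all parameter pairs (midrank ties).

    Computed across all individual animals by default; set
    ``strain_means`` to correlate per-strain means instead.
    """
    data = table[list(("strain",) + tuple(parameters))]
    if strain_means:
        data = data.groupby("strain", as_index=False).mean(numeric_only=True)
    mat = data[list(parameters)].dropna()
    n = len(mat)
    if n < 3:
        raise ValueError("need at least 3 individuals for correlation")
    k = len(parameters)
    rho = np.eye(k)
    pv = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x, y = mat.iloc[:, i], mat.iloc[:, j]
            if x.nunique() < 2 or y.nunique() < 2:
                warnings.warn(
                    f"constant column in ({parameters[i]}, {parameters[j]}); "
                    "rho undefined",
                    stacklevel=2,
                )
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pv[i, j] = pv[j, i] = p
    idx = list(parameters)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(pv, index=idx, columns=idx),
        n=n,
    )


def nonadditivity_index(
    result: ScreenResult,
    parameter: str,
    include_all: bool = False,
) -> float:
    """Summed single-substitution effects as % of the parental difference.

    ``100 * sum_s (mean_s - mean_control) / (mean_donor - mean_control)``
    over consomic strains flagged significant (or all consomic strains
    if ``include_all``), excluding both parents.  Values much larger
    than 100% indicate nonadditive interaction.
    """
    sub = result.frame[result.frame["parameter"] == parameter].set_index("strain")
    if result.control not in sub.index or result.donor not in sub.index:
        raise ValueError("control and donor means are required")
    m0 = sub.loc[result.control, "mean"]
    md = sub.loc[result.donor, "mean"]
    parental = md - m0
    if parental == 0:
        raise ValueError("parental difference is zero; index undefined")
    strains = [s for s in sub.index if s not in (result.control, result.donor)]
    if not include_all:
        strains = [s for s in strains if bool(sub.loc[s, "significant"])]
    total = sum(sub.loc[s, "mean"] - m0 for s in strains)
    return 100.0 * total / parental
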