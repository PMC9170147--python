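"""Multi-environment field-trial simulation and mixed-model analysis.

The trial model is a one-stage simplification of a lattice-design analysis:

    y_ijk = mu + g_i + u_j + (gu)_ij + eps_ijk

with genotype g ~ N(0, sigma2_g) (one variance per population when several
population tags are present, populations being stochastically independent),
environment u fixed, genotype-by-environment interaction
(gu) ~ N(0, sigma2_gxe) and plot residual eps ~ N(0, sigma2_eps).  Balanced
data admit the closed-form ANOVA solution, which coincides with REML when
the estimates are interior; unbalanced data are fitted by iterative REML.
BLUEs of entry values come from the fixed-genotype refit.

Entry-mean heritability: h2 = sigma2_g / (sigma2_g + sigma2_gxe/E +
sigma2_eps/(E R)), with a delta-method standard error from the component
covariance matrix, and the rule that an estimate exceeding twice its SE is
declared significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "TrialData",
    "simulate_trials",
    "curate_outliers",
    "TrialModel",
    "TrialResults",
    "entry_mean_heritability",
    "significance_by_2se",
    "pp_tp_genetic_correlation",
]


def curate_outliers(plots: pd.DataFrame, threshold: float = 4.0) -> tuple[pd.DataFrame, int]:
    """Automated stand-in for manual residual-plot curation (off by default).

    Residuals are taken against the additive entry + environment fit; plots
    with |studentized residual| above ``threshold`` are set missing
    (dropped).  Returns the curated table and the number of plots removed.
    """
    df = plots.copy()
    entry_mean = df.groupby("entry", observed=True)["value"].transform("mean")
    env_mean = df.groupby("env", observed=True)["value"].transform("mean")
    resid = df["value"] - entry_mean - env_mean + df["value"].mean()
    sd = resid.std(ddof=1)
    if sd == 0:
        return df, 0
    keep = (resid.abs() / sd) <= threshold
    return df[keep].reset_index(drop=True), int((~keep).sum())


@dataclass
class TrialData:
    """Plot-level phenotypes plus the generating truth."""

    plots: pd.DataFrame  # entry, population, env, rep, block, value
    genotypic_values: np.ndarray
    sigma2_g: dict  # per population, realized variance of true values
    sigma2_gxe: float
    sigma2_eps: float
    n_env: int
    n_rep: int


def simulate_trials(
    genotypic_values,
    E: int = 4,
    R: int = 2,
    target_h2: float | None = 0.9,
    variances: tuple[float, float] | None = None,
    seed=None,
    population=None,
    env_sd: float | None = None,
) -> TrialData:
    """Simulate a balanced multi-environment replicated trial.

    Either ``variances = (sigma2_gxe, sigma2_eps)`` is given explicitly, or
    both are back-solved from ``target_h2`` via the entry-mean heritability
    formula using the realized variance of the true genotypic values and
    the convention sigma2_eps = 2 * sigma2_gxe.  Defaults E=4, R=2 mirror a
    per-se evaluation in four environments with two replicates.
    """
    if E < 1 or R < 1:
        raise ValueError("E and R must be >= 1")
    g = np.asarray(genotypic_values, dtype=float)
    n = g.size
    pop = np.asarray(population) if population is not None else np.repeat("POP", n)
    rng = np.random.default_rng(seed)
    var_g = float(np.var(g, ddof=1))
    if variances is not None:
        s2_ge, s2_eps = map(float, variances)
    else:
        if not 0 < target_h2 <= 1:
            raise ValueError("target_h2 must be in (0, 1]")
        excess = var_g * (1.0 / target_h2 - 1.0)
        s2_ge = excess / (1.0 / E + 2.0 / (E * R))
        s2_eps = 2.0 * s2_ge
        if not np.isfinite(s2_ge) or s2_ge < 0:
            raise ValueError("infeasible target_h2 for the given genotypic values")
    env_sd = np.sqrt(var_g) if env_sd is None else env_sd
    env_eff = rng.normal(0.0, env_sd, size=E)
    ge = rng.normal(0.0, np.sqrt(s2_ge), size=(n, E))
    rows = []
    for j in range(E):
        for r in range(R):
            eps = rng.normal(0.0, np.sqrt(s2_eps), size=n)
            rows.append(
                pd.DataFrame(
                    {
                        "entry": np.arange(n),
                        "population": pop,
                        "env": f"E{j+1}",
                        "rep": r + 1,
                        "block": r + 1,
                        "value": g + env_eff[j] + ge[:, j] + eps,
                    }
                )
            )
    plots = pd.concat(rows, ignore_index=True)
    s2g = {str(k): float(np.var(g[pop == k], ddof=1)) for k in np.unique(pop)}
    return TrialData(
        plots=plots,
        genotypic_values=g,
        sigma2_g=s2g,
        sigma2_gxe=s2_ge,
        sigma2_eps=s2_eps,
        n_env=E,
        n_rep=R,
    )


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_gxe: float
    sigma2_eps: float
    se: np.ndarray  # SEs in the same order
    cov: np.ndarray  # 3x3 covariance of the estimates
    converged: bool
    loglik: float
    truncated: bool


class TrialModel:
    """Mixed model for plot-level trial data (genotype random, environment fixed).

    Parameters
    ----------
    data : TrialData or DataFrame with columns entry, population, env, rep, value.
    """

    def __init__(self, data):
        self.plots = data.plots if isinstance(data, TrialData) else data.copy()
        req = {"entry", "env", "value"}
        if not req <= set(self.plots.columns):
            raise ValueError(f"trial data must have columns {sorted(req)}")
        if "population" not in self.plots:
            self.plots["population"] = "POP"
        self.populations = list(pd.unique(self.plots["population"]))

    # --- REML machinery ------------------------------------------------------
    @staticmethod
    def _design(df: pd.DataFrame):
        entries, zi = np.unique(df["entry"], return_inverse=True)
        envs, ei = np.unique(df["env"], return_inverse=True)
        n = len(df)
        X = np.zeros((n, len(envs)))
        X[np.arange(n), ei] = 1.0  # env cell means parameterization (mu absorbed)
        Zg = np.zeros((n, len(entries)))
        Zg[np.arange(n), zi] = 1.0
        cells, ci = np.unique(zi * len(envs) + ei, return_inverse=True)
        Zge = np.zeros((n, len(cells)))
        Zge[np.arange(n), ci] = 1.0
        return X, Zg, Zge, entries, envs

    @staticmethod
    def _reml_loglik(y, X, Zg, Zge, s2g, s2ge, s2e):
        n = len(y)
        V = s2g * (Zg @ Zg.T) + s2ge * (Zge @ Zge.T) + s2e * np.eye(n)
        L = np.linalg.cholesky(V)
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        sign, logdetX = np.linalg.slogdet(XtViX)
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        resid = y - X @ beta
        quad = float(resid @ np.linalg.solve(V, resid))
        return -0.5 * (logdetV + logdetX + quad)

    def reml_loglik(self, sigma2_g, sigma2_gxe, sigma2_eps, population=None):
        """Restricted log-likelihood at the given components (one population)."""
        df = self.plots
        if population is not None:
            df = df[df["population"] == population]
        elif len(self.populations) > 1:
            raise ValueError("specify a population for multi-population data")
        X, Zg, Zge, _, _ = self._design(df)
        return self._reml_loglik(
            df["value"].to_numpy(float), X, Zg, Zge, sigma2_g, sigma2_gxe, sigma2_eps
        )

    @staticmethod
    def _is_balanced(df: pd.DataFrame) -> bool:
        counts = df.groupby(["entry", "env"], observed=True).size()
        n_entry = df["entry"].nunique()
        n_env = df["env"].nunique()
        return len(counts) == n_entry * n_env and counts.nunique() == 1

    @classmethod
    def _anova_fit(cls, df: pd.DataFrame) -> VarianceComponents:
        """Closed-form balanced ANOVA-REML with method-of-moments SEs."""
        y = df["value"].to_numpy(float)
        entries = df["entry"].to_numpy()
        envs = df["env"].to_numpy()
        uniq_g, gi = np.unique(entries, return_inverse=True)
        uniq_e, ei = np.unique(envs, return_inverse=True)
        nG, nE = len(uniq_g), len(uniq_e)
        R = len(df) // (nG * nE)
        cell = np.zeros((nG, nE))
        np.add.at(cell, (gi, ei), y)
        cell /= R
        gmean = cell.mean(axis=1)
        emean = cell.mean(axis=0)
        grand = cell.mean()
        ss_g = nE * R * float(((gmean - grand) ** 2).sum())
        ss_ge = R * float(((cell - gmean[:, None] - emean[None, :] + grand) ** 2).sum())
        fitted_cell = cell[gi, ei]
        ss_err = float(((y - fitted_cell) ** 2).sum())
        df_g, df_ge, df_err = nG - 1, (nG - 1) * (nE - 1), nG * nE * (R - 1)
        ms_g = ss_g / df_g
        ms_ge = ss_ge / df_ge if df_ge > 0 else np.nan
        ms_err = ss_err / df_err if df_err > 0 else 0.0
        if df_ge == 0:  # single environment: gxe not separable, folded into error
            ms_ge = ms_err
        s2e = ms_err
        s2ge = max((ms_ge - ms_err) / R, 0.0) if df_ge > 0 else 0.0
        s2g = max((ms_g - ms_ge) / (nE * R), 0.0)
        truncated = ((ms_ge - ms_err) / R < 0 and df_ge > 0) or (ms_g - ms_ge) / (nE * R) < 0
        # Var(MS) = 2 MS^2 / df; components are linear in the mean squares
        var_ms = np.array(
            [
                2 * ms_g**2 / df_g,
                2 * ms_ge**2 / df_ge if df_ge > 0 else 0.0,
                2 * ms_err**2 / df_err if df_err > 0 else 0.0,
            ]
        )
        A = np.array(
            [
                [1.0 / (nE * R), -1.0 / (nE * R), 0.0],
                [0.0, 1.0 / R, -1.0 / R],
                [0.0, 0.0, 1.0],
            ]
        )
        cov = A @ np.diag(var_ms) @ A.T
        se = np.sqrt(np.diag(cov))
        ll = np.nan  # filled by caller if requested
        return VarianceComponents(
            sigma2_g=s2g, sigma2_gxe=s2ge, sigma2_eps=s2e, se=se, cov=cov,
            converged=True, loglik=ll, truncated=truncated,
        )

    def _iterative_fit(self, df: pd.DataFrame) -> VarianceComponents:
        X, Zg, Zge, _, _ = self._design(df)
        y = df["value"].to_numpy(float)
        vy = float(np.var(y, ddof=1))

        def nll(logtheta):
            s2g, s2ge, s2e = np.exp(logtheta)
            try:
                return -self._reml_loglik(y, X, Zg, Zge, s2g, s2ge, s2e)
            except np.linalg.LinAlgError:
                return 1e12

        x0 = np.log(np.array([vy / 2, vy / 4, vy / 2]) + 1e-8)
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        s2g, s2ge, s2e = np.exp(res.x)
        # numerical Hessian on the variance scale for delta-method SEs
        theta = np.array([s2g, s2ge, s2e])
        h = np.maximum(1e-4 * theta, 1e-8)
        H = np.zeros((3, 3))
        def f(t):
            return -self._reml_loglik(y, X, Zg, Zge, *np.maximum(t, 1e-12))
        f0 = f(theta)
        for i in range(3):
            for j in range(i, 3):
                ti = theta.copy(); ti[i] += h[i]
                tj = theta.copy(); tj[j] += h[j]
                tij = theta.copy(); tij[i] += h[i]; tij[j] += h[j]
                H[i, j] = H[j, i] = (f(tij) - f(ti) - f(tj) + f0) / (h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            cov = np.full((3, 3), np.nan)
            se = np.full(3, np.nan)
        return VarianceComponents(
            sigma2_g=float(s2g), sigma2_gxe=float(s2ge), sigma2_eps=float(s2e),
            se=se, cov=cov, converged=bool(res.success), loglik=float(-res.fun),
            truncated=False,
        )

    def fit(self, method: str = "auto") -> "TrialResults":
        comp = {}
        for popname in self.populations:
            sub = self.plots[self.plots["population"] == popname]
            balanced = self._is_balanced(sub)
            if method == "anova" or (method == "auto" and balanced):
                vc = self._anova_fit(sub)
            else:
                vc = self._iterative_fit(sub)
            comp[str(popname)] = vc
        blues = self._blues()
        E = self.plots["env"].nunique()
        R = int(round(len(self.plots) / (self.plots["entry"].nunique() * E)))
        return TrialResults(model=self, components=comp, blues=blues, n_env=E, n_rep=R)

    def _blues(self) -> pd.Series:
        """Fixed-genotype refit: BLUE per entry, env effects averaged out."""
        df = self.plots
        X, Zg, _, entries, envs = self._design(df)
        # design: [entry dummies | env dummies without last] -- full-rank
        D = np.hstack([Zg, X[:, :-1]])
        coef, *_ = np.linalg.lstsq(D, df["value"].to_numpy(float), rcond=None)
        entry_eff = coef[: len(entries)]
        env_eff = np.append(coef[len(entries):], 0.0)
        blue = entry_eff + env_eff.mean()
        return pd.Series(blue, index=pd.Index(entries, name="entry"), name="blue")


@dataclass
class TrialResults:
    """Variance components per population, BLUEs and heritabilities."""

    model: TrialModel
    components: dict  # population -> VarianceComponents
    blues: pd.Series
    n_env: int
    n_rep: int

    def heritability(self, population=None) -> tuple[float, float]:
        vc = self._vc(population)
        return entry_mean_heritability(
            (vc.sigma2_g, vc.sigma2_gxe, vc.sigma2_eps), self.n_env, self.n_rep, cov=vc.cov
        )

    def _vc(self, population=None) -> VarianceComponents:
        if population is None:
            if len(self.components) != 1:
                raise ValueError("specify a population")
            return next(iter(self.components.values()))
        return self.components[str(population)]

    def components_frame(self) -> pd.DataFrame:
        rows = []
        for popname, vc in self.components.items():
            h2, se_h2 = entry_mean_heritability(
                (vc.sigma2_g, vc.sigma2_gxe, vc.sigma2_eps), self.n_env, self.n_rep, cov=vc.cov
            )
            rows.append(
                {
                    "population": popname,
                    "sigma2_g": vc.sigma2_g,
                    "se_g": vc.se[0],
                    "sigma2_gxe": vc.sigma2_gxe,
                    "se_gxe": vc.se[1],
                    "sigma2_eps": vc.sigma2_eps,
                    "se_eps": vc.se[2],
                    "h2": h2,
                    "se_h2": se_h2,
                    "g_significant": significance_by_2se(vc.sigma2_g, vc.se[0]),
                    "converged": vc.converged,
                    "truncated": vc.truncated,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.components_frame()
        lines = ["Trial mixed-model fit (genotype random, environment fixed)",
                 f"environments: {self.n_env}, replicates: {self.n_rep}, entries: {len(self.blues)}",
                 ""]
        lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)


def entry_mean_heritability(components, E: int, R: int, cov=None) -> tuple[float, float]:
    """h2 on an entry-mean basis with a delta-method SE.

    ``components`` is (sigma2_g, sigma2_gxe, sigma2_eps); ``cov`` their 3x3
    covariance matrix (SE is nan without it).
    """
    if E < 1 or R < 1:
        raise ValueError("E and R must be >= 1")
    s2g, s2ge, s2e = map(float, components)
    denom = s2g + s2ge / E + s2e / (E * R)
    if denom == 0:
        raise ValueError("all variance components are zero; h2 undefined")
    h2 = s2g / denom
    if cov is None:
        return h2, float("nan")
    grad = np.array(
        [(denom - s2g) / denom**2, -s2g / (E * denom**2), -s2g / (E * R * denom**2)]
    )
    var = float(grad @ np.asarray(cov) @ grad)
    return h2, float(np.sqrt(max(var, 0.0)))


def significance_by_2se(estimate: float, se: float) -> bool:
    """True iff the estimate exceeds twice its standard error."""
    if se < 0:
        raise ValueError("SE must be >= 0")
    return bool(estimate > 2.0 * se)


def pp_tp_genetic_correlation(
    blues_pp: pd.Series, blues_tp: pd.Series, h2_pp: float | None = None, h2_tp: float | None = None
) -> dict:
    """Correlation of estimated genetic values for PP and TP on common entries.

    Optionally attenuation-corrected by 1/sqrt(h2_pp * h2_tp), clipped to
    [-1, 1].  This replaces a bivariate REML genetic-covariance model with
    the correlation of the univariate BLUEs.
    """
    common = blues_pp.index.intersection(blues_tp.index)
    if len(common) < 3:
        raise ValueError("need at least 3 common entries")
    x = blues_pp.loc[common].to_numpy(float)
    y = blues_tp.loc[common].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in BLUEs")
    r = float(np.corrcoef(x, y)[0, 1])
    out = {"r": r, "n": int(len(common))}
    if h2_pp is not None and h2_tp is not None:
        out["r_corrected"] = float(np.clip(r / np.sqrt(h2_pp * h2_tp), -1.0, 1.0))
    return out
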