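"""Genomic prediction: VanRaden relationship matrix, REML GBLUP and the
cross-validation scenario engine.

The model is y = 1 mu + Z u + e with u ~ N(0, U sigma2_g), e ~ N(0, I
sigma2_e), where U is the realized relationship matrix from marker data
(VanRaden method 1) computed over all genotypes treated as one population.
REML is profiled over the variance ratio on the spectral decomposition of
U, which makes every fit a cheap 1-D optimization; the significance of the
genomic variance is assessed by a likelihood-ratio test against the
variance-free null model.

Prediction accuracy follows the convention rho = cor(observed phenotype,
predicted genetic value) / sqrt(h2 of the prediction set); rho can exceed 1
by sampling noise and is deliberately not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

__all__ = [
    "vanraden_g",
    "GBLUP",
    "GBLUPResults",
    "predict_unphenotyped",
    "prediction_accuracy",
    "CVResult",
    "cv_within",
    "cv_across",
    "cv_combined",
]


def vanraden_g(marker_matrix, allele_freqs=None) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    ``marker_matrix`` holds 0/1/2 allele counts (entries x markers);
    ``allele_freqs`` defaults to the frequencies of the supplied entry set
    (the all-genotypes-as-one-population convention).  Monomorphic markers
    are dropped.  U = W W' / (2 sum p_j (1 - p_j)) with W the column-centred
    dose matrix.
    """
    M = np.asarray(marker_matrix, dtype=float)
    p = M.mean(axis=0) / 2.0 if allele_freqs is None else np.asarray(allele_freqs, dtype=float)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic")
    W = M[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    return (W @ W.T) / denom


@dataclass
class GBLUPResults:
    """REML fit of the GBLUP model on the training entries."""

    mu: float
    sigma2_g: float
    sigma2_e: float
    u: np.ndarray  # shrunken genetic values of training entries
    loglik: float  # restricted log-likelihood at the optimum
    loglik_null: float  # restricted log-likelihood with sigma2_g = 0
    converged: bool
    model: "GBLUP" = field(repr=False, default=None)

    @property
    def lam(self) -> float:
        """Variance ratio lambda = sigma2_e / sigma2_g (inf when sigma2_g=0)."""
        return self.sigma2_e / self.sigma2_g if self.sigma2_g > 0 else float("inf")

    @property
    def lrt_pvalue(self) -> float:
        """LRT p-value for sigma2_g > 0 against chi2(1)."""
        stat = max(2.0 * (self.loglik - self.loglik_null), 0.0)
        return float(chi2.sf(stat, df=1))

    @property
    def lrt_pvalue_boundary(self) -> float:
        """Boundary-corrected p-value from the 0.5 chi2(0) : 0.5 chi2(1) mixture."""
        stat = max(2.0 * (self.loglik - self.loglik_null), 0.0)
        return float(0.5 * chi2.sf(stat, df=1)) if stat > 0 else 1.0

    def predict(self, U_full: np.ndarray, training_ids, prediction_ids) -> np.ndarray:
        return predict_unphenotyped(self, U_full, training_ids, prediction_ids)

    def summary(self) -> str:
        return (
            "GBLUP REML fit\n"
            f"  n training entries : {len(self.u)}\n"
            f"  mu                 : {self.mu:.4f}\n"
            f"  sigma2_g           : {self.sigma2_g:.4f}\n"
            f"  sigma2_e           : {self.sigma2_e:.4f}\n"
            f"  restricted loglik  : {self.loglik:.4f}\n"
            f"  LRT p (sigma2_g>0) : {self.lrt_pvalue:.4g}\n"
            f"  converged          : {self.converged}"
        )


class GBLUP:
    """GBLUP model for a vector of entry BLUEs and a relationship matrix.

    ``y`` are training phenotypes (BLUEs) and ``U`` the matching square
    relationship matrix.  ``fit`` profiles the restricted likelihood over
    the ratio gamma = sigma2_g / sigma2_e on the spectrum of U.
    """

    def __init__(self, y, U):
        self.y = np.asarray(y, dtype=float)
        self.U = np.asarray(U, dtype=float)
        n = len(self.y)
        if self.U.shape != (n, n):
            raise ValueError("U must be square and match y")
        # spectral decomposition once per model
        d, Q = np.linalg.eigh(self.U)
        self._d = np.maximum(d, 0.0)
        self._Q = Q
        self._z = Q.T @ self.y
        self._x = Q.T @ np.ones(n)
        self._n = n

    def _profile(self, gamma: float):
        """Profiled REML pieces at ratio gamma = sigma2_g / sigma2_e."""
        w = gamma * self._d + 1.0  # V = sigma2_e * diag(w)
        xwx = float(np.sum(self._x**2 / w))
        beta = float(np.sum(self._x * self._z / w) / xwx)
        resid2 = float(np.sum((self._z - beta * self._x) ** 2 / w))
        s2e = resid2 / (self._n - 1)
        ll = -0.5 * (
            float(np.sum(np.log(w)))
            + (self._n - 1) * np.log(s2e)
            + np.log(xwx)
            + (self._n - 1)
        )
        return ll, beta, s2e

    def loglik(self, sigma2_g: float, sigma2_e: float) -> float:
        """Restricted log-likelihood at explicit variance components."""
        w = sigma2_g * self._d + sigma2_e
        xwx = float(np.sum(self._x**2 / w))
        beta = float(np.sum(self._x * self._z / w) / xwx)
        quad = float(np.sum((self._z - beta * self._x) ** 2 / w))
        return -0.5 * (float(np.sum(np.log(w))) + np.log(xwx) + quad)

    def fit(self, log10_gamma_bounds=(-8.0, 8.0)) -> GBLUPResults:
        if np.var(self.y) == 0:
            # degenerate: no variance at all; logliks set equal so the LRT is null
            return GBLUPResults(
                mu=float(self.y[0]), sigma2_g=0.0, sigma2_e=0.0, u=np.zeros(self._n),
                loglik=0.0, loglik_null=0.0, converged=True, model=self,
            )

        def neg(l10g):
            return -self._profile(10.0**l10g)[0]

        res = minimize_scalar(
            neg, bounds=log10_gamma_bounds, method="bounded",
            options={"xatol": 1e-10},
        )
        gamma = 10.0 ** float(res.x)
        ll, beta, s2e = self._profile(gamma)
        ll0 = self._profile(0.0)[0]
        if ll0 >= ll:  # boundary optimum: no genomic variance
            gamma, ll = 0.0, ll0
            _, beta, s2e = self._profile(0.0)
        s2g = gamma * s2e
        # BLUP of training entries: u = s2g U V^-1 (y - mu)
        if s2g > 0:
            # u = s2g U V^-1 (y - mu); V^-1 (y - mu) in the eigenbasis is zc / (s2e w)
            w = gamma * self._d + 1.0
            zc = self._z - beta * self._x
            u = s2g * (self.U @ (self._Q @ (zc / (s2e * w))))
        else:
            u = np.zeros(self._n)
        return GBLUPResults(
            mu=beta, sigma2_g=float(s2g), sigma2_e=float(s2e), u=u,
            loglik=float(ll), loglik_null=float(ll0),
            converged=bool(res.success), model=self,
        )


def predict_unphenotyped(fit: GBLUPResults, U_full, training_ids, prediction_ids) -> np.ndarray:
    """Predict genetic values of unphenotyped entries.

    u_pred = U[pred, train] (U[train, train] + lambda I)^-1 (y - mu), with
    lambda = sigma2_e / sigma2_g.  Training and prediction sets must be
    disjoint; a tiny ridge is added (and noted on the fit) if the training
    block is numerically singular.
    """
    U_full = np.asarray(U_full, dtype=float)
    tr = np.asarray(training_ids)
    pr = np.asarray(prediction_ids)
    if np.intersect1d(tr, pr).size:
        raise ValueError("prediction entries must be disjoint from training entries")
    if fit.sigma2_g <= 0:
        return np.zeros(len(pr))
    lam = fit.lam
    Utt = U_full[np.ix_(tr, tr)]
    Upt = U_full[np.ix_(pr, tr)]
    resid = fit.model.y - fit.mu
    A = Utt + lam * np.eye(len(tr))
    try:
        sol = np.linalg.solve(A, resid)
    except np.linalg.LinAlgError:
        sol = np.linalg.solve(A + 1e-8 * np.eye(len(tr)), resid)
    return Upt @ sol


def prediction_accuracy(predicted, observed, h2_prediction_set: float) -> float:
    """rho = cor(observed, predicted) / sqrt(h2).  NaN if either is constant."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if len(pred) < 3:
        raise ValueError("need at least 3 pairs")
    if not 0 < h2_prediction_set <= 1:
        raise ValueError("h2 must be in (0, 1]")
    if np.std(pred) == 0 or np.std(obs) == 0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1] / np.sqrt(h2_prediction_set))


@dataclass
class CVResult:
    """Outcome of a genomic-prediction scenario.

    ``accuracies`` holds one rho per replicate unit (NaN = non-converged /
    undefined, never dropped); ``nonsignificant`` flags replicates whose
    training fit had a non-significant genomic variance (LRT P > 0.05).
    """

    scenario: dict
    accuracies: np.ndarray
    nonsignificant: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.accuracies)) if np.any(~np.isnan(self.accuracies)) else float("nan")

    @property
    def quantiles(self) -> tuple[float, float]:
        ok = self.accuracies[~np.isnan(self.accuracies)]
        if ok.size == 0:
            return float("nan"), float("nan")
        return float(np.quantile(ok, 0.025)), float(np.quantile(ok, 0.975))

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.accuracies).sum())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"replicate": np.arange(len(self.accuracies)), "rho": self.accuracies,
             "nonsignificant": self.nonsignificant}
        )

    def summary_row(self) -> dict:
        lo, hi = self.quantiles
        return {
            **self.scenario,
            "mean_rho": self.mean,
            "q2.5": lo,
            "q97.5": hi,
            "n_missing": self.n_missing,
            "n_nonsignificant": int(self.nonsignificant.sum()),
            "n_replicates": len(self.accuracies),
        }


def _one_cv_round(y, U, h2, folds: int, rng) -> tuple[float, bool]:
    """One round of k-fold CV: pooled predictions vs observed, one rho."""
    n = len(y)
    perm = rng.permutation(n)
    pred = np.full(n, np.nan)
    nonsig = False
    ok = True
    for k in range(folds):
        test = perm[k::folds]
        train = np.setdiff1d(perm, test)
        fit = GBLUP(y[train], U[np.ix_(train, train)]).fit()
        if not fit.converged:
            ok = False
            continue
        if fit.lrt_pvalue > 0.05:
            nonsig = True
        pred[test] = predict_unphenotyped(fit, U, train, test)
    if not ok or np.isnan(pred).any():
        return float("nan"), nonsig
    return prediction_accuracy(pred, y, h2), nonsig


def cv_within(
    y,
    marker_matrix,
    h2: float,
    n_lines: int | None = None,
    n_markers: int | None = None,
    reps: int = 100,
    cv_repeats: int = 10,
    folds: int = 5,
    seed=None,
) -> CVResult:
    """Within-population cross-validation (N-curves and M-curves).

    Per outer replicate, ``n_lines`` entries are sampled without
    replacement (or ``n_markers`` markers for the marker-density curve),
    then ``cv_repeats`` x ``folds``-fold CV is run; each CV repetition
    contributes one rho (pooled over folds).  Defaults: 10x5-fold CV,
    100 sampling replicates.
    """
    y = np.asarray(y, dtype=float)
    M = np.asarray(marker_matrix, dtype=float)
    n_total = len(y)
    n_use = n_total if n_lines is None else n_lines
    if n_use < 10:
        raise ValueError("need at least 10 lines for 5-fold cross-validation")
    if n_use > n_total:
        raise ValueError("n_lines exceeds the population size")
    rng = np.random.default_rng(seed)
    accs, nonsigs = [], []
    for _ in range(reps):
        lines = rng.choice(n_total, size=n_use, replace=False) if n_lines is not None else np.arange(n_total)
        cols = (
            rng.choice(M.shape[1], size=n_markers, replace=False)
            if n_markers is not None
            else slice(None)
        )
        U = vanraden_g(M[lines][:, cols])
        ysub = y[lines]
        for _ in range(cv_repeats):
            rho, nonsig = _one_cv_round(ysub, U, h2, folds, rng)
            accs.append(rho)
            nonsigs.append(nonsig)
    return CVResult(
        scenario={
            "type": "within",
            "n_lines": n_use,
            "n_markers": M.shape[1] if n_markers is None else n_markers,
            "reps": reps,
            "cv": f"{cv_repeats}x{folds}-fold",
        },
        accuracies=np.array(accs),
        nonsignificant=np.array(nonsigs),
    )


def cv_across(
    y_train,
    markers_train,
    y_predict,
    markers_predict,
    h2_predict: float,
    n_train: int = 200,
    n_predict: int = 50,
    reps: int = 100,
    seed=None,
    same_population: bool = False,
    scenario_label: str = "across",
) -> CVResult:
    """Across-population (or across-landrace) prediction.

    Per replicate, ``n_train`` entries are sampled from the training
    population and ``n_predict`` from the prediction population; with
    ``same_population=True`` the two samples are drawn disjoint from one
    population.  Defaults N=200/50 (per se) -- use 75/25 for testcross
    scenarios.  The relationship matrix is built per replicate over the
    union of the sampled entries, treating them as one population.
    """
    y_tr = np.asarray(y_train, float)
    M_tr = np.asarray(markers_train, float)
    y_pr = np.asarray(y_predict, float)
    M_pr = np.asarray(markers_predict, float)
    rng = np.random.default_rng(seed)
    if same_population and (y_tr is not y_predict) and len(y_tr) < n_train + n_predict:
        raise ValueError("population too small for disjoint train/prediction samples")
    accs, nonsigs = [], []
    for _ in range(reps):
        if same_population:
            perm = rng.permutation(len(y_tr))
            tr_idx, pr_idx = perm[:n_train], perm[n_train : n_train + n_predict]
            Mtr, Mpr = M_tr[tr_idx], M_tr[pr_idx]
            ytr, ypr = y_tr[tr_idx], y_tr[pr_idx]
        else:
            tr_idx = rng.choice(len(y_tr), size=n_train, replace=False)
            pr_idx = rng.choice(len(y_pr), size=n_predict, replace=False)
            Mtr, Mpr = M_tr[tr_idx], M_pr[pr_idx]
            ytr, ypr = y_tr[tr_idx], y_pr[pr_idx]
        U = vanraden_g(np.vstack([Mtr, Mpr]))
        fit = GBLUP(ytr, U[: n_train, : n_train]).fit()
        if not fit.converged:
            accs.append(float("nan"))
            nonsigs.append(False)
            continue
        nonsigs.append(fit.lrt_pvalue > 0.05)
        pred = predict_unphenotyped(
            fit, U, np.arange(n_train), np.arange(n_train, n_train + n_predict)
        )
        accs.append(prediction_accuracy(pred, ypr, h2_predict))
    return CVResult(
        scenario={
            "type": scenario_label,
            "n_train": n_train,
            "n_predict": n_predict,
            "reps": reps,
        },
        accuracies=np.array(accs),
        nonsignificant=np.array(nonsigs),
    )


def cv_combined(
    populations: dict,
    h2: dict,
    n_train_each: int | None = None,
    n_predict: int = 50,
    reps: int = 100,
    seed=None,
) -> pd.DataFrame:
    """Pooled-training prediction with within-population baselines.

    ``populations`` maps name -> (y, marker_matrix); ``h2`` maps name ->
    entry-mean heritability of the prediction population.  For each
    population, a prediction sample is held out, the model is trained
    either on the remaining entries of the same population (baseline) or on
    those plus a sample of every other population (combined), and both
    mean accuracies are reported.
    """
    if len(populations) < 2:
        raise ValueError("need at least 2 populations")
    rng = np.random.default_rng(seed)
    rows = []
    names = list(populations)
    for target in names:
        y_t, M_t = populations[target]
        y_t = np.asarray(y_t, float)
        M_t = np.asarray(M_t, float)
        base_acc, comb_acc = [], []
        for _ in range(reps):
            perm = rng.permutation(len(y_t))
            pr = perm[:n_predict]
            tr_own = perm[n_predict:]
            if n_train_each is not None:
                tr_own = tr_own[:n_train_each]
            blocks_y = [y_t[tr_own]]
            blocks_M = [M_t[tr_own]]
            for other in names:
                if other == target:
                    continue
                y_o, M_o = populations[other]
                y_o = np.asarray(y_o, float)
                M_o = np.asarray(M_o, float)
                k = len(tr_own) if n_train_each is None else n_train_each
                idx = rng.choice(len(y_o), size=min(k, len(y_o)), replace=False)
                blocks_y.append(y_o[idx])
                blocks_M.append(M_o[idx])
            # baseline: own training only
            for label, ys, Ms in (
                ("baseline", [blocks_y[0]], [blocks_M[0]]),
                ("combined", blocks_y, blocks_M),
            ):
                ytr = np.concatenate(ys)
                Mtr = np.vstack(Ms)
                U = vanraden_g(np.vstack([Mtr, M_t[pr]]))
                ntr = len(ytr)
                fit = GBLUP(ytr, U[:ntr, :ntr]).fit()
                if not fit.converged:
                    acc = float("nan")
                else:
                    pred = predict_unphenotyped(
                        fit, U, np.arange(ntr), np.arange(ntr, ntr + len(pr))
                    )
                    acc = prediction_accuracy(pred, y_t[pr], h2[target])
                (base_acc if label == "baseline" else comb_acc).append(acc)
        rows.append(
            {
                "population": target,
                "mean_rho_baseline": float(np.nanmean(base_acc)),
                "mean_rho_combined": float(np.nanmean(comb_acc)),
                "n_predict": n_predict,
                "reps": reps,
            }
        )
    return pd.DataFrame(rows)
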