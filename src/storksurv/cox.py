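"""Stratified Cox proportional-hazards regression, written from scratch.

The partial likelihood uses the Efron correction for tied event times
(Breslow available by flag) and is maximised by Newton-Raphson with
step-halving; convergence requires the infinity-norm of the score to
drop below 1e-8.  Stratification (one baseline hazard per stratum,
shared coefficients) simply sums the per-stratum partial likelihoods.

For a stratum with ordered distinct event times, let ``R`` be the risk
set and ``D`` the deaths (size ``d``) at one event time.  The Efron
contribution to the log partial likelihood is

    sum_{i in D} eta_i  -  sum_{j=0}^{d-1} log( S_R - (j/d) S_D )

with ``eta = X beta`` and ``S_A = sum_{i in A} exp(eta_i)``; gradient
and Hessian follow by differentiating the same expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignInfo, build_design

__all__ = ["CoxPH", "CoxPHResults", "cox_fit", "model_r2"]

_SEPARATION_BOUND = 15.0


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# partial likelihood kernels


@dataclass
class _StratumData:
    """One stratum, sorted by ascending time, with tie groups resolved."""

    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    # per distinct event time: slice of tied deaths and start of risk set
    death_groups: list  # (risk_start, death_idx array)

    @classmethod
    def from_arrays(cls, X, time, event):
        order = np.lexsort((1 - event, time))  # deaths before censorings at ties
        X, time, event = X[order], time[order], event[order]
        groups = []
        for t in np.unique(time[event == 1]):
            risk_start = int(np.searchsorted(time, t, side="left"))
            didx = np.flatnonzero((time == t) & (event == 1))
            groups.append((risk_start, didx))
        return cls(X=X, time=time, event=event, death_groups=groups)


def _loglik_grad_hess(strata: list, beta: np.ndarray, ties: str = "efron",
                      order: int = 2):
    """Log partial likelihood and derivatives, summed over strata."""
    p = len(beta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for st in strata:
        eta = st.X @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        wX = st.X * w[:, None]
        # suffix sums over the ascending-time ordering
        S = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
        Z = np.vstack([np.cumsum(wX[::-1], axis=0)[::-1], np.zeros(p)])
        if order >= 2:
            wXX = np.einsum("ij,ik->ijk", st.X, wX)
            Q = np.concatenate(
                [np.cumsum(wXX[::-1], axis=0)[::-1], np.zeros((1, p, p))]
            )
        for risk_start, didx in st.death_groups:
            d = len(didx)
            S_R = S[risk_start]
            Z_R = Z[risk_start]
            S_D = w[didx].sum()
            Z_D = wX[didx].sum(axis=0)
            ll += eta[didx].sum()
            if order >= 1:
                grad += st.X[didx].sum(axis=0)
            if order >= 2:
                Q_R = Q[risk_start]
                Q_D = wXX[didx].sum(axis=0)
            if ties == "breslow":
                fracs = np.zeros(d)
            else:
                fracs = np.arange(d) / d
            for f in fracs:
                phi = S_R - f * S_D
                ll -= np.log(phi)
                if order >= 1:
                    zeta = (Z_R - f * Z_D) / phi
                    grad -= zeta
                if order >= 2:
                    hess -= (Q_R - f * Q_D) / phi - np.outer(zeta, zeta)
    return ll, grad, hess


def _schoenfeld_residuals(strata: list, beta: np.ndarray, ties: str = "efron"):
    """Per-death Schoenfeld residuals x_i - xbar(t_i), with event times.

    At a tied event time the Efron risk-set mean is averaged over the
    tie fractions, and each of the ``d`` deaths receives the residual
    against that averaged mean, so the residual sum equals the score.
    """
    res, times = [], []
    p = strata[0].X.shape[1]
    for st in strata:
        eta = np.clip(st.X @ beta, -500, 500)
        w = np.exp(eta)
        wX = st.X * w[:, None]
        S = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
        Z = np.vstack([np.cumsum(wX[::-1], axis=0)[::-1], np.zeros(p)])
        for risk_start, didx in st.death_groups:
            d = len(didx)
            S_R, Z_R = S[risk_start], Z[risk_start]
            S_D, Z_D = w[didx].sum(), wX[didx].sum(axis=0)
            fracs = np.zeros(d) if ties == "breslow" else np.arange(d) / d
            zbar = np.mean(
                [(Z_R - f * Z_D) / (S_R - f * S_D) for f in fracs], axis=0
            )
            for i in didx:
                res.append(st.X[i] - zbar)
                times.append(st.time[i])
    order = np.argsort(times, kind="stable")
    return np.asarray(res)[order], np.asarray(times)[order]


# ---------------------------------------------------------------------------
# model / results


class CoxPH:
    """Cox proportional-hazards model on a stage survival table.

    Parameters
    ----------
    data : DataFrame
        One row per individual with duration, event flag, covariates and
        (optionally) a stratum column.
    terms : list of str
        Model terms in the small term language of :mod:`storksurv.design`
        (linear columns, ``C(x)``, ``rcs(x)``, products ``a:rcs(b)``).
    duration_col, event_col, strata_col : str
        Column names; ``strata_col=None`` fits a single baseline hazard.
    ties : {"efron", "breslow"}
    """

    def __init__(self, data: pd.DataFrame, terms, duration_col="time_days",
                 event_col="event", strata_col=None, ties="efron"):
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.data = data.reset_index(drop=True)
        self.terms = list(terms)
        self.duration_col = duration_col
        self.event_col = event_col
        self.strata_col = strata_col
        self.ties = ties

        X, info = build_design(self.data, self.terms)
        row_ok = np.isfinite(X).all(axis=1) if X.size else np.ones(
            len(self.data), dtype=bool)
        if not row_ok.all():
            warnings.warn(
                f"dropped {int((~row_ok).sum())} row(s) with missing "
                "covariate values")
            self.data = self.data[row_ok].reset_index(drop=True)
            X, info = build_design(self.data, self.terms)
        if int(self.data[event_col].sum()) == 0:
            raise ValueError("no events in the data; Cox model undefined")
        keep = X.std(axis=0) > 0
        if not keep.all():
            dropped = [n for n, k in zip(info.column_names, keep) if not k]
            warnings.warn(f"constant covariate column(s) excluded: {dropped}")
        self.exog = X[:, keep]
        self.exog_names = [n for n, k in zip(info.column_names, keep) if k]
        self.exog_groups = [g for g, k in zip(info.groups, keep) if k]
        self.design_info: DesignInfo = info
        self._keep = keep
        self._strata = self._split_strata(self.exog)

    from_dataframe = classmethod(
        lambda cls, data, terms, **kw: cls(data, terms, **kw)
    )

    def _split_strata(self, X):
        t = self.data[self.duration_col].to_numpy(float)
        e = self.data[self.event_col].to_numpy(int)
        if self.strata_col is None:
            return [_StratumData.from_arrays(X, t, e)]
        out = []
        for _, idx in self.data.groupby(self.strata_col).groups.items():
            idx = np.asarray(idx)
            if e[idx].sum() == 0:
                continue  # stratum with no events contributes nothing
            out.append(_StratumData.from_arrays(X[idx], t[idx], e[idx]))
        return out

    def loglik(self, beta) -> float:
        beta = np.asarray(beta, dtype=float)
        ll, _, _ = _loglik_grad_hess(self._strata, beta, self.ties, order=0)
        return ll

    def fit(self, max_iter: int = 50, tol: float = 1e-8) -> "CoxPHResults":
        p = self.exog.shape[1]
        beta = np.zeros(p)
        if p == 0:  # null model: partial likelihood has no free parameters
            ll, _, _ = _loglik_grad_hess(self._strata, beta, self.ties, 0)
            return CoxPHResults(model=self, params=beta,
                                cov=np.zeros((0, 0)), loglik=ll,
                                loglik_null=ll, converged=True,
                                separation=False)
        ll, grad, hess = _loglik_grad_hess(self._strata, beta, self.ties)
        ll_null = ll
        converged = False
        for _ in range(max_iter):
            if np.max(np.abs(grad)) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
            # step-halving on partial-likelihood decrease
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new, g_new, h_new = _loglik_grad_hess(
                    self._strata, cand, self.ties
                )
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                scale /= 2.0
            beta, ll, grad, hess = cand, ll_new, g_new, h_new
        else:
            if np.max(np.abs(grad)) < tol:
                converged = True
        separation = bool(np.any(np.abs(beta) > _SEPARATION_BOUND))
        if separation:
            warnings.warn(
                "monotone partial likelihood suspected (|beta| > 15); "
                "estimates unreliable", ConvergenceWarning,
            )
        if not converged and not separation:
            warnings.warn("Newton iterations did not converge",
                          ConvergenceWarning)
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-hess)
        return CoxPHResults(
            model=self, params=beta, cov=cov, loglik=ll, loglik_null=ll_null,
            converged=converged, separation=separation,
        )

    def fit_regularized(self, alpha: float = 0.5, lambdas=None, n_lambdas=50,
                        cv_folds: int = 10, seed: int = 0):
        from .enet import CoxnetPath

        return CoxnetPath.fit(self, alpha=alpha, lambdas=lambdas,
                              n_lambdas=n_lambdas, cv_folds=cv_folds,
                              seed=seed)


class CoxPHResults:
    """Fitted Cox model: coefficients, tests, fit indices, predictions."""

    def __init__(self, model, params, cov, loglik, loglik_null, converged,
                 separation):
        self.model = model
        self.params = pd.Series(params, index=model.exog_names, name="coef")
        self.cov = pd.DataFrame(cov, index=model.exog_names,
                                columns=model.exog_names)
        self.loglik = float(loglik)
        self.loglik_null = float(loglik_null)
        self.converged = converged
        self.separation = separation
        self.n = len(model.data)
        self.n_events = int(model.data[model.event_col].sum())

    # -- inference ---------------------------------------------------------

    @property
    def bse(self) -> pd.Series:
        # a degenerate (non-PSD) Hessian leaves NaN standard errors
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(self.cov.to_numpy()))
        return pd.Series(se, index=self.params.index, name="se")

    @property
    def df_model(self) -> int:
        return len(self.params)

    @property
    def lr_statistic(self) -> float:
        return max(2.0 * (self.loglik - self.loglik_null), 0.0)

    @property
    def lr_pvalue(self) -> float:
        if self.df_model == 0:
            return 1.0
        return float(stats.chi2.sf(self.lr_statistic, self.df_model))

    @property
    def wald_z(self) -> pd.Series:
        return self.params / self.bse

    @property
    def wald_pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.wald_z)),
                         index=self.params.index, name="p")

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params).rename("HR")

    @property
    def r_squared(self) -> float:
        """Nagelkerke-style explained-variation index.

        ``(1 - exp(-LR/n)) / (1 - exp(2 loglik_null / n))`` with ``n``
        the number of observations.
        """
        n = self.n
        if self.df_model == 0:
            return 0.0
        num = 1.0 - np.exp(-self.lr_statistic / n)
        den = 1.0 - np.exp(2.0 * self.loglik_null / n)
        return float(num / den) if den > 0 else 0.0

    @property
    def r_squared_coxsnell(self) -> float:
        """Unscaled (Cox-Snell style) variant, ``1 - exp(-LR/n)``."""
        return float(1.0 - np.exp(-self.lr_statistic / self.n))

    def wald_table(self) -> pd.DataFrame:
        """Group (per-term) Wald chi-square tests."""
        rows = []
        for ti, term in enumerate(self.model.terms):
            cols = [n for n, g in zip(self.model.exog_names,
                                      self.model.exog_groups) if g == ti]
            if not cols:
                continue
            b = self.params[cols].to_numpy()
            V = self.cov.loc[cols, cols].to_numpy()
            chi2 = float(b @ np.linalg.solve(V, b))
            df = len(cols)
            rows.append({"term": term, "chi2": chi2, "df": df,
                         "p": float(stats.chi2.sf(chi2, df))})
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                "se": self.bse,
                "z": self.wald_z,
                "p": self.wald_pvalues,
            }
        )
        tab.attrs["loglik"] = self.loglik
        tab.attrs["lr_statistic"] = self.lr_statistic
        tab.attrs["lr_pvalue"] = self.lr_pvalue
        tab.attrs["df"] = self.df_model
        tab.attrs["r_squared"] = self.r_squared
        tab.attrs["n"] = self.n
        tab.attrs["n_events"] = self.n_events
        return tab

    def to_report(self) -> dict:
        """JSON-ready model report."""
        return {
            "terms": self.model.terms,
            "coef": self.params.to_dict(),
            "se": self.bse.to_dict(),
            "hazard_ratio": self.hazard_ratios.to_dict(),
            "wald_p": self.wald_pvalues.to_dict(),
            "loglik": self.loglik,
            "loglik_null": self.loglik_null,
            "lr_statistic": self.lr_statistic,
            "lr_pvalue": self.lr_pvalue,
            "df": self.df_model,
            "r_squared": self.r_squared,
            "r_squared_coxsnell": self.r_squared_coxsnell,
            "n": self.n,
            "n_events": self.n_events,
            "converged": self.converged,
        }

    # -- residuals / diagnostics --------------------------------------------

    def schoenfeld_residuals(self):
        return _schoenfeld_residuals(self.model._strata,
                                     self.params.to_numpy(), self.model.ties)

    def check_proportional_hazards(self, transform: str = "km"):
        from .diagnostics import schoenfeld_test

        return schoenfeld_test(self, transform=transform)

    # -- adjusted effect curves ---------------------------------------------

    def predict_log_relative_hazard(self, focus: str, grid=None,
                                    n_grid: int = 100,
                                    conf_level: float = 0.95) -> pd.DataFrame:
        """Adjusted log relative hazard along one covariate.

        Other covariates are held at their sample means (reference level
        for categoricals); the curve is centred at the focus covariate's
        median (reference level if categorical).  The confidence band is
        the delta-method interval on the centred linear predictor.
        """
        model = self.model
        data = model.data
        col = _focus_column(model.terms, focus)
        if col is None:
            raise ValueError(f"focus {focus!r} not found among model terms")
        series = data[col]
        categorical = series.dtype == object or isinstance(
            series.dtype, pd.CategoricalDtype)
        base = {}
        for c in data.columns:
            if data[c].dtype == object or isinstance(data[c].dtype,
                                                     pd.CategoricalDtype):
                base[c] = sorted(data[c].dropna().unique().tolist())[0]
            elif np.issubdtype(data[c].dtype, np.number):
                base[c] = float(data[c].mean())
            else:
                base[c] = data[c].iloc[0]
        if categorical:
            values = sorted(series.dropna().unique().tolist())
            ref_value = values[0]
        else:
            if grid is None:
                lo, hi = np.quantile(series.to_numpy(float), [0.05, 0.95])
                values = np.linspace(lo, hi, n_grid)
            else:
                values = np.asarray(grid, dtype=float)
            ref_value = float(np.median(series.to_numpy(float)))
        rows = pd.DataFrame([dict(base, **{col: v}) for v in values])
        ref = pd.DataFrame([dict(base, **{col: ref_value})])
        Xg = model.design_info.transform(rows)[:, model._keep]
        Xr = model.design_info.transform(ref)[:, model._keep]
        D = Xg - Xr
        beta = self.params.to_numpy()
        V = self.cov.to_numpy()
        eta = D @ beta
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, V, D), 0.0))
        z = stats.norm.ppf(0.5 + conf_level / 2.0)
        return pd.DataFrame(
            {col: values, "log_rel_hazard": eta,
             "ci_lo": eta - z * se, "ci_hi": eta + z * se}
        )

    def plot_partial_effect(self, focus: str, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        curve = self.predict_log_relative_hazard(focus, **kwargs)
        if ax is None:
            _, ax = plt.subplots()
        xcol = curve.columns[0]
        ax.plot(curve[xcol], curve["log_rel_hazard"], color="k")
        ax.fill_between(curve[xcol], curve["ci_lo"], curve["ci_hi"],
                        alpha=0.25, color="gray")
        ax.set_xlabel(xcol)
        ax.set_ylabel("log relative hazard")
        return ax


def _focus_column(terms, focus: str):
    """Map a focus name (column or term) to its underlying data column."""
    import re

    for term in terms:
        for part in term.split(":"):
            part = part.strip()
            m = re.match(r"^(?:rcs|C)\(\s*([^,()\s]+)", part)
            name = m.group(1) if m else part
            if focus in (term, part, name):
                return name
    return None


def cox_fit(data, terms, duration_col="time_days", event_col="event",
            strata_col=None, ties="efron") -> CoxPHResults:
    """Functional wrapper: build and fit a :class:`CoxPH` in one call."""
    return CoxPH(data, terms, duration_col=duration_col, event_col=event_col,
                 strata_col=strata_col, ties=ties).fit()


def model_r2(fit: CoxPHResults) -> float:
    """Explained-variation index of a fitted Cox model (see results)."""
    return fit.r_squared
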