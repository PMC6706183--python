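"""Kaplan-Meier product-limit estimation with Greenwood confidence bands.

Implemented from first principles: at each distinct event time ``t_i``
with ``d_i`` deaths among ``n_i`` at risk, the survival estimate is

    S(t) = prod_{t_i <= t} (1 - d_i / n_i)

with Greenwood's variance ``S(t)^2 * sum d_i / (n_i (n_i - d_i))`` and a
95% interval on the log scale, ``S * exp(+/- 1.96 * se(log S))``.  The
median survival time is the smallest event time with ``S(t) <= 0.5``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["KaplanMeier", "KaplanMeierResults", "km_fit"]


class KaplanMeier:
    """Product-limit survival model for right-censored durations.

    Parameters
    ----------
    times : array-like of float
        Positive follow-up durations.
    events : array-like of {0, 1}
        1 if the duration ends in a death, 0 if censored.
    """

    def __init__(self, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if times.shape != events.shape:
            raise ValueError("times and events must have equal length")
        if len(times) and times.min() <= 0:
            raise ValueError("durations must be positive")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("events must be 0 or 1")
        self.times = times
        self.events = events

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, duration_col="time_days",
                       event_col="event") -> "KaplanMeier":
        return cls(data[duration_col].to_numpy(), data[event_col].to_numpy())

    def fit(self, conf_level: float = 0.95) -> "KaplanMeierResults":
        t, e = self.times, self.events
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        n = len(t)
        event_times = np.unique(t[e == 1])
        n_risk, n_events, n_censored = [], [], []
        surv, var_term = [], []
        s, gw = 1.0, 0.0
        for ti in event_times:
            at_risk = int(np.sum(t >= ti))
            d = int(np.sum((t == ti) & (e == 1)))
            s *= 1.0 - d / at_risk
            if at_risk > d:
                gw += d / (at_risk * (at_risk - d))
            else:
                gw = np.inf
            n_risk.append(at_risk)
            n_events.append(d)
            surv.append(s)
            var_term.append(gw)
        surv = np.asarray(surv)
        var_term = np.asarray(var_term)
        z = stats.norm.ppf(0.5 + conf_level / 2.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se_log = np.sqrt(var_term)
            lo = surv * np.exp(-z * se_log)
            hi = np.minimum(surv * np.exp(z * se_log), 1.0)
        lo = np.where(surv > 0, lo, 0.0)
        hi = np.where(surv > 0, hi, 0.0)
        table = pd.DataFrame(
            {
                "time": event_times,
                "n_risk": n_risk,
                "n_event": n_events,
                "surv": surv,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )
        below = table[table["surv"] <= 0.5]
        median = float(below["time"].iloc[0]) if len(below) else None
        return KaplanMeierResults(
            model=self, table=table, median_survival_time=median, n=n,
            n_events_total=int(e.sum()),
        )


class KaplanMeierResults:
    """Fitted product-limit curve with Greenwood bands."""

    def __init__(self, model, table, median_survival_time, n, n_events_total):
        self.model = model
        self.table = table
        self.median_survival_time = median_survival_time
        self.n = n
        self.n_events_total = n_events_total

    def survival_at(self, t) -> np.ndarray:
        """Step-function value of S at time(s) ``t`` (right-continuous)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        et = self.table["time"].to_numpy()
        s = self.table["surv"].to_numpy()
        if len(et) == 0:
            out = np.ones_like(t)
        else:
            idx = np.searchsorted(et, t, side="right") - 1
            out = np.where(idx >= 0, s[np.clip(idx, 0, None)], 1.0)
        return out if out.size > 1 else float(out[0])

    def ci_at(self, t) -> tuple:
        t = float(t)
        et = self.table["time"].to_numpy()
        idx = np.searchsorted(et, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        row = self.table.iloc[idx]
        return (float(row["ci_lo"]), float(row["ci_hi"]))

    def summary(self) -> pd.DataFrame:
        return self.table.copy()

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.table["time"].to_numpy()])
        s = np.concatenate([[1.0], self.table["surv"].to_numpy()])
        ax.step(t, s, where="post", **kwargs)
        ax.fill_between(
            t,
            np.concatenate([[1.0], self.table["ci_lo"].to_numpy()]),
            np.concatenate([[1.0], self.table["ci_hi"].to_numpy()]),
            step="post",
            alpha=0.25,
        )
        ax.set_xlabel("time (days)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        return ax


def km_fit(times, events) -> KaplanMeierResults:
    """Functional wrapper: fit a product-limit curve in one call."""
    return KaplanMeier(times, events).fit()
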