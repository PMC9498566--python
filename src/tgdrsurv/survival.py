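"""Censored survival data and the Cox partial likelihood on arbitrary risk scores.

The central object is :class:`SurvivalDataset`, holding a covariate matrix
``Z`` (one row per sample), observed times ``time`` and event indicators
``event`` (1 = event, 0 = right-censored).  On top of it this module provides
the log partial likelihood evaluated at per-sample log hazard ratios
("risk scores"), its exact gradient with respect to those scores, and
Harrell's concordance index.

Risk sets use the non-strict convention {j : t_j >= t_i} and tied event
times share the full risk set (Breslow convention).  The partial
likelihood is computed with a single sort and suffix accumulation,
O(N log N), with a max-shift for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "log_partial_likelihood",
    "score_gradient",
    "concordance_index",
    "read_survival_csv",
    "write_survival_csv",
    "CoxPartialLikelihood",
]


@dataclass(frozen=True)
class SurvivalDataset:
    """An N-sample survival dataset.

    Parameters
    ----------
    Z : (N, p) ndarray
        Covariate matrix (omics measurements), no missing values.
    time : (N,) ndarray
        Observed times ``Y_i = min(T_i, C_i)``, strictly positive.
    event : (N,) ndarray
        Event indicators ``delta_i = I(T_i <= C_i)``, values in {0, 1}.
    """

    Z: np.ndarray
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        time = np.asarray(self.time, dtype=float).ravel()
        event = np.asarray(self.event).ravel()
        if Z.shape[0] != time.size or time.size != event.size:
            raise ValueError(
                f"inconsistent sizes: Z has {Z.shape[0]} rows, "
                f"time has {time.size}, event has {event.size}"
            )
        if not np.all(np.isfinite(Z)):
            raise ValueError("covariates contain non-finite values")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("observed times must be finite and > 0")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int64))

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def n_features(self) -> int:
        return self.Z.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        """Row subset (copy) of the dataset."""
        idx = np.asarray(idx)
        return SurvivalDataset(self.Z[idx], self.time[idx], self.event[idx])

    def to_dataframe(self, feature_names: list[str] | None = None) -> pd.DataFrame:
        if feature_names is None:
            feature_names = [f"z{j + 1}" for j in range(self.n_features)]
        df = pd.DataFrame({"time": self.time, "status": self.event})
        for j, name in enumerate(feature_names):
            df[name] = self.Z[:, j]
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SurvivalDataset":
        if "time" not in df.columns or "status" not in df.columns:
            raise ValueError("dataframe must have 'time' and 'status' columns")
        covs = [c for c in df.columns if c not in ("time", "status")]
        return cls(
            df[covs].to_numpy(dtype=float),
            df["time"].to_numpy(dtype=float),
            df["status"].to_numpy(),
        )


def read_survival_csv(path, sep: str = ",") -> SurvivalDataset:
    """Read a delimited survival table: columns ``time``, ``status``, covariates."""
    return SurvivalDataset.from_dataframe(pd.read_csv(path, sep=sep))


def write_survival_csv(data: SurvivalDataset, path, sep: str = ",",
                       feature_names: list[str] | None = None) -> None:
    data.to_dataframe(feature_names).to_csv(path, sep=sep, index=False)


class CoxPartialLikelihood:
    """Cox log partial likelihood for one dataset, with the sort precomputed.

    Repeated evaluation at different score vectors (as in iterative
    fitting) only pays for the O(N) suffix sums, not the sort.
    """

    def __init__(self, data: SurvivalDataset):
        self.data = data
        if data.n_events == 0:
            raise ValueError("degenerate likelihood: dataset has no events")
        order = np.argsort(data.time, kind="stable")
        self._order = order
        t_sorted = data.time[order]
        self._delta = data.event[order].astype(float)
        # tie groups: first/last sorted index of each block of equal times
        is_new = np.empty(t_sorted.size, dtype=bool)
        is_new[0] = True
        np.not_equal(t_sorted[1:], t_sorted[:-1], out=is_new[1:])
        group_id = np.cumsum(is_new) - 1
        first = np.flatnonzero(is_new)
        last = np.append(first[1:] - 1, t_sorted.size - 1)
        self._group_first = first[group_id]
        self._group_last = last[group_id]

    def _prepare(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.size != self.data.n_samples:
            raise ValueError("score vector length does not match dataset")
        if not np.all(np.isfinite(theta)):
            raise ValueError("risk scores contain non-finite values")
        th = theta[self._order]
        m = th.max()
        s = np.exp(th - m)
        # suffix sums of exp(theta); risk set of a sample starts at the
        # first member of its tie group (non-strict t_j >= t_i)
        suffix = np.cumsum(s[::-1])[::-1]
        risk = suffix[self._group_first]
        return th, m, s, risk

    def value(self, theta: np.ndarray) -> float:
        th, m, s, risk = self._prepare(theta)
        d = self._delta
        return float(np.sum(d * (th - (np.log(risk) + m))))

    def gradient(self, theta: np.ndarray) -> np.ndarray:
        """d l / d theta, returned in original sample order."""
        th, m, s, risk = self._prepare(theta)
        d = self._delta
        # cumulative hazard increments d_q / risk_q accumulated over all
        # event times <= t_i; ties resolved at the last member of the group
        cum = np.cumsum(d / risk)[self._group_last]
        g_sorted = d - s * cum
        g = np.empty_like(g_sorted)
        g[self._order] = g_sorted
        return g


def log_partial_likelihood(theta: np.ndarray, data: SurvivalDataset) -> float:
    """Cox log partial likelihood l = sum_{delta_i=1} [theta_i - log sum_{t_j>=t_i} e^{theta_j}].

    Larger is better; the training loss is ``-l``.
    """
    return CoxPartialLikelihood(data).value(theta)


def score_gradient(theta: np.ndarray, data: SurvivalDataset) -> np.ndarray:
    """Gradient of :func:`log_partial_likelihood` with respect to the scores."""
    return CoxPartialLikelihood(data).gradient(theta)


def concordance_index(theta: np.ndarray, data: SurvivalDataset) -> float:
    """Harrell's C-index of risk scores against observed survival.

    A pair (i, j) with ``t_i < t_j`` is comparable iff sample i had an
    event; it counts as concordant when the shorter-lived sample has the
    larger risk score, and tied scores earn half credit.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    t, d = data.time, data.event
    if theta.size != t.size:
        raise ValueError("score vector length does not match dataset")
    # comparable[i, j]: t_i < t_j and delta_i == 1
    comparable = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs: cannot compute C-index")
    greater = theta[:, None] > theta[None, :]
    tied = theta[:, None] == theta[None, :]
    score = np.sum(comparable & greater) + 0.5 * np.sum(comparable & tied)
    return float(score / n_comp)
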