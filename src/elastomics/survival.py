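"""Signature-stratified survival analysis.

Compares survival between signature-positive ("signal") and
signature-negative ("no-signal") subjects: Kaplan-Meier product-limit
curves, the log-rank test, and covariate-adjusted Cox proportional-hazards
regression (Efron tie handling by default, Breslow available for
cross-checking).  The numerical engines are lifelines'; this module owns
the cohort schema, encodings and reporting conventions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

SIGNAL = "signal"
NO_SIGNAL = "no-signal"


@dataclass
class SurvivalCohort:
    """Per-subject survival table.

    Requires columns ``time`` (days, > 0), ``event`` (1 death, 0 censored)
    and ``signature_class`` ("signal"/"no-signal"); optional covariates
    ``age`` (years), ``sex`` and ``treatment`` (unordered category).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("time", "event", "signature_class"):
            if col not in t.columns:
                raise ValueError(f"survival table lacks column {col!r}")
        if (t["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(t["event"].unique()) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        if t["signature_class"].isna().any():
            raise ValueError("signature_class must be set for every subject")
        bad = set(t["signature_class"]) - {SIGNAL, NO_SIGNAL}
        if bad:
            raise ValueError(f"signature_class values must be signal/no-signal, got {bad}")

    def split(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        t = self.table
        return (
            t[t["signature_class"] == SIGNAL],
            t[t["signature_class"] == NO_SIGNAL],
        )


class KMEstimate(NamedTuple):
    times: np.ndarray  # event/censoring grid
    survival: np.ndarray  # S(t) at those times
    median: float | None  # earliest t with S(t) <= 0.5, None if never reached

    def at(self, t: float) -> float:
        """S(t) by right-continuous step lookup."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMEstimate:
    """Kaplan-Meier product-limit estimate plus the median survival time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMEstimate(grid, surv, median)


class LogrankResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> LogrankResult:
    """Two-group log-rank test on tables with ``time``/``event`` columns.

    The statistic is the 1-df chi-square from the observed-minus-expected
    event counts with hypergeometric variance at each event time.  With no
    events at all the test is degenerate (statistic 0, p 1, flagged).
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    if int(group_a["event"].sum() + group_b["event"].sum()) == 0:
        return LogrankResult(0.0, 1.0, degenerate=True)
    res = _ll_logrank(
        group_a["time"], group_b["time"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    stat = float(res.test_statistic)
    if not np.isfinite(stat):  # identical groups can yield 0/0
        return LogrankResult(0.0, 1.0, degenerate=True)
    return LogrankResult(stat, float(res.p_value), degenerate=False)


def _encode_covariates(table: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Design columns for the Cox fit; the signature class is always first.

    Categorical covariates are dummy-coded with the most frequent level as
    the reference.
    """
    out = pd.DataFrame(index=table.index)
    out["signature[signal]"] = (table["signature_class"] == SIGNAL).astype(float)
    for cov in covariates:
        if cov not in table.columns:
            raise ValueError(f"covariate {cov!r} not in survival table")
        col = table[cov]
        if pd.api.types.is_numeric_dtype(col):
            out[cov] = col.astype(float)
        else:
            ref = col.value_counts().idxmax()
            for lev in sorted(set(col) - {ref}):
                out[f"{cov}[{lev}]"] = (col == lev).astype(float)
    const = [c for c in out.columns if out[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate columns: {const}")
    return out


def cox_fit(
    cohort: SurvivalCohort,
    covariates: Sequence[str] = (),
    ties: str = "efron",
) -> pd.DataFrame:
    """Cox proportional-hazards regression of survival on the signature.

    Maximizes the partial likelihood by Newton-Raphson with Efron tie
    correction (``ties="breslow"`` for cross-checking).  Returns one row
    per coefficient: beta, HR = exp(beta), Wald 95% CI on the log scale,
    p-value, with the convergence flag in ``.attrs``.  Warns when the
    event count is below five per coefficient; perfect separation is
    surfaced as an error naming the covariate.
    """
    X = _encode_covariates(cohort.table, covariates)
    df = pd.concat([cohort.table[["time", "event"]], X], axis=1)
    n_events = int(df["event"].sum())
    if n_events < 5 * X.shape[1]:
        warnings.warn(
            f"only {n_events} events for {X.shape[1]} coefficients; "
            "estimates may be unstable"
        )
    if ties == "efron":
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event",
                        fit_options={"step_size": 0.95})
        except ConvergenceError as err:
            raise ValueError(
                f"Cox fit failed (possible perfect separation): {err}"
            ) from err
        summ = cph.summary
        out = pd.DataFrame(
            {
                "beta": summ["coef"],
                "hr": summ["exp(coef)"],
                "ci_low": summ["exp(coef) lower 95%"],
                "ci_high": summ["exp(coef) upper 95%"],
                "pvalue": summ["p"],
            }
        )
    elif ties == "breslow":
        from statsmodels.duration.hazard_regression import PHReg

        mod = PHReg(df["time"], X.to_numpy(), status=df["event"], ties="breslow")
        res = mod.fit()
        beta = res.params
        se = res.bse
        out = pd.DataFrame(
            {
                "beta": beta,
                "hr": np.exp(beta),
                "ci_low": np.exp(beta - 1.959963984540054 * se),
                "ci_high": np.exp(beta + 1.959963984540054 * se),
                "pvalue": res.pvalues,
            },
            index=X.columns,
        )
    else:
        raise ValueError(f"unknown tie handling {ties!r}")
    out.attrs["converged"] = True
    out.attrs["n_events"] = n_events
    return out


def compare_groups(cohort: SurvivalCohort, covariates: Sequence[str] = ()) -> dict:
    """KM curves, medians, log-rank test and Cox fit for the two classes."""
    sig, nosig = cohort.split()
    km_sig = km_estimate(sig["time"], sig["event"]) if len(sig) else None
    km_nosig = km_estimate(nosig["time"], nosig["event"]) if len(nosig) else None
    lr = logrank_test(sig, nosig) if len(sig) and len(nosig) else None
    cox = cox_fit(cohort, covariates)
    return {
        "km_signal": km_sig,
        "km_no_signal": km_nosig,
        "median_signal": None if km_sig is None else km_sig.median,
        "median_no_signal": None if km_nosig is None else km_nosig.median,
        "logrank": lr,
        "cox": cox,
    }
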