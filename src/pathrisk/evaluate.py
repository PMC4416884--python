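"""Performance statistics for (predicted risk, censored survival) pairs.

Four statistics are reported for every evaluation:

* **likelihood_ratio** — 2*(fitted - null) log partial likelihood of a
  univariate Cox model of survival on the risk score (Breslow ties);
  ~ chi-square(1) under the null.
* **c_index** — Harrell's concordance: over usable pairs (the shorter
  time carries an event), the probability that the higher-risk sample
  fails first; risk ties count 1/2.
* **r_squared** — the Cox–Snell form 1 - exp(-LR/n), an explained-
  variation summary on [0, 1).
* **logrank_p** — two-sample log-rank test after splitting samples at the
  median risk (ties at the median go to the low-risk group).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from lifelines import KaplanMeierFitter

from .io import SurvivalData, ValidationError
from ._cox import fit_univariate_cox

__all__ = [
    "EvaluationReport",
    "likelihood_ratio",
    "harrell_c",
    "r_squared",
    "logrank_median_split",
    "evaluate_risk",
    "km_curves",
]


@dataclass
class EvaluationReport:
    likelihood_ratio: float
    c_index: float
    r_squared: float
    logrank_p: float
    logrank_chi2: float
    n_high: int
    n_low: int
    median_risk: float
    n_samples: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle, indent=2)

    def to_tsv(self, path: str) -> None:
        pd.DataFrame([self.to_dict()]).to_csv(path, sep="\t", index=False)


def _check(risk: np.ndarray, surv: SurvivalData) -> np.ndarray:
    risk = np.asarray(risk, dtype=float)
    if risk.shape != (surv.n_samples,):
        raise ValidationError("risk length does not match survival data")
    if not np.isfinite(risk).all():
        raise ValidationError("non-finite risk score")
    return risk


def likelihood_ratio(risk: np.ndarray, surv: SurvivalData) -> float:
    """Cox partial-likelihood ratio statistic of survival on risk."""
    risk = _check(risk, surv)
    if risk.std(ddof=1) <= 0:
        raise ValidationError("constant risk: likelihood ratio undefined")
    fit = fit_univariate_cox(risk, surv.time, surv.event)
    return fit.likelihood_ratio


def harrell_c(risk: np.ndarray, surv: SurvivalData) -> float:
    """Harrell's C of a risk score (higher risk should fail earlier)."""
    risk = _check(risk, surv)
    # lifelines scores "higher prediction = longer survival", so negate.
    return float(concordance_index(surv.time, -risk, surv.event))


def r_squared(risk: np.ndarray, surv: SurvivalData) -> float:
    """Cox–Snell explained variation, 1 - exp(-LR/n)."""
    lr = likelihood_ratio(risk, surv)
    return float(1.0 - np.exp(-lr / surv.n_samples))


def logrank_median_split(risk: np.ndarray, surv: SurvivalData):
    """Two-group log-rank test after a median-risk split.

    Returns ``(p_value, chi2, labels)`` where ``labels`` is a boolean
    array marking the high-risk group (risk strictly above the median;
    ties at the median go low-risk).
    """
    risk = _check(risk, surv)
    med = float(np.median(risk))
    high = risk > med
    if not high.any() or high.all():
        raise ValidationError("median split produced an empty group (risks all tied?)")
    res = logrank_test(
        surv.time[high], surv.time[~high], surv.event[high], surv.event[~high]
    )
    return float(res.p_value), float(res.test_statistic), high


def evaluate_risk(risk: np.ndarray, surv: SurvivalData) -> EvaluationReport:
    """All four statistics in one report."""
    risk = _check(risk, surv)
    lr = likelihood_ratio(risk, surv)
    c = harrell_c(risk, surv)
    r2 = float(1.0 - np.exp(-lr / surv.n_samples))
    p, chi2, high = logrank_median_split(risk, surv)
    return EvaluationReport(
        likelihood_ratio=lr,
        c_index=c,
        r_squared=r2,
        logrank_p=p,
        logrank_chi2=chi2,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        median_risk=float(np.median(risk)),
        n_samples=surv.n_samples,
    )


def km_curves(risk: np.ndarray, surv: SurvivalData) -> pd.DataFrame:
    """Kaplan–Meier estimates per median-split group, for plotting.

    Columns: group, time, at_risk, survival.
    """
    risk = _check(risk, surv)
    _, _, high = logrank_median_split(risk, surv)
    frames = []
    for label, mask in (("high", high), ("low", ~high)):
        km = KaplanMeierFitter()
        km.fit(surv.time[mask], surv.event[mask])
        table = km.event_table
        frames.append(
            pd.DataFrame(
                {
                    "group": label,
                    "time": table.index.to_numpy(dtype=float),
                    "at_risk": table["at_risk"].to_numpy(dtype=int),
                    "survival": km.survival_function_["KM_estimate"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
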