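"""Survival statistics: Cox-based gene filtering, median-split univariate Cox,
Kaplan-Meier estimation, the logrank test and Benjamini-Hochberg adjustment.

The prognostic gene filter uses the Cox score test evaluated at beta = 0,
which for a single covariate coincides with the (generalized) logrank test;
it is computed in closed form and vectorized across genes. Hazard ratios and
Wald confidence intervals for the median-split analysis come from a full Cox
fit (Efron tie handling) via lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_preprocess import ClinicalTable, OmicsMatrix

Direction = Literal["up_worse", "down_worse"]


@dataclass
class GeneSurvivalRecord:
    """Median-split Cox result for one gene: HR (up vs down), Wald CI, logrank p, BH q."""

    gene: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    direction: Direction

    @property
    def significant(self) -> bool:
        return self.p <= 0.05 and self.q <= 0.05


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate with at-risk counts at each event/censor time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, horizon: float) -> float:
        """Survival probability at a fixed horizon (step-function evaluation)."""
        idx = np.searchsorted(self.times, horizon, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _surv_arrays(clinical: ClinicalTable) -> tuple[np.ndarray, np.ndarray]:
    time = clinical.data["os_time"].to_numpy(dtype=float)
    raw_event = clinical.data["os_event"].to_numpy()
    event = np.where(pd.isna(raw_event), False, raw_event).astype(bool)
    if np.isnan(time).any():
        raise ValueError("os_time contains missing values")
    return time, event


def cox_score_test(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Cox score test at beta=0 for each row of X (Breslow ties).

    Returns (chi2, p) arrays, one entry per row. For a binary covariate this
    is exactly the logrank test; for continuous covariates it is the trend
    logrank/score test used for prognostic feature screening.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    order = np.argsort(-time, kind="stable")
    t_s, e_s, X_s = time[order], event[order], X[:, order]
    n = t_s.size
    # risk set of subject i = all subjects with time >= t_i: a prefix after the
    # tie block containing i is extended to its end
    block_end = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_s[j + 1] == t_s[i]:
            j += 1
        block_end[i : j + 1] = j
        i = j + 1
    csum = np.cumsum(X_s, axis=1)
    csum2 = np.cumsum(X_s**2, axis=1)
    ev = np.where(e_s)[0]
    if ev.size == 0:
        raise ValueError("no events in cohort")
    ends = block_end[ev]
    counts = (ends + 1).astype(float)
    mean_rs = csum[:, ends] / counts
    var_rs = csum2[:, ends] / counts - mean_rs**2
    U = (X_s[:, ev] - mean_rs).sum(axis=1)
    V = var_rs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(V > 0, U**2 / V, 0.0)
    p = np.where(V > 0, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p


def cox_feature_select(m: OmicsMatrix, clinical: ClinicalTable, alpha: float = 0.05) -> list[str]:
    """Keep genes whose univariate Cox score (logrank) test on the continuous
    value has p <= alpha."""
    if m.sample_ids != clinical.sample_ids:
        raise ValueError("matrix and clinical table are not sample-aligned")
    time, event = _surv_arrays(clinical)
    if event.sum() < 2:
        raise ValueError("need at least 2 events for Cox feature selection")
    X = m.values.to_numpy(dtype=float)
    keep_var = X.var(axis=1) > 0
    if not keep_var.all():
        warnings.warn(f"skipped {int((~keep_var).sum())} zero-variance gene(s)", stacklevel=2)
    _, p = cox_score_test(X[keep_var], time, event)
    genes = np.asarray(m.gene_ids)[keep_var]
    return [g for g, pi in zip(genes, p) if pi <= alpha]


def median_split(values: Sequence[float]) -> np.ndarray:
    """Dichotomize at the median: value > median -> "up", value <= median -> "down"."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("median split needs at least 4 values")
    med = np.median(v)
    return np.where(v > med, "up", "down")


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1, rank-monotone)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def logrank_test(groups: Sequence, clinical: ClinicalTable) -> tuple[float, float]:
    """Logrank chi-square statistic and p-value across the group partition."""
    time, event = _surv_arrays(clinical)
    g = np.asarray(groups)
    if len(np.unique(g)) < 2:
        raise ValueError("logrank test needs at least 2 groups")
    if event.sum() < 1:
        raise ValueError("logrank test needs at least 1 event")
    res = multivariate_logrank_test(time, g, event)
    return float(res.test_statistic), float(res.p_value)


def univariate_cox_median(
    m: OmicsMatrix,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    q_alpha: float = 0.05,
) -> list[GeneSurvivalRecord]:
    """Median-split univariate Cox per gene with BH correction over all tested genes.

    Each gene is dichotomized at its median; a Cox model on the binary
    up-vs-down indicator yields the hazard ratio (up vs down) and its 95% Wald
    CI; the reported p-value is the logrank test between the two groups (the
    score test for this model). Genes whose split is degenerate or whose fit
    fails are skipped with a warning. The BH family is the set of genes tested
    in this call, so run CNA-correlated and MET-correlated panels separately.
    """
    if m.sample_ids != clinical.sample_ids:
        raise ValueError("matrix and clinical table are not sample-aligned")
    time, event = _surv_arrays(clinical)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    rows: list[tuple[str, float, float, float, float]] = []
    for gene in m.gene_ids:
        values = m.values.loc[gene].to_numpy(dtype=float)
        labels = median_split(values)
        up = labels == "up"
        if up.all() or (~up).all():
            warnings.warn(f"gene {gene}: degenerate median split, skipped", stacklevel=2)
            continue
        df = pd.DataFrame({"time": time, "event": event.astype(int), "up": up.astype(float)})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except Exception:  # noqa: BLE001 - non-converging fits are expected occasionally
            warnings.warn(f"gene {gene}: Cox fit failed, skipped", stacklevel=2)
            continue
        coef = float(cph.params_["up"])
        se = float(cph.standard_errors_["up"])
        _, p = logrank_test(labels, clinical)
        rows.append((gene, coef, se, p, np.exp(coef)))
    if not rows:
        return []
    qs = bh_adjust([r[3] for r in rows])
    records = []
    zcrit = stats.norm.ppf(0.975)
    for (gene, coef, se, p, hr), q in zip(rows, qs):
        records.append(
            GeneSurvivalRecord(
                gene=gene,
                hr=float(hr),
                ci_low=float(np.exp(coef - zcrit * se)),
                ci_high=float(np.exp(coef + zcrit * se)),
                p=float(p),
                q=float(q),
                direction="up_worse" if hr > 1 else "down_worse",
            )
        )
    return records


def km_curve(groups: Sequence, clinical: ClinicalTable) -> dict[str, SurvivalCurve]:
    """Kaplan-Meier product-limit curve per group."""
    time, event = _surv_arrays(clinical)
    g = np.asarray(groups)
    curves: dict[str, SurvivalCurve] = {}
    for label in np.unique(g):
        mask = g == label
        if not mask.any():
            raise ValueError(f"empty group {label}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        sf = kmf.survival_function_
        tbl = kmf.event_table
        times = sf.index.to_numpy(dtype=float)
        curves[str(label)] = SurvivalCurve(
            times=times,
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
            at_risk=tbl["at_risk"].reindex(sf.index).to_numpy(dtype=float),
        )
    return curves


def survival_records_frame(records: Sequence[GeneSurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "HR": [r.hr for r in records],
            "CI_low": [r.ci_low for r in records],
            "CI_high": [r.ci_high for r in records],
            "p": [r.p for r in records],
            "q": [r.q for r in records],
            "direction": [r.direction for r in records],
            "significant": [r.significant for r in records],
        }
    )
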