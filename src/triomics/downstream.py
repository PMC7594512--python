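"""Post-subtyping characterization: subgroup summaries, PAM50 composition,
age-threshold survival interaction, copy-number burden comparison, and a
descriptive subgroup-vs-omics regression."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_preprocess import ClinicalTable, OmicsMatrix
from .survival import logrank_test


@dataclass
class SubgroupSummary:
    subgroup: int
    n: int
    mean_age: float
    mean_survival_time: float
    pam50_composition: dict[str, float] | None


@dataclass
class BurdenResult:
    """Per-sample copy-number burden with a Welch two-sample comparison across subgroups."""

    per_sample_burden: pd.Series
    group_means: dict[int, float]
    t_stat: float
    p: float


@dataclass
class RegressionResult:
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    note: str


def summarize_subgroups(clinical: ClinicalTable, labels: Sequence) -> list[SubgroupSummary]:
    """Per-subgroup n, mean age, mean observed survival time and PAM50 composition."""
    lab = np.asarray(labels)
    if lab.size != len(clinical):
        raise ValueError("labels do not align with clinical table")
    d = clinical.data
    has_pam = d["pam50"].notna().any()
    out = []
    for g in sorted(np.unique(lab).tolist()):
        mask = lab == g
        if not mask.any():
            raise ValueError(f"empty subgroup {g}")
        comp = None
        if has_pam:
            pam = d.loc[mask, "pam50"].dropna()
            comp = (pam.value_counts(normalize=True)).to_dict() if len(pam) else {}
        out.append(
            SubgroupSummary(
                subgroup=int(g),
                n=int(mask.sum()),
                mean_age=float(d.loc[mask, "age"].mean()),
                mean_survival_time=float(d.loc[mask, "os_time"].mean()),
                pam50_composition=comp,
            )
        )
    return out


def age_split_survival(
    clinical: ClinicalTable, labels: Sequence, age_threshold: float = 65.0
) -> dict[int, tuple[float, float] | None]:
    """Within each subgroup, logrank test of non-old (age <= threshold) vs old (> threshold).

    Subgroups where either side of the split is empty (or eventless) are
    skipped with a warning and reported as None.
    """
    lab = np.asarray(labels)
    d = clinical.data
    results: dict[int, tuple[float, float] | None] = {}
    for g in sorted(np.unique(lab).tolist()):
        mask = lab == g
        sub = ClinicalTable(d[mask].copy())
        old = (sub.data["age"] > age_threshold).to_numpy()
        if old.all() or (~old).all():
            warnings.warn(f"subgroup {g}: one-sided age split, skipped", stacklevel=2)
            results[int(g)] = None
            continue
        try:
            results[int(g)] = logrank_test(np.where(old, "old", "non-old"), sub)
        except ValueError as exc:
            warnings.warn(f"subgroup {g}: logrank skipped ({exc})", stacklevel=2)
            results[int(g)] = None
    return results


def cna_burden(cna: OmicsMatrix, amplitude_threshold: float = 0.3) -> pd.Series:
    """Fraction of genes per sample with |copy-number value| > amplitude_threshold.

    This operationalizes genome-wide alteration load for log-ratio-scaled
    copy-number matrices; the threshold is configurable.
    """
    exceed = cna.values.abs() > amplitude_threshold
    return exceed.mean(axis=0).rename("cna_burden")


def compare_burden(burden: pd.Series, labels: Sequence) -> BurdenResult:
    """Welch t-test (unequal variances) of per-sample burden between two subgroups."""
    lab = np.asarray(labels)
    groups = sorted(np.unique(lab).tolist())
    if len(groups) != 2:
        raise ValueError("burden comparison requires exactly 2 subgroups")
    a = burden.to_numpy()[lab == groups[0]]
    b = burden.to_numpy()[lab == groups[1]]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return BurdenResult(
        per_sample_burden=burden,
        group_means={int(groups[0]): float(a.mean()), int(groups[1]): float(b.mean())},
        t_stat=float(t),
        p=float(p),
    )


def subgroup_omics_regression(
    labels: Sequence,
    cna_summary: Sequence[float],
    met_summary: Sequence[float],
    logistic: bool = False,
) -> RegressionResult:
    """Regress the binary subgroup indicator on per-sample CNA and MET summaries.

    Ordinary least squares by default (a logistic option exists); fitting a
    binary outcome linearly is descriptive only and the result carries that
    note.
    """
    lab = np.asarray(labels)
    groups = sorted(np.unique(lab).tolist())
    if len(groups) != 2:
        raise ValueError("regression requires exactly 2 subgroups")
    y = (lab == groups[1]).astype(float)
    X = pd.DataFrame({"cna": np.asarray(cna_summary, float), "met": np.asarray(met_summary, float)})
    if X["cna"].std() == 0 or X["met"].std() == 0 or X.corr().abs().iloc[0, 1] > 0.9999:
        raise ValueError("collinear or constant regressors")
    Xd = sm.add_constant(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, Xd).fit(disp=0) if logistic else sm.OLS(y, Xd).fit()
    note = (
        "logistic fit of subgroup indicator"
        if logistic
        else "OLS fit of a binary outcome: descriptive only, not a calibrated probability model"
    )
    return RegressionResult(
        coefficients=model.params.to_dict(),
        std_errors=model.bse.to_dict(),
        p_values=model.pvalues.to_dict(),
        note=note,
    )


def crosstab_pam50(labels: Sequence, clinical: ClinicalTable) -> pd.DataFrame:
    """Percentage composition of PAM50 labels within each subgroup (rows sum to 100)."""
    lab = np.asarray(labels)
    pam = clinical.data["pam50"]
    if pam.isna().all():
        raise ValueError("no PAM50 labels available")
    mask = pam.notna().to_numpy()
    table = pd.crosstab(
        pd.Series(lab[mask], name="subgroup"),
        pd.Series(pam.to_numpy()[mask], name="pam50"),
    )
    return table.div(table.sum(axis=1), axis=0) * 100.0


def summaries_frame(summaries: Sequence[SubgroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subgroup": [s.subgroup for s in summaries],
            "n": [s.n for s in summaries],
            "mean_age": [s.mean_age for s in summaries],
            "mean_survival_time": [s.mean_survival_time for s in summaries],
        }
    )
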