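"""Per-gene correlation of CNA/MET profiles with mRNA expression.

For every gene shared by two sample-aligned matrices the Pearson coefficient
between the gene's rows is computed with an exact two-sided t-test p-value.
Significant coefficients are variance-stabilized with the Fisher
Z-transformation and the skewness of the resulting Z distribution is tested
with the D'Agostino skewness test; a right-skew indicates predominantly
positive coupling (CNA vs mRNA), a left-skew predominantly negative coupling
(MET vs mRNA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_preprocess import OmicsMatrix

SignConstraint = Literal["any", "positive", "negative"]


@dataclass
class GeneCorrelationRecord:
    """Pearson r, its p-value and (when significant) the Fisher Z value for one gene."""

    gene: str
    r: float
    p: float
    z: float | None = None


@dataclass
class CorrelationSetResult:
    """A selection of significantly correlated genes plus the Z-distribution skew test."""

    records: list[GeneCorrelationRecord]
    selected: list[str]
    skewness: float
    skew_p: float
    alpha: float
    sign_constraint: SignConstraint

    @property
    def selected_set(self) -> set[str]:
        return set(self.selected)

    def to_frame(self) -> pd.DataFrame:
        sel = self.selected_set
        return pd.DataFrame(
            {
                "gene": [r.gene for r in self.records],
                "r": [r.r for r in self.records],
                "p": [r.p for r in self.records],
                "z": [np.nan if r.z is None else r.z for r in self.records],
                "selected": [r.gene in sel for r in self.records],
            }
        )


def pairwise_gene_correlation(x: OmicsMatrix, y: OmicsMatrix) -> list[GeneCorrelationRecord]:
    """Pearson correlation between matched gene rows of two sample-aligned matrices.

    Returns one record per gene present in both matrices (in x's gene order).
    The p-value is the exact two-sided t-test with n-2 degrees of freedom.
    Genes with zero variance in either matrix, or with |r| = 1 exactly, are
    dropped with a warning: their Fisher Z is undefined and degenerate rows
    must not crash the skewness stage.
    """
    if x.sample_ids != y.sample_ids:
        raise ValueError("matrices are not sample-aligned")
    n = len(x.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 matched samples for a correlation p-value")
    shared = [g for g in x.gene_ids if g in set(y.gene_ids)]
    if not shared:
        return []
    xv = x.values.loc[shared].to_numpy(dtype=float)
    yv = y.values.loc[shared].to_numpy(dtype=float)

    xc = xv - xv.mean(axis=1, keepdims=True)
    yc = yv - yv.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    syy = np.einsum("ij,ij->i", yc, yc)
    sxy = np.einsum("ij,ij->i", xc, yc)

    records: list[GeneCorrelationRecord] = []
    dropped = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    for gene, ri, varx, vary in zip(shared, r, sxx, syy):
        if varx == 0.0 or vary == 0.0 or not np.isfinite(ri) or abs(ri) >= 1.0:
            dropped += 1
            continue
        t = ri * np.sqrt((n - 2) / (1.0 - ri * ri))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
        records.append(GeneCorrelationRecord(gene=gene, r=float(ri), p=float(min(p, 1.0))))
    if dropped:
        warnings.warn(f"dropped {dropped} degenerate gene pair(s) (zero variance or |r|=1)", stacklevel=2)
    return records


def fisher_z(r):
    """Fisher Z-transformation 0.5*ln((1+r)/(1-r)); defined for -1 < r < 1.

    Accepts scalars or arrays; strictly increasing and odd.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def skewness_test(z_values: Sequence[float]) -> tuple[float, float]:
    """Sample skewness g1 plus the two-sided D'Agostino skewness-test p-value.

    The estimator is the bias-uncorrected moment ratio g1, which is the input
    to the classical D'Agostino transformed-Z statistic. Requires >= 9 values
    with nonzero variance.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size < 9:
        raise ValueError("skewness test needs at least 9 values")
    if np.var(z) == 0.0:
        raise ValueError("skewness test undefined for zero-variance input")
    g1 = float(stats.skew(z, bias=True))
    _, p = stats.skewtest(z)
    return g1, float(p)


def select_correlated_genes(
    records: Sequence[GeneCorrelationRecord],
    alpha: float = 0.05,
    sign_constraint: SignConstraint = "any",
) -> CorrelationSetResult:
    """Select genes with p <= alpha (optionally sign-constrained) and test the Z skew.

    No multiple-testing correction is applied at this stage; the raw
    significance threshold defines the correlated-gene sets. The skewness and
    its p-value are computed over the Fisher Z values of the selected genes
    only; with fewer than 9 selected genes the test is skipped (NaN) with a
    warning.
    """
    if not records:
        raise ValueError("no correlation records supplied")
    selected: list[str] = []
    out_records: list[GeneCorrelationRecord] = []
    z_sel: list[float] = []
    for rec in records:
        keep = rec.p <= alpha
        if keep and sign_constraint == "positive":
            keep = rec.r > 0
        elif keep and sign_constraint == "negative":
            keep = rec.r < 0
        z = fisher_z(rec.r) if rec.p <= alpha else None
        out_records.append(GeneCorrelationRecord(rec.gene, rec.r, rec.p, z))
        if keep:
            selected.append(rec.gene)
            z_sel.append(fisher_z(rec.r))
    if len(z_sel) >= 9 and np.var(z_sel) > 0:
        skewness, skew_p = skewness_test(z_sel)
    else:
        warnings.warn("too few significant genes for a skewness test", stacklevel=2)
        skewness, skew_p = float("nan"), float("nan")
    return CorrelationSetResult(
        records=out_records,
        selected=selected,
        skewness=skewness,
        skew_p=skew_p,
        alpha=alpha,
        sign_constraint=sign_constraint,
    )


def intersect_gene_sets(a: Iterable[str], b: Iterable[str]) -> tuple[set[str], int]:
    """Exact set intersection and its size."""
    shared = set(a) & set(b)
    return shared, len(shared)
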