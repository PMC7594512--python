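"""Subgroup-specific gene detection: each candidate gene is assigned to the
subgroup where its mean value is largest and flagged significant when a
one-way ANOVA across subgroups has p <= alpha."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_preprocess import OmicsMatrix


@dataclass
class SubgroupSpecificRecord:
    gene: str
    assigned_subgroup: int
    group_means: dict[int, float]
    f_stat: float
    p: float
    significant: bool
    tied: bool = False


def one_way_anova(values: Sequence[float], labels: Sequence) -> tuple[float, float]:
    """Classical one-way ANOVA F and p with (g-1, n-g) degrees of freedom.

    Zero within-group variance with distinct group means follows the
    F = inf, p = 0 convention.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = [v[lab == g] for g in np.unique(lab)]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 members")
    if np.var(v) == 0.0:
        raise ValueError("total variance is zero")
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0.0:
        return float("inf"), 0.0
    grand = v.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    df_b = len(groups) - 1
    df_w = v.size - len(groups)
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), float(stats.f.sf(f, df_b, df_w))


def assign_specific_genes(
    m: OmicsMatrix,
    labels: Sequence,
    alpha: float = 0.05,
    candidate_genes: Sequence[str] | None = None,
) -> list[SubgroupSpecificRecord]:
    """Assign candidate genes to their highest-mean subgroup with ANOVA significance.

    ``candidate_genes`` restricts the scan (e.g. to a previously selected
    correlated-gene panel); by default every gene in the matrix is tested.
    Exact mean ties go to the lowest-indexed subgroup and are flagged. No
    multiple-testing correction is applied; raw p <= alpha defines
    significance.
    """
    lab = np.asarray(labels)
    if lab.size != len(m.sample_ids):
        raise ValueError("labels do not align with matrix samples")
    subgroups = sorted(np.unique(lab).tolist())
    genes = list(candidate_genes) if candidate_genes is not None else m.gene_ids
    missing = set(genes) - set(m.gene_ids)
    if missing:
        raise KeyError(f"candidate genes absent from matrix: {sorted(missing)[:5]}")
    records: list[SubgroupSpecificRecord] = []
    values = m.values.loc[genes].to_numpy(dtype=float)
    for gene, row in zip(genes, values):
        means = {int(g): float(row[lab == g].mean()) for g in subgroups}
        best = max(means.values())
        winners = [g for g, mu in means.items() if mu == best]
        tied = len(winners) > 1
        if np.var(row) == 0.0:
            records.append(
                SubgroupSpecificRecord(gene, winners[0], means, 0.0, 1.0, False, tied=True)
            )
            continue
        f, p = one_way_anova(row, lab)
        records.append(
            SubgroupSpecificRecord(
                gene=gene,
                assigned_subgroup=winners[0],
                group_means=means,
                f_stat=f,
                p=p,
                significant=p <= alpha,
                tied=tied,
            )
        )
    return records


def specific_genes_frame(records: Sequence[SubgroupSpecificRecord]) -> pd.DataFrame:
    subgroups = sorted({g for r in records for g in r.group_means})
    data = {
        "gene": [r.gene for r in records],
        "assigned_subgroup": [r.assigned_subgroup for r in records],
    }
    for g in subgroups:
        data[f"mean_subgroup_{g}"] = [r.group_means.get(g, np.nan) for r in records]
    data["F"] = [r.f_stat for r in records]
    data["p"] = [r.p for r in records]
    data["significant"] = [r.significant for r in records]
    data["tied"] = [r.tied for r in records]
    return pd.DataFrame(data)
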