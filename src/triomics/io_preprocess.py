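"""Reading, validating, filtering, matching and imputing omics matrices and clinical tables.

The on-disk dialect is the cBioPortal-style tab-delimited layout: a header row
starting with ``Hugo_Symbol`` (optionally followed by ``Entrez_Gene_Id``), then
one column per sample. Clinical tables are TSV with columns ``SAMPLE_ID``,
``OS_MONTHS``, ``OS_STATUS``, ``AGE``, ``GENDER`` and optionally ``PAM50``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

OmicsKind = Literal["mRNA", "CNA", "MET"]

#: Missing-value tokens accepted in matrix files (case-insensitive).
MISSING_TOKENS = ("", "na", "nan", "null")

_GENDER_MAP = {
    "female": "female",
    "f": "female",
    "male": "male",
    "m": "male",
}

PAM50_LABELS = ("LumA", "LumB", "Basal", "HER2", "Normal")


class PreprocessError(ValueError):
    """Raised when an input file or cohort violates a structural contract."""


@dataclass
class OmicsMatrix:
    """A genes x samples continuous matrix for one omics kind.

    ``values`` is a DataFrame indexed by gene symbol with sample-id columns;
    missing entries are NaN. Gene and sample identifiers must be unique.
    """

    kind: OmicsKind
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise PreprocessError(f"{self.kind}: duplicate gene symbols in matrix")
        if self.values.columns.has_duplicates:
            raise PreprocessError(f"{self.kind}: duplicate sample ids in matrix")
        self.values = self.values.astype(float)
        self.values.index.name = "gene"
        self.values.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().sum().sum())

    def select_samples(self, sample_ids: Iterable[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.kind, self.values.loc[:, list(sample_ids)].copy())

    def select_genes(self, gene_ids: Iterable[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.kind, self.values.loc[list(gene_ids)].copy())


@dataclass
class ClinicalTable:
    """Per-sample clinical metadata: survival, age, gender, optional PAM50 label.

    ``data`` is indexed by sample id with columns ``os_time`` (months),
    ``os_event`` (bool, deceased=True), ``age`` (years), ``gender``
    (female/male/unknown) and ``pam50`` (nullable string).
    """

    data: pd.DataFrame

    REQUIRED = ("os_time", "os_event", "age", "gender")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise PreprocessError(f"clinical table lacks columns: {missing}")
        if self.data.index.has_duplicates:
            raise PreprocessError("clinical table has duplicate sample ids")
        if (self.data["os_time"].dropna() < 0).any():
            raise PreprocessError("negative os_time in clinical table")
        if "pam50" not in self.data.columns:
            self.data = self.data.assign(pam50=pd.Series(pd.NA, index=self.data.index, dtype="string"))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def select_samples(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(sample_ids)].copy())


@dataclass
class MatchedCohort:
    """Sample-matched mRNA/CNA/MET matrices plus clinical table, identically ordered."""

    mrna: OmicsMatrix
    cna: OmicsMatrix
    met: OmicsMatrix
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        ref = self.mrna.sample_ids
        for part, ids in (
            ("CNA", self.cna.sample_ids),
            ("MET", self.met.sample_ids),
            ("clinical", self.clinical.sample_ids),
        ):
            if ids != ref:
                raise PreprocessError(f"sample ids of {part} do not match mRNA ordering")

    @property
    def sample_ids(self) -> list[str]:
        return self.mrna.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def omics(self) -> dict[str, OmicsMatrix]:
        return {"mRNA": self.mrna, "CNA": self.cna, "MET": self.met}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_omics_matrix(
    path: str | Path,
    kind: OmicsKind,
    duplicate_policy: Literal["drop", "keep_first"] = "drop",
) -> OmicsMatrix:
    """Parse a cBioPortal-style tab-delimited matrix file.

    Non-numeric cells and the tokens in :data:`MISSING_TOKENS` become NaN.
    Duplicate gene symbols are dropped entirely (default) or collapsed to the
    first occurrence with ``duplicate_policy="keep_first"``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PreprocessError(f"cannot read omics matrix {path}: {exc}") from exc
    if raw.shape[1] == 0 or raw.columns[0] not in ("Hugo_Symbol", "gene", "Gene"):
        raise PreprocessError(f"{path}: first column must be Hugo_Symbol")
    gene_col = raw.columns[0]
    drop_cols = [gene_col]
    if len(raw.columns) > 1 and raw.columns[1] in ("Entrez_Gene_Id", "Entrez_Id"):
        drop_cols.append(raw.columns[1])
    sample_cols = [c for c in raw.columns if c not in drop_cols]
    if not sample_cols:
        raise PreprocessError(f"{path}: no sample columns")

    genes = raw[gene_col].astype(str)
    values = raw[sample_cols].copy()
    for token in MISSING_TOKENS:
        values = values.mask(values.apply(lambda s: s.str.strip().str.lower()) == token)

    def _parse_column(s: pd.Series) -> np.ndarray:
        # pd.to_numeric's fast path is not correctly rounded; use it only to
        # flag non-numeric cells and convert through numpy's strtod instead
        valid = pd.to_numeric(s, errors="coerce").notna() & s.notna()
        out = np.full(len(s), np.nan)
        out[valid.to_numpy()] = s[valid].to_numpy(dtype="U32").astype(np.float64)
        return out

    values = pd.DataFrame(
        {c: _parse_column(values[c]) for c in values.columns}, index=raw.index
    )
    values.index = genes

    dup = genes.duplicated(keep=False).values
    if dup.all():
        raise PreprocessError(f"{path}: every gene symbol is duplicated")
    if dup.any():
        if duplicate_policy == "keep_first":
            values = values[~genes.duplicated(keep="first").values]
        else:
            values = values[~dup]
    return OmicsMatrix(kind, values)


def write_omics_matrix(m: OmicsMatrix, path: str | Path, entrez: bool = False) -> None:
    """Write a matrix in the same dialect accepted by :func:`read_omics_matrix`."""
    out = m.values.copy()
    out.insert(0, "Hugo_Symbol", out.index)
    if entrez:
        out.insert(1, "Entrez_Gene_Id", range(1, len(out) + 1))
    # %.17g guarantees exact float64 round-trip through text
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def _strtod_series(s: pd.Series) -> np.ndarray:
    """Correctly rounded string-to-float conversion with NaN for bad cells."""
    valid = pd.to_numeric(s, errors="coerce").notna()
    out = np.full(len(s), np.nan)
    out[valid.to_numpy()] = s[valid].to_numpy(dtype="U32").astype(np.float64)
    return out


def _parse_os_status(value: str) -> bool | float:
    s = str(value).strip().upper()
    if s in ("", "NA", "NAN", "NULL"):
        return np.nan
    if ":" in s:  # cBioPortal "1:DECEASED" / "0:LIVING"
        s = s.split(":", 1)[1]
    if s in ("DECEASED", "DEAD", "1", "TRUE"):
        return True
    if s in ("LIVING", "ALIVE", "0", "FALSE"):
        return False
    return np.nan


def read_clinical(path: str | Path) -> ClinicalTable:
    """Parse a clinical TSV (SAMPLE_ID, OS_MONTHS, OS_STATUS, AGE, GENDER[, PAM50])."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.upper(): c for c in raw.columns}
    for req in ("SAMPLE_ID", "OS_MONTHS", "OS_STATUS", "AGE", "GENDER"):
        if req not in cols:
            raise PreprocessError(f"{path}: missing clinical column {req}")
    gender = (
        raw[cols["GENDER"]].astype(str).str.strip().str.lower().map(_GENDER_MAP).fillna("unknown")
    )
    data = pd.DataFrame(
        {
            "os_time": _strtod_series(raw[cols["OS_MONTHS"]]),
            "os_event": raw[cols["OS_STATUS"]].map(_parse_os_status).to_numpy(),
            "age": _strtod_series(raw[cols["AGE"]]),
            "gender": gender.values,
        },
        index=pd.Index(raw[cols["SAMPLE_ID"]].astype(str), name="sample_id"),
    )
    if "PAM50" in cols:
        pam = raw[cols["PAM50"]].astype(str).str.strip()
        pam = pam.where(pam.isin(PAM50_LABELS), pd.NA)
        data["pam50"] = pd.array(pam.values, dtype="string")
    return ClinicalTable(data)


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    d = clinical.data
    out = pd.DataFrame(
        {
            "SAMPLE_ID": d.index,
            "OS_MONTHS": d["os_time"].values,
            "OS_STATUS": np.where(d["os_event"].fillna(False).astype(bool), "DECEASED", "LIVING"),
            "AGE": d["age"].values,
            "GENDER": d["gender"].values,
            "PAM50": d["pam50"].fillna("NA").values,
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def filter_patients(clinical: ClinicalTable) -> ClinicalTable:
    """Retain female records only; male and unknown-gender patients are removed."""
    keep = clinical.data["gender"] == "female"
    if not keep.any():
        warnings.warn("gender filter removed every patient", stacklevel=2)
    return ClinicalTable(clinical.data[keep].copy())


def match_samples(
    mrna: OmicsMatrix, cna: OmicsMatrix, met: OmicsMatrix, clinical: ClinicalTable
) -> MatchedCohort:
    """Restrict all four components to their common samples, ordered lexicographically.

    The deterministic ordering makes every downstream stochastic stage
    reproducible regardless of input file column order.
    """
    shared = (
        set(mrna.sample_ids) & set(cna.sample_ids) & set(met.sample_ids) & set(clinical.sample_ids)
    )
    if not shared:
        raise PreprocessError("no samples shared by the three omics matrices and clinical table")
    order = sorted(shared)
    return MatchedCohort(
        mrna=mrna.select_samples(order),
        cna=cna.select_samples(order),
        met=met.select_samples(order),
        clinical=clinical.select_samples(order),
    )


def filter_missing_genes(m: OmicsMatrix, max_missing_frac: float = 0.5) -> OmicsMatrix:
    """Drop genes whose missing fraction strictly exceeds ``max_missing_frac``."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    frac = m.values.isna().mean(axis=1)
    return OmicsMatrix(m.kind, m.values[frac <= max_missing_frac].copy())


def impute_knn(m: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """Impute missing cells gene-wise with a k-nearest-neighbour rule.

    Genes are the objects and samples the features. The distance between two
    genes is the root-mean-square difference over their commonly observed
    samples (infinite when no sample is shared). A missing cell (g, s) becomes
    the mean over the ``k`` nearest genes *that are observed in sample s*.
    Observed cells are never modified.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = m.values.to_numpy(dtype=float, copy=True)
    miss = np.isnan(X)
    if not miss.any():
        return OmicsMatrix(m.kind, m.values.copy())
    obs = ~miss
    if (~obs.any(axis=1)).any():
        bad = [m.gene_ids[i] for i in np.where(~obs.any(axis=1))[0]]
        raise PreprocessError(f"genes with zero observed values (filter first): {bad[:5]}")

    filled = X.copy()
    for i in np.where(miss.any(axis=1))[0]:
        common = obs[i] & obs  # (G, S) pairs of commonly observed samples
        counts = common.sum(axis=1)
        diff = np.where(common, X[i] - np.where(obs, X, 0.0), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.einsum("gs,gs->g", diff, diff) / counts)
        dist[counts == 0] = np.inf
        dist[i] = np.inf
        for s in np.where(miss[i])[0]:
            cand = np.where(obs[:, s] & np.isfinite(dist))[0]
            if cand.size == 0:
                raise PreprocessError(
                    f"cannot impute gene {m.gene_ids[i]} at sample {m.sample_ids[s]}: no neighbours"
                )
            nearest = cand[np.argsort(dist[cand], kind="stable")[:k]]
            filled[i, s] = X[nearest, s].mean()
    return OmicsMatrix(m.kind, pd.DataFrame(filled, index=m.values.index, columns=m.values.columns))


def truncate_followup(clinical: ClinicalTable, max_months: float) -> ClinicalTable:
    """Administratively censor follow-up beyond ``max_months``.

    Records with os_time > max_months are set to os_time = max_months with
    os_event = False; patients are censored, never dropped.
    """
    if max_months <= 0:
        raise ValueError("max_months must be positive")
    d = clinical.data.copy()
    over = d["os_time"] > max_months
    d.loc[over, "os_time"] = float(max_months)
    d.loc[over, "os_event"] = False
    return ClinicalTable(d)


def preprocess_cohort(
    mrna: OmicsMatrix,
    cna: OmicsMatrix,
    met: OmicsMatrix,
    clinical: ClinicalTable,
    max_missing_frac: float = 0.5,
    knn_k: int = 10,
    truncate_months: float | None = None,
) -> MatchedCohort:
    """Full preprocessing chain: gender filter -> match -> gene filter -> kNN imputation."""
    clinical = filter_patients(clinical)
    if truncate_months is not None:
        clinical = truncate_followup(clinical, truncate_months)
    cohort = match_samples(mrna, cna, met, clinical)
    cleaned = {}
    for name, matrix in cohort.omics().items():
        filtered = filter_missing_genes(matrix, max_missing_frac)
        cleaned[name] = impute_knn(filtered, k=knn_k)
    return MatchedCohort(
        mrna=cleaned["mRNA"], cna=cleaned["CNA"], met=cleaned["MET"], clinical=cohort.clinical
    )


def cohort_manifest(cohort: MatchedCohort) -> pd.DataFrame:
    """Per-omics gene/sample counts plus the matched sample count, as a tidy table."""
    rows = [
        {"component": name, "n_genes": m.shape[0], "n_samples": m.shape[1], "n_missing": m.n_missing}
        for name, m in cohort.omics().items()
    ]
    rows.append(
        {
            "component": "clinical",
            "n_genes": 0,
            "n_samples": len(cohort.clinical),
            "n_missing": int(cohort.clinical.data[["os_time", "age"]].isna().sum().sum()),
        }
    )
    return pd.DataFrame(rows)
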