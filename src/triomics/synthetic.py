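"""Synthetic matched three-omics cohorts with planted structure and ground truth.

The generator plants, reproducibly from one seed:

* a categorical subgroup structure expressed jointly in all three omics
  (mean shifts on disjoint informative gene sets per omics);
* copy-number-coupled genes whose expression is ``slope * CNA + noise`` and
  methylation-coupled genes whose expression is ``-slope * MET + noise`` —
  for these the population Pearson correlation has the closed form
  ``slope / sqrt(slope^2 + noise_sd^2)`` (unit-variance source);
* prognostic genes driving an exponential survival hazard, plus a subgroup
  main effect; independent exponential censoring tuned to a target rate;
* age distributions shifted between subgroups, a male fraction, and random
  missing cells.

Structure, not biological realism, is the goal: the planted effects give
every downstream stage a known truth to recover.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_preprocess import (
    ClinicalTable,
    MatchedCohort,
    OmicsMatrix,
    read_clinical,
    read_omics_matrix,
    write_clinical,
    write_omics_matrix,
)

_PAM50 = ("LumA", "LumB", "Basal", "HER2", "Normal")
# subgroup-dependent PAM50 draw weights (first subgroup LumA-heavy)
_PAM50_WEIGHTS = (
    (0.42, 0.22, 0.21, 0.13, 0.02),
    (0.27, 0.42, 0.09, 0.22, 0.00),
)


@dataclass
class SimulationParams:
    """Knobs of the synthetic cohort generator; all randomness flows from ``seed``."""

    n_samples: int = 292
    subgroup_props: tuple[float, ...] = (0.79, 0.21)
    n_genes: int = 300
    frac_subgroup_informative: float = 0.10
    subgroup_effect: float = 1.5
    n_cnacor: int = 50
    n_metcor: int = 50
    coupling_slope: float = 1.0
    coupling_noise_sd: float = 0.5
    n_prognostic: int = 20
    coupled_informative_frac: float = 0.5
    log_hazard_effect: float = 0.15
    subgroup_log_hazard: float = 1.5
    baseline_hazard: float = 0.01
    censoring_rate: float = 0.4
    age_mean: float = 58.0
    age_sd: float = 8.0
    age_shift: tuple[float, ...] = (0.0, 6.0)
    missing_frac: float = 0.0
    male_frac: float = 0.0
    with_pam50: bool = True
    seed: int = 0

    def validate(self) -> None:
        props = np.asarray(self.subgroup_props, float)
        if props.min() <= 0 or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("subgroup_props must be positive and sum to 1")
        if len(self.age_shift) != len(self.subgroup_props):
            raise ValueError("age_shift must have one entry per subgroup")
        if self.n_cnacor + self.n_metcor + self.n_prognostic > self.n_genes:
            raise ValueError("planted gene sets exceed the gene universe")
        if not 0 <= self.missing_frac < 1 or not 0 <= self.male_frac < 1:
            raise ValueError("missing_frac and male_frac must lie in [0, 1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.coupling_noise_sd <= 0 or self.age_sd <= 0 or self.baseline_hazard <= 0:
            raise ValueError("sd and hazard parameters must be positive")
        if not 0 <= self.coupled_informative_frac <= 1:
            raise ValueError("coupled_informative_frac must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort: planted labels, gene sets and effects."""

    labels: pd.Series
    cnacor_genes: list[str]
    metcor_genes: list[str]
    prognostic_genes: list[str]
    informative_genes: dict[str, list[str]]
    informative_subgroup: dict[str, dict[str, int]]
    expected_coupling_r: float
    params: SimulationParams

    def to_dict(self) -> dict:
        return {
            "labels": {s: int(v) for s, v in self.labels.items()},
            "cnacor_genes": self.cnacor_genes,
            "metcor_genes": self.metcor_genes,
            "prognostic_genes": self.prognostic_genes,
            "informative_genes": self.informative_genes,
            "informative_subgroup": self.informative_subgroup,
            "expected_coupling_r": self.expected_coupling_r,
            "params": asdict(self.params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        params = SimulationParams(**{
            **d["params"],
            "subgroup_props": tuple(d["params"]["subgroup_props"]),
            "age_shift": tuple(d["params"]["age_shift"]),
        })
        return cls(
            labels=pd.Series(d["labels"], name="subgroup"),
            cnacor_genes=list(d["cnacor_genes"]),
            metcor_genes=list(d["metcor_genes"]),
            prognostic_genes=list(d["prognostic_genes"]),
            informative_genes={k: list(v) for k, v in d["informative_genes"].items()},
            informative_subgroup={k: dict(v) for k, v in d["informative_subgroup"].items()},
            expected_coupling_r=float(d["expected_coupling_r"]),
            params=params,
        )


def _subgroup_labels(props: Sequence[float], n: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder counts per subgroup, randomly placed."""
    props = np.asarray(props, float)
    counts = np.floor(props * n).astype(int)
    remainder = props * n - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(len(props)), counts)
    return labels[rng.permutation(n)]


def _tune_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean P(censor) = target, by bisection.

    For exponential event time with rate h and censoring rate c,
    P(censored) = c / (h + c).
    """
    lo, hi = 1e-12, float(hazards.max()) * 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        frac = float(np.mean(mid / (hazards + mid)))
        if frac < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_cohort(params: SimulationParams) -> tuple[MatchedCohort, SyntheticTruth]:
    """Generate one matched cohort plus its ground truth, reproducibly from the seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, g = params.n_samples, params.n_genes
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    gene_ids = [f"G{i:04d}" for i in range(1, g + 1)]
    labels = _subgroup_labels(params.subgroup_props, n, rng)

    # disjoint planted gene sets (coupled genes excluded from informative sets so
    # the closed-form coupling correlation holds exactly)
    perm = rng.permutation(g)
    cnacor_idx = perm[: params.n_cnacor]
    metcor_idx = perm[params.n_cnacor : params.n_cnacor + params.n_metcor]
    prog_idx = perm[
        params.n_cnacor + params.n_metcor : params.n_cnacor + params.n_metcor + params.n_prognostic
    ]
    coupled = set(cnacor_idx) | set(metcor_idx)
    free_idx = np.array([i for i in range(g) if i not in coupled], dtype=int)

    cna = rng.normal(0.0, 1.0, size=(g, n))
    met = rng.normal(0.0, 1.0, size=(g, n))
    mrna = rng.normal(0.0, 1.0, size=(g, n))

    # subgroup-informative genes: a mean shift for one designated subgroup,
    # cycling through subgroups for balance. For CNA and MET a configurable
    # fraction of the quota is drawn from that omics' coupled gene set (the
    # shift is applied to the source omics before coupling, so the coupled
    # mRNA inherits it and those genes stay survival-associated through the
    # subgroup hazard term); mRNA-informative genes are drawn from free genes
    # only so coupling correlations keep their closed form.
    n_inform = int(round(params.frac_subgroup_informative * g))
    n_subgroups = len(params.subgroup_props)
    informative_genes: dict[str, list[str]] = {}
    informative_subgroup: dict[str, dict[str, int]] = {}

    def _plant_shifts(name: str, matrix: np.ndarray, pool_coupled: np.ndarray) -> None:
        n_from_coupled = min(
            int(round(params.coupled_informative_frac * n_inform)), pool_coupled.size
        )
        chosen = list(rng.choice(pool_coupled, size=n_from_coupled, replace=False)) if n_from_coupled else []
        n_free = min(n_inform - len(chosen), free_idx.size)
        if n_free > 0:
            chosen.extend(rng.choice(free_idx, size=n_free, replace=False))
        assigned = {}
        for j, idx in enumerate(np.sort(np.asarray(chosen, dtype=int))):
            target = j % n_subgroups
            matrix[idx, labels == target] += params.subgroup_effect
            assigned[gene_ids[idx]] = int(target)
        informative_genes[name] = sorted(assigned)
        informative_subgroup[name] = assigned

    _plant_shifts("CNA", cna, cnacor_idx)
    _plant_shifts("MET", met, metcor_idx)
    mrna[cnacor_idx] = params.coupling_slope * cna[cnacor_idx] + rng.normal(
        0.0, params.coupling_noise_sd, size=(params.n_cnacor, n)
    )
    mrna[metcor_idx] = -params.coupling_slope * met[metcor_idx] + rng.normal(
        0.0, params.coupling_noise_sd, size=(params.n_metcor, n)
    )
    _plant_shifts("mRNA", mrna, np.empty(0, dtype=int))

    # survival: exponential event times with multiplicative hazards so a Cox
    # model is correctly specified
    if params.n_prognostic > 0 and params.log_hazard_effect != 0.0:
        prog = mrna[prog_idx]
        z = (prog - prog.mean(axis=1, keepdims=True)) / prog.std(axis=1, keepdims=True)
        lp = params.log_hazard_effect * z.sum(axis=0)
    else:
        lp = np.zeros(n)
    lp = lp + params.subgroup_log_hazard * (labels > 0).astype(float)
    hazards = params.baseline_hazard * np.exp(lp)
    event_time = rng.exponential(1.0 / hazards)
    if params.censoring_rate > 0:
        c_rate = _tune_censoring_rate(hazards, params.censoring_rate)
        censor_time = rng.exponential(1.0 / c_rate, size=n)
        os_time = np.minimum(event_time, censor_time)
        os_event = event_time <= censor_time
    else:
        os_time = event_time
        os_event = np.ones(n, dtype=bool)

    age = rng.normal(
        params.age_mean + np.asarray(params.age_shift)[labels], params.age_sd
    )
    gender = np.where(rng.random(n) < params.male_frac, "male", "female")
    if params.with_pam50 and n_subgroups <= len(_PAM50_WEIGHTS):
        pam50 = np.array(
            [rng.choice(_PAM50, p=_PAM50_WEIGHTS[lab]) for lab in labels], dtype=object
        )
    else:
        pam50 = np.full(n, pd.NA, dtype=object)

    matrices = {}
    for kind, matrix in (("mRNA", mrna), ("CNA", cna), ("MET", met)):
        vals = matrix.copy()
        if params.missing_frac > 0:
            mask = rng.random(vals.shape) < params.missing_frac
            fully = mask.all(axis=1)
            if fully.any():  # keep >= 1 observed value per gene
                mask[fully, rng.integers(0, n, size=int(fully.sum()))] = False
            vals[mask] = np.nan
        matrices[kind] = OmicsMatrix(
            kind, pd.DataFrame(vals, index=pd.Index(gene_ids, name="gene"), columns=sample_ids)
        )

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "age": age,
                "gender": gender,
                "pam50": pd.array(pam50, dtype="string"),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    cohort = MatchedCohort(
        mrna=matrices["mRNA"], cna=matrices["CNA"], met=matrices["MET"], clinical=clinical
    )
    slope, sd = params.coupling_slope, params.coupling_noise_sd
    truth = SyntheticTruth(
        labels=pd.Series(labels, index=sample_ids, name="subgroup"),
        cnacor_genes=sorted(gene_ids[i] for i in cnacor_idx),
        metcor_genes=sorted(gene_ids[i] for i in metcor_idx),
        prognostic_genes=sorted(gene_ids[i] for i in prog_idx),
        informative_genes=informative_genes,
        informative_subgroup=informative_subgroup,
        expected_coupling_r=float(slope / np.sqrt(slope**2 + sd**2)),
        params=params,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def preset_params(name: str, seed: int = 0, **overrides) -> SimulationParams:
    """Named parameter presets: ``default``, ``null`` and ``integration-gain``.

    ``default`` mirrors the discovery-cohort geometry (292 samples, ~79/21
    subgroup split) with clearly recoverable effects. ``null`` has no planted
    structure at all. ``integration-gain`` splits a weak subgroup signal
    across the three omics so that only their fusion recovers it reliably.
    """
    if name == "default":
        base = SimulationParams(seed=seed, missing_frac=0.02, male_frac=0.05)
    elif name == "null":
        base = SimulationParams(
            n_samples=200,
            subgroup_props=(0.5, 0.5),
            n_genes=2000,
            frac_subgroup_informative=0.0,
            subgroup_effect=0.0,
            n_cnacor=0,
            n_metcor=0,
            n_prognostic=0,
            log_hazard_effect=0.0,
            subgroup_log_hazard=0.0,
            censoring_rate=0.3,
            age_shift=(0.0, 0.0),
            seed=seed,
        )
    elif name == "integration-gain":
        base = SimulationParams(
            n_samples=200,
            subgroup_props=(0.6, 0.4),
            n_genes=100,
            frac_subgroup_informative=0.10,
            subgroup_effect=1.1,
            n_cnacor=10,
            n_metcor=10,
            n_prognostic=5,
            log_hazard_effect=0.3,
            subgroup_log_hazard=1.2,
            censoring_rate=0.4,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    for key, value in overrides.items():
        if not hasattr(base, key):
            raise ValueError(f"unknown parameter {key!r}")
        setattr(base, key, value)
    base.validate()
    return base


# ---------------------------------------------------------------------------
# disk round-trip
# ---------------------------------------------------------------------------

def write_cohort(cohort: MatchedCohort, truth: SyntheticTruth, directory: str | Path) -> list[Path]:
    """Write the cohort in the tab-delimited dialect plus a truth JSON; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, matrix in (("mrna", cohort.mrna), ("cna", cohort.cna), ("met", cohort.met)):
        path = directory / f"{name}.tsv"
        write_omics_matrix(matrix, path)
        paths.append(path)
    clin_path = directory / "clinical.tsv"
    write_clinical(cohort.clinical, clin_path)
    paths.append(clin_path)
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    paths.append(truth_path)
    return paths


def read_cohort(directory: str | Path) -> tuple[MatchedCohort, SyntheticTruth | None]:
    """Read a cohort written by :func:`write_cohort` (truth is optional)."""
    directory = Path(directory)
    cohort = MatchedCohort(
        mrna=read_omics_matrix(directory / "mrna.tsv", "mRNA"),
        cna=read_omics_matrix(directory / "cna.tsv", "CNA"),
        met=read_omics_matrix(directory / "met.tsv", "MET"),
        clinical=read_clinical(directory / "clinical.tsv"),
    )
    truth_path = directory / "truth.json"
    truth = SyntheticTruth.from_dict(json.loads(truth_path.read_text())) if truth_path.exists() else None
    return cohort, truth
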