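"""Core containers for genotype-dosage and phenotype data.

Genotypes are stored as dosages: expected counts of the nonreference
allele in [0, 2], possibly non-integer after imputation.  Missing dosages
are NaN and are excluded pairwise from descriptive statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantInfo",
    "GenotypeMatrix",
    "PhenotypeTable",
    "SubregionPartition",
    "TestResult",
    "TestStatus",
    "compute_mac_tilde",
    "compute_maf",
    "filter_polymorphic",
    "partition_by_position",
    "derive_hypertension",
]


class TestStatus(str, Enum):
    CONVERGED = "converged"
    FALLBACK = "fallback"
    FAILED = "failed"


@dataclass
class VariantInfo:
    """Per-variant metadata.

    ``maf`` is the folded allele frequency min(p, 1-p) with
    p = mean(dosage)/2 over non-missing samples.  ``mac_tilde`` is the
    number of individuals with dosage strictly greater than zero — the
    carrier count used in place of a minor allele count when dosages are
    imputed and non-integer.  ``pos`` is 1-based (VCF convention).
    """

    id: str
    chrom: str = "."
    pos: int = 0
    maf: float = float("nan")
    mac_tilde: int = -1
    functional: bool = False


@dataclass
class GenotypeMatrix:
    """n x m matrix of allele dosages with variant metadata.

    Rows are samples, columns are variants.  Values lie in [0, 2] or are
    NaN (missing).
    """

    dosages: np.ndarray
    sample_ids: Sequence[str]
    variants: list[VariantInfo]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant records for {m} columns")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValueError("dosage values outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def annotate(self) -> "GenotypeMatrix":
        """Fill per-variant MAF and carrier count from the dosages."""
        for j, v in enumerate(self.variants):
            col = self.dosages[:, j]
            v.maf = compute_maf(col)
            v.mac_tilde = compute_mac_tilde(col)
        return self

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        ids = [s for s, keep in zip(self.sample_ids, mask) if keep]
        return GenotypeMatrix(self.dosages[mask], ids, list(self.variants))

    def subset_variants(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.sample_ids),
            [self.variants[j] for j in idx],
        )

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants])

    @property
    def mafs(self) -> np.ndarray:
        return np.array([v.maf for v in self.variants])


@dataclass
class PhenotypeTable:
    """Binary outcome plus covariates for a cohort.

    ``outcome`` is 0/1 (NaN when missing); ``sex`` is a 0/1 code.  The
    optional blood-pressure columns support deriving a hypertension
    outcome; ``q1`` carries the latent quantitative trait used by the
    simulation scenarios.
    """

    sample_ids: Sequence[str]
    outcome: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    sbp: Optional[np.ndarray] = None
    dbp: Optional[np.ndarray] = None
    meds: Optional[np.ndarray] = None
    q1: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        n = len(self.sample_ids)
        for name in ("outcome", "age", "sex"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length of {name} does not match sample_ids")
        obs = self.outcome[~np.isnan(self.outcome)]
        if obs.size and not np.all(np.isin(obs, [0.0, 1.0])):
            raise ValueError("outcome must be 0/1 where observed")

    def complete_case_mask(self) -> np.ndarray:
        """Samples with non-missing outcome, age and sex."""
        return (
            ~np.isnan(self.outcome) & ~np.isnan(self.age) & ~np.isnan(self.sex)
        )

    def covariate_design(self, mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Design matrix [1, AGE, SEX] over the given sample mask."""
        if mask is None:
            mask = self.complete_case_mask()
        return np.column_stack(
            [np.ones(int(mask.sum())), self.age[mask], self.sex[mask]]
        )

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            "sample_id": list(self.sample_ids),
            "outcome": self.outcome,
            "age": self.age,
            "sex": self.sex,
        }
        for name in ("sbp", "dbp", "meds", "q1"):
            val = getattr(self, name)
            if val is not None:
                data[name] = val
        return pd.DataFrame(data)


@dataclass
class SubregionPartition:
    """Assignment of variants to K position-contiguous subregions (1..K)."""

    assignments: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        labels = np.unique(self.assignments)
        if labels.size and (labels.min() < 1 or labels.max() > self.K):
            raise ValueError("subregion labels must lie in 1..K")

    def indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == k)

    def sizes(self) -> list[int]:
        return [int(np.sum(self.assignments == k)) for k in range(1, self.K + 1)]


@dataclass
class TestResult:
    """One association test outcome for a variant or a subregion."""

    target: str
    method: str
    statistic: float
    p_value: float
    df_or_params: dict = field(default_factory=dict)
    status: TestStatus = TestStatus.CONVERGED

    def __post_init__(self) -> None:
        if self.status != TestStatus.FAILED:
            if not (0.0 <= self.p_value <= 1.0):
                raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def compute_mac_tilde(dosage_column: np.ndarray) -> int:
    """Count of individuals with dosage strictly greater than zero.

    This carrier count stands in for the minor allele count when
    dosages are imputed (possibly fractional); the two coincide closely
    at low MAF.
    """
    col = np.asarray(dosage_column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValueError("all dosages missing; variant unusable")
    return int(np.sum(obs > 0))


def compute_maf(dosage_column: np.ndarray) -> float:
    """Folded minor allele frequency min(p, 1-p), p = mean(dosage)/2."""
    col = np.asarray(dosage_column, dtype=float)
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValueError("all dosages missing; variant unusable")
    p = float(np.mean(obs)) / 2.0
    return min(p, 1.0 - p)


def filter_polymorphic(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep variants with >=2 distinct observed dosage values and MAF > 0."""
    keep = []
    for j in range(gm.n_variants):
        col = gm.dosages[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            continue
        if np.unique(obs).size < 2:
            continue
        if compute_maf(col) <= 0:
            continue
        keep.append(j)
    out = gm.subset_variants(keep)
    out.annotate()
    return out


def partition_by_position(
    variants: Sequence[VariantInfo],
    K: int,
    sizes: Optional[Sequence[int]] = None,
) -> SubregionPartition:
    """Group variants into K position-contiguous subregions.

    The default rule cuts the position order into K equal-count bins.
    ``sizes`` overrides with explicit group sizes (in position order),
    for boundaries chosen by eye from the physical layout.
    """
    m = len(variants)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > m:
        raise ValueError(f"K={K} exceeds the number of variants ({m})")
    order = np.argsort([v.pos for v in variants], kind="stable")
    assignments = np.empty(m, dtype=int)
    if sizes is not None:
        if len(sizes) != K or sum(sizes) != m:
            raise ValueError("explicit sizes must be length K and sum to m")
        bounds = np.cumsum([0] + list(sizes))
        for k in range(K):
            assignments[order[bounds[k] : bounds[k + 1]]] = k + 1
    else:
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(m)
        assignments[:] = (ranks * K) // m + 1
    return SubregionPartition(assignments, K)


def derive_hypertension(sbp, dbp, meds):
    """Hypertension from diagnostic criteria: SBP > 140, DBP > 90, or meds.

    Boundary readings (exactly 140/90) are non-hypertensive.  Vectorized;
    returns NaN where all three inputs are missing, or where the pressures
    are missing and medication status alone cannot establish the outcome.
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    meds_arr = np.asarray(meds, dtype=float)
    scalar = sbp.ndim == 0
    sbp, dbp, meds_arr = np.atleast_1d(sbp, dbp, meds_arr)

    with np.errstate(invalid="ignore"):
        high = (sbp > 140) | (dbp > 90)
    on_meds = meds_arr == 1
    out = np.where(high | on_meds, 1.0, 0.0)
    # A negative determination needs both pressures observed (or meds=1).
    pressures_known = ~np.isnan(sbp) & ~np.isnan(dbp)
    undetermined = ~(high | on_meds) & ~pressures_known
    out[undetermined] = np.nan
    all_missing = np.isnan(sbp) & np.isnan(dbp) & np.isnan(meds_arr)
    out[all_missing] = np.nan
    return float(out[0]) if scalar else out
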