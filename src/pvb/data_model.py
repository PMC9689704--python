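"""Core data structures for partially verified diagnostic test data.

A diagnostic accuracy study with partial verification records, per subject,
a binary index test result ``T``, a verification indicator ``V`` (whether
the gold standard was applied), and the gold-standard disease status ``D``,
which is observed only when ``V = 1``.  Every estimator in this package is
a function of the six-cell reduction of such data: the 2x2 table of (T, D)
among verified subjects plus the unverified counts in each test stratum.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "VerificationDataset",
    "CellCounts",
    "AccuracyEstimate",
    "Violation",
    "reduce_to_counts",
    "counts_to_dataset",
    "validate_dataset",
]


@dataclass(frozen=True)
class VerificationDataset:
    """Subject-level records of a partially verified diagnostic study.

    Parameters
    ----------
    test
        Index test result, 0/1, length ``N``.
    verified
        Verification indicator, 0/1, length ``N``.
    disease
        Gold-standard disease status, stored as floats with ``nan`` marking
        the unverified subjects.  An unverified subject never carries a 0/1
        disease value, so no estimator can accidentally use it.
    """

    test: np.ndarray
    verified: np.ndarray
    disease: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "test", np.asarray(self.test, dtype=np.int8))
        object.__setattr__(self, "verified", np.asarray(self.verified, dtype=np.int8))
        object.__setattr__(self, "disease", np.asarray(self.disease, dtype=float))
        if not (len(self.test) == len(self.verified) == len(self.disease)):
            raise ValueError("test, verified and disease must have equal length")
        if len(self.test) == 0:
            raise ValueError("dataset must contain at least one subject")

    @property
    def n_subjects(self) -> int:
        return len(self.test)

    @property
    def n_verified(self) -> int:
        return int(self.verified.sum())

    @property
    def pct_unverified(self) -> float:
        """Percentage of subjects without gold-standard verification."""
        return 100.0 * (1.0 - self.n_verified / self.n_subjects)

    def validate(self) -> None:
        """Raise ``ValueError`` listing every invariant violation."""
        violations = validate_dataset(self)
        if violations:
            raise ValueError(
                "invalid dataset: " + "; ".join(str(v) for v in violations)
            )


@dataclass(frozen=True)
class CellCounts:
    """Sufficient statistic: the six observable cells of a PVB data set.

    ``s`` cells count verified subjects by (test, disease); ``u`` cells
    count unverified subjects by test result alone.
    """

    s11: int  # T=1, D=1, V=1
    s10: int  # T=1, D=0, V=1
    s01: int  # T=0, D=1, V=1
    s00: int  # T=0, D=0, V=1
    u1: int = 0  # T=1, V=0
    u0: int = 0  # T=0, V=0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {f.name}={v} must be a nonnegative integer")

    @property
    def n(self) -> int:
        """Number of verified (complete-case) subjects."""
        return self.s11 + self.s10 + self.s01 + self.s00

    @property
    def total(self) -> int:
        """Total sample size N."""
        return self.n + self.u1 + self.u0

    @property
    def n_t1(self) -> int:
        """Subjects with a positive test, verified or not."""
        return self.s11 + self.s10 + self.u1

    @property
    def n_t0(self) -> int:
        return self.s01 + self.s00 + self.u0

    @property
    def p_t1(self) -> float:
        """Empirical P(T=1) over all N subjects."""
        return self.n_t1 / self.total

    @property
    def fully_verified(self) -> bool:
        return self.u1 == 0 and self.u0 == 0


@dataclass(frozen=True)
class AccuracyEstimate:
    """Paired sensitivity/specificity estimate from one correction method.

    ``sn_se``/``sp_se`` and the confidence intervals are ``None`` where a
    method does not define them.  Intervals are clipped to [0, 1]; the
    unclipped endpoints are retained in ``sn_ci_raw``/``sp_ci_raw`` for
    diagnostics.
    """

    method: str
    sn: float
    sp: float
    sn_se: float | None = None
    sp_se: float | None = None
    sn_ci: tuple[float, float] | None = None
    sp_ci: tuple[float, float] | None = None
    sn_ci_raw: tuple[float, float] | None = None
    sp_ci_raw: tuple[float, float] | None = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("sn", "sp"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 or math.isnan(v)):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("sn_se", "sp_se"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name}={v} must be nonnegative")


@dataclass(frozen=True)
class Violation:
    """A single invariant violation found by :func:`validate_dataset`."""

    rule: str
    rows: tuple[int, ...]
    message: str

    def __str__(self) -> str:
        rows = ", ".join(map(str, self.rows[:10]))
        more = "" if len(self.rows) <= 10 else f" (+{len(self.rows) - 10} more)"
        return f"{self.rule} at rows [{rows}{more}]: {self.message}"


def validate_dataset(data: VerificationDataset) -> list[Violation]:
    """Check a dataset against the structural invariants, returning findings.

    An empty list means the dataset is valid.  Row indices are 0-based.
    """
    out: list[Violation] = []

    def _bad_binary(arr: np.ndarray, name: str) -> None:
        bad = np.flatnonzero(~np.isin(arr, (0, 1)))
        if bad.size:
            out.append(
                Violation(
                    rule=f"{name}_not_binary",
                    rows=tuple(int(i) for i in bad),
                    message=f"column '{name}' must be 0 or 1",
                )
            )

    _bad_binary(data.test, "test")
    _bad_binary(data.verified, "verified")

    miss = np.isnan(data.disease)
    verified = data.verified == 1
    bad = np.flatnonzero(verified & miss)
    if bad.size:
        out.append(
            Violation(
                rule="disease_missing_for_verified",
                rows=tuple(int(i) for i in bad),
                message="disease must be observed where verified=1",
            )
        )
    bad = np.flatnonzero(~verified & ~miss)
    if bad.size:
        out.append(
            Violation(
                rule="disease_present_for_unverified",
                rows=tuple(int(i) for i in bad),
                message="disease must be missing where verified=0",
            )
        )
    obs = data.disease[~miss]
    bad_vals = np.flatnonzero(~miss)[~np.isin(obs, (0.0, 1.0))]
    if bad_vals.size:
        out.append(
            Violation(
                rule="disease_not_binary",
                rows=tuple(int(i) for i in bad_vals),
                message="observed disease must be 0 or 1",
            )
        )
    return out


def reduce_to_counts(data: VerificationDataset) -> CellCounts:
    """Tabulate a subject-level dataset into its six-cell sufficient statistic.

    Raises ``ValueError`` (naming offending rows) if the dataset violates
    the structural invariants.
    """
    data.validate()
    t = data.test
    v = data.verified == 1
    d = data.disease
    return CellCounts(
        s11=int(np.sum(v & (t == 1) & (d == 1))),
        s10=int(np.sum(v & (t == 1) & (d == 0))),
        s01=int(np.sum(v & (t == 0) & (d == 1))),
        s00=int(np.sum(v & (t == 0) & (d == 0))),
        u1=int(np.sum(~v & (t == 1))),
        u0=int(np.sum(~v & (t == 0))),
    )


def counts_to_dataset(counts: CellCounts) -> VerificationDataset:
    """Expand cell counts into a canonical subject-level dataset.

    Inverse of :func:`reduce_to_counts` up to subject order.
    """
    blocks: list[tuple[int, int, float, int]] = [
        (counts.s11, 1, 1.0, 1),
        (counts.s10, 1, 0.0, 1),
        (counts.s01, 0, 1.0, 1),
        (counts.s00, 0, 0.0, 1),
        (counts.u1, 1, np.nan, 0),
        (counts.u0, 0, np.nan, 0),
    ]
    test: list[int] = []
    disease: list[float] = []
    verified: list[int] = []
    for k, t, d, v in blocks:
        test.extend([t] * k)
        disease.extend([d] * k)
        verified.extend([v] * k)
    return VerificationDataset(
        test=np.array(test), verified=np.array(verified), disease=np.array(disease)
    )
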