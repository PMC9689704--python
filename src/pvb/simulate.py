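"""Synthetic data generation for partial verification bias studies.

Complete data are multinomial over the four (T, D) cells with probabilities
determined by prevalence ``p``, sensitivity and specificity:

    pi1 = P(T=1, D=1) = Sn * p
    pi2 = P(T=0, D=1) = (1 - Sn) * p
    pi3 = P(T=1, D=0) = (1 - Sp) * (1 - p)
    pi4 = P(T=0, D=0) = Sp * (1 - p)

Partial verification is then imposed missing-at-random: each subject is
verified with probability depending only on the test result,
``P(V=1 | T=t)``, and disease status is masked for unverified subjects.
The default verification probabilities (0.8 for test-positives, 0.4 for
test-negatives) encode the usual clinical work-up pattern in which a
positive index test makes gold-standard referral twice as likely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .data_model import CellCounts, VerificationDataset

__all__ = [
    "ScenarioConfig",
    "CompleteTable",
    "cell_probabilities",
    "verification_fraction",
    "generate_complete",
    "apply_mar_verification",
    "generate_replicate_counts",
    "generate_dataset",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """True parameters of one simulation scenario.

    Parameters
    ----------
    p
        Disease prevalence P(D=1), in (0, 1).
    sn_true, sp_true
        True sensitivity P(T=1|D=1) and specificity P(T=0|D=0), in (0, 1].
    pv1, pv0
        Verification probabilities P(V=1|T=1) and P(V=1|T=0).
    n
        Sample size N per generated dataset.
    seed
        Master seed; replicate streams are derived from it.
    """

    p: float
    sn_true: float
    sp_true: float
    pv1: float = 0.8
    pv0: float = 0.4
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"prevalence p={self.p} must be in (0, 1)")
        for name in ("sn_true", "sp_true"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} must be in (0, 1]")
        if not 0.0 < self.pv1 <= 1.0:
            raise ValueError(f"pv1={self.pv1} must be in (0, 1]")
        if not 0.0 <= self.pv0 <= 1.0:
            raise ValueError(f"pv0={self.pv0} must be in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def p_t1(self) -> float:
        """Marginal P(T=1) implied by the scenario."""
        pi1, _, pi3, _ = cell_probabilities(self)
        return pi1 + pi3


class CompleteTable(NamedTuple):
    """Complete-data 2x2 cell counts (every subject verified)."""

    n11: int  # T=1, D=1
    n01: int  # T=0, D=1
    n10: int  # T=1, D=0
    n00: int  # T=0, D=0

    @property
    def total(self) -> int:
        return sum(self)

    def as_counts(self) -> CellCounts:
        return CellCounts(s11=self.n11, s10=self.n10, s01=self.n01, s00=self.n00)


def cell_probabilities(cfg: ScenarioConfig) -> tuple[float, float, float, float]:
    """Multinomial cell probabilities (pi1, pi2, pi3, pi4) of the complete data."""
    pi1 = cfg.sn_true * cfg.p
    pi2 = (1.0 - cfg.sn_true) * cfg.p
    pi3 = (1.0 - cfg.sp_true) * (1.0 - cfg.p)
    pi4 = cfg.sp_true * (1.0 - cfg.p)
    return pi1, pi2, pi3, pi4


def verification_fraction(cfg: ScenarioConfig) -> float:
    """Analytic overall verification probability P(V=1).

    P(V=1) = pv1 * P(T=1) + pv0 * (1 - P(T=1)).
    """
    pt1 = cfg.p_t1
    return cfg.pv1 * pt1 + cfg.pv0 * (1.0 - pt1)


def generate_complete(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> VerificationDataset:
    """Draw a complete dataset of size N with every subject verified.

    A single N-trial multinomial over the four cells, expanded to subject
    rows and shuffled; equivalent in distribution to per-subject
    categorical draws.
    """
    pi = cell_probabilities(cfg)
    counts = rng.multinomial(cfg.n, pi)
    # cell order: (T=1,D=1), (T=0,D=1), (T=1,D=0), (T=0,D=0)
    t = np.repeat([1, 0, 1, 0], counts).astype(np.int8)
    d = np.repeat([1.0, 1.0, 0.0, 0.0], counts)
    order = rng.permutation(cfg.n)
    return VerificationDataset(
        test=t[order], verified=np.ones(cfg.n, dtype=np.int8), disease=d[order]
    )


def apply_mar_verification(
    data: VerificationDataset,
    pv1: float,
    pv0: float,
    rng: np.random.Generator,
) -> VerificationDataset:
    """Mask disease status missing-at-random given the test result.

    Each subject's verification indicator is drawn Bernoulli with
    probability ``pv1`` if test-positive, ``pv0`` if test-negative; disease
    is set missing where unverified.  Test results are never altered.
    """
    if not np.all(data.verified == 1):
        raise ValueError("apply_mar_verification expects a fully verified dataset")
    pv = np.where(data.test == 1, pv1, pv0)
    verified = (rng.random(data.n_subjects) < pv).astype(np.int8)
    disease = np.where(verified == 1, data.disease, np.nan)
    return VerificationDataset(test=data.test, verified=verified, disease=disease)


def generate_dataset(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[VerificationDataset, VerificationDataset]:
    """Generate one replicate: the complete dataset and its masked version."""
    complete = generate_complete(cfg, rng)
    masked = apply_mar_verification(complete, cfg.pv1, cfg.pv0, rng)
    return complete, masked


def generate_replicate_counts(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[CompleteTable, CellCounts]:
    """Count-level replicate generator used by the Monte-Carlo engine.

    Draws the complete 2x2 table from the multinomial and thins each cell
    binomially with the test-specific verification probability.  This is
    distributionally identical to generating subjects and masking them one
    by one, and orders of magnitude faster.
    """
    pi = cell_probabilities(cfg)
    n11, n01, n10, n00 = rng.multinomial(cfg.n, pi)
    complete = CompleteTable(n11=int(n11), n01=int(n01), n10=int(n10), n00=int(n00))
    s11 = int(rng.binomial(n11, cfg.pv1))
    s10 = int(rng.binomial(n10, cfg.pv1))
    s01 = int(rng.binomial(n01, cfg.pv0))
    s00 = int(rng.binomial(n00, cfg.pv0))
    masked = CellCounts(
        s11=s11,
        s10=s10,
        s01=s01,
        s00=s00,
        u1=int(n11 + n10 - s11 - s10),
        u0=int(n01 + n00 - s01 - s00),
    )
    return complete, masked
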