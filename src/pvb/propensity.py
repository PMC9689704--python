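"""Verification propensity scores and inverse-probability bootstrap weights.

The propensity score here is the probability of gold-standard verification
given the test result, PS_i = P(V_i=1 | T_i).  With a single binary
covariate the logistic regression of V on T is saturated, so its fitted
probabilities are exactly the verified fractions within each test stratum;
the closed form is used (an iterative fit gives the identical numbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import CellCounts, VerificationDataset, reduce_to_counts

__all__ = ["PropensityModel", "fit_propensity", "ipb_weights"]


@dataclass(frozen=True)
class PropensityModel:
    """Verification probability per test stratum.

    ``source`` is "fitted" when estimated from data, "known" when supplied
    externally (e.g. the true mechanism in oracle experiments).
    """

    ps_t1: float
    ps_t0: float
    source: str = "fitted"

    def __post_init__(self) -> None:
        for name in ("ps_t1", "ps_t0"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(
                    f"non-positive propensity ({name}={v}); IPWE/IPB undefined"
                )

    def for_tests(self, test: np.ndarray) -> np.ndarray:
        """Per-subject propensity vector for a 0/1 test-result vector."""
        return np.where(np.asarray(test) == 1, self.ps_t1, self.ps_t0)

    @classmethod
    def known(cls, pv1: float, pv0: float) -> "PropensityModel":
        return cls(ps_t1=pv1, ps_t0=pv0, source="known")


def fit_propensity(data: VerificationDataset | CellCounts) -> PropensityModel:
    """Fit PS = P(V=1 | T) by (saturated) logistic regression of V on T.

    Raises ``ValueError`` when a test stratum is empty or has no verified
    subject, since a zero propensity makes the inverse weighting undefined.
    """
    counts = reduce_to_counts(data) if isinstance(data, VerificationDataset) else data
    k1, k0 = counts.s11 + counts.s10, counts.s01 + counts.s00
    if counts.n_t1 == 0 or counts.n_t0 == 0:
        raise ValueError("both test strata must be non-empty to fit the propensity")
    if k1 == 0 or k0 == 0:
        raise ValueError("non-positive propensity; IPWE/IPB undefined")
    return PropensityModel(
        ps_t1=k1 / counts.n_t1, ps_t0=k0 / counts.n_t0, source="fitted"
    )


def ipb_weights(ps: np.ndarray) -> np.ndarray:
    """Normalized inverse-propensity resampling weights over complete cases.

    w_i = (1 / PS_i) / sum_j (1 / PS_j), so the weights sum to one and are
    invariant to rescaling every PS by a common constant.  Subjects from
    under-verified strata receive proportionally more resampling mass,
    which is what removes the verification bias from bootstrap samples.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.ndim != 1 or ps.size == 0:
        raise ValueError("ps must be a non-empty 1-d vector")
    if np.any(ps <= 0):
        raise ValueError("all propensity scores must be positive")
    inv = 1.0 / ps
    return inv / inv.sum()
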