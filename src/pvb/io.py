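"""Readers and writers for the subject-level CSV layout and result tables.

The clinical CSV layout has three binary columns, ``disease``, ``test``
and ``verified`` (any order, case-insensitive header); ``disease`` is
empty or ``NA`` for unverified subjects.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import AccuracyEstimate, VerificationDataset, validate_dataset

__all__ = [
    "read_clinical_csv",
    "write_clinical_csv",
    "estimates_to_frame",
    "write_estimates",
    "write_results",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("disease", "test", "verified")
MISSING_TOKENS = {"", "na"}


class SchemaError(ValueError):
    """Raised when a CSV does not match the clinical data layout."""


def _parse_binary(series: pd.Series, name: str, allow_missing: bool) -> np.ndarray:
    raw = series.astype("string").str.strip()
    out = np.full(len(raw), np.nan)
    bad_rows = []
    for i, tok in enumerate(raw):
        low = "" if pd.isna(tok) else tok.lower()
        if low in MISSING_TOKENS:
            if not allow_missing:
                bad_rows.append(i)
            continue
        if low in {"0", "1"}:
            out[i] = float(low)
        else:
            bad_rows.append(i)
    if bad_rows:
        shown = ", ".join(str(r + 2) for r in bad_rows[:10])  # 1-based + header
        raise SchemaError(
            f"column '{name}': invalid values at file line(s) {shown}"
            + ("" if len(bad_rows) <= 10 else f" (+{len(bad_rows) - 10} more)")
        )
    return out


def read_clinical_csv(path: str | Path) -> VerificationDataset:
    """Read and validate a subject-level CSV in the clinical layout.

    Accepts empty cells or the literal ``NA`` (case-insensitive) as missing
    disease status; any other non-0/1 token is a schema error naming the
    offending line.  Logs N, the number verified, and the percentage of
    unverified subjects.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    df.columns = [c.strip().lower() for c in df.columns]
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing_cols)}")
    if len(df) == 0:
        raise SchemaError(f"{path}: no data rows")

    test = _parse_binary(df["test"], "test", allow_missing=False)
    verified = _parse_binary(df["verified"], "verified", allow_missing=False)
    disease = _parse_binary(df["disease"], "disease", allow_missing=True)

    data = VerificationDataset(
        test=test.astype(int), verified=verified.astype(int), disease=disease
    )
    violations = validate_dataset(data)
    if violations:
        raise SchemaError(
            f"{path}: " + "; ".join(str(v) for v in violations)
        )
    logger.info(
        "%s: N = %d, verified = %d, %% unverified = %.1f%%",
        path.name, data.n_subjects, data.n_verified, data.pct_unverified,
    )
    return data


def write_clinical_csv(data: VerificationDataset, path: str | Path) -> None:
    """Write a dataset in the clinical CSV layout (missing disease as NA)."""
    df = pd.DataFrame(
        {
            "disease": [
                "NA" if np.isnan(d) else str(int(d)) for d in data.disease
            ],
            "test": data.test.astype(int),
            "verified": data.verified.astype(int),
        }
    )
    df.to_csv(path, index=False)


def _fmt_ci(ci: tuple[float, float] | None) -> str:
    return "" if ci is None else f"({ci[0]:.3f}, {ci[1]:.3f})"


def estimates_to_frame(estimates: list[AccuracyEstimate]) -> pd.DataFrame:
    """One row per method: point estimates, SEs and interval endpoints."""
    return pd.DataFrame(
        {
            "method": [e.method for e in estimates],
            "sn": [e.sn for e in estimates],
            "sn_se": [e.sn_se for e in estimates],
            "sn_ci_lo": [e.sn_ci[0] if e.sn_ci else np.nan for e in estimates],
            "sn_ci_hi": [e.sn_ci[1] if e.sn_ci else np.nan for e in estimates],
            "sp": [e.sp for e in estimates],
            "sp_se": [e.sp_se for e in estimates],
            "sp_ci_lo": [e.sp_ci[0] if e.sp_ci else np.nan for e in estimates],
            "sp_ci_hi": [e.sp_ci[1] if e.sp_ci else np.nan for e in estimates],
            "alpha": [e.alpha for e in estimates],
        }
    )


def write_estimates(estimates: list[AccuracyEstimate], path: str | Path) -> None:
    """Write method estimates to CSV at full precision, fixed column order."""
    if not estimates:
        raise ValueError("no estimates to write")
    estimates_to_frame(estimates).to_csv(path, index=False)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write long-format simulation results to CSV at full precision."""
    if len(results) == 0:
        raise ValueError("no results to write")
    results.to_csv(path, index=False)
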