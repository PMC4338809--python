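"""Pearson correlation battery and cubic trend fit for endpoint tables.

The battery mirrors the six response/predictor pairs of the study design:
{ETSA, DOC, stability} against species richness (SR) and community metabolic
diversity (CMD), in the fixed order

    (etsa, richness), (doc, richness), (stability, richness),
    (etsa, cmd), (doc, cmd), (stability, cmd).

No multiple-testing correction is applied (flagged in the report).
Significance stars: ``•`` p < 0.05, ``••`` p < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import DegenerateCorrelationError, DomainError, FormatError

__all__ = [
    "CorrelationResult",
    "pearson",
    "correlation_battery",
    "consortium_mean_table",
    "cubic_trend",
    "validate_endpoint_table",
    "battery_summary_text",
    "BATTERY_PAIRS",
]

BATTERY_PAIRS: tuple[tuple[str, str], ...] = (
    ("etsa", "richness"),
    ("doc", "richness"),
    ("stability", "richness"),
    ("etsa", "cmd"),
    ("doc", "cmd"),
    ("stability", "cmd"),
)

ENDPOINT_COLUMNS = ("microcosm_id", "consortium_label", "richness", "cmd", "etsa", "doc")


@dataclass(frozen=True)
class CorrelationResult:
    response: str
    predictor: str
    r: float
    p: float
    n: int

    @property
    def stars(self) -> str:
        if self.p < 0.01:
            return "••"
        if self.p < 0.05:
            return "•"
        return ""


def pearson(x, y, labels: tuple[str, str] = ("y", "x")) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-test p-value.

    r = S_xy / sqrt(S_xx S_yy); p from t = r sqrt((n-2)/(1-r^2)) with n-2
    degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError(f"shape mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n < 3:
        raise DomainError(f"need at least 3 observations, got {n}")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0 or syy == 0:
        raise DegenerateCorrelationError(
            f"zero-variance input for pair ({labels[0]}, {labels[1]})"
        )
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    return CorrelationResult(labels[0], labels[1], r, p, n)


def validate_endpoint_table(table: pd.DataFrame, require_stability: bool = False) -> None:
    cols = list(ENDPOINT_COLUMNS) + (["stability"] if require_stability else [])
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise FormatError(f"endpoint table missing columns: {missing}")
    analyzed = [c for c in ("richness", "cmd", "etsa", "doc") if c in table.columns]
    if require_stability:
        analyzed.append("stability")
    if table[analyzed].isna().any().any():
        raise FormatError("endpoint table has missing values in analyzed columns")
    for col in ("richness", "cmd"):
        per = table.groupby("consortium_label")[col].nunique()
        bad = per[per > 1]
        if len(bad):
            raise FormatError(f"{col} varies within consortium replicates: {list(bad.index)}")


def correlation_battery(table: pd.DataFrame) -> list[CorrelationResult]:
    """The six Pearson correlations in fixed order; errors name the pair."""
    validate_endpoint_table(table, require_stability=True)
    out = []
    for response, predictor in BATTERY_PAIRS:
        out.append(
            pearson(
                table[predictor].to_numpy(),
                table[response].to_numpy(),
                labels=(response, predictor),
            )
        )
    return out


def consortium_mean_table(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate microcosms to consortium means (n = 17 at defaults)."""
    value_cols = [c for c in ("richness", "cmd", "etsa", "doc", "stability") if c in table.columns]
    out = table.groupby("consortium_label", as_index=False)[value_cols].mean()
    out.insert(0, "microcosm_id", out["consortium_label"])
    return out


def cubic_trend(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares cubic fit.

    Returns ``(coeffs, fitted)`` with coefficients in ascending power order
    (c0 + c1 x + c2 x^2 + c3 x^3).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError(f"shape mismatch: {x.shape} vs {y.shape}")
    if len(np.unique(x)) < 4:
        raise DomainError("cubic fit requires at least 4 distinct x values")
    X = np.vander(x, 4, increasing=True)
    coeffs, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coeffs, X @ coeffs


def battery_summary_text(results: list[CorrelationResult]) -> str:
    """Plain-text statistics block with significance stars."""
    lines = ["pair                     r        p        n  sig"]
    for res in results:
        pair = f"{res.response} ~ {res.predictor}"
        lines.append(f"{pair:<22} {res.r:+.3f}  {res.p:.4g}  {res.n:3d}  {res.stars}")
    lines.append("note: no multiple-testing correction applied")
    return "\n".join(lines)
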