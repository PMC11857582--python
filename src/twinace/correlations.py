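"""Intra-pair correlations by zygosity and Falconer-style moment estimators.

The intra-pair correlation is computed on the *double-entered* pairing: each
pair contributes both member orderings, so the estimate is invariant to the
arbitrary order in which members appear in the file.  Confidence intervals
use the Fisher z transform with the number of pairs (not doubled rows) as
the effective sample size.  An intraclass-correlation (ANOVA) variant is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError, ValidationError
from .io import TwinPairRecord

__all__ = [
    "CorrelationResult",
    "FalconerEstimates",
    "intrapair_correlation",
    "falconer_estimates",
    "residualize",
]


@dataclass(frozen=True)
class CorrelationResult:
    trait: str
    zygosity: str
    r: float
    n_pairs: int
    ci95: tuple[float, float]


@dataclass(frozen=True)
class FalconerEstimates:
    """Moment estimates h2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ, e2 = 1 - rMZ.

    The raw formula values always sum to 1; when any is negative the triple
    is clamped to [0, 1] and renormalized, with ``clamped=True``.
    """

    h2: float
    c2: float
    e2: float
    clamped: bool


def _values_matrix(pairs: Sequence[TwinPairRecord]) -> np.ndarray:
    return np.array([p.values for p in pairs], dtype=float)


def intrapair_correlation(
    pairs: Sequence[TwinPairRecord],
    trait: str = "",
    *,
    method: str = "double_entry",
    conf_level: float = 0.95,
) -> CorrelationResult:
    """Intra-pair correlation for one zygosity group of complete pairs.

    ``method="double_entry"`` (default) computes a Pearson correlation on the
    table with each pair entered in both orders; ``method="icc"`` computes the
    one-way ANOVA intraclass correlation.  Both are member-order invariant.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise InsufficientDataError(f"need >=3 complete pairs, got {len(pairs)}")
    zygs = {p.zygosity for p in pairs}
    if len(zygs) != 1:
        raise ValidationError(f"pairs span multiple zygosity groups: {sorted(zygs)}")
    v = _values_matrix(pairs)
    if np.ptp(v) == 0:
        raise DegenerateDataError("trait is constant across all pair members")
    n = len(pairs)

    if method == "double_entry":
        x = np.concatenate([v[:, 0], v[:, 1]])
        y = np.concatenate([v[:, 1], v[:, 0]])
        sx = x.std()
        if sx == 0 or y.std() == 0:
            raise DegenerateDataError("zero variance in double-entered values")
        r = float(np.corrcoef(x, y)[0, 1])
    elif method == "icc":
        ms_b = 2.0 * v.mean(axis=1).var(ddof=1)
        ms_w = float(((v[:, 0] - v[:, 1]) ** 2).sum() / (2.0 * n))
        r = float((ms_b - ms_w) / (ms_b + ms_w))
    else:
        raise ValidationError(f"unknown correlation method {method!r}")

    r = float(np.clip(r, -1.0, 1.0))
    # Fisher z interval with n_pairs as the effective sample size
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        q = stats.norm.ppf(0.5 + conf_level / 2.0)
        lo, hi = float(np.tanh(z - q * se)), float(np.tanh(z + q * se))
    else:
        lo, hi = -1.0, 1.0
    return CorrelationResult(trait=trait, zygosity=zygs.pop(), r=r, n_pairs=n, ci95=(lo, hi))


def falconer_estimates(r_mz: float, r_dz: float) -> FalconerEstimates:
    """Falconer decomposition from the two intra-pair correlations."""
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValidationError(f"correlation out of [-1, 1]: {r}")
    h2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    e2 = 1.0 - r_mz
    if min(h2, c2, e2) >= 0.0 and max(h2, c2, e2) <= 1.0:
        return FalconerEstimates(h2=h2, c2=c2, e2=e2, clamped=False)
    vals = np.clip([h2, c2, e2], 0.0, 1.0)
    total = vals.sum()
    if total == 0:
        vals = np.array([0.0, 0.0, 1.0])
        total = 1.0
    vals = vals / total
    return FalconerEstimates(h2=float(vals[0]), c2=float(vals[1]), e2=float(vals[2]), clamped=True)


def residualize(pairs: Iterable[TwinPairRecord]) -> list[TwinPairRecord]:
    """Replace trait values with residuals from an OLS fit on age and sex.

    All members of all supplied pairs (both zygosity groups together) enter a
    single regression ``value ~ 1 + age + [sex == M]``; the returned records
    carry the residuals.  Used for age/sex-adjusted correlations, mirroring
    the covariate adjustment inside the likelihood models.
    """
    import statsmodels.api as sm

    pairs = list(pairs)
    if not pairs:
        return []
    y = np.array([v for p in pairs for v in p.values], dtype=float)
    age = np.array([a for p in pairs for a in p.ages], dtype=float)
    sex = np.array([1.0 if s == "M" else 0.0 for p in pairs for s in p.sexes])
    X = sm.add_constant(np.column_stack([age, sex]), has_constant="add")
    resid = sm.OLS(y, X).fit().resid
    out = []
    for i, p in enumerate(pairs):
        out.append(
            TwinPairRecord(
                pair_id=p.pair_id,
                zygosity=p.zygosity,
                values=(float(resid[2 * i]), float(resid[2 * i + 1])),
                ages=p.ages,
                sexes=p.sexes,
            )
        )
    return out
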