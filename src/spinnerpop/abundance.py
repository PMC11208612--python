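"""Scaling marked abundance to total abundance.

Estimates from capture histories refer to the marked (distinctive) animals
only.  Total abundance divides by the mark rate,

    N_total = N_m / θ,

with a delta-method standard error combining the relative variance of N_m and
the binomial uncertainty of θ,

    SE(N_total) = sqrt( N_total² · ( SE(N_m)²/N_m² + (1−θ)/(nθ) ) ),

and log-normal 95% confidence limits (N_total/C, N_total·C) with

    C = exp( z · sqrt( ln(1 + (SE/N_total)²) ) ),  z = 1.96.

``n`` is the sample size behind the binomial term; here it is the number of
distinct individuals identified in the period being scaled (exposed as an
explicit argument so callers can substitute another convention).  All
computation is on unrounded values; the reporting layer rounds abundances to
integers and SEs to one decimal, and additionally recomputes CI bounds from
the rounded (N, SE) pair, which is how published tables are typically
assembled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

Z_95 = 1.96  # fixed conventional value, not the exact 97.5% quantile


@dataclass(frozen=True)
class AbundanceRow:
    """One primary period's scaled abundance, unrounded and as-reported."""

    period: str
    n: int
    N_m: float
    se_N_m: float
    N_total: float
    se_N_total: float
    ci_low: float
    ci_high: float
    # presentation values (integers / one decimal; CI from rounded pair)
    N_total_reported: int = 0
    se_reported: float = 0.0
    ci_low_reported: int = 0
    ci_high_reported: int = 0


def total_abundance(N_m: float, theta: float) -> float:
    """Scale marked abundance by the mark rate: N_total = N_m / θ."""
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must be in (0, 1]")
    if N_m < 0:
        raise ValueError("N_m must be non-negative")
    return N_m / theta


def total_abundance_se(N_m: float, se_N_m: float, theta: float,
                       n: int) -> float:
    """Delta-method SE of total abundance."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must be in (0, 1) for the binomial term")
    if N_m <= 0:
        raise ValueError("N_m must be positive")
    N_total = N_m / theta
    rel_var = (se_N_m / N_m) ** 2 + (1.0 - theta) / (n * theta)
    return math.sqrt(N_total ** 2 * rel_var)


def lognormal_ci(N_total: float, se: float,
                 z: float = Z_95) -> tuple[float, float]:
    """Log-normal confidence limits (N/C, N·C); geometric about N_total."""
    if N_total <= 0:
        raise ValueError("N_total must be positive")
    if se < 0:
        raise ValueError("se must be non-negative")
    C = math.exp(z * math.sqrt(math.log1p((se / N_total) ** 2)))
    return N_total / C, N_total * C


def scale_row(period: str, n: int, N_m: float, se_N_m: float,
              theta: float) -> AbundanceRow:
    """Apply the scaling chain to one primary period."""
    N_total = total_abundance(N_m, theta)
    se = total_abundance_se(N_m, se_N_m, theta, n)
    lo, hi = lognormal_ci(N_total, se)
    N_rep = int(round(N_total))
    se_rep = round(se, 1)
    lo_rep, hi_rep = lognormal_ci(float(N_rep), se_rep)
    return AbundanceRow(
        period=period, n=n, N_m=N_m, se_N_m=se_N_m,
        N_total=N_total, se_N_total=se, ci_low=lo, ci_high=hi,
        N_total_reported=N_rep, se_reported=se_rep,
        ci_low_reported=int(round(lo_rep)), ci_high_reported=int(round(hi_rep)),
    )


def scale_table(per_period: Sequence[Mapping], theta: float) -> list[AbundanceRow]:
    """Scale every primary period; entries need period, n, N_m, se_N_m."""
    return [
        scale_row(str(row["period"]), int(row["n"]), float(row["N_m"]),
                  float(row["se_N_m"]), theta)
        for row in per_period
    ]


def table_to_frame(rows: Sequence[AbundanceRow]) -> pd.DataFrame:
    """Tabular view mirroring the published abundance-table columns."""
    return pd.DataFrame(
        {
            "period": [r.period for r in rows],
            "n": [r.n for r in rows],
            "N_m": [r.N_m for r in rows],
            "se_N_m": [r.se_N_m for r in rows],
            "N_total": [r.N_total_reported for r in rows],
            "se_N_total": [r.se_reported for r in rows],
            "ci_low": [r.ci_low_reported for r in rows],
            "ci_high": [r.ci_high_reported for r in rows],
        }
    )
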