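"""Telomere length by monochrome multiplex qPCR: T/S ratios and short flags.

The assay quantifies telomeric repeat signal (T) and a single-copy gene
signal (S) against standard curves fitted on a dilution series; the T/S
ratio is proportional to mean telomere length.  Samples are run in
quadruplicate; a sample is flagged as short-telomere when its ratio falls
below the chosen centile (default 10th) of a healthy-control distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


class StandardCurveError(ValueError):
    """Dilution series unusable for calibration."""


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares calibration line Cq = slope * log10(quantity) + intercept.

    ``slope`` must be negative for a valid amplification (more template,
    earlier crossing); ``efficiency`` = 10**(-1/slope) - 1 equals 1.0 for
    perfect doubling each cycle.
    """

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10 ** (-1.0 / self.slope) - 1.0

    def quantity(self, cq: float) -> float:
        """Invert the curve: relative template quantity at a measured Cq."""
        return 10 ** ((cq - self.intercept) / self.slope)


@dataclass
class TelomereResult:
    sample_id: str
    t_quantity: float
    s_quantity: float
    ts_ratio: float
    percentile_vs_controls: float | None = None
    short_flag: bool | None = None
    replicate_warning: bool = False
    warnings: list[str] = field(default_factory=list)


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Fit the calibration line to (log10 quantity, Cq) dilution points.

    Requires at least three points spanning distinct quantities; a flat or
    rising line (slope >= 0) indicates failed amplification and is rejected.
    """
    if len(points) < 3:
        raise StandardCurveError("need at least 3 dilution points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise StandardCurveError("no variation in dilution quantities")
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise StandardCurveError(
            f"non-negative slope {fit.slope:.3f}: invalid amplification"
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def compute_ts_ratio(
    t_cqs: list[float],
    s_cqs: list[float],
    t_curve: StandardCurve,
    s_curve: StandardCurve,
    sample_id: str = "",
    cq_tolerance: float = 0.5,
) -> TelomereResult:
    """T/S ratio from replicate Cq values (quadruplicate in routine use).

    Each replicate Cq is converted to a quantity through its channel's
    standard curve; quantities (not cycles) are averaged because quantity is
    the additive scale.  Replicate spread beyond ``cq_tolerance`` cycles
    raises a warning flag but does not block the result.
    """
    if not t_cqs or not s_cqs:
        raise ValueError("need at least one replicate per channel")
    warnings: list[str] = []
    replicate_warning = False
    for channel, cqs in (("T", t_cqs), ("S", s_cqs)):
        spread = max(cqs) - min(cqs)
        if spread > cq_tolerance:
            replicate_warning = True
            warnings.append(
                f"{channel} replicate Cq spread {spread:.2f} exceeds "
                f"{cq_tolerance:.2f}"
            )
    t_quantity = float(np.mean([t_curve.quantity(cq) for cq in t_cqs]))
    s_quantity = float(np.mean([s_curve.quantity(cq) for cq in s_cqs]))
    return TelomereResult(
        sample_id=sample_id,
        t_quantity=t_quantity,
        s_quantity=s_quantity,
        ts_ratio=t_quantity / s_quantity,
        replicate_warning=replicate_warning,
        warnings=warnings,
    )


def flag_short_telomere(
    result: TelomereResult,
    controls: list[float],
    centile: float = 10.0,
    min_controls: int = 20,
) -> TelomereResult:
    """Empirical percentile of a T/S ratio against healthy controls.

    The percentile is rank-based with no distributional assumption: the
    percentage of control ratios strictly below the sample's.  The short
    flag uses a strict inequality (a sample sitting exactly on the centile
    value is not flagged).  With fewer than ``min_controls`` controls the
    flag stays null.
    """
    if len(controls) < min_controls:
        result.percentile_vs_controls = None
        result.short_flag = None
        result.warnings.append(
            f"only {len(controls)} controls (< {min_controls}); no centile flag"
        )
        return result
    below = sum(c < result.ts_ratio for c in controls)
    percentile = 100.0 * below / len(controls)
    result.percentile_vs_controls = percentile
    result.short_flag = percentile < centile
    return result


def read_cq_table(path: str | Path) -> dict[str, dict[str, list[float]]]:
    """Read a plate CSV with columns sample, channel (T or S), replicate, cq."""
    df = pd.read_csv(path)
    required = {"sample", "channel", "cq"}
    if not required.issubset(df.columns):
        raise ValueError(f"Cq table needs columns {sorted(required)}")
    out: dict[str, dict[str, list[float]]] = {}
    for _, row in df.iterrows():
        channel = str(row["channel"]).upper()
        if channel not in ("T", "S"):
            raise ValueError(f"unknown channel {row['channel']!r}")
        out.setdefault(str(row["sample"]), {"T": [], "S": []})[channel].append(
            float(row["cq"])
        )
    return out
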