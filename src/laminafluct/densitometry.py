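"""Dual-channel immunoblot quantification of prelamin A processing.

Consumes already-measured band signals from a two-color infrared blot
scan: prelamin A in one channel and total lamin A (mature + precursor) in
the other.  Each channel is first normalized to its own maximum across
samples (transfection normalization), then the per-sample processing ratio
prelamin A / (lamin A + prelamin A) is formed, and groups of ratios are
compared with a two-tailed Welch (heteroscedastic) t-test.

Band extraction from gel images is out of scope; this module implements
only the downstream arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError


@dataclass(frozen=True)
class BlotMeasurement:
    """One lane's signals: prelamin A channel and total-lamin channel."""

    sample_id: str
    prelamin_signal: float
    total_signal: float
    replicate_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if self.prelamin_signal < 0 or self.total_signal < 0:
            raise ContractError(f"signals must be non-negative (sample {self.sample_id})")


def normalize_channels(measurements: list[BlotMeasurement]) -> list[BlotMeasurement]:
    """Divide each channel by its own maximum across samples (maxima become 1)."""
    if not measurements:
        raise ContractError("no measurements to normalize")
    pre_max = max(m.prelamin_signal for m in measurements)
    tot_max = max(m.total_signal for m in measurements)
    if pre_max <= 0 or tot_max <= 0:
        raise ContractError("each channel needs at least one positive signal")
    return [
        replace(m, prelamin_signal=m.prelamin_signal / pre_max, total_signal=m.total_signal / tot_max)
        for m in measurements
    ]


def prelamin_ratio(m: BlotMeasurement) -> float:
    """Processing ratio prelamin A / (lamin A + prelamin A) for one sample."""
    if m.total_signal <= 0:
        raise ContractError(f"total signal must be positive for a ratio (sample {m.sample_id})")
    return m.prelamin_signal / m.total_signal


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_difference: float
    t_statistic: float
    p_value: float


def compare_groups(ratios_a, ratios_b) -> GroupComparison:
    """Two-tailed Welch (unequal-variance) t-test between two ratio groups."""
    a = np.asarray(ratios_a, dtype=np.float64)
    b = np.asarray(ratios_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ContractError("each group needs at least 2 ratios for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        mean_difference=float(a.mean() - b.mean()),
        t_statistic=float(t),
        p_value=float(p),
    )


def blot_table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize a measurement table and attach per-sample ratios.

    Expects columns sample_id, prelamin_signal, total_signal and optionally
    replicate_id / group; returns a copy with normalized signals and a
    ``ratio`` column.
    """
    required = {"sample_id", "prelamin_signal", "total_signal"}
    missing = required - set(df.columns)
    if missing:
        raise ContractError(f"blot table is missing columns: {sorted(missing)}")
    measurements = [
        BlotMeasurement(
            sample_id=str(row.sample_id),
            prelamin_signal=float(row.prelamin_signal),
            total_signal=float(row.total_signal),
            replicate_id=str(row.replicate_id) if "replicate_id" in df.columns else None,
            group=str(row.group) if "group" in df.columns else None,
        )
        for row in df.itertuples()
    ]
    normalized = normalize_channels(measurements)
    out = df.copy()
    out["prelamin_norm"] = [m.prelamin_signal for m in normalized]
    out["total_norm"] = [m.total_signal for m in normalized]
    out["ratio"] = [prelamin_ratio(m) for m in normalized]
    return out


def compare_blot_groups(df: pd.DataFrame, group_a: str, group_b: str) -> GroupComparison:
    """Normalize, form ratios, and Welch-compare two named groups of a blot table."""
    table = blot_table(df)
    if "group" not in table.columns:
        raise ContractError("blot table needs a 'group' column for a comparison")
    a = table.loc[table.group == group_a, "ratio"].to_numpy()
    b = table.loc[table.group == group_b, "ratio"].to_numpy()
    return compare_groups(a, b)
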