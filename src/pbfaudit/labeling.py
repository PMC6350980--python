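"""Quarterly bonus computation and the binary over-reporting label.

A facility's quarterly bonus is the price-weighted sum of its nine
incentivized service counts.  A facility-quarter is labeled as
over-reporting when the bonus implied by its own report exceeds the bonus
implied by independently verified counts by 10% or more (inclusive
boundary).  A positive reported bonus against zero verified services is
treated as over-reporting by default: it is the clearest possible gaming
signal (infinite relative excess).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

N_INDICATORS = 9

#: Default relative-excess threshold for the over-reporting flag.
DEFAULT_THRESHOLD = 0.10

#: Plausible unit prices (USD per service) for the nine incentivized
#: indicators of a rural primary-care PBF scheme.  Chosen so that a typical
#: facility's quarterly bonus is on the order of $1,900.
DEFAULT_PRICES: Mapping[str, float] = {
    "institutional_delivery": 10.0,
    "anc_first_visit": 2.0,
    "anc_fourth_visit": 3.0,
    "postnatal_visit": 2.5,
    "child_fully_immunized": 5.0,
    "growth_monitoring": 0.5,
    "family_planning_new": 3.0,
    "pmtct_hiv_test": 2.0,
    "tb_case_detection": 25.0,
}


@dataclass(frozen=True)
class PriceSchedule:
    """Unit price per incentivized indicator, in a fixed indicator order."""

    names: tuple[str, ...]
    prices: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != N_INDICATORS or len(self.prices) != N_INDICATORS:
            raise ValueError(
                f"price schedule must list exactly {N_INDICATORS} indicators, "
                f"got {len(self.names)} names / {len(self.prices)} prices"
            )
        if any(p <= 0 for p in self.prices):
            bad = [n for n, p in zip(self.names, self.prices) if p <= 0]
            raise ValueError(f"prices must be > 0; offending indicators: {bad}")

    @classmethod
    def default(cls) -> "PriceSchedule":
        return cls(tuple(DEFAULT_PRICES), tuple(DEFAULT_PRICES.values()))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "PriceSchedule":
        return cls(tuple(mapping), tuple(float(v) for v in mapping.values()))

    @classmethod
    def from_yaml(cls, path) -> "PriceSchedule":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.prices, dtype=float)


@dataclass(frozen=True)
class LabelConfig:
    """Parameters of the over-reporting rule.

    threshold
        Relative excess of the reported over the verified bonus at which a
        quarter is flagged; the boundary is inclusive ("10% or more").
    zero_verified_rule
        Flag quarters with a zero verified bonus but a positive reported
        bonus.
    """

    threshold: float = DEFAULT_THRESHOLD
    zero_verified_rule: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")


def compute_bonus(counts: Sequence[float], schedule: PriceSchedule) -> float:
    """Return the bonus Σ_i counts_i × price_i for one facility-quarter."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (N_INDICATORS,):
        raise ValueError(
            f"expected {N_INDICATORS} counts matching indicators "
            f"{list(schedule.names)}, got shape {counts.shape}"
        )
    if np.any(counts < 0):
        bad = [schedule.names[i] for i in np.flatnonzero(counts < 0)]
        raise ValueError(f"negative counts for indicators: {bad}")
    return float(counts @ schedule.as_array())


def label_quarter(
    reported_bonus: float,
    verified_bonus: float,
    config: LabelConfig | None = None,
) -> int:
    """Binary over-reporting flag for one facility-quarter."""
    config = config or LabelConfig()
    if reported_bonus < 0 or verified_bonus < 0:
        raise ValueError(
            f"bonuses must be >= 0, got reported={reported_bonus}, "
            f"verified={verified_bonus}"
        )
    if verified_bonus == 0:
        return int(config.zero_verified_rule and reported_bonus > 0)
    # inclusive boundary ("10% or more"), robust to float rounding of the
    # threshold product
    cutoff = (1.0 + config.threshold) * verified_bonus
    at_or_above = reported_bonus > cutoff or np.isclose(
        reported_bonus, cutoff, rtol=1e-12, atol=0.0
    )
    return int(at_or_above and reported_bonus > verified_bonus)


def label_panel(
    panel: pd.DataFrame,
    schedule: PriceSchedule | None = None,
    config: LabelConfig | None = None,
) -> pd.DataFrame:
    """Label every facility-quarter of a panel.

    Returns a frame with columns facility_id, quarter, reported_bonus,
    verified_bonus, over_report (one row per facility-quarter, panel order).
    """
    schedule = schedule or PriceSchedule.default()
    config = config or LabelConfig()

    quarters_per_fac = panel.groupby("facility_id")["quarter"].nunique()
    incomplete = quarters_per_fac[quarters_per_fac != 4]
    if len(incomplete):
        raise ValueError(
            "facilities missing quarters: " f"{sorted(incomplete.index.tolist())}"
        )

    prices = schedule.as_array()
    rep_cols = [f"rep_{i}" for i in range(1, N_INDICATORS + 1)]
    ver_cols = [f"ver_{i}" for i in range(1, N_INDICATORS + 1)]
    rep_bonus = panel[rep_cols].to_numpy(dtype=float) @ prices
    ver_bonus = panel[ver_cols].to_numpy(dtype=float) @ prices
    flags = [
        label_quarter(r, v, config) for r, v in zip(rep_bonus, ver_bonus)
    ]
    return pd.DataFrame(
        {
            "facility_id": panel["facility_id"].to_numpy(),
            "quarter": panel["quarter"].to_numpy(),
            "reported_bonus": rep_bonus,
            "verified_bonus": ver_bonus,
            "over_report": np.asarray(flags, dtype=int),
        }
    )


def offender_distribution(labels: pd.DataFrame) -> pd.DataFrame:
    """Distribution of facilities by number of quarters flagged (0..4).

    Returns a frame indexed by n_quarters with columns n_facilities and
    percent; counts sum to the number of facilities and percentages to 100
    within rounding.
    """
    per_fac = labels.groupby("facility_id")["over_report"].agg(["sum", "count"])
    if not (per_fac["count"] == 4).all():
        bad = per_fac.index[per_fac["count"] != 4].tolist()
        raise ValueError(f"facilities without 4 labeled quarters: {bad}")
    counts = (
        per_fac["sum"].astype(int).value_counts().reindex(range(5), fill_value=0)
    )
    out = pd.DataFrame(
        {
            "n_facilities": counts,
            "percent": 100.0 * counts / counts.sum(),
        }
    )
    out.index.name = "n_quarters_flagged"
    return out


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=False)


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path)
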