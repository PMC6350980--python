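"""Audit-plan construction: four sampling schemes plus model-ranked targeting.

The sampling schemes mirror operational counter-verification practice:

* simple random sampling (SRS) of a fixed fraction of facilities;
* SRS stratified by district (guarantees every district is visited);
* a mixed design drawing half the sample from the previous quarter's
  offenders and half from the rest;
* an offenders-first design that fills the sample with prior offenders
  before topping up at random.

``model_ranked`` selects the top-k facilities by a classifier risk score.
All schemes take explicit seeds; there is no hidden global random state.
Fractional stratum sizes are rounded half-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class AuditPlan:
    """A strategy's selected facility set for one quarter."""

    quarter: int | None
    strategy_name: str
    selected: tuple[str, ...]
    target_size: int
    seed: int | None

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("audit plan contains duplicate facilities")

    def __len__(self) -> int:
        return len(self.selected)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _as_ids(population: Iterable[str]) -> list[str]:
    ids = list(population)
    if not ids:
        raise ValueError("population is empty")
    if len(set(ids)) != len(ids):
        raise ValueError("population contains duplicate facility ids")
    return ids


def srs(population: Iterable[str], fraction: float, seed: int,
        quarter: int | None = None) -> AuditPlan:
    """Simple random sample of round(fraction × N) facilities."""
    ids = _as_ids(population)
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = _round_half_up(fraction * len(ids))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=k, replace=False)
    return AuditPlan(quarter, "srs", tuple(ids[i] for i in sorted(chosen)),
                     k, seed)


def stratified_srs(districts: Mapping[str, str] | pd.Series, fraction: float,
                   seed: int, quarter: int | None = None) -> AuditPlan:
    """District-stratified SRS: round(fraction × N_d) facilities per district.

    ``districts`` maps facility_id -> district_id.
    """
    if isinstance(districts, pd.Series):
        districts = districts.to_dict()
    ids = _as_ids(districts)
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    by_district: dict[str, list[str]] = {}
    for fid in ids:
        by_district.setdefault(districts[fid], []).append(fid)
    selected: list[str] = []
    for district in sorted(by_district):
        members = by_district[district]
        k = _round_half_up(fraction * len(members))
        chosen = rng.choice(len(members), size=k, replace=False)
        selected.extend(members[i] for i in sorted(chosen))
    return AuditPlan(quarter, "stratified_srs", tuple(selected),
                     len(selected), seed)


def _srs_from(ids: Sequence[str], k: int, rng: np.random.Generator) -> list[str]:
    if k >= len(ids):
        return list(ids)
    chosen = rng.choice(len(ids), size=k, replace=False)
    return [ids[i] for i in sorted(chosen)]


def offender_mixed(population: Iterable[str], prior_offenders: Iterable[str],
                   target_size: int, seed: int,
                   quarter: int | None = None) -> AuditPlan:
    """Half prior offenders, half others; shortfalls reallocated.

    ⌈target/2⌉ facilities are drawn by SRS from the prior offenders (all of
    them if fewer, with the shortfall moved to the non-offender draw), the
    remainder by SRS from the rest of the population.
    """
    ids = _as_ids(population)
    offenders = sorted(set(prior_offenders))
    if not set(offenders) <= set(ids):
        raise ValueError("prior_offenders must be a subset of the population")
    if not 0 < target_size <= len(ids):
        raise ValueError(f"target_size must be in 1..{len(ids)}")
    rng = np.random.default_rng(seed)
    n_off = min(math.ceil(target_size / 2), len(offenders))
    others = [fid for fid in ids if fid not in set(offenders)]
    n_other = min(target_size - n_off, len(others))
    # a short non-offender pool reallocates back to offenders, keeping the
    # plan at the target size whenever the population allows
    n_off = min(len(offenders), target_size - n_other)
    picked = _srs_from(offenders, n_off, rng) + _srs_from(others, n_other, rng)
    return AuditPlan(quarter, "offender_mixed", tuple(picked),
                     target_size, seed)


def offenders_first(population: Iterable[str], prior_offenders: Iterable[str],
                    target_size: int, seed: int,
                    quarter: int | None = None) -> AuditPlan:
    """All prior offenders first (subsampled if too many), SRS fill after."""
    ids = _as_ids(population)
    offenders = sorted(set(prior_offenders))
    if not set(offenders) <= set(ids):
        raise ValueError("prior_offenders must be a subset of the population")
    if not 0 < target_size <= len(ids):
        raise ValueError(f"target_size must be in 1..{len(ids)}")
    rng = np.random.default_rng(seed)
    if len(offenders) >= target_size:
        picked = _srs_from(offenders, target_size, rng)
    else:
        others = [fid for fid in ids if fid not in set(offenders)]
        picked = list(offenders) + _srs_from(
            others, target_size - len(offenders), rng
        )
    return AuditPlan(quarter, "offenders_first", tuple(picked),
                     target_size, seed)


def model_ranked(population: Iterable[str], risk_scores: Mapping[str, float],
                 target_size: int, seed: int = 0,
                 quarter: int | None = None) -> AuditPlan:
    """Top-k facilities by classifier risk score.

    Ties are broken deterministically: facilities are shuffled once with
    the seed, then stably sorted by descending score, so equal-scoring
    facilities are chosen in seeded-shuffle order.
    """
    ids = _as_ids(population)
    missing = [fid for fid in ids if fid not in risk_scores]
    if missing:
        raise ValueError(f"missing risk scores for facilities: {missing}")
    bad = [fid for fid in ids if not np.isfinite(risk_scores[fid])]
    if bad:
        raise ValueError(f"non-finite risk scores for facilities: {bad}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    ranked = sorted(shuffled, key=lambda fid: -risk_scores[fid])
    k = min(target_size, len(ids))
    return AuditPlan(quarter, "model_ranked", tuple(ranked[:k]), k, seed)


def plans_to_frame(plans: Iterable[AuditPlan]) -> pd.DataFrame:
    """Flatten plans to a CSV-ready frame (quarter, strategy, facility, seed)."""
    rows = [
        {
            "quarter": p.quarter,
            "strategy_name": p.strategy_name,
            "facility_id": fid,
            "seed": p.seed,
        }
        for p in plans
        for fid in p.selected
    ]
    return pd.DataFrame(rows)
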