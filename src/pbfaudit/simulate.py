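"""Synthetic facility-quarter reporting panels.

Emulates the structure of a four-quarter PBF counter-verification dataset:
140 rural health facilities across 18 districts (10 PBF, 8 non-PBF), nine
incentivized service indicators per quarter with both a facility-reported
and an independently verified count, and a latent gaming process with
realistic quarterly prevalence (15–23%), strong cross-quarter persistence,
and a heavy mass of facilities that never over-report.

The generator is the test bed for the whole pipeline: every downstream
stage (labeling, audit strategies, classifiers, cost model) is exercised
against panels drawn from it, so its defaults are calibrated to the
published marginal structure of the Zambia pilot data: a facility
over-reports in 0/1/2/3/4 quarters with probabilities 81/140, 32/140,
12/140, 9/140, 6/140, and a facility gaming in one quarter games in the
next with probability ≈ 0.58.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .labeling import DEFAULT_THRESHOLD, N_INDICATORS

QUARTERS = (1, 2, 3, 4)

#: Audit-probability arms of the embedded audit experiment (percent).
AUDIT_ARMS = (0, 10, 30, 100)

FACILITY_TYPES = (
    "health_post",
    "rural_health_centre",
    "urban_health_centre",
    "district_hospital",
    "mission_clinic",
    "mobile_outreach",
    "private_clinic",
    "other",
)
MANAGING_AUTHORITIES = ("government", "faith_based", "private")
LOCATIONS = ("rural", "peri_urban", "urban")

#: Expected quarterly verified counts per indicator at a median-sized
#: facility, ordered as the default price schedule.
DEFAULT_INDICATOR_MEANS = (45.0, 90.0, 60.0, 70.0, 55.0, 180.0, 75.0, 85.0, 6.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic panel generator.

    Defaults reproduce the published marginal structure: 140 facilities in
    18 districts, over-reporting frequency classes 81/32/12/9/6 over
    {0,1,2,3,4} quarters, and quarter-to-quarter gaming persistence 0.577.
    """

    n_facilities: int = 140
    n_pbf_districts: int = 10
    n_nonpbf_districts: int = 8
    #: Probability a facility games in 0,1,2,3,4 of the four quarters.
    type_probs: tuple[float, ...] = (81 / 140, 32 / 140, 12 / 140, 9 / 140, 6 / 140)
    #: P(game in t+1 | game in t); drives placement of gaming quarters.
    persistence: float = 0.577
    indicator_means: tuple[float, ...] = DEFAULT_INDICATOR_MEANS
    #: Negative-binomial shape (larger = less overdispersed).
    dispersion: float = 8.0
    #: Multiplicative inflation applied to reports in gamed quarters.
    inflation_range: tuple[float, float] = (1.15, 1.60)
    #: Max symmetric relative reporting error in honest quarters.
    honest_noise: float = 0.05
    #: Allocation over audit arms (0, 10, 30, 100 percent); the zero arm is
    #: reserved for non-PBF districts, so its weight applies only there.
    audit_arm_probs: tuple[float, ...] = (0.0, 1 / 3, 1 / 3, 1 / 3)
    #: Share of facilities in PBF districts (105/140 in the pilot).
    pbf_share: float = 105 / 140
    #: "frequency": gaming driven by the frequency-class distribution and
    #: persistence (default).  "additive": each quarter games independently
    #: with probability logistic-linear in facility covariates.
    gaming_mechanism: str = "frequency"
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.type_probs, dtype=float)
        if probs.shape != (5,) or np.any(probs < 0):
            raise ValueError("type_probs must be 5 non-negative entries")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError(f"type_probs must sum to 1, got {probs.sum()!r}")
        lo, hi = self.inflation_range
        if not lo <= hi:
            raise ValueError("inflation_range must be (lo, hi) with lo <= hi")
        if lo <= 1.0 + DEFAULT_THRESHOLD:
            raise ValueError(
                f"inflation lower bound {lo} must exceed 1 + label threshold "
                f"{1 + DEFAULT_THRESHOLD} so gamed quarters are flaggable"
            )
        if not 0 <= self.honest_noise < DEFAULT_THRESHOLD:
            raise ValueError(
                f"honest_noise {self.honest_noise} must be below the label "
                f"threshold {DEFAULT_THRESHOLD}"
            )
        if not 0 < self.persistence < 1:
            raise ValueError("persistence must be in (0, 1)")
        if len(self.indicator_means) != N_INDICATORS:
            raise ValueError(f"indicator_means must have {N_INDICATORS} entries")
        if self.gaming_mechanism not in ("frequency", "additive"):
            raise ValueError(f"unknown gaming_mechanism {self.gaming_mechanism!r}")
        n_districts = self.n_pbf_districts + self.n_nonpbf_districts
        if self.n_facilities < n_districts:
            raise ValueError(
                f"n_facilities={self.n_facilities} cannot populate "
                f"{n_districts} districts"
            )

    @property
    def quarterly_prevalence(self) -> float:
        """Expected share of facility-quarters gamed, E[k]/4."""
        k = np.arange(5)
        return float(np.asarray(self.type_probs) @ k) / 4.0

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        kwargs = dict(raw)
        for key in ("type_probs", "indicator_means", "inflation_range",
                    "audit_arm_probs"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _place_gaming_quarters(k: int, persistence: float, base: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Choose which of the 4 quarters a k-quarter gamer games.

    Sequential draw: the first gamed quarter is uniform; each subsequent
    quarter is drawn with weight `persistence` if adjacent to an already
    chosen quarter and weight `base` (the unconditional quarterly
    prevalence) otherwise.  When persistence == base the draw is uniform
    over k-subsets, which makes the quarter indicators i.i.d. whenever the
    frequency-class distribution is Binomial(4, base).
    """
    flags = np.zeros(4, dtype=bool)
    if k == 0:
        return flags
    flags[rng.integers(4)] = True
    for _ in range(k - 1):
        candidates = np.flatnonzero(~flags)
        weights = np.array(
            [
                persistence
                if (q > 0 and flags[q - 1]) or (q < 3 and flags[q + 1])
                else base
                for q in candidates
            ]
        )
        flags[rng.choice(candidates, p=weights / weights.sum())] = True
    return flags


def _facility_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_facilities
    n_pbf_fac = int(round(config.pbf_share * n))
    n_pbf_fac = min(max(n_pbf_fac, config.n_pbf_districts),
                    n - config.n_nonpbf_districts)

    pbf_districts = [f"D{i:02d}" for i in range(1, config.n_pbf_districts + 1)]
    nonpbf_districts = [
        f"D{i:02d}"
        for i in range(config.n_pbf_districts + 1,
                       config.n_pbf_districts + config.n_nonpbf_districts + 1)
    ]
    districts = [pbf_districts[i % len(pbf_districts)] for i in range(n_pbf_fac)]
    districts += [
        nonpbf_districts[i % len(nonpbf_districts)] for i in range(n - n_pbf_fac)
    ]
    pbf_flag = np.array([1] * n_pbf_fac + [0] * (n - n_pbf_fac))

    arm_probs = np.asarray(config.audit_arm_probs, dtype=float)
    pbf_arm_probs = arm_probs[1:]
    if pbf_arm_probs.sum() <= 0:
        raise ValueError("audit_arm_probs must put mass on the non-zero arms")
    pbf_arm_probs = pbf_arm_probs / pbf_arm_probs.sum()
    audit_arm = np.where(
        pbf_flag == 1,
        rng.choice(AUDIT_ARMS[1:], size=n, p=pbf_arm_probs),
        0,
    )

    established = rng.poisson(6, size=n) + 1
    filled = rng.binomial(established, 0.8)
    return pd.DataFrame(
        {
            "facility_id": [f"F{i:04d}" for i in range(1, n + 1)],
            "district_id": districts,
            "pbf_flag": pbf_flag,
            "audit_arm": audit_arm,
            "facility_type": rng.choice(
                FACILITY_TYPES, size=n,
                p=(0.28, 0.30, 0.10, 0.05, 0.10, 0.05, 0.07, 0.05),
            ),
            "managing_authority": rng.choice(
                MANAGING_AUTHORITIES, size=n, p=(0.70, 0.20, 0.10)
            ),
            "location": rng.choice(LOCATIONS, size=n, p=(0.60, 0.25, 0.15)),
            "catchment_population": rng.lognormal(9.0, 0.5, size=n).astype(int),
            "established_posts": established,
            "filled_posts": filled,
        }
    )


def _largest_remainder_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Apportion n facilities over classes matching probs exactly."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _gaming_risk_index(fac: pd.DataFrame, rng: np.random.Generator,
                       signal: float = 2.5) -> np.ndarray:
    """Latent gaming propensity; a threshold-interaction in covariates.

    Gaming concentrates where exactly one of {large catchment, severe
    understaffing} holds: facilities under volume pressure with the slack
    to manipulate records, or small facilities stretched past capacity.
    The exclusive-or makes the propensity non-representable by any linear
    (logistic-additive) function of the covariates.  Gumbel noise keeps
    the coupling between covariates and gaming class imperfect.
    """
    z_pop = (np.log(fac["catchment_population"].to_numpy(dtype=float)) - 9.0) / 0.5
    understaffed = (
        1.0 - fac["filled_posts"] / fac["established_posts"].clip(lower=1)
    ).to_numpy(dtype=float)
    interaction = (z_pop > 0.3) ^ (understaffed > 0.25)
    return signal * interaction + rng.gumbel(size=len(fac))


def _gaming_flags(config: SimConfig, fac: pd.DataFrame,
                  rng: np.random.Generator) -> np.ndarray:
    """(n_facilities, 4) boolean array of latent gaming quarters."""
    n = len(fac)
    if config.gaming_mechanism == "frequency":
        # Frequency classes follow type_probs exactly (largest-remainder
        # apportionment); which facilities land in the gaming classes is
        # driven by the covariate risk index.
        counts = _largest_remainder_counts(np.asarray(config.type_probs), n)
        order = np.argsort(-_gaming_risk_index(fac, rng))
        ks = np.zeros(n, dtype=int)
        pos = 0
        for k in (4, 3, 2, 1, 0):
            ks[order[pos:pos + counts[k]]] = k
            pos += counts[k]
        base = max(config.quarterly_prevalence, 1e-9)
        return np.vstack(
            [_place_gaming_quarters(k, config.persistence, base, rng) for k in ks]
        )
    # Additive log-odds mechanism: quarters game independently with a
    # facility-level probability that is logistic-linear in covariates.
    logpop = np.log(fac["catchment_population"].to_numpy(dtype=float))
    z_pop = (logpop - 9.0) / 0.5
    understaffed = 1.0 - fac["filled_posts"] / fac["established_posts"].clip(lower=1)
    rural = (fac["location"] == "rural").astype(float)
    eta = -2.1 + 0.9 * z_pop + 3.0 * (understaffed - 0.2) + 0.7 * rural
    p_game = 1.0 / (1.0 + np.exp(-eta.to_numpy(dtype=float)))
    return rng.random((n, 4)) < p_game[:, None]


def generate_panel(config: SimConfig) -> pd.DataFrame:
    """Draw a facility-quarter panel; deterministic given config.seed.

    Long format, one row per facility-quarter: facility identifiers and
    covariates, reported counts rep_1..rep_9, verified counts ver_1..ver_9,
    and the latent gaming_flag (evaluation-only ground truth; never a model
    feature).  Gamed quarters inflate all nine reported counts by a common
    factor drawn from inflation_range; honest quarters perturb each count
    by at most honest_noise, so the bonus-level label reproduces the latent
    flag exactly.
    """
    rng = np.random.default_rng(config.seed)
    fac = _facility_frame(config, rng)
    gaming = _gaming_flags(config, fac, rng)

    means = np.asarray(config.indicator_means, dtype=float)
    size_factor = fac["catchment_population"].to_numpy(dtype=float) / np.exp(9.0)

    rows = []
    for i in range(len(fac)):
        mu = means * size_factor[i]
        for qi, quarter in enumerate(QUARTERS):
            p_nb = config.dispersion / (config.dispersion + mu)
            verified = rng.negative_binomial(config.dispersion, p_nb)
            if gaming[i, qi]:
                infl = rng.uniform(*config.inflation_range)
                reported = verified * infl
                if reported.sum() == 0:
                    # fabricated claim against zero verified services;
                    # flagged by the zero-verified labeling rule
                    reported = reported.astype(float)
                    reported[0] = 1.0
            else:
                noise = rng.uniform(-config.honest_noise, config.honest_noise,
                                    size=N_INDICATORS)
                reported = verified * (1.0 + noise)
            row = fac.iloc[i].to_dict()
            row["quarter"] = quarter
            row.update({f"rep_{j+1}": reported[j] for j in range(N_INDICATORS)})
            row.update({f"ver_{j+1}": int(verified[j]) for j in range(N_INDICATORS)})
            row["gaming_flag"] = int(gaming[i, qi])
            rows.append(row)

    cols = [
        "facility_id", "district_id", "pbf_flag", "audit_arm", "quarter",
        *[f"rep_{j}" for j in range(1, N_INDICATORS + 1)],
        *[f"ver_{j}" for j in range(1, N_INDICATORS + 1)],
        "facility_type", "managing_authority", "location",
        "catchment_population", "established_posts", "filled_posts",
        "gaming_flag",
    ]
    return pd.DataFrame(rows)[cols]


def empirical_persistence(labels: pd.DataFrame) -> pd.DataFrame:
    """4×4 conditional over-reporting matrix.

    Entry (i, j) is the share of facilities flagged in quarter i that are
    also flagged in quarter j; the diagonal is 1 wherever quarter i has at
    least one flagged facility.  Quarters with no flagged facilities yield
    NaN rows (undefined conditionals, never zero).
    """
    wide = labels.pivot(index="facility_id", columns="quarter",
                        values="over_report").reindex(columns=QUARTERS)
    if wide.isna().any().any():
        raise ValueError("labels must cover all 4 quarters for every facility")
    mat = np.full((4, 4), np.nan)
    flags = wide.to_numpy(dtype=bool)
    for i in range(4):
        n_i = flags[:, i].sum()
        if n_i == 0:
            continue
        for j in range(4):
            mat[i, j] = flags[flags[:, i], j].sum() / n_i
    return pd.DataFrame(mat, index=list(QUARTERS), columns=list(QUARTERS))


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    return pd.read_csv(path)
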