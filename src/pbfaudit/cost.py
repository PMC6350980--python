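"""Verification cost model.

Total cost of auditing n facilities in a period, with a fraction p of them
found to be misreporting:

    tc = n[p(mc − s) + (1 − p)mc] + fc = n(mc − p·s) + fc

where mc is the marginal verification cost per facility, s the sanction
recovered per detected misreporter, and fc the fixed cost per period.  The
per-facility form uses the average fixed cost afc instead:

    cost_per_facility = mc − p·s + afc

which equals tc/n exactly when afc = fc/n.  Raising the detection
probability p (e.g. by risk-targeted auditing) lowers cost linearly with
slope −s per facility.
"""

from __future__ import annotations

from dataclasses import dataclass


def _check_p(p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"detection proportion p must be in [0, 1], got {p}")


@dataclass(frozen=True)
class CostParams:
    """Parameters of the verification cost function (currency units)."""

    n: int
    p: float
    mc: float
    s: float
    fc: float = 0.0
    afc: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        _check_p(self.p)
        for name in ("mc", "s", "fc", "afc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CostResult:
    tc: float
    per_facility: float
    relative_savings: float | None = None


def total_cost(params: CostParams) -> CostResult:
    """Total verification cost tc = n[p(mc − s) + (1 − p)mc] + fc."""
    tc = params.n * (params.p * (params.mc - params.s)
                     + (1 - params.p) * params.mc) + params.fc
    per_fac = tc / params.n if params.n else float("nan")
    return CostResult(tc=tc, per_facility=per_fac)


def per_facility_cost(p: float, mc: float, s: float, afc: float) -> float:
    """Average verification cost per facility: mc − p·s + afc."""
    _check_p(p)
    if min(mc, s, afc) < 0:
        raise ValueError("mc, s and afc must be >= 0")
    return mc - p * s + afc


def relative_savings(p_base: float, p_alt: float, mc: float, s: float,
                     afc: float) -> float:
    """Relative per-facility saving of moving detection from p_base to p_alt."""
    base = per_facility_cost(p_base, mc, s, afc)
    if base == 0:
        raise ValueError("baseline per-facility cost is zero; savings undefined")
    return (base - per_facility_cost(p_alt, mc, s, afc)) / base
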