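"""Summary economics: per-1,000 scaling, ICER, net monetary/health benefit, CIs.

All quantities are computed from the retained per-draw incrementals of a paired PSA,
so every summary is recomputable and the per-draw linear identities
NMB = lambda * dQ - dC and NHB = dQ - dC / lambda hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simulation import PairedRun
from .synthetic_ehr import STATE_CLASSES

WTP_THRESHOLDS: tuple[float, ...] = (20_000.0, 30_000.0)


class EconomicsError(ValueError):
    pass


def per_thousand(value, n_entrants: float):
    """Scale a total to a rate per 1,000 entrants."""
    if n_entrants <= 0:
        raise EconomicsError("n_entrants must be positive")
    return np.asarray(value) * (1000.0 / n_entrants) if np.ndim(value) else \
        float(value) * (1000.0 / n_entrants)


@dataclass(frozen=True)
class Icer:
    """ICER with dominance flags.  ``value`` is None when dQ = 0 (undefined)."""

    value: float | None
    dominant: bool = False    # cheaper and more effective
    dominated: bool = False   # costlier and less effective
    undefined: bool = False


def icer(delta_cost: float, delta_qaly: float) -> Icer:
    """Incremental cost-effectiveness ratio in GBP per QALY."""
    if delta_qaly == 0:
        return Icer(None, undefined=True)
    if delta_cost < 0 and delta_qaly > 0:
        return Icer(delta_cost / delta_qaly, dominant=True)
    if delta_cost > 0 and delta_qaly < 0:
        return Icer(delta_cost / delta_qaly, dominated=True)
    return Icer(delta_cost / delta_qaly)


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit: lambda * dQ - dC (GBP)."""
    if wtp <= 0:
        raise EconomicsError("willingness-to-pay threshold must be positive")
    return wtp * delta_qaly - delta_cost


def nhb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net health benefit: dQ - dC / lambda (QALYs)."""
    if wtp <= 0:
        raise EconomicsError("willingness-to-pay threshold must be positive")
    return delta_qaly - delta_cost / wtp


def percentile_interval(values: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Empirical central interval (2.5/97.5 percentiles at the default level)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise EconomicsError("at least 2 draws required for a percentile interval")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(v, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class Summary:
    """Mean and 95% percentile CI over PSA draws."""

    mean: float
    ci: tuple[float, float] | None

    @classmethod
    def of(cls, values: np.ndarray) -> "Summary":
        v = np.asarray(values, dtype=float)
        ci = percentile_interval(v) if v.size >= 2 else None
        return cls(float(v.mean()), ci)


@dataclass
class CEAResult:
    """Cost-utility summary per 1,000 entrants over the PSA draws.

    Costs are in GBP millions; QALYs, life-years and person-years in natural units.
    Keyed by discount rate where applicable; NMB/NHB/ICER use the base-case 3.5% rate.
    """

    n_draws: int
    n_entrants: float
    total_cost: dict[float, dict[str, Summary]]      # rate -> arm -> Summary (millions)
    total_qalys: dict[float, dict[str, Summary]]
    inc_cost: dict[float, Summary]                   # millions
    inc_qalys: dict[float, Summary]
    icer: dict[float, Summary]                       # GBP/QALY, per-draw ratio CI
    icer_of_means: dict[float, float]
    nmb: dict[float, Summary]                        # wtp -> Summary (millions)
    nhb: dict[float, Summary]                        # wtp -> Summary (QALYs)
    person_years: dict[str, dict[str, Summary]]      # class -> arm -> Summary
    inc_person_years: dict[str, Summary]
    inc_life_years: Summary
    # raw per-draw incrementals at the base rate, for downstream recomputation
    draws_inc_cost: np.ndarray = field(repr=False, default=None)
    draws_inc_qalys: np.ndarray = field(repr=False, default=None)

    base_rate: float = 0.035


def summarize(runs: Sequence[PairedRun], base_rate: float = 0.035,
              wtp_thresholds: Sequence[float] = WTP_THRESHOLDS) -> CEAResult:
    """Collapse paired PSA runs into the reporting summary (per 1,000 entrants)."""
    if not runs:
        raise EconomicsError("no PSA draws to summarise")
    n_entrants = runs[0].surgery.entrants
    k = 1000.0 / n_entrants
    rates = sorted(runs[0].surgery.costs)
    M = 1e-6  # GBP -> millions

    total_cost, total_qalys, inc_cost, inc_qalys, icer_s = {}, {}, {}, {}, {}
    icer_means = {}
    for r in rates:
        cs = np.array([p.surgery.costs[r] for p in runs]) * k * M
        cc = np.array([p.comparator.costs[r] for p in runs]) * k * M
        qs = np.array([p.surgery.qalys[r] for p in runs]) * k
        qc = np.array([p.comparator.qalys[r] for p in runs]) * k
        total_cost[r] = {"surgery": Summary.of(cs), "no_surgery": Summary.of(cc)}
        total_qalys[r] = {"surgery": Summary.of(qs), "no_surgery": Summary.of(qc)}
        inc_cost[r] = Summary.of(cs - cc)
        inc_qalys[r] = Summary.of(qs - qc)
        dc, dq = (cs - cc) / M, qs - qc
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(dq != 0, dc / dq, np.nan)
        valid = ratios[np.isfinite(ratios)]
        icer_s[r] = Summary.of(valid) if valid.size else Summary(float("nan"), None)
        icer_means[r] = float(dc.mean() / dq.mean()) if dq.mean() != 0 else float("nan")

    dc = np.array([p.incremental_cost(base_rate) for p in runs]) * k
    dq = np.array([p.incremental_qalys(base_rate) for p in runs]) * k
    nmb_s = {w: Summary.of((w * dq - dc) * M) for w in wtp_thresholds}
    nhb_s = {w: Summary.of(dq - dc / w) for w in wtp_thresholds}

    person_years, inc_py = {}, {}
    for i, cls in enumerate(STATE_CLASSES):
        ps = np.array([p.surgery.person_years[i] for p in runs]) * k
        pc = np.array([p.comparator.person_years[i] for p in runs]) * k
        person_years[cls] = {"surgery": Summary.of(ps), "no_surgery": Summary.of(pc)}
        inc_py[cls] = Summary.of(ps - pc)
    dep_s = np.array([p.surgery.depression_person_years for p in runs]) * k
    dep_c = np.array([p.comparator.depression_person_years for p in runs]) * k
    person_years["depression"] = {"surgery": Summary.of(dep_s), "no_surgery": Summary.of(dep_c)}
    inc_py["depression"] = Summary.of(dep_s - dep_c)
    ly = np.array([p.surgery.life_years - p.comparator.life_years for p in runs]) * k

    return CEAResult(
        n_draws=len(runs), n_entrants=n_entrants,
        total_cost=total_cost, total_qalys=total_qalys,
        inc_cost=inc_cost, inc_qalys=inc_qalys, icer=icer_s, icer_of_means=icer_means,
        nmb=nmb_s, nhb=nhb_s, person_years=person_years, inc_person_years=inc_py,
        inc_life_years=Summary.of(ly),
        draws_inc_cost=dc, draws_inc_qalys=dq, base_rate=base_rate,
    )
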