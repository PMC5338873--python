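"""Serialisation: versioned parameter JSON, result JSON and paper-layout CSV tables."""

from __future__ import annotations

import json
from typing import Mapping

import numpy as np
import pandas as pd

from .economics import CEAResult, Summary
from .estimation import (
    AGE_BANDS,
    CostEstimate,
    DepressionPrevalence,
    ModelParameters,
    TransitionEvidenceTable,
    WeibullFit,
)

PARAMETER_SCHEMA_VERSION = 1


def _json_default(o):
    if isinstance(o, np.generic):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)!r}")


def _fit_to_dict(fit: WeibullFit) -> dict:
    return {
        "event_type": fit.event_type,
        "shape": fit.shape,
        "log_scale": fit.log_scale,
        "coef_age": fit.coef_age,
        "coef_age_sq": fit.coef_age_sq,
        "beta": fit.beta.tolist(),
        "param_names": list(fit.param_names),
        "cov": None if fit.cov is None else fit.cov.tolist(),
        "n_events": fit.n_events,
        "n_exposure": fit.n_exposure,
        "converged": fit.converged,
        "log_likelihood": fit.log_likelihood,
    }


def _fit_from_dict(d: Mapping) -> WeibullFit:
    return WeibullFit(
        event_type=d["event_type"], shape=d["shape"], log_scale=d["log_scale"],
        coef_age=d["coef_age"], coef_age_sq=d["coef_age_sq"],
        beta=np.asarray(d["beta"], dtype=float), param_names=tuple(d["param_names"]),
        cov=None if d["cov"] is None else np.asarray(d["cov"], dtype=float),
        n_events=d["n_events"], n_exposure=d["n_exposure"],
        converged=d["converged"], log_likelihood=d["log_likelihood"],
    )


def save_parameters(params: ModelParameters, path) -> None:
    ev = params.evidence
    doc = {
        "schema_version": PARAMETER_SCHEMA_VERSION,
        "fits": {k: _fit_to_dict(v) for k, v in params.fits.items()},
        "evidence": {
            "ages": ev.ages.tolist(),
            "p_incidence": ev.p_incidence.tolist(),
            "n_at_risk": ev.n_at_risk.tolist(),
            "p_death": ev.p_death.tolist(),
            "n_by_class": ev.n_by_class.tolist(),
        },
        "depression": {
            k: {"numerator": v.numerator, "denominator": v.denominator}
            for k, v in params.depression.items()
        },
        "costs": [
            {"state_class": cls, "age_band": b, "sex": s, **{
                f: getattr(est, f) for f in (
                    "p_any_cost", "successes", "trials", "mean_positive",
                    "gamma_shape", "gamma_scale", "n_observations", "gamma_valid")}}
            for (cls, b, s), est in params.costs.items()
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, default=_json_default)


def load_parameters(path) -> ModelParameters:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != PARAMETER_SCHEMA_VERSION:
        raise ValueError(f"unsupported parameter schema: {doc.get('schema_version')!r}")
    ev = doc["evidence"]
    evidence = TransitionEvidenceTable(
        ages=np.asarray(ev["ages"]),
        p_incidence=np.asarray(ev["p_incidence"], dtype=float),
        n_at_risk=np.asarray(ev["n_at_risk"], dtype=float),
        p_death=np.asarray(ev["p_death"], dtype=float),
        n_by_class=np.asarray(ev["n_by_class"], dtype=float),
    )
    depression = {k: DepressionPrevalence(k, v["numerator"], v["denominator"])
                  for k, v in doc["depression"].items()}
    costs = {}
    for c in doc["costs"]:
        est = CostEstimate(
            state_class=c["state_class"],
            age_band=AGE_BANDS[c["age_band"]], sex=c["sex"],
            p_any_cost=c["p_any_cost"], successes=c["successes"], trials=c["trials"],
            mean_positive=c["mean_positive"], gamma_shape=c["gamma_shape"],
            gamma_scale=c["gamma_scale"], n_observations=c["n_observations"],
            gamma_valid=c["gamma_valid"],
        )
        costs[(c["state_class"], c["age_band"], c["sex"])] = est
    fits = {k: _fit_from_dict(v) for k, v in doc["fits"].items()}
    return ModelParameters(fits, evidence, depression, costs)


def _summary_dict(s: Summary) -> dict:
    return {"mean": s.mean, "ci": None if s.ci is None else list(s.ci)}


def cea_result_to_dict(res: CEAResult) -> dict:
    return {
        "n_draws": res.n_draws,
        "n_entrants": res.n_entrants,
        "base_rate": res.base_rate,
        "total_cost_millions": {str(r): {a: _summary_dict(s) for a, s in d.items()}
                                for r, d in res.total_cost.items()},
        "total_qalys": {str(r): {a: _summary_dict(s) for a, s in d.items()}
                        for r, d in res.total_qalys.items()},
        "incremental_cost_millions": {str(r): _summary_dict(s) for r, s in res.inc_cost.items()},
        "incremental_qalys": {str(r): _summary_dict(s) for r, s in res.inc_qalys.items()},
        "icer_per_draw": {str(r): _summary_dict(s) for r, s in res.icer.items()},
        "icer_of_means": {str(r): v for r, v in res.icer_of_means.items()},
        "nmb_millions": {str(w): _summary_dict(s) for w, s in res.nmb.items()},
        "nhb_qalys": {str(w): _summary_dict(s) for w, s in res.nhb.items()},
        "person_years": {c: {a: _summary_dict(s) for a, s in d.items()}
                         for c, d in res.person_years.items()},
        "incremental_person_years": {c: _summary_dict(s)
                                     for c, s in res.inc_person_years.items()},
        "incremental_life_years": _summary_dict(res.inc_life_years),
    }


def save_cea_result(res: CEAResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(cea_result_to_dict(res), fh, indent=1, default=_json_default)


def write_table3(res: CEAResult, path) -> None:
    """Cost-utility table: totals and incrementals per 1,000 at each discount rate."""
    rows = []
    for r in sorted(res.total_cost):
        label = "Not discounted" if r == 0 else f"Discounted {r * 100:g}%"
        rows.append({
            "measure": f"Health care costs per 1,000 (GBP millions), {label}",
            "surgery": round(res.total_cost[r]["surgery"].mean, 2),
            "no_surgery": round(res.total_cost[r]["no_surgery"].mean, 2),
            "incremental": round(res.inc_cost[r].mean, 2),
            "ci_low": None if res.inc_cost[r].ci is None else round(res.inc_cost[r].ci[0], 2),
            "ci_high": None if res.inc_cost[r].ci is None else round(res.inc_cost[r].ci[1], 2),
        })
    for r in sorted(res.total_qalys):
        label = "Not discounted" if r == 0 else f"Discounted {r * 100:g}%"
        rows.append({
            "measure": f"QALYs per 1,000, {label}",
            "surgery": round(res.total_qalys[r]["surgery"].mean, 0),
            "no_surgery": round(res.total_qalys[r]["no_surgery"].mean, 0),
            "incremental": round(res.inc_qalys[r].mean, 0),
            "ci_low": None if res.inc_qalys[r].ci is None else round(res.inc_qalys[r].ci[0], 0),
            "ci_high": None if res.inc_qalys[r].ci is None else round(res.inc_qalys[r].ci[1], 0),
        })
    for r, v in res.icer_of_means.items():
        s = res.icer[r]
        rows.append({"measure": f"Cost (GBP) per QALY, rate {r * 100:g}%",
                     "surgery": None, "no_surgery": None,
                     "incremental": round(v, 0),
                     "ci_low": None if s.ci is None else round(s.ci[0], 0),
                     "ci_high": None if s.ci is None else round(s.ci[1], 0)})
    for w, s in res.nmb.items():
        rows.append({"measure": f"NMB per 1,000 (GBP millions), {w:g}/QALY",
                     "surgery": None, "no_surgery": None,
                     "incremental": round(s.mean, 2),
                     "ci_low": None if s.ci is None else round(s.ci[0], 2),
                     "ci_high": None if s.ci is None else round(s.ci[1], 2)})
    for w, s in res.nhb.items():
        rows.append({"measure": f"NHB per 1,000 (QALYs), {w:g}/QALY",
                     "surgery": None, "no_surgery": None,
                     "incremental": round(s.mean, 0),
                     "ci_low": None if s.ci is None else round(s.ci[0], 0),
                     "ci_high": None if s.ci is None else round(s.ci[1], 0)})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_table4(rows: list[dict], path) -> None:
    """Subgroup/sensitivity table, one row per scenario."""
    pd.DataFrame(rows).to_csv(path, index=False)


def write_table5(projection: dict, path) -> None:
    """Commissioning projection as measure/estimate pairs."""
    pd.DataFrame([{"measure": k, "estimate": v} for k, v in projection.items()]
                 ).to_csv(path, index=False)
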