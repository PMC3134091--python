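"""From cohort traces to discounted QALYs, costs and CE statistics.

Utility in a cycle is the occupancy-weighted state utility
``clamp(c + b_f * BASFI + b_d * BASDAI, 0, 1)`` minus the expected
disutility of the adverse events occurring in that cycle (event costs and
disutilities accrue only in the cycle of occurrence).  Costs split into
four categories: treatment (drug acquisition including PPI / aspirin /
anti-TNF), GI events, CV events and other adverse events (congestive heart
failure carries the only non-zero "other" cost).  Discounting uses
``(1 + r) ** -(t - 1)``: the first cycle is undiscounted, so the year-1
treatment cost of a strategy equals its annual drug cost.

The incremental comparison follows standard cost-effectiveness practice:
the ICER is the ratio of mean incremental cost to mean incremental QALYs
(per-draw ICER ratios are unstable); dominance is classified on the means;
acceptability curves and P(best) are fractions of iterations, with NMB
ties splitting probability mass equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov import EVENTS, CohortTrace, HealthState, state_drug_cost, \
    state_scores
from .parameters import ParameterDraw

__all__ = [
    "ArmResult",
    "CEResult",
    "DEFAULT_WTP_GRID",
    "discounted_sum",
    "cycle_rewards",
    "accrue",
    "ce_compare",
    "p_best",
]

#: default willingness-to-pay grid, NOK per QALY
DEFAULT_WTP_GRID = np.arange(0, 1_000_001, 10_000)

COST_CATEGORIES = ("treatment", "gi", "cv", "other")

_GI_EVENT_COST = {
    "pub": ("cost_pub_surgery", "cost_pub_inpatient", "cost_pub_outpatient"),
}


def discounted_sum(values: np.ndarray, rate: float,
                   axis: int = -1) -> np.ndarray:
    """``sum_t values_t * (1 + rate) ** -(t - 1)`` along ``axis``."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    values = np.asarray(values, dtype=float)
    t = np.arange(values.shape[axis])
    factor = (1.0 + rate) ** -t
    shape = [1] * values.ndim
    shape[axis] = len(t)
    return np.sum(values * factor.reshape(shape), axis=axis)


# ---------------------------------------------------------------------------
# per-event expected costs and disutilities
# ---------------------------------------------------------------------------

def expected_event_cost(draw: ParameterDraw) -> dict[str, np.ndarray]:
    """Expected cost (NOK) per occurrence of each costed event type.

    PUB costs weight the hospitalisation / surgery / outpatient pathway
    probabilities; suspected PUBs the inpatient-investigation split; minor
    GI symptoms are costed when treated.  Edema, hypertension, hepatic and
    renal events carry no cost.
    """
    s, c = draw.safety, draw.cost
    hosp, surg = s["p_hosp_given_pub"], s["p_surgery_given_hosp"]
    inp = s["p_inpatient_given_suspected"]
    treat = s["p_treatment_given_minor_gi"]
    return {
        "pub": hosp * (surg * c["cost_pub_surgery"]
                       + (1 - surg) * c["cost_pub_inpatient"])
        + (1 - hosp) * c["cost_pub_outpatient"],
        "suspected_pub": inp * c["cost_suspected_inpatient"]
        + (1 - inp) * c["cost_suspected_outpatient"],
        "minor_gi": treat * c["cost_minor_treated"],
        "cv": c["cost_cv"],
        "chf": c["cost_chf"],
    }


def expected_event_disutility(draw: ParameterDraw) -> dict[str, np.ndarray]:
    """Expected utility decrement per occurrence of each event type."""
    s, d = draw.safety, draw.disutility
    hosp, surg = s["p_hosp_given_pub"], s["p_surgery_given_hosp"]
    inp = s["p_inpatient_given_suspected"]
    treat = s["p_treatment_given_minor_gi"]
    return {
        "pub": hosp * (surg * d["disutility_pub_surgery"]
                       + (1 - surg) * d["disutility_pub_inpatient"])
        + (1 - hosp) * d["disutility_pub_outpatient"],
        "suspected_pub": inp * d["disutility_suspected_inpatient"]
        + (1 - inp) * d["disutility_suspected_outpatient"],
        "minor_gi": treat * d["disutility_minor_treated"]
        + (1 - treat) * d["disutility_minor_untreated"],
        "cv": d["disutility_cv"],
        "edema": d["disutility_edema"],
        "hypertension": d["disutility_hypertension"],
        "chf": d["disutility_chf"],
        "hepatic": d["disutility_hepatic"],
        "renal": d["disutility_renal"],
    }


def cycle_rewards(trace: CohortTrace, draw: ParameterDraw) -> CohortTrace:
    """Fill the undiscounted per-cycle utility and cost ledgers in place."""
    n, horizon, _ = trace.occupancy.shape
    arm = trace.arm
    u = draw.utility
    ev_cost = expected_event_cost(draw)
    ev_disu = expected_event_disutility(draw)
    drug = state_drug_cost(draw, arm)            # (n, 8)
    eidx = {e: i for i, e in enumerate(EVENTS)}

    utility = np.zeros((n, horizon))
    costs = {k: np.zeros((n, horizon)) for k in COST_CATEGORIES}

    for t in range(horizon):
        occ = trace.occupancy[:, t, :]
        basfi, basdai = state_scores(draw, arm, t + 1)
        su = np.clip(u["utility_constant"][:, None]
                     + u["utility_basfi_coef"][:, None] * basfi
                     + u["utility_basdai_coef"][:, None] * basdai,
                     0.0, 1.0)
        su[:, HealthState.DEAD] = 0.0
        util = np.sum(occ * su, axis=1)
        for e, du in ev_disu.items():
            util = util - trace.events[:, t, eidx[e]] * du
        utility[:, t] = util

        costs["treatment"][:, t] = np.sum(occ * drug, axis=1)
        costs["gi"][:, t] = sum(
            trace.events[:, t, eidx[e]] * ev_cost[e]
            for e in ("pub", "suspected_pub", "minor_gi"))
        costs["cv"][:, t] = trace.events[:, t, eidx["cv"]] * ev_cost["cv"]
        costs["other"][:, t] = (trace.events[:, t, eidx["chf"]]
                                * ev_cost["chf"])

    if np.isnan(utility).any() or any(np.isnan(v).any()
                                      for v in costs.values()):
        raise AssertionError("NaN in reward ledgers")
    trace.utility = utility
    trace.costs = costs
    return trace


# ---------------------------------------------------------------------------
# accrual
# ---------------------------------------------------------------------------

@dataclass
class ArmResult:
    """Discounted per-iteration outcomes of one strategy at one horizon."""

    arm: str
    horizon: int
    discount_rate: float
    life_years: np.ndarray
    qalys: np.ndarray
    cost_treatment: np.ndarray
    cost_gi: np.ndarray
    cost_cv: np.ndarray
    cost_other: np.ndarray

    @property
    def cost_total(self) -> np.ndarray:
        return (self.cost_treatment + self.cost_gi + self.cost_cv
                + self.cost_other)

    def summary_row(self) -> dict:
        def mci(x):
            lo, hi = np.percentile(x, [2.5, 97.5])
            return float(np.mean(x)), float(lo), float(hi)

        row = {"arm": self.arm, "horizon": self.horizon}
        for name, x in (("life_years", self.life_years),
                        ("qalys", self.qalys),
                        ("cost_treatment", self.cost_treatment),
                        ("cost_gi", self.cost_gi),
                        ("cost_cv", self.cost_cv),
                        ("cost_other", self.cost_other),
                        ("cost_total", self.cost_total)):
            m, lo, hi = mci(x)
            row[name], row[f"{name}_lo"], row[f"{name}_hi"] = m, lo, hi
        return row


def accrue(trace: CohortTrace, draw: ParameterDraw,
           discount_rate: float | None = None,
           horizon: int | None = None) -> ArmResult:
    """Discount and sum a trace's ledgers up to ``horizon`` cycles."""
    if horizon is None:
        horizon = trace.horizon
    if horizon > trace.horizon:
        raise ValueError(
            f"trace covers {trace.horizon} cycles, requested {horizon}")
    rate = draw.discount_rate if discount_rate is None else discount_rate
    if trace.utility is None or trace.costs is None:
        cycle_rewards(trace, draw)

    alive = 1.0 - trace.occupancy[:, :horizon, HealthState.DEAD]
    ly = discounted_sum(alive, rate, axis=1)
    qaly = discounted_sum(trace.utility[:, :horizon], rate, axis=1)
    comps = {k: discounted_sum(v[:, :horizon], rate, axis=1)
             for k, v in trace.costs.items()}
    return ArmResult(
        arm=trace.arm, horizon=horizon, discount_rate=rate,
        life_years=ly, qalys=qaly,
        cost_treatment=comps["treatment"], cost_gi=comps["gi"],
        cost_cv=comps["cv"], cost_other=comps["other"],
    )


# ---------------------------------------------------------------------------
# incremental comparison
# ---------------------------------------------------------------------------

def p_best(values: dict[str, np.ndarray], largest: bool = True
           ) -> dict[str, float]:
    """Fraction of iterations in which each arm is best; ties split."""
    arms = list(values)
    mat = np.stack([values[a] for a in arms], axis=0)  # (arms, n)
    if not largest:
        mat = -mat
    best = mat.max(axis=0)
    is_best = mat == best[None, :]
    share = is_best / is_best.sum(axis=0, keepdims=True)
    return {a: float(share[i].mean()) for i, a in enumerate(arms)}


@dataclass
class CEResult:
    """Incremental cost-effectiveness of a reference arm vs comparators."""

    reference: str
    horizon: int
    incremental: pd.DataFrame          # per comparator: dC, dQ, ICER, flags
    ceac: pd.DataFrame                 # long format: wtp, arm, probability
    p_best_qaly: dict[str, float]
    p_best_cost: dict[str, float]
    wtp_grid: np.ndarray = field(default_factory=lambda: DEFAULT_WTP_GRID)

    def ceac_at(self, wtp: float, arm: str | None = None) -> float:
        arm = self.reference if arm is None else arm
        sel = self.ceac[(self.ceac["wtp"] == wtp)
                        & (self.ceac["arm"] == arm)]
        if sel.empty:
            raise KeyError(f"wtp {wtp} not on the grid")
        return float(sel["probability"].iloc[0])


def _icer(dc: float, dq: float) -> tuple[float | None, str]:
    if dc < 0 and dq > 0:
        return None, "dominant"
    if dc > 0 and dq < 0:
        return None, "dominated"
    if dq == 0:
        return None, "undefined"
    return dc / dq, ""


def ce_compare(results: dict[str, ArmResult],
               reference: str = "etoricoxib",
               wtp_grid: np.ndarray | None = None) -> CEResult:
    """Compare aligned per-draw arm results against a reference strategy.

    All arms must hold draws from common parameter iterations (same index
    ordering), which makes per-draw increments and the CEAC coherent.
    """
    if len(results) < 2:
        raise ValueError("need at least two arms to compare")
    if reference not in results:
        raise KeyError(f"reference arm {reference!r} not in results")
    wtp = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid)
    horizon = results[reference].horizon
    ref = results[reference]

    rows = []
    for arm, res in results.items():
        if arm == reference:
            continue
        if len(res.qalys) != len(ref.qalys):
            raise ValueError("arms hold different numbers of draws")
        dc = ref.cost_total - res.cost_total
        dq = ref.qalys - res.qalys
        dc_m, dq_m = float(dc.mean()), float(dq.mean())
        icer, flag = _icer(dc_m, dq_m)
        dc_lo, dc_hi = np.percentile(dc, [2.5, 97.5])
        dq_lo, dq_hi = np.percentile(dq, [2.5, 97.5])
        rows.append({
            "comparator": arm, "delta_cost": dc_m,
            "delta_cost_lo": float(dc_lo), "delta_cost_hi": float(dc_hi),
            "delta_qaly": dq_m,
            "delta_qaly_lo": float(dq_lo), "delta_qaly_hi": float(dq_hi),
            "icer": icer if icer is not None else np.nan,
            "dominance": flag,
        })
    incremental = pd.DataFrame(rows).set_index("comparator")

    qalys = {a: r.qalys for a, r in results.items()}
    costs = {a: r.cost_total for a, r in results.items()}
    arms = list(results)
    q_mat = np.stack([qalys[a] for a in arms])
    c_mat = np.stack([costs[a] for a in arms])
    ceac_rows = []
    for w in wtp:
        nmb = q_mat * w - c_mat
        best = nmb.max(axis=0)
        is_best = nmb == best[None, :]
        share = is_best / is_best.sum(axis=0, keepdims=True)
        for i, a in enumerate(arms):
            ceac_rows.append({"wtp": float(w), "arm": a,
                              "probability": float(share[i].mean())})
    ceac = pd.DataFrame(ceac_rows)

    return CEResult(
        reference=reference, horizon=horizon, incremental=incremental,
        ceac=ceac, p_best_qaly=p_best(qalys, largest=True),
        p_best_cost=p_best(costs, largest=False), wtp_grid=wtp,
    )
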