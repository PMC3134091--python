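"""Probabilistic sensitivity analysis, scenario suite and variance
decomposition.

Each PSA iteration draws one joint parameter set (efficacy from the MTC
posteriors, everything else from the registry distributions), runs the
cohort model once per strategy with *common* parameter draws across
strategies, and accrues discounted outcomes at the 1-, 5- and 30-year
horizons.  Common draws make per-iteration increments, acceptability
curves and P(best) coherent.  The base case uses 10,000 iterations;
everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import markov, outcomes
from .markov import CohortTrace, HealthState, LifeTable
from .outcomes import ArmResult, CEResult
from .parameters import (DistributionSpec, ParameterDraw, draw_to_frame,
                         sample_parameter_draw)

__all__ = [
    "ScenarioConfig",
    "PsaOutput",
    "SCENARIOS",
    "run_psa",
    "run_scenario_suite",
    "explained_uncertainty",
    "time_on_nsaid",
]

BASE_ARMS = ("etoricoxib", "celecoxib", "diclofenac", "naproxen")
HORIZONS = (1, 5, 30)

_GI_KEYS = ("pub_etoricoxib", "pub_celecoxib", "pub_nsnsaid",
            "suspected_pub_coxib", "suspected_pub_nsnsaid",
            "minor_gi_coxib", "minor_gi_nsnsaid")
_CV_KEYS = ("cv_etoricoxib", "cv_celecoxib", "cv_diclofenac", "cv_naproxen")
_OTHER_AE_KEYS = tuple(
    f"{ae}_{cls}" for ae in ("edema", "hypertension", "chf", "hepatic",
                             "renal") for cls in ("coxib", "nsnsaid"))


@dataclass(frozen=True)
class ScenarioConfig:
    """One analysis configuration (the base case or an alternative).

    ``adverse_events`` selects which event classes stay switched on:
    ``all``, ``gi`` (GI events only), ``cv`` (CV events only) or ``none``.
    """

    name: str
    arms: tuple[str, ...] = BASE_ARMS
    adverse_events: str = "all"
    discount_rate: float = 0.04
    basfi_progression: bool = True
    start_age: float = 45.0
    include_antitnf_cost: bool = True
    iterations: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.adverse_events not in ("all", "gi", "cv", "none"):
            raise ValueError(
                f"unknown adverse-event switch {self.adverse_events!r}")
        if self.iterations < 1:
            raise ValueError("iteration count must be >= 1")


def _base(**kw) -> ScenarioConfig:
    return ScenarioConfig(**kw)


#: the base case plus the nine alternative scenarios
SCENARIOS: dict[str, ScenarioConfig] = {
    "base": _base(name="base"),
    "celecoxib-200": _base(
        name="celecoxib-200",
        arms=("etoricoxib", "celecoxib200", "diclofenac", "naproxen")),
    "gi-only": _base(name="gi-only", adverse_events="gi"),
    "cv-only": _base(name="cv-only", adverse_events="cv"),
    "no-adverse-events": _base(name="no-adverse-events",
                               adverse_events="none"),
    "discount-0": _base(name="discount-0", discount_rate=0.0),
    "discount-8": _base(name="discount-8", discount_rate=0.08),
    "stable-basfi": _base(name="stable-basfi", basfi_progression=False),
    "age-20": _base(name="age-20", start_age=20.0),
    "no-antitnf-cost": _base(name="no-antitnf-cost",
                             include_antitnf_cost=False),
}


def apply_scenario(draw: ParameterDraw,
                   scenario: ScenarioConfig) -> ParameterDraw:
    """Overwrite a sampled draw with the scenario's switches.

    Returned draw shares unaffected arrays with the input (the PSA applies
    this once, immediately after sampling).
    """
    safety = dict(draw.safety)
    disease = dict(draw.disease)
    cost = dict(draw.cost)
    zeros = np.zeros(draw.n)
    off: tuple[str, ...] = ()
    if scenario.adverse_events == "gi":
        off = _CV_KEYS + _OTHER_AE_KEYS
    elif scenario.adverse_events == "cv":
        off = _GI_KEYS + _OTHER_AE_KEYS
    elif scenario.adverse_events == "none":
        off = _GI_KEYS + _CV_KEYS + _OTHER_AE_KEYS
    for k in off:
        safety[k] = zeros
    if not scenario.basfi_progression:
        disease["basfi_progression"] = zeros
    if not scenario.include_antitnf_cost:
        cost["cost_drug_antitnf"] = zeros
    return replace(draw, safety=safety, disease=disease, cost=cost,
                   start_age=scenario.start_age,
                   discount_rate=scenario.discount_rate)


@dataclass
class PsaOutput:
    """Everything one probabilistic run produces."""

    scenario: ScenarioConfig
    draw: ParameterDraw
    inputs: pd.DataFrame
    traces: dict[str, CohortTrace]
    arm_results: dict[int, dict[str, ArmResult]]
    ce: dict[int, CEResult]
    metadata: dict = field(default_factory=dict)

    def arm_table(self) -> pd.DataFrame:
        rows = []
        for h, per_arm in self.arm_results.items():
            for arm, res in per_arm.items():
                rows.append(res.summary_row())
        return pd.DataFrame(rows)

    def incremental_table(self) -> pd.DataFrame:
        frames = []
        for h, ce in self.ce.items():
            df = ce.incremental.reset_index()
            df.insert(0, "horizon", h)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def run_psa(
    scenario: ScenarioConfig | str,
    mtc: dict[str, dict[str, np.ndarray]],
    registry: dict[str, DistributionSpec],
    life_table: LifeTable | None = None,
    iterations: int | None = None,
    seed: int | None = None,
    point_estimate: bool = False,
    horizons: tuple[int, ...] = HORIZONS,
    reference: str = "etoricoxib",
) -> PsaOutput:
    """Run one full probabilistic analysis.

    Parameters
    ----------
    mtc:
        ``{"basfi": ..., "basdai": ..., "disc": ...}`` absolute posterior
        draws per treatment (resampled with replacement when fewer draws
        than iterations are available).
    """
    if isinstance(scenario, str):
        try:
            scenario = SCENARIOS[scenario]
        except KeyError:
            raise KeyError(
                f"unknown scenario {scenario!r}; valid names: "
                f"{sorted(SCENARIOS)}") from None
    if life_table is None:
        from .synthetic import default_life_table
        life_table = default_life_table()
    n = scenario.iterations if iterations is None else iterations
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    draw = sample_parameter_draw(registry, mtc, n=n, rng=rng,
                                 point_estimate=point_estimate)
    draw = apply_scenario(draw, scenario)
    inputs = draw_to_frame(draw)

    horizon_max = max(horizons)
    traces: dict[str, CohortTrace] = {}
    arm_results: dict[int, dict[str, ArmResult]] = {h: {} for h in horizons}
    for arm in scenario.arms:
        trace = markov.run_cohort(arm, draw, life_table,
                                  horizon=horizon_max)
        outcomes.cycle_rewards(trace, draw)
        traces[arm] = trace
        for h in horizons:
            arm_results[h][arm] = outcomes.accrue(
                trace, draw, discount_rate=scenario.discount_rate,
                horizon=h)

    ref = reference if reference in scenario.arms else scenario.arms[0]
    ce = {h: outcomes.ce_compare(arm_results[h], reference=ref)
          for h in horizons}

    return PsaOutput(
        scenario=scenario, draw=draw, inputs=inputs, traces=traces,
        arm_results=arm_results, ce=ce,
        metadata={"seed": seed, "iterations": n,
                  "point_estimate": point_estimate,
                  "arms": list(scenario.arms), "reference": ref},
    )


def run_scenario_suite(
    registry, mtc, life_table=None, iterations: int = 2000,
    seed: int | None = None, names: tuple[str, ...] | None = None,
) -> dict[str, PsaOutput]:
    """Run the base case and the alternative scenarios.

    Each scenario gets its own deterministic child seed so results do not
    change when a subset is run.
    """
    names = tuple(SCENARIOS) if names is None else names
    out = {}
    for i, name in enumerate(names):
        child = None if seed is None else int(
            np.random.SeedSequence([seed, i]).generate_state(1)[0]
            % (2**31 - 1))
        out[name] = run_psa(name, mtc, registry, life_table=life_table,
                            iterations=iterations, seed=child)
    return out


# ---------------------------------------------------------------------------
# derived statistics
# ---------------------------------------------------------------------------

def time_on_nsaid(trace: CohortTrace) -> np.ndarray:
    """Undiscounted expected years in any NSAID state (states 1-5),
    per iteration."""
    nsaid = [HealthState.INITIAL_NSAID, HealthState.INITIAL_NSAID_PPI,
             HealthState.ALT_NSNSAID, HealthState.ALT_NSNSAID_PPI,
             HealthState.ALT_NSNSAID_PPI_ASA]
    return trace.occupancy[:, :, nsaid].sum(axis=(1, 2))


#: Fig-3-style input groups: registry/posterior columns per label
UNCERTAINTY_GROUPS = {
    "discontinuation": lambda c: c.startswith("p_disc."),
    "cfb_basfi": lambda c: c.startswith("basfi_cfb."),
    "cfb_basdai": lambda c: c.startswith("basdai_cfb."),
    "pub": lambda c: c.startswith(("pub_", "suspected_pub_", "minor_gi_")),
    "cv": lambda c: c.startswith("cv_"),
    "utilities": lambda c: c.startswith(("utility_", "disutility_")),
    "costs": lambda c: c.startswith("cost_"),
}


def _r2(X: np.ndarray, y: np.ndarray) -> float:
    yc = y - y.mean()
    ss_tot = float(yc @ yc)
    if ss_tot == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    resid = yc - Xc @ beta
    return 1.0 - float(resid @ resid) / ss_tot


def explained_uncertainty(
    psa: PsaOutput,
    output: str = "delta_nmb",
    wtp: float = 400_000.0,
    horizon: int = 30,
    comparator: str | None = None,
    groups: dict | None = None,
    rank_transform: bool = False,
) -> pd.Series:
    """Share of output variance attributable to each input group.

    ANCOVA-style linear decomposition: for each group the drop in R² when
    its columns are removed from the full regression, normalised so the
    group shares sum to the total explained share.  ``output`` is one of
    ``delta_qaly``, ``delta_cost`` or ``delta_nmb`` (at ``wtp``), for the
    reference strategy versus ``comparator`` (default: first non-reference
    arm).  A rank transform is available for robustness to non-linearity.
    """
    if psa.draw.n < 2:
        raise ValueError("variance decomposition needs >= 2 iterations")
    per_arm = psa.arm_results[horizon]
    ref = psa.metadata["reference"]
    if comparator is None:
        comparator = next(a for a in per_arm if a != ref)
    r0, r1 = per_arm[ref], per_arm[comparator]
    dq = r0.qalys - r1.qalys
    dc = r0.cost_total - r1.cost_total
    y = {"delta_qaly": dq, "delta_cost": dc,
         "delta_nmb": dq * wtp - dc}[output]

    groups = UNCERTAINTY_GROUPS if groups is None else groups
    df = psa.inputs
    # drop constant and duplicated columns (pooled nodes repeat draws)
    df = df.loc[:, df.std() > 0]
    df = df.T.drop_duplicates().T
    cols_by_group = {g: [c for c in df.columns if match(c)]
                     for g, match in groups.items()}
    used = [c for cs in cols_by_group.values() for c in cs]
    X = df[used].to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    if rank_transform:
        X = np.argsort(np.argsort(X, axis=0), axis=0).astype(float)
        yv = np.argsort(np.argsort(yv)).astype(float)

    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        import warnings
        warnings.warn("collinear inputs; decomposition uses the "
                      "pseudo-inverse fit", RuntimeWarning, stacklevel=2)

    r2_full = _r2(X, yv)
    incremental = {}
    for g, cs in cols_by_group.items():
        if not cs:
            incremental[g] = 0.0
            continue
        keep = [i for i, c in enumerate(used) if c not in cs]
        r2_wo = _r2(X[:, keep], yv) if keep else 0.0
        incremental[g] = max(r2_full - r2_wo, 0.0)
    total = sum(incremental.values())
    if total > 0:
        shares = {g: v / total * r2_full for g, v in incremental.items()}
    else:
        shares = {g: 0.0 for g in incremental}
    return pd.Series(shares, name=f"{output}@{wtp:g}").sort_values(
        ascending=False)
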