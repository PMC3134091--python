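"""Annual-cycle eight-state Markov cohort model of sequential NSAID therapy.

States encode the treatment a patient is currently receiving:

0. ``INITIAL_NSAID``          -- the strategy's NSAID (etoricoxib,
   combined-dose celecoxib, diclofenac or naproxen)
1. ``INITIAL_NSAID_PPI``      -- same NSAID plus proton-pump inhibitor
2. ``ALT_NSNSAID``            -- alternative nonselective NSAID
3. ``ALT_NSNSAID_PPI``
4. ``ALT_NSNSAID_PPI_ASA``    -- + aspirin, after a survived CV event
5. ``ANTI_TNF``               -- biologic therapy after NSAID failure
6. ``ANTI_TNF_DISCONTINUED``  -- absorbing except death
7. ``DEAD``                   -- absorbing

Within a cycle, competing events are allocated mutually exclusively at
their annual probabilities, applied directly to start-of-cycle occupancy:
thrombotic CV event (fatal with the class case fatality; survivors move to
the aspirin+PPI state, or to anti-TNF from there), upper GI PUB (fatal
with probability 3.6%), suspected PUB, minor GI symptoms, the five
switch-triggering adverse events (edema, hypertension, CHF, hepatic,
renal) and lack-of-efficacy discontinuation.  Age-dependent background
mortality applies to the no-event remainder (patients not experiencing an
event that cycle).  Should a sampled probability set ever sum above one,
the event slice is renormalised, preserving the order above.  PUB
probabilities are reduced by the PPI risk reduction in PPI states.
Anti-TNF states have no adverse events; the anti-TNF state loses a fixed
annual fraction to permanent discontinuation.

Everything is vectorised over probabilistic iterations: a
:class:`~ascea.parameters.ParameterDraw` of size ``n`` yields an
``(n, cycles, ...)`` cohort trace in one pass.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .parameters import ParameterDraw

__all__ = [
    "HealthState",
    "LifeTable",
    "CohortTrace",
    "EVENTS",
    "read_life_table",
    "default_life_table_path",
    "cycle_transition",
    "run_cohort",
    "state_scores",
    "state_drug_cost",
]


class HealthState(IntEnum):
    INITIAL_NSAID = 0
    INITIAL_NSAID_PPI = 1
    ALT_NSNSAID = 2
    ALT_NSNSAID_PPI = 3
    ALT_NSNSAID_PPI_ASA = 4
    ANTI_TNF = 5
    ANTI_TNF_DISCONTINUED = 6
    DEAD = 7


N_STATES = len(HealthState)

#: event-ledger columns of a cohort trace
EVENTS = (
    "pub", "suspected_pub", "minor_gi", "cv",
    "edema", "hypertension", "chf", "hepatic", "renal",
    "discontinuation", "antitnf_withdrawal",
    "death_background", "death_pub", "death_cv",
)

# destination of each event by living NSAID state (indices 0..4)
_DEST_CV = (4, 4, 4, 4, 5)       # survived CV event
_DEST_PUB = (3, 3, 5, 5, 5)      # survived PUB
_DEST_GI = (1, 1, 3, 3, 4)       # suspected PUB / minor GI (may equal state)
_DEST_SWITCH = (2, 3, 5, 5, 5)   # other AE with switch, lack of efficacy

_OTHER_AES = ("edema", "hypertension", "chf", "hepatic", "renal")

_PPI_STATES = (1, 3, 4)


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Annual probability of death ``qx`` indexed by integer age."""

    age: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValueError("life-table qx must lie in [0, 1]")
        if len(self.age) != len(self.qx):
            raise ValueError("age and qx must have equal length")

    def q(self, age: float) -> float:
        """qx at the given (floored) age; errors outside coverage."""
        a = int(age)
        idx = np.searchsorted(self.age, a)
        if idx >= len(self.age) or self.age[idx] != a:
            raise ValueError(f"life table does not cover age {a}")
        return float(self.qx[idx])


def default_life_table_path():
    return importlib.resources.files("ascea.data") / "lifetable.csv"


def read_life_table(path=None) -> LifeTable:
    """Two-column delimited file (age, qx); ``#`` lines are comments."""
    if path is None:
        path = default_life_table_path()
    with open(path) if isinstance(path, str) else path.open() as fh:
        df = pd.read_csv(fh, comment="#")
    cols = list(df.columns)
    if "age" not in cols or "qx" not in cols:
        raise ValueError(f"life table needs columns (age, qx), got {cols}")
    df = df.sort_values("age")
    return LifeTable(df["age"].to_numpy(dtype=int),
                     df["qx"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# per-arm parameter views
# ---------------------------------------------------------------------------

def _arm_class(arm: str) -> str:
    return "coxib" if arm in ("etoricoxib", "celecoxib",
                              "celecoxib200") else "nsnsaid"


def _initial_pub(draw: ParameterDraw, arm: str) -> np.ndarray:
    key = {"etoricoxib": "pub_etoricoxib",
           "celecoxib": "pub_celecoxib",
           "celecoxib200": "pub_celecoxib",
           "diclofenac": "pub_nsnsaid",
           "naproxen": "pub_nsnsaid"}[arm]
    return draw.safety[key]


def _initial_cv(draw: ParameterDraw, arm: str) -> np.ndarray:
    key = {"etoricoxib": "cv_etoricoxib",
           "celecoxib": "cv_celecoxib",
           "celecoxib200": "cv_celecoxib",
           "diclofenac": "cv_diclofenac",
           "naproxen": "cv_naproxen"}[arm]
    return draw.safety[key]


def _event_probs(draw: ParameterDraw, arm: str) -> dict[str, np.ndarray]:
    """Per-state event probabilities for one strategy.

    Returns arrays of shape (n, 5) over the living NSAID states 0..4.
    Second-line nsNSAID therapy uses the published diclofenac/naproxen
    class values, with the CV rate averaged over the two drugs.
    """
    n = draw.n
    cls = _arm_class(arm)
    s = draw.safety
    alt_cv = 0.5 * (s["cv_diclofenac"] + s["cv_naproxen"])
    ppi_mult = 1.0 - s["ppi_pub_risk_reduction"]

    def stack(initial, alt):
        cols = [initial, initial, alt, alt, alt]
        return np.stack(cols, axis=1)

    pub = stack(_initial_pub(draw, arm), s["pub_nsnsaid"])
    for j in _PPI_STATES:
        pub[:, j] *= ppi_mult
    probs = {
        "pub": pub,
        "suspected_pub": stack(s[f"suspected_pub_{cls}"],
                               s["suspected_pub_nsnsaid"]),
        "minor_gi": stack(s[f"minor_gi_{cls}"], s["minor_gi_nsnsaid"]),
        "cv": stack(_initial_cv(draw, arm), alt_cv),
        "discontinuation": stack(draw.p_disc[arm], draw.p_disc["nsnsaid"]),
        "cf_cv": stack(s[f"case_fatality_cv_{cls}"],
                       s["case_fatality_cv_nsnsaid"]),
    }
    for ae in _OTHER_AES:
        probs[ae] = stack(s[f"{ae}_{cls}"], s[f"{ae}_nsnsaid"])
    return probs


def build_event_tree(draw: ParameterDraw, arm: str):
    """Event allocation, transitions and no-event remainders per state.

    Returns ``(M, A, S)``:

    * ``M`` -- ``(n, 8, 8)`` transition matrix excluding background
      mortality, rows summing to one (the no-event mass stays put);
    * ``A`` -- ``(n, 8, len(EVENTS) - 1)`` per-state event probabilities,
      columns following :data:`EVENTS` without ``death_background``;
    * ``S`` -- ``(n, 8)`` no-event remainder per living state, the mass
      exposed to background mortality (zero for the dead state).

    Event probabilities are applied unconditioned to start-of-cycle
    occupancy; if a sampled set sums above one it is renormalised.
    """
    n = draw.n
    p = _event_probs(draw, arm)
    cf_pub = draw.safety["case_fatality_pub"]

    M = np.zeros((n, N_STATES, N_STATES))
    a_events = [e for e in EVENTS if e != "death_background"]
    A = np.zeros((n, N_STATES, len(a_events)))
    S = np.zeros((n, N_STATES))
    eidx = {e: i for i, e in enumerate(a_events)}
    ordered = (["cv", "pub", "suspected_pub", "minor_gi"]
               + list(_OTHER_AES) + ["discontinuation"])

    for s in range(5):
        total = sum(p[ev][:, s] for ev in ordered)
        scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-300), 1.0)

        p_cv = scale * p["cv"][:, s]
        M[:, s, HealthState.DEAD] += p_cv * p["cf_cv"][:, s]
        M[:, s, _DEST_CV[s]] += p_cv * (1.0 - p["cf_cv"][:, s])
        A[:, s, eidx["cv"]] += p_cv
        A[:, s, eidx["death_cv"]] += p_cv * p["cf_cv"][:, s]

        p_pub = scale * p["pub"][:, s]
        M[:, s, HealthState.DEAD] += p_pub * cf_pub
        M[:, s, _DEST_PUB[s]] += p_pub * (1.0 - cf_pub)
        A[:, s, eidx["pub"]] += p_pub
        A[:, s, eidx["death_pub"]] += p_pub * cf_pub

        for ev in ("suspected_pub", "minor_gi"):
            pe = scale * p[ev][:, s]
            M[:, s, _DEST_GI[s]] += pe
            A[:, s, eidx[ev]] += pe
        for ev in _OTHER_AES:
            pe = scale * p[ev][:, s]
            M[:, s, _DEST_SWITCH[s]] += pe
            A[:, s, eidx[ev]] += pe
        pd_ = scale * p["discontinuation"][:, s]
        M[:, s, _DEST_SWITCH[s]] += pd_
        A[:, s, eidx["discontinuation"]] += pd_

        stay = 1.0 - np.minimum(total, 1.0)
        M[:, s, s] += stay
        S[:, s] = stay

    w = draw.disease["p_antitnf_withdraw"]
    M[:, HealthState.ANTI_TNF, HealthState.ANTI_TNF_DISCONTINUED] = w
    M[:, HealthState.ANTI_TNF, HealthState.ANTI_TNF] = 1.0 - w
    A[:, HealthState.ANTI_TNF, eidx["antitnf_withdrawal"]] = w
    S[:, HealthState.ANTI_TNF] = 1.0 - w
    M[:, HealthState.ANTI_TNF_DISCONTINUED,
      HealthState.ANTI_TNF_DISCONTINUED] = 1.0
    S[:, HealthState.ANTI_TNF_DISCONTINUED] = 1.0
    M[:, HealthState.DEAD, HealthState.DEAD] = 1.0

    np.testing.assert_allclose(M.sum(axis=2), 1.0, atol=1e-9)
    return M, A, S


def cycle_transition(state: HealthState, draw: ParameterDraw, age: float,
                     arm: str, life_table: LifeTable | None = None,
                     q_background: float | None = None):
    """One-cycle transition probabilities and event ledger for one state.

    Scalar convenience wrapper over :func:`build_event_tree` (used by tests
    and the micro-simulation oracle); returns a probability vector over the
    eight states and a ``{event: probability}`` ledger.
    """
    if state == HealthState.DEAD:
        raise ValueError("cycle_transition is defined for living states")
    q = life_table.q(age) if q_background is None else q_background
    M, A, S = build_event_tree(draw, arm)
    s = int(state)
    vec = M[:, s, :].mean(axis=0)
    stay = S[:, s].mean()
    vec[s] -= stay * q                       # background death hits the
    vec[HealthState.DEAD] += stay * q        # no-event remainder
    a_events = [e for e in EVENTS if e != "death_background"]
    ledger = {"death_background": float(stay * q)}
    ledger.update({
        ev: float(A[:, s, i].mean()) for i, ev in enumerate(a_events)
    })
    assert abs(vec.sum() - 1.0) < 1e-9
    return vec, ledger


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """State occupancy and per-cycle ledgers for one strategy.

    ``occupancy[:, t, :]`` is the cohort distribution at the *start* of
    cycle ``t + 1`` (cycles are 1-based); ``events[:, t, e]`` the expected
    number of events of type ``EVENTS[e]`` during that cycle, per patient.
    Cost and utility ledgers are undiscounted and filled by
    :func:`ascea.outcomes.cycle_rewards`.
    """

    arm: str
    start_age: float
    occupancy: np.ndarray          # (n, horizon, 8)
    events: np.ndarray             # (n, horizon, len(EVENTS))
    utility: np.ndarray | None = None       # (n, horizon)
    costs: dict[str, np.ndarray] | None = None  # category -> (n, horizon)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Iteration-averaged trace, one row per cycle."""
        occ = self.occupancy.mean(axis=0)
        ev = self.events.mean(axis=0)
        data = {"cycle": np.arange(1, self.horizon + 1)}
        for s in HealthState:
            data[f"occ_{s.name.lower()}"] = occ[:, s]
        for i, e in enumerate(EVENTS):
            data[f"ev_{e}"] = ev[:, i]
        if self.utility is not None:
            data["utility"] = self.utility.mean(axis=0)
        if self.costs is not None:
            for k, v in self.costs.items():
                data[f"cost_{k}"] = v.mean(axis=0)
        return pd.DataFrame(data)


def run_cohort(arm: str, draw: ParameterDraw, life_table: LifeTable,
               horizon: int = 30,
               start_age: float | None = None) -> CohortTrace:
    """Propagate a full cohort from ``INITIAL_NSAID`` over annual cycles.

    Age during cycle ``t`` is ``start_age + t - 1``; background mortality is
    layered on top of the event tree as the first competing risk.  Row sums
    of the occupancy matrix are conserved to 1e-9 per cycle.
    """
    if not 1 <= horizon <= 30:
        raise ValueError("horizon must be in [1, 30] cycles")
    age0 = draw.start_age if start_age is None else start_age
    for t in range(horizon):
        life_table.q(age0 + t)  # fail early if coverage is missing

    n = draw.n
    M, A, S = build_event_tree(draw, arm)
    occupancy = np.zeros((n, horizon, N_STATES))
    events = np.zeros((n, horizon, len(EVENTS)))

    occ = np.zeros((n, N_STATES))
    occ[:, HealthState.INITIAL_NSAID] = 1.0
    bg_idx = EVENTS.index("death_background")
    cols = [i for i in range(len(EVENTS)) if i != bg_idx]

    for t in range(horizon):
        occupancy[:, t, :] = occ
        q = life_table.q(age0 + t)
        events[:, t, cols] = np.einsum("ns,nse->ne", occ, A)
        # background mortality strikes the no-event remainder, which sits
        # on each state's own diagonal of M
        bg = q * occ * S                                  # (n, 8)
        events[:, t, bg_idx] = bg.sum(axis=1)
        nxt = np.einsum("ns,nst->nt", occ, M) - bg
        nxt[:, HealthState.DEAD] += bg.sum(axis=1)
        occ = nxt
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)

    return CohortTrace(arm=arm, start_age=age0, occupancy=occupancy,
                       events=events)


# ---------------------------------------------------------------------------
# disease scores and drug costs by state
# ---------------------------------------------------------------------------

def state_scores(draw: ParameterDraw, arm: str, cycle: int):
    """BASFI/BASDAI score pair per state for a given 1-based cycle.

    Returns two arrays of shape ``(n, 8)``.  Background BASFI progresses
    linearly from baseline; BASDAI stays at baseline.  NSAID states apply
    the (negative) treatment change-from-baseline; anti-TNF states use the
    sampled on-treatment and post-withdrawal scores.  Scores for the dead
    state are zero-filled (never used: dead accrue no utility).
    """
    if cycle < 1:
        raise ValueError("cycles are 1-based")
    d = draw.disease
    n = draw.n
    bg_basfi = np.clip(d["basfi_baseline"]
                       + d["basfi_progression"] * (cycle - 1), 0.0, 100.0)
    bg_basdai = d["basdai_baseline"]

    basfi = np.zeros((n, N_STATES))
    basdai = np.zeros((n, N_STATES))
    init_f = np.clip(bg_basfi + draw.basfi_cfb[arm], 0.0, 100.0)
    init_d = np.clip(bg_basdai + draw.basdai_cfb[arm], 0.0, 100.0)
    alt_f = np.clip(bg_basfi + draw.basfi_cfb["nsnsaid"], 0.0, 100.0)
    alt_d = np.clip(bg_basdai + draw.basdai_cfb["nsnsaid"], 0.0, 100.0)
    for s in (0, 1):
        basfi[:, s] = init_f
        basdai[:, s] = init_d
    for s in (2, 3, 4):
        basfi[:, s] = alt_f
        basdai[:, s] = alt_d
    basfi[:, HealthState.ANTI_TNF] = d["basfi_antitnf"]
    basdai[:, HealthState.ANTI_TNF] = d["basdai_antitnf"]
    basfi[:, HealthState.ANTI_TNF_DISCONTINUED] = d["basfi_post_antitnf"]
    basdai[:, HealthState.ANTI_TNF_DISCONTINUED] = d["basdai_post_antitnf"]
    return basfi, basdai


def state_drug_cost(draw: ParameterDraw, arm: str) -> np.ndarray:
    """Annual drug acquisition cost (NOK) per state, shape ``(n, 8)``.

    PPI and aspirin co-medication costs continue for as long as the
    corresponding state is occupied; the discontinued-anti-TNF state
    accrues no drug cost.
    """
    c = draw.cost
    init = c[f"cost_drug_{arm}"]
    alt = 0.5 * (c["cost_drug_diclofenac"] + c["cost_drug_naproxen"])
    ppi = c["cost_drug_ppi"]
    asa = c["cost_drug_aspirin"]
    cols = [
        init,
        init + ppi,
        alt,
        alt + ppi,
        alt + ppi + asa,
        c["cost_drug_antitnf"],
        np.zeros(draw.n),
        np.zeros(draw.n),
    ]
    return np.stack(cols, axis=1)
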