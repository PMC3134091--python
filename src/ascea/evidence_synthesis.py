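"""Bayesian mixed treatment comparison (network meta-analysis).

Two likelihoods are supported, matching the two kinds of trial evidence:

* arm-level normal likelihood on change-from-baseline (CFB) means with known
  standard errors (BASFI / BASDAI), identity link;
* arm-level binomial likelihood on discontinuation counts, logit link.

Both share the same linear predictor: a trial-specific baseline ``mu_i``
plus a treatment contrast ``d_t`` relative to the reference treatment
(placebo), with vague normal priors.  The fixed-effect model is the base
case; a random-effects variant with arm-level exchangeable effects and a
half-normal heterogeneity prior is available.

Posterior sampling uses a self-contained adaptive random-walk
Metropolis-within-Gibbs sampler, vectorised over chains.  Absolute
treatment-level values (expected CFB; annual discontinuation probability)
are constructed per posterior draw by anchoring the contrasts at the
unweighted mean of the baselines of the trials that randomised a placebo
arm; on the logit scale the anchored linear predictor is inverse-linked
before averaging.  The anchoring rule is this implementation's convention
(the source evidence reports absolute values without stating one).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "TrialArm",
    "MtcPosterior",
    "read_trials",
    "default_trials_path",
    "mtc_continuous",
    "mtc_binomial",
    "posterior_summary",
]

#: canonical network node names for the trial-file treatment labels
TREATMENT_ALIASES = {
    "etoricoxib90": "etoricoxib",
    "etoricoxib120": "etoricoxib120",
    "naproxen1000": "naproxen",
    "diclofenac150": "diclofenac",
    "nsNSAID-pooled": "nsnsaid",
    "nsnsaid": "nsnsaid",
}

RHAT_WARN = 1.05


@dataclass(frozen=True)
class TrialArm:
    """One randomised arm of one trial for one outcome.

    Continuous outcomes carry ``(cfb_mean, cfb_se)``; the discontinuation
    outcome carries event count ``r`` out of ``n`` randomised.
    """

    study: str
    treatment: str
    outcome: str
    cfb_mean: float | None = None
    cfb_se: float | None = None
    r: int | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        has_cont = self.cfb_mean is not None and self.cfb_se is not None
        has_bin = self.r is not None and self.n is not None
        if has_cont == has_bin:
            raise ValueError(
                f"arm {self.study}/{self.treatment}: exactly one of "
                "(cfb_mean, cfb_se) or (r, n) must be populated"
            )
        if has_cont and self.cfb_se <= 0:
            raise ValueError("cfb_se must be positive")
        if has_bin and not (0 <= self.r <= self.n):
            raise ValueError(
                f"arm {self.study}/{self.treatment}: need 0 <= r <= n, "
                f"got r={self.r}, n={self.n}"
            )


def default_trials_path():
    """Bundled trial-level evidence table."""
    return importlib.resources.files("ascea.data") / "trials.csv"


def read_trials(path=None) -> list[TrialArm]:
    """Read the delimited trial table into :class:`TrialArm` records."""
    if path is None:
        path = default_trials_path()
    with open(path) if isinstance(path, str) else path.open() as fh:
        df = pd.read_csv(fh, float_precision="round_trip")
    expected = {"study", "treatment", "outcome", "mean", "se", "r", "n"}
    if not expected.issubset(df.columns):
        raise ValueError(
            f"trial file must have columns {sorted(expected)}, "
            f"got {list(df.columns)}"
        )
    if df.empty:
        raise ValueError("no arms parsed from trial file")
    arms = []
    for _, row in df.iterrows():
        cont = pd.notna(row["mean"])
        arms.append(TrialArm(
            study=str(row["study"]),
            treatment=str(row["treatment"]),
            outcome=str(row["outcome"]),
            cfb_mean=float(row["mean"]) if cont else None,
            cfb_se=float(row["se"]) if cont else None,
            r=int(row["r"]) if not cont else None,
            n=int(row["n"]) if not cont else None,
        ))
    return arms


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class MtcPosterior:
    """Joint posterior draws from one MTC fit.

    ``contrasts`` are treatment effects versus the reference node on the
    linear-predictor scale, aligned across treatments within a draw;
    ``anchor`` is the per-draw absolute placebo level used to construct
    absolute values.
    """

    outcome: str
    link: str                       # "identity" | "logit"
    reference: str
    contrasts: dict[str, np.ndarray]
    baselines: dict[str, np.ndarray]
    anchor: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_draws(self) -> int:
        return len(self.anchor)

    def absolute(self) -> dict[str, np.ndarray]:
        """Per-treatment absolute draws (CFB points, or probability)."""
        out = {}
        for t, d in self.contrasts.items():
            eta = self.anchor + d
            out[t] = expit(eta) if self.link == "logit" else eta
        return out

    def to_frame(self) -> pd.DataFrame:
        """Columnar export of the absolute draws (one row per draw)."""
        return pd.DataFrame(self.absolute())


def posterior_summary(post: MtcPosterior) -> pd.DataFrame:
    """Posterior mean and empirical central 95% interval per treatment."""
    rows = []
    for t, draws in post.absolute().items():
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append({"treatment": t, "mean": float(np.mean(draws)),
                     "ci_lo": float(lo), "ci_hi": float(hi)})
    return pd.DataFrame(rows).set_index("treatment")


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

def _canon(t: str) -> str:
    return TREATMENT_ALIASES.get(t, t)


def _check_connected(studies, treatments, arm_study, arm_trt) -> None:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(treatments)
    by_study: dict[str, list[str]] = {}
    for s, t in zip(arm_study, arm_trt):
        by_study.setdefault(s, []).append(t)
    for ts in by_study.values():
        for a in ts[1:]:
            g.add_edge(ts[0], a)
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        raise ValueError(f"treatment network is disconnected: {comps}")


def _prepare(arms: list[TrialArm], outcome: str, pool_nsnsaid: bool):
    sel = [a for a in arms if a.outcome == outcome]
    if not sel:
        raise ValueError(f"no arms with outcome {outcome!r}")
    trts, studies, labels = [], [], []
    for a in sel:
        t = _canon(a.treatment)
        if pool_nsnsaid and t in ("diclofenac", "naproxen"):
            t = "nsnsaid"
        labels.append(t)
        studies.append(a.study)
    study_ids = sorted(set(studies))
    trt_ids = sorted(set(labels))
    reference = "placebo" if "placebo" in trt_ids else trt_ids[0]
    trt_ids = [reference] + [t for t in trt_ids if t != reference]
    _check_connected(study_ids, trt_ids, studies, labels)
    return sel, studies, labels, study_ids, trt_ids, reference


# ---------------------------------------------------------------------------
# adaptive Metropolis-within-Gibbs
# ---------------------------------------------------------------------------

def _sample_network(
    *, study_idx, trt_idx, study_ids, trt_ids, y=None, w=None, r=None,
    n=None, link, effects, chains, iterations, seed, prior_sd,
    het_prior_sd,
):
    """Shared sampler for both likelihoods.

    Parameter vector: ``[mu_0..mu_{S-1}, d_1..d_{T-1}]`` (fixed effect) with
    additional arm-level effects ``delta_a`` and ``log tau`` under random
    effects.  Proposal scales adapt towards ~44% acceptance during the
    burn-in half and are frozen afterwards.
    """
    rng = np.random.default_rng(seed)
    A = len(study_idx)
    S, T = len(study_ids), len(trt_ids)
    C = chains
    re = effects == "random"

    # baseline (reference-treatment-free) design: eta = mu_i + effect_a
    # fixed: effect_a = d_{t_a}; random: effect_a = delta_a ~ N(d_{t_a}, tau^2)
    nonbase = np.where(trt_idx > 0)[0]          # arms with a non-reference trt
    M = len(nonbase)
    P = S + (T - 1) + (M + 1 if re else 0)

    theta = np.zeros((P, C))
    # data-informed start for trial baselines, overdispersed across chains
    for i in range(S):
        mask = study_idx == i
        if y is not None:
            theta[i] = np.average(y[mask], weights=w[mask])
        else:
            p0 = (r[mask].sum() + 0.5) / (n[mask].sum() + 1.0)
            theta[i] = logit(p0)
    theta += rng.normal(0, 1.0, size=theta.shape)

    def eta_of(th):
        e = th[study_idx]
        if re:
            d_arm = np.zeros((A, C))
            d_arm[nonbase] = th[S + T - 1 + np.arange(M)]
        else:
            d_arm = np.zeros((A, C))
            live = trt_idx > 0
            d_arm[live] = th[S + trt_idx[live] - 1]
        return e + d_arm

    eta = eta_of(theta)

    if y is not None:
        yA = y[:, None]
        wA = w[:, None]

        def dloglik(rows, eta_old, eta_new):
            return 0.5 * np.sum(
                wA[rows] * ((yA[rows] - eta_old) ** 2
                            - (yA[rows] - eta_new) ** 2), axis=0)
    else:
        rA = r[:, None]
        nA = n[:, None]

        def dloglik(rows, eta_old, eta_new):
            return np.sum(
                rA[rows] * (eta_new - eta_old)
                - nA[rows] * (np.logaddexp(0, eta_new)
                              - np.logaddexp(0, eta_old)), axis=0)

    # which arms each parameter touches through the linear predictor
    rows_of: list[np.ndarray] = []
    for i in range(S):
        rows_of.append(np.where(study_idx == i)[0])
    for t in range(1, T):
        if re:
            rows_of.append(np.array([], dtype=int))   # d_t: prior-only
        else:
            rows_of.append(np.where(trt_idx == t)[0])
    if re:
        for a in nonbase:
            rows_of.append(np.array([a]))
        rows_of.append(np.array([], dtype=int))        # log tau

    nonbase_trt = trt_idx[nonbase]                     # treatment of delta_a

    def dlogprior(j, old, new):
        # vague normal priors on mu and d
        if j < S + T - 1:
            dp = 0.5 * (old**2 - new**2) / prior_sd**2
            if re and j >= S:
                t = j - S + 1
                sel = nonbase_trt == t
                if sel.any():
                    tau = np.exp(theta[P - 1])
                    dd = theta[S + T - 1 + np.where(sel)[0]]
                    dp = dp + 0.5 * np.sum(
                        (dd - old) ** 2 - (dd - new) ** 2, axis=0) / tau**2
            return dp
        if re and j < P - 1:
            t = nonbase_trt[j - (S + T - 1)]
            d_t = theta[S + t - 1]
            tau = np.exp(theta[P - 1])
            return 0.5 * ((old - d_t) ** 2 - (new - d_t) ** 2) / tau**2
        # log tau: half-normal prior on tau, with log-scale Jacobian
        tau_o, tau_n = np.exp(old), np.exp(new)
        dd = theta[S + T - 1 + np.arange(M)]
        d_t = theta[S + nonbase_trt - 1]
        res = (dd - d_t) ** 2
        lp_o = (-M * old - 0.5 * np.sum(res, axis=0) / tau_o**2
                - 0.5 * tau_o**2 / het_prior_sd**2 + old)
        lp_n = (-M * new - 0.5 * np.sum(res, axis=0) / tau_n**2
                - 0.5 * tau_n**2 / het_prior_sd**2 + new)
        return lp_n - lp_o

    burn = iterations // 2
    steps = np.full(P, 0.5)
    acc = np.zeros(P)
    keep = iterations - burn
    out = np.empty((keep, P, C))

    for it in range(iterations):
        for j in range(P):
            dz = steps[j] * rng.standard_normal(C)
            old = theta[j].copy()
            new = old + dz
            rows = rows_of[j]
            if len(rows):
                # every parameter enters the touched rows' linear
                # predictor with unit coefficient
                eta_old = eta[rows]
                eta_new = eta_old + dz[None, :]
                dll = dloglik(rows, eta_old, eta_new)
            else:
                dll = 0.0
            dlp = dll + dlogprior(j, old, new)
            accept = np.log(rng.random(C)) < dlp
            theta[j] = np.where(accept, new, old)
            if len(rows):
                eta[rows] = np.where(accept[None, :], eta_new, eta_old)
            acc[j] += accept.mean()
            if it < burn and (it + 1) % 50 == 0:
                rate = acc[j] / 50.0
                steps[j] *= float(np.exp(np.clip(rate - 0.44, -0.5, 0.5)))
                acc[j] = 0.0
        if it >= burn:
            out[it - burn] = theta

    return out, dict(S=S, T=T, M=M, P=P, re=re, burn=burn)


def _rhat_split(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for (draws, chains)."""
    k, c = x.shape
    half = k // 2
    segs = np.concatenate([x[:half], x[half:2 * half]], axis=1)  # (half, 2c)
    m = segs.mean(axis=0)
    v = segs.var(axis=0, ddof=1)
    w = v.mean()
    b = half * m.var(ddof=1)
    if w == 0:
        return 1.0
    var_hat = (half - 1) / half * w + b / half
    return float(np.sqrt(var_hat / w))


def _ess(x: np.ndarray) -> float:
    """Crude effective sample size from pooled autocorrelation."""
    k, c = x.shape
    total = 0.0
    for j in range(c):
        z = x[:, j] - x[:, j].mean()
        var = np.dot(z, z) / k
        if var == 0:
            total += k
            continue
        rho_sum = 0.0
        for lag in range(1, min(k - 1, 200)):
            rho = np.dot(z[:-lag], z[lag:]) / (k * var)
            if rho < 0.05:
                break
            rho_sum += rho
        total += k / (1.0 + 2.0 * rho_sum)
    return float(total)


def _finalize(draws, info, study_ids, trt_ids, reference, outcome, link,
              seed, placebo_studies):
    S, T = info["S"], info["T"]
    keep, P, C = draws.shape
    flat = draws.transpose(0, 2, 1).reshape(keep * C, P)  # draw-major

    contrasts = {reference: np.zeros(keep * C)}
    for t in range(1, T):
        contrasts[trt_ids[t]] = flat[:, S + t - 1]
    baselines = {s: flat[:, i] for i, s in enumerate(study_ids)}

    if placebo_studies:
        anchor = np.mean([baselines[s] for s in placebo_studies], axis=0)
    else:
        anchor = np.mean(list(baselines.values()), axis=0)

    diagnostics = {"rhat": {}, "ess": {}, "n_draws": keep * C,
                   "chains": C, "warnings": []}
    names = study_ids + [f"d_{trt_ids[t]}" for t in range(1, T)]
    for j, name in enumerate(names):
        diagnostics["rhat"][name] = _rhat_split(draws[:, j, :])
        diagnostics["ess"][name] = _ess(draws[:, j, :])
    worst = max(diagnostics["rhat"].values())
    if worst > RHAT_WARN:
        msg = (f"MTC ({outcome}) convergence diagnostic {worst:.3f} "
               f"exceeds {RHAT_WARN}")
        diagnostics["warnings"].append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=3)

    return MtcPosterior(
        outcome=outcome, link=link, reference=reference,
        contrasts=contrasts, baselines=baselines, anchor=anchor,
        diagnostics=diagnostics, seed=seed,
    )


# ---------------------------------------------------------------------------
# public fits
# ---------------------------------------------------------------------------

def mtc_continuous(
    arms: list[TrialArm],
    outcome: str = "basfi_cfb",
    effects: str = "fixed",
    chains: int = 4,
    iterations: int = 20000,
    seed: int | None = None,
    prior_sd: float = 100.0,
    het_prior_sd: float = 5.0,
) -> MtcPosterior:
    """MTC of change-from-baseline scores with arm-level normal likelihood.

    For the BASDAI outcome the naproxen and diclofenac arms are pooled into
    a single nsNSAID node, mirroring how the trial evidence is reported.
    Returns absolute expected CFB per treatment via the placebo-anchored
    construction described in the module docstring.
    """
    pool = outcome == "basdai_cfb"
    sel, studies, labels, study_ids, trt_ids, reference = _prepare(
        arms, outcome, pool_nsnsaid=pool)
    for a in sel:
        if a.cfb_mean is None:
            raise ValueError(
                f"arm {a.study}/{a.treatment} lacks continuous data")
    study_idx = np.array([study_ids.index(s) for s in studies])
    trt_idx = np.array([trt_ids.index(t) for t in labels])
    y = np.array([a.cfb_mean for a in sel])
    w = np.array([1.0 / a.cfb_se**2 for a in sel])

    draws, info = _sample_network(
        study_idx=study_idx, trt_idx=trt_idx, study_ids=study_ids,
        trt_ids=trt_ids, y=y, w=w, link="identity", effects=effects,
        chains=chains, iterations=iterations, seed=seed,
        prior_sd=prior_sd, het_prior_sd=het_prior_sd,
    )
    placebo_studies = sorted(
        {s for s, t in zip(studies, labels) if t == reference}
    ) if reference == "placebo" else []
    return _finalize(draws, info, study_ids, trt_ids, reference, outcome,
                     "identity", seed, placebo_studies)


def mtc_binomial(
    arms: list[TrialArm],
    effects: str = "fixed",
    chains: int = 4,
    iterations: int = 20000,
    seed: int | None = None,
    prior_sd: float = 100.0,
    het_prior_sd: float = 2.0,
) -> MtcPosterior:
    """Binomial-logit MTC of discontinuation for lack of efficacy.

    Naproxen and diclofenac arms are pooled into one nsNSAID node (the
    evidence reports a single diclofenac/naproxen value).  The per-cycle
    annual discontinuation probability per treatment is the inverse-logit of
    the anchored linear predictor, per draw.
    """
    sel, studies, labels, study_ids, trt_ids, reference = _prepare(
        arms, "discontinuation", pool_nsnsaid=True)
    for a in sel:
        if a.r is None:
            raise ValueError(f"arm {a.study}/{a.treatment} lacks r/n data")
    study_idx = np.array([study_ids.index(s) for s in studies])
    trt_idx = np.array([trt_ids.index(t) for t in labels])
    r = np.array([float(a.r) for a in sel])
    n = np.array([float(a.n) for a in sel])

    draws, info = _sample_network(
        study_idx=study_idx, trt_idx=trt_idx, study_ids=study_ids,
        trt_ids=trt_ids, r=r, n=n, link="logit", effects=effects,
        chains=chains, iterations=iterations, seed=seed,
        prior_sd=prior_sd, het_prior_sd=het_prior_sd,
    )
    placebo_studies = sorted(
        {s for s, t in zip(studies, labels) if t == reference}
    ) if reference == "placebo" else []
    return _finalize(draws, info, study_ids, trt_ids, reference,
                     "discontinuation", "logit", seed, placebo_studies)
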