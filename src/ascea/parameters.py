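"""Model parameters: uncertainty distributions and joint sampling.

Every non-efficacy input of the decision model (event probabilities, case
fatalities, utilities, disutilities, unit costs, disease scores) is housed in
a *registry*: a mapping from parameter name to a :class:`DistributionSpec`.
Published summaries given only as point estimate + 95% interval are converted
into samplable two-parameter distributions by moment matching: the mean is
matched exactly and the free scale parameter is solved by root-finding so
that the central 95% interval width matches the published one.

Efficacy parameters (change-from-baseline scores and discontinuation
probabilities) are *not* refit here: their posterior draws come straight from
the mixed treatment comparison (:mod:`ascea.evidence_synthesis`) and are
assembled into a joint :class:`ParameterDraw` by
:func:`sample_parameter_draw`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = [
    "DistributionSpec",
    "ParameterDraw",
    "fit_beta_from_mean_ci",
    "fit_positive_from_mean_ci",
    "load_registry",
    "default_registry_path",
    "sample_parameter_draw",
    "draw_to_frame",
]

_FAMILIES = ("beta", "gamma", "lognormal", "uniform", "normal", "fixed")


@dataclass(frozen=True)
class DistributionSpec:
    """One samplable uncertainty distribution.

    Parameters
    ----------
    family:
        One of ``beta`` (a, b), ``gamma`` (shape, rate), ``lognormal``
        (mu, sigma of the underlying normal), ``uniform`` (lo, hi),
        ``normal`` (mean, sd) or ``fixed`` (value,).
    params:
        Family-specific parameter tuple.
    source:
        Free-text citation / provenance string.
    """

    family: str
    params: tuple[float, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        p = self.params
        ok = {
            "beta": lambda: len(p) == 2 and p[0] > 0 and p[1] > 0,
            "gamma": lambda: len(p) == 2 and p[0] > 0 and p[1] > 0,
            "lognormal": lambda: len(p) == 2 and p[1] > 0,
            "uniform": lambda: len(p) == 2 and p[0] < p[1],
            "normal": lambda: len(p) == 2 and p[1] > 0,
            "fixed": lambda: len(p) == 1,
        }[self.family]
        if not ok():
            raise ValueError(
                f"invalid parameters {p!r} for family {self.family!r}"
            )

    # -- frozen distribution ------------------------------------------------
    def _frozen(self):
        a, *rest = self.params
        if self.family == "beta":
            return stats.beta(a, rest[0])
        if self.family == "gamma":
            return stats.gamma(a, scale=1.0 / rest[0])
        if self.family == "lognormal":
            return stats.lognorm(rest[0], scale=np.exp(a))
        if self.family == "uniform":
            return stats.uniform(a, rest[0] - a)
        if self.family == "normal":
            return stats.norm(a, rest[0])
        raise AssertionError(self.family)

    def mean(self) -> float:
        if self.family == "fixed":
            return float(self.params[0])
        return float(self._frozen().mean())

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        """Central credible interval (for ``fixed``, a zero-width pair)."""
        if self.family == "fixed":
            v = float(self.params[0])
            return (v, v)
        lo, hi = self._frozen().interval(level)
        return (float(lo), float(hi))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(size, float(self.params[0]))
        return np.asarray(self._frozen().rvs(size=size, random_state=rng))


# ---------------------------------------------------------------------------
# moment-matching fits
# ---------------------------------------------------------------------------

def _solve_width(width_of, target: float, name: str, side: str,
                 lo: float = -12.0, hi: float = 30.0) -> float:
    """Root-find a log-scale parameter so the 95% width matches ``target``.

    ``width_of`` maps the log-parameter to the central 95% interval width.
    The width is unimodal in the log-parameter (it collapses both in the
    degenerate small-scale limit and in the concentrated large-scale
    limit), so the root is searched on one monotone branch: ``side="hi"``
    (right of the peak -- concentration-like parameters where narrow
    intervals mean large values) or ``side="lo"`` (left of the peak --
    dispersion-like parameters such as a lognormal sigma).
    """
    xs = np.linspace(lo, hi, 120)
    ws = np.array([width_of(x) for x in xs])
    ipk = int(np.argmax(ws))
    if target > ws[ipk]:
        raise ValueError(
            f"interval-width root search failed for {name!r}: target "
            f"width {target} exceeds the family's maximum {ws[ipk]:.4g}"
        )
    a, b = (xs[ipk], hi) if side == "hi" else (lo, xs[ipk])
    f = lambda x: width_of(x) - target  # noqa: E731
    if f(a) * f(b) > 0:
        raise ValueError(
            f"interval-width root search failed to bracket for {name!r} "
            f"(target width {target})"
        )
    return optimize.brentq(f, a, b, xtol=1e-12)


def fit_beta_from_mean_ci(mean: float, lo: float, hi: float,
                          source: str = "") -> DistributionSpec:
    """Beta distribution with the given mean and 95% interval width.

    The mean is matched exactly via ``a = mean * s``, ``b = (1 - mean) * s``
    and the concentration ``s`` is solved so that the central 95% interval
    width equals ``hi - lo``.  A zero-width interval yields a ``fixed`` spec.
    """
    # lower bounds printed as 0 are accepted (rounded-to-zero quantiles)
    if not (0.0 <= lo <= mean <= hi < 1.0 and mean > 0.0):
        raise ValueError(
            f"infeasible beta summary: need 0 <= lo <= mean <= hi < 1, "
            f"mean > 0; got mean={mean}, lo={lo}, hi={hi}"
        )
    if hi == lo:
        return DistributionSpec("fixed", (mean,), source)

    def width(log_s: float) -> float:
        s = np.exp(log_s)
        q = stats.beta.ppf([0.025, 0.975], mean * s, (1 - mean) * s)
        return float(q[1] - q[0])

    log_s = _solve_width(width, hi - lo, "beta fit", side="hi")
    s = float(np.exp(log_s))
    return DistributionSpec("beta", (mean * s, (1 - mean) * s), source)


def fit_positive_from_mean_ci(mean: float, lo: float, hi: float,
                              family: str = "gamma",
                              source: str = "") -> DistributionSpec:
    """Gamma or lognormal with exact mean and matched 95% interval width.

    Gamma is the conventional choice for cost parameters, lognormal for
    rate-like safety parameters whose posterior summaries are published
    without a closed-form distribution.
    """
    if not (0.0 <= lo <= mean <= hi and mean > 0.0):
        raise ValueError(
            f"infeasible positive summary: need 0 <= lo <= mean <= hi, "
            f"mean > 0; got mean={mean}, lo={lo}, hi={hi}"
        )
    if hi == lo:
        return DistributionSpec("fixed", (mean,), source)
    if family == "gamma":

        def width(log_k: float) -> float:
            k = np.exp(log_k)
            q = stats.gamma.ppf([0.025, 0.975], k, scale=mean / k)
            return float(q[1] - q[0])

        log_k = _solve_width(width, hi - lo, "gamma fit", side="hi")
        k = float(np.exp(log_k))
        return DistributionSpec("gamma", (k, k / mean), source)
    if family == "lognormal":

        def width(log_sig: float) -> float:
            sig = np.exp(log_sig)
            mu = np.log(mean) - sig**2 / 2.0
            return float(np.exp(mu) * (np.exp(1.959963985 * sig)
                                       - np.exp(-1.959963985 * sig)))

        log_sig = _solve_width(width, hi - lo, "lognormal fit",
                               side="lo", hi=float(np.log(40.0)))
        sig = float(np.exp(log_sig))
        return DistributionSpec(
            "lognormal", (float(np.log(mean) - sig**2 / 2.0), sig), source
        )
    raise ValueError(f"family must be 'gamma' or 'lognormal', got {family!r}")


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def default_registry_path():
    """Path-like handle to the bundled parameter registry."""
    return importlib.resources.files("ascea.data") / "parameters.yaml"


def load_registry(path=None) -> dict[str, DistributionSpec]:
    """Read a registry file into ``{name: DistributionSpec}``.

    Each YAML entry either states a family with explicit parameters::

        edema_coxib: {family: beta, params: [101.4, 9459.7], source: "..."}

    or a published summary plus the family to fit::

        pub_etoricoxib: {fit: lognormal, mean: 0.0111, lo: 0.0074,
                         hi: 0.0159, source: "..."}
    """
    if path is None:
        path = default_registry_path()
    with open(path) if isinstance(path, str) else path.open() as fh:
        raw = yaml.safe_load(fh)
    registry: dict[str, DistributionSpec] = {}
    for name, entry in raw.items():
        src = entry.get("source", "")
        if "fit" in entry:
            m, lo, hi = entry["mean"], entry["lo"], entry["hi"]
            if lo == hi:
                registry[name] = DistributionSpec("fixed", (float(m),), src)
            elif entry["fit"] == "beta":
                registry[name] = fit_beta_from_mean_ci(m, lo, hi, src)
            else:
                registry[name] = fit_positive_from_mean_ci(
                    m, lo, hi, entry["fit"], src
                )
        else:
            registry[name] = DistributionSpec(
                entry["family"], tuple(float(x) for x in entry["params"]), src
            )
    return registry


# ---------------------------------------------------------------------------
# joint parameter draws
# ---------------------------------------------------------------------------

#: treatment strategies of the decision model; ``celecoxib`` is the combined
#: 200/400 mg arm (equal mixture of dose-level parameters).
ARMS = ("etoricoxib", "celecoxib", "diclofenac", "naproxen")

_SAFETY_KEYS = (
    "pub_etoricoxib", "pub_celecoxib", "pub_nsnsaid",
    "suspected_pub_coxib", "suspected_pub_nsnsaid",
    "minor_gi_coxib", "minor_gi_nsnsaid",
    "cv_etoricoxib", "cv_celecoxib", "cv_diclofenac", "cv_naproxen",
    "edema_coxib", "edema_nsnsaid",
    "hypertension_coxib", "hypertension_nsnsaid",
    "chf_coxib", "chf_nsnsaid",
    "hepatic_coxib", "hepatic_nsnsaid",
    "renal_coxib", "renal_nsnsaid",
    "ppi_pub_risk_reduction", "case_fatality_pub",
    "case_fatality_cv_coxib", "case_fatality_cv_nsnsaid",
    "p_hosp_given_pub", "p_surgery_given_hosp",
    "p_inpatient_given_suspected", "p_treatment_given_minor_gi",
)
_UTILITY_KEYS = ("utility_constant", "utility_basfi_coef",
                 "utility_basdai_coef")
_DISUTILITY_KEYS = (
    "disutility_pub_surgery", "disutility_pub_inpatient",
    "disutility_pub_outpatient", "disutility_suspected_inpatient",
    "disutility_suspected_outpatient", "disutility_minor_treated",
    "disutility_minor_untreated", "disutility_cv", "disutility_edema",
    "disutility_hypertension", "disutility_hepatic", "disutility_chf",
    "disutility_renal",
)
_COST_KEYS = (
    "cost_pub_surgery", "cost_pub_inpatient", "cost_pub_outpatient",
    "cost_suspected_inpatient", "cost_suspected_outpatient",
    "cost_minor_treated", "cost_cv", "cost_chf",
    "cost_drug_etoricoxib", "cost_drug_celecoxib200",
    "cost_drug_celecoxib400", "cost_drug_diclofenac", "cost_drug_naproxen",
    "cost_drug_ppi", "cost_drug_aspirin", "cost_drug_antitnf",
)
_DISEASE_KEYS = (
    "basfi_baseline", "basdai_baseline", "basfi_progression",
    "basfi_antitnf", "basdai_antitnf", "basfi_post_antitnf",
    "basdai_post_antitnf", "p_antitnf_withdraw",
)
_PROBABILITY_KEYS = frozenset(
    k for k in _SAFETY_KEYS
) | {"p_antitnf_withdraw"}


@dataclass
class ParameterDraw:
    """One (vectorised) joint parameter sample for the PSA.

    All leaf values are ``numpy`` arrays of length ``n`` so that ``n``
    probabilistic iterations are carried through the cohort model at once.
    ``n == 1`` with ``point_estimate=True`` gives the deterministic base
    case.
    """

    n: int
    basfi_cfb: dict[str, np.ndarray]
    basdai_cfb: dict[str, np.ndarray]
    p_disc: dict[str, np.ndarray]
    safety: dict[str, np.ndarray]
    utility: dict[str, np.ndarray]
    disutility: dict[str, np.ndarray]
    cost: dict[str, np.ndarray]
    disease: dict[str, np.ndarray]
    start_age: float = 45.0
    discount_rate: float = 0.04

    def __getitem__(self, key: str) -> np.ndarray:
        for group in (self.safety, self.utility, self.disutility,
                      self.cost, self.disease):
            if key in group:
                return group[key]
        raise KeyError(key)


def _resample(draws: Mapping[str, np.ndarray], n: int,
              rng: np.random.Generator,
              point_estimate: bool) -> dict[str, np.ndarray]:
    """Jointly resample aligned posterior draw columns to length ``n``."""
    keys = list(draws)
    m = len(next(iter(draws.values())))
    if point_estimate:
        return {k: np.full(n, float(np.mean(draws[k]))) for k in keys}
    idx = rng.integers(0, m, size=n)
    return {k: np.asarray(draws[k])[idx] for k in keys}


def sample_parameter_draw(
    registry: Mapping[str, DistributionSpec],
    efficacy: Mapping[str, Mapping[str, np.ndarray]],
    n: int = 1,
    rng: np.random.Generator | int | None = None,
    point_estimate: bool = False,
) -> ParameterDraw:
    """Assemble a coherent joint parameter draw of size ``n``.

    Parameters
    ----------
    registry:
        Output of :func:`load_registry`.
    efficacy:
        ``{"basfi": {treatment: draws}, "basdai": ..., "disc": ...}`` with
        aligned posterior draw vectors from the mixed treatment comparison
        (see :meth:`ascea.evidence_synthesis.MtcPosterior.absolute`).
        Within each outcome the treatment columns are resampled jointly so
        posterior correlations are preserved; outcomes come from separate
        model fits and are resampled independently.
    point_estimate:
        Collapse every distribution (and the efficacy posteriors) to its
        mean -- the deterministic mode.

    Notes
    -----
    Derived entries follow the model's arm definitions: the combined
    celecoxib arm is an equal 50/50 mixture of the 200 mg and 400 mg dose
    parameters (efficacy, discontinuation, drug cost); second-line nsNSAID
    efficacy is the mean of the diclofenac and naproxen draws.
    """
    rng = np.random.default_rng(rng)
    missing = [
        k for k in (_SAFETY_KEYS + _UTILITY_KEYS + _DISUTILITY_KEYS
                    + _COST_KEYS + _DISEASE_KEYS
                    + ("start_age", "discount_rate"))
        if k not in registry
    ]
    if missing:
        raise KeyError(f"registry is missing entries: {missing}")

    def group(keys) -> dict[str, np.ndarray]:
        out = {}
        for k in keys:
            spec = registry[k]
            if point_estimate:
                out[k] = np.full(n, spec.mean())
            else:
                out[k] = spec.sample(rng, n)
            if k in _PROBABILITY_KEYS:
                out[k] = np.clip(out[k], 0.0, 1.0)
        return out

    basfi = _resample(efficacy["basfi"], n, rng, point_estimate)
    basdai = _resample(efficacy["basdai"], n, rng, point_estimate)
    disc = _resample(efficacy["disc"], n, rng, point_estimate)

    basfi["celecoxib"] = 0.5 * (basfi["celecoxib200"]
                                + basfi["celecoxib400"])
    basfi["nsnsaid"] = 0.5 * (basfi["diclofenac"] + basfi["naproxen"])
    basdai["celecoxib"] = 0.5 * (basdai["celecoxib200"]
                                 + basdai["celecoxib400"])
    # BASDAI trials pool diclofenac/naproxen into one nsNSAID node already
    basdai.setdefault("diclofenac", basdai["nsnsaid"])
    basdai.setdefault("naproxen", basdai["nsnsaid"])
    disc["celecoxib"] = 0.5 * (disc["celecoxib200"] + disc["celecoxib400"])
    # discontinuation evidence pools diclofenac/naproxen; both arms and the
    # second-line nsNSAID use the pooled node
    disc.setdefault("diclofenac", disc["nsnsaid"])
    disc.setdefault("naproxen", disc["nsnsaid"])
    disc = {k: np.clip(v, 1e-9, 1 - 1e-9) for k, v in disc.items()}

    cost = group(_COST_KEYS)
    cost["cost_drug_celecoxib"] = 0.5 * (cost["cost_drug_celecoxib200"]
                                         + cost["cost_drug_celecoxib400"])

    return ParameterDraw(
        n=n,
        basfi_cfb=basfi,
        basdai_cfb=basdai,
        p_disc=disc,
        safety=group(_SAFETY_KEYS),
        utility=group(_UTILITY_KEYS),
        disutility=group(_DISUTILITY_KEYS),
        cost=cost,
        disease=group(_DISEASE_KEYS),
        start_age=float(registry["start_age"].mean()),
        discount_rate=float(registry["discount_rate"].mean()),
    )


def draw_to_frame(draw: ParameterDraw):
    """Flatten a :class:`ParameterDraw` into a DataFrame (one row per
    iteration) for audit export or variance decomposition."""
    import pandas as pd

    cols: dict[str, np.ndarray] = {}
    for prefix, grp in (("basfi_cfb", draw.basfi_cfb),
                        ("basdai_cfb", draw.basdai_cfb),
                        ("p_disc", draw.p_disc)):
        for k, v in grp.items():
            cols[f"{prefix}.{k}"] = v
    for grp in (draw.safety, draw.utility, draw.disutility, draw.cost,
                draw.disease):
        for k, v in grp.items():
            cols[k] = v
    return pd.DataFrame(cols)
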