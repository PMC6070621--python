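"""Synthetic longitudinal microbiome counts and power / type-I-error studies.

The generator emulates a two-group (case/control) longitudinal design:
counts for one taxon are drawn from a negative binomial whose log mean is

    eta_ij = log(T_ij) + b0 + b1 x_i + b2 t_ij + b3 x_i t_ij
             + u_0i (+ u_1i t_ij) (+ eps_ij)

with half the subjects cases (x_i = 1), per-observation library sizes
log(T_ij) ~ Unif[7.1, 10.5] against a fixed intercept b0 = -7 (so the
baseline log mean spans [0.1, 3.5]), subject random effects
u ~ N(0, tau^2), and — in the time-series setting — a Gaussian AR(1)
disturbance on the linear predictor with lag-1 correlation rho and
marginal standard deviation sigma.

Four layouts are provided:

    A: 5 time points, random intercept only, independent errors
    B: 10 time points, random intercept, AR(1) errors
    C: 5 time points, random intercept and slope, independent errors
    D: 4 or 5 time points per subject, random intercept, independent errors

Per replicate, nuisance parameters are redrawn from their ranges
(theta ~ Unif[0.1, 5], tau ~ Unif[0.5, 1], rho ~ Unif[0.1, 0.5],
sigma ~ Unif[0.1, 0.5]) and the effect sizes follow the scenario:
null (all zero), a/b (interaction only, from [0.2, 0.35] or [0.35, 0.8]),
c/d (all three effects from the same ranges).  A study run fits each
simulated dataset with the layout-matched model and reports the empirical
rejection rate of the Wald tests of the group effect (beta1) and the
group-by-time interaction (beta3) at the chosen level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import LongitudinalDataset
from .nbmm_fit import FitControl, ModelSpec, fit_lmm_arcsine, fit_nbmm

__all__ = [
    "SimulationConfig",
    "SimParams",
    "PowerResult",
    "draw_parameters",
    "make_parameters",
    "simulate_dataset",
    "setting_model_spec",
    "run_power_study",
    "read_config",
]

logger = logging.getLogger(__name__)

SETTINGS = ("A", "B", "C", "D")
SCENARIOS = ("null", "a", "b", "c", "d")

#: parameter ranges redrawn at every replicate
LOG_T_RANGE = (7.1, 10.5)
BETA0 = -7.0
THETA_RANGE = (0.1, 5.0)
TAU_RANGE = (0.5, 1.0)
RHO_RANGE = (0.1, 0.5)
SIGMA_RANGE = (0.1, 0.5)
EFFECT_RANGES = {"small": (0.2, 0.35), "large": (0.35, 0.8)}


@dataclass
class SimulationConfig:
    """One simulation study: layout, sample size, effect scenario."""

    setting: str = "A"
    n_subjects: int = 100
    scenario: str = "null"
    n_reps: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.n_subjects < 2 or self.n_subjects % 2:
            raise ValueError("n_subjects must be even and >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")


@dataclass
class SimParams:
    """Drawn parameters for a single replicate."""

    beta: np.ndarray  # (b0, b1, b2, b3)
    theta: float
    tau: float
    rho: float
    sigma: float
    times: list  # per-subject time vectors
    log_T: np.ndarray  # per-observation log library sizes


def _scenario_betas(scenario: str, rng: np.random.Generator) -> np.ndarray:
    small, large = EFFECT_RANGES["small"], EFFECT_RANGES["large"]
    b1 = b2 = b3 = 0.0
    if scenario == "a":
        b3 = rng.uniform(*small)
    elif scenario == "b":
        b3 = rng.uniform(*large)
    elif scenario == "c":
        b1, b2, b3 = rng.uniform(*small, size=3)
    elif scenario == "d":
        b1, b2, b3 = rng.uniform(*large, size=3)
    return np.array([BETA0, b1, b2, b3])


def _layout_times(cfg: SimulationConfig, rng: np.random.Generator) -> list:
    """Per-subject measurement times, equally spaced on [0, 1]."""
    if cfg.setting == "B":
        base = np.linspace(0.0, 1.0, 10)
        return [base] * cfg.n_subjects
    if cfg.setting == "D":
        n_pts = rng.choice([4, 5], size=cfg.n_subjects)
        return [np.linspace(0.0, 1.0, k) for k in n_pts]
    base = np.linspace(0.0, 1.0, 5)
    return [base] * cfg.n_subjects


def make_parameters(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    beta=None,
    theta: float | None = None,
    tau: float | None = None,
    rho: float | None = None,
    sigma: float | None = None,
) -> SimParams:
    """Assemble replicate parameters, drawing any left unspecified.

    The layout (time points per subject) and the per-observation log
    library sizes are always drawn here, so a :class:`SimParams` fully
    determines the design of one replicate.
    """
    if theta is None:
        theta = float(rng.uniform(*THETA_RANGE))
    if tau is None:
        tau = float(rng.uniform(*TAU_RANGE))
    if beta is None:
        beta = _scenario_betas(cfg.scenario, rng)
    beta = np.asarray(beta, dtype=float)
    if rho is None:
        rho = float(rng.uniform(*RHO_RANGE))
    if sigma is None:
        sigma = float(rng.uniform(*SIGMA_RANGE))
    times = _layout_times(cfg, rng)
    n_rows = int(sum(len(t) for t in times))
    log_T = rng.uniform(*LOG_T_RANGE, size=n_rows)
    return SimParams(beta, theta, tau, rho, sigma, times, log_T)


def draw_parameters(cfg: SimulationConfig, rng: np.random.Generator) -> SimParams:
    """Draw one replicate's parameters from the study ranges.

    Under the null scenario all three effects are zero; rho and sigma are
    always drawn but enter the generator only in setting B, the only
    layout with within-subject correlation.
    """
    return make_parameters(cfg, rng)


def _ar1_noise(n: int, rho: float, sigma: float, rng: np.random.Generator):
    """Gaussian AR(1) sequence with lag-1 correlation rho and marginal sd
    sigma (stationary start)."""
    e = np.empty(n)
    e[0] = rng.normal(0.0, sigma)
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    for j in range(1, n):
        e[j] = rho * e[j - 1] + rng.normal(0.0, innov_sd)
    return e


def simulate_dataset(
    params: SimParams,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> LongitudinalDataset:
    """Generate one longitudinal dataset (a single taxon) from ``params``.

    The first half of the subjects are cases (group = 1).  Setting C adds
    an independent random time slope N(0, tau^2); setting B adds the AR(1)
    disturbance on the linear predictor.
    """
    n = cfg.n_subjects
    half = n // 2
    total_reads = np.rint(np.exp(params.log_T)).astype(np.int64)
    log_T = np.log(total_reads.astype(float))
    b0i = rng.normal(0.0, params.tau, size=n)
    b1i = rng.normal(0.0, params.tau, size=n) if cfg.setting == "C" else np.zeros(n)

    rows_subject = []
    rows_time = []
    eta_parts = []
    pos = 0
    for i in range(n):
        t = params.times[i]
        k = len(t)
        x = 1.0 if i < half else 0.0
        lt = log_T[pos : pos + k]
        pos += k
        b = params.beta
        eta = lt + b[0] + b[1] * x + b[2] * t + b[3] * x * t + b0i[i] + b1i[i] * t
        if cfg.setting == "B":
            eta = eta + _ar1_noise(k, params.rho, params.sigma, rng)
        eta_parts.append(eta)
        rows_subject.extend([f"S{i + 1:04d}"] * k)
        rows_time.extend(t.tolist())

    eta_all = np.concatenate(eta_parts)
    mu = np.exp(eta_all)
    y = rng.negative_binomial(params.theta, params.theta / (params.theta + mu))

    n_rows = len(rows_subject)
    sample_ids = [f"s{j + 1:05d}" for j in range(n_rows)]
    group = np.repeat(
        [1.0 if i < half else 0.0 for i in range(n)],
        [len(t) for t in params.times],
    )
    samples = pd.DataFrame(
        {
            "subject": rows_subject,
            "time": rows_time,
            "total_reads": total_reads,
            "group": group,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    counts = pd.DataFrame(
        {"taxon_1": y.astype(np.int64)}, index=samples.index
    )
    return LongitudinalDataset(samples, counts)


def setting_model_spec(setting: str, psi_structure: str = "diagonal") -> ModelSpec:
    """The analysis model matched to a simulation layout (the model is
    correctly specified): random slope only in setting C, AR(1) residual
    correlation only in setting B."""
    return ModelSpec(
        group_var="group",
        time_var="time",
        include_interaction=True,
        random="intercept_and_time" if setting == "C" else "intercept_only",
        correlation="ar1" if setting == "B" else "independent",
        psi_structure=psi_structure,
    )


@dataclass
class PowerResult:
    """Empirical rejection rates with Monte-Carlo standard errors."""

    method: str
    setting: str
    n_subjects: int
    scenario: str
    alpha: float
    n_reps: int
    n_used: int
    n_failed: int
    n_nonconverged: int
    rejection_rate: dict
    mc_se: dict

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                method=self.method,
                setting=self.setting,
                n_subjects=self.n_subjects,
                scenario=self.scenario,
                alpha=self.alpha,
                term=term,
                rejection_rate=self.rejection_rate[term],
                mc_se=self.mc_se[term],
                n_reps=self.n_reps,
                n_used=self.n_used,
                n_failed=self.n_failed,
                n_nonconverged=self.n_nonconverged,
            )
            for term in self.rejection_rate
        ]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def run_power_study(
    cfg: SimulationConfig,
    methods=("nbmm", "lmm_arcsine"),
    control: FitControl | None = None,
) -> dict:
    """Monte-Carlo power / false-positive-rate study.

    Every replicate draws fresh parameters, simulates one dataset, and
    fits each requested method with the layout-matched model; the Wald
    p-values for the group effect ("beta1") and the interaction ("beta3")
    are compared against ``cfg.alpha``.  Both methods see the same
    datasets (paired comparison).  Replicate-level fit failures — a raised
    error, non-finite p-values, or a fit that did not converge — are
    excluded from that method's denominator; errors count toward
    ``n_failed`` and convergence failures toward ``n_nonconverged``.
    Fully reproducible from ``cfg.seed``.
    """
    for m in methods:
        if m not in ("nbmm", "lmm_arcsine"):
            raise ValueError(f"unknown method {m!r}")
    spec = setting_model_spec(cfg.setting)
    terms = {"beta1": "group", "beta3": "group:time"}
    reject = {m: {k: [] for k in terms} for m in methods}
    n_failed = {m: 0 for m in methods}
    n_noncvg = {m: 0 for m in methods}

    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_reps)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = draw_parameters(cfg, rng)
        ds = simulate_dataset(params, cfg, rng)
        for m in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if m == "nbmm":
                        fit = fit_nbmm(ds, "taxon_1", spec, control)
                    else:
                        fit = fit_lmm_arcsine(ds, "taxon_1", spec)
                pvals = {k: float(fit.wald.loc[v, "p"]) for k, v in terms.items()}
                if not all(np.isfinite(p) for p in pvals.values()):
                    raise ValueError("non-finite p-value")
            except Exception as err:
                logger.warning("replicate %d (%s) failed: %s", rep, m, err)
                n_failed[m] += 1
                continue
            if not fit.converged:
                n_noncvg[m] += 1
                continue
            for k in terms:
                reject[m][k].append(pvals[k] < cfg.alpha)

    out = {}
    for m in methods:
        rates, ses = {}, {}
        n_used = 0
        for k in terms:
            arr = np.asarray(reject[m][k], dtype=float)
            n_used = arr.size
            rate = float(arr.mean()) if arr.size else float("nan")
            rates[k] = rate
            ses[k] = (
                float(np.sqrt(rate * (1.0 - rate) / arr.size)) if arr.size else float("nan")
            )
        out[m] = PowerResult(
            method=m,
            setting=cfg.setting,
            n_subjects=cfg.n_subjects,
            scenario=cfg.scenario,
            alpha=cfg.alpha,
            n_reps=cfg.n_reps,
            n_used=n_used,
            n_failed=n_failed[m],
            n_nonconverged=n_noncvg[m],
            rejection_rate=rates,
            mc_se=ses,
        )
    return out


def read_config(path) -> SimulationConfig:
    """Parse a plain key=value (or key<TAB>value) text file into a
    :class:`SimulationConfig`.  Recognized keys: setting, n, scenario,
    reps, alpha, seed."""
    values = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line:
                key, val = line.split("=", 1)
            else:
                key, *rest = line.split()
                val = rest[0] if rest else ""
            values[key.strip().lower()] = val.strip()
    kwargs = {}
    if "setting" in values:
        kwargs["setting"] = values["setting"].upper()
    if "n" in values:
        kwargs["n_subjects"] = int(values["n"])
    if "scenario" in values:
        kwargs["scenario"] = values["scenario"].lower()
    if "reps" in values:
        kwargs["n_reps"] = int(values["reps"])
    if "alpha" in values:
        kwargs["alpha"] = float(values["alpha"])
    if "seed" in values:
        kwargs["seed"] = int(values["seed"])
    unknown = set(values) - {"setting", "n", "scenario", "reps", "alpha", "seed"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**kwargs)
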