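"""Mismatch-distribution analysis for expansion dating.

The mismatch distribution is the histogram of pairwise nucleotide
differences in a sample.  Under a stationary population of scaled diversity
θ (=2Nu with u the per-gene mutation rate) it is geometric,
``F_i = θ^i/(1+θ)^{i+1}``; a sudden demographic expansion (θ0 -> θ1 at
mutational time τ = 2ut before present) or a spatial expansion into many
weakly connected demes (parameters τ, θ, M = 2Nm immigrants) each produce a
characteristic travelling wave whose position estimates τ.

Closed forms are derived from the coalescent density of a sampled pair:
conditional on coalescing at mutational time x the number of differences is
Poisson(x); the recent epoch contributes an incomplete-gamma term and the
ancestral epoch a Poisson-geometric convolution.  For the spatial model the
pair either coalesces within its deme, or is split by migration and only
coalesces in the pre-expansion ancestral deme (the infinite-island limit).
A Monte-Carlo expectation from the structured-coalescent simulator is
available as a cross-check.

Fitting minimizes the sum of squared deviations (SSD) between observed and
expected relative frequencies over the observed difference classes, by
coarse grid search refined with Nelder–Mead.  Goodness of fit (SSD and
Harpending's raggedness) is assessed by parametric bootstrap: datasets are
re-simulated from the fitted model, refit, and the observed statistics
compared with the bootstrap distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import poisson

from .coalescent_sim import (Deme, DemographicScenario, Event, Locus,
    simulate_dataset, simulate_infinite_island_dataset)
from .mlst_io import LocusAlignment
from .popgen_stats import pairwise_difference_matrix

__all__ = [
    "MismatchSpectrum",
    "MismatchFit",
    "observed_mismatch",
    "spectrum_from_diffs",
    "expected_mismatch",
    "raggedness",
    "fit_mismatch",
    "bootstrap_gof",
    "tau_to_generations",
    "generations_to_years",
]

MODELS = ("constant", "demographic_expansion", "spatial_expansion")


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass
class MismatchSpectrum:
    """Relative frequencies of pairwise-difference classes 0..d_max."""

    frequencies: np.ndarray
    counts: np.ndarray | None = None
    n_pairs: int = 0
    mean_differences: float = 0.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.frequencies.size and abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    @property
    def d_max(self) -> int:
        return len(self.frequencies) - 1


def spectrum_from_diffs(diffs: np.ndarray) -> MismatchSpectrum:
    """Spectrum from the upper triangle of a pairwise difference matrix."""
    n = diffs.shape[0]
    vals = diffs[np.triu_indices(n, 1)]
    counts = np.bincount(vals)
    freqs = counts / counts.sum()
    return MismatchSpectrum(freqs, counts, int(vals.size), float(vals.mean()))


def observed_mismatch(aln: LocusAlignment) -> MismatchSpectrum:
    if aln.n < 2:
        raise ValueError("need >= 2 sequences")
    return spectrum_from_diffs(pairwise_difference_matrix(aln))


def _matrix_spectrum(mat01: np.ndarray) -> MismatchSpectrum:
    """Spectrum straight from a 0/1 haplotype matrix."""
    m = mat01.astype(np.float32)
    d = m @ (1 - m).T
    diffs = np.rint(d + d.T).astype(np.int64)
    return spectrum_from_diffs(diffs)


# ---------------------------------------------------------------------------
# closed-form expectations
# ---------------------------------------------------------------------------

def _stationary(theta: float, j: np.ndarray) -> np.ndarray:
    """F_j = theta^j / (1+theta)^{j+1}, stable in log space; point mass at 0
    for theta = 0."""
    if theta == 0:
        out = np.zeros_like(j, dtype=float)
        out[j == 0] = 1.0
        return out
    logf = j * math.log(theta) - (j + 1) * math.log1p(theta)
    return np.exp(logf)


def _ancestral_kernel(tau: float, theta: float, d_max: int) -> np.ndarray:
    """G_j = sum_{i<=j} Pois(i; tau) * F_hat_{j-i}(theta): differences for a
    pair that survives the recent epoch and coalesces ancestrally."""
    j = np.arange(d_max + 1)
    if tau == 0:
        return _stationary(theta, j)
    pois = poisson.pmf(j, tau)
    statn = _stationary(theta, j)
    return np.convolve(pois, statn)[: d_max + 1]


def _recent_kernel(tau: float, theta: float, exit_rate: float, d_max: int) -> np.ndarray:
    """I_j = (1/theta) * int_0^tau e^{-exit_rate*x/theta} Pois(j;x) dx:
    pair coalescing in the recent epoch (exit_rate = 1, or 1+M with
    migration competing)."""
    if tau == 0 or theta == 0:
        return np.zeros(d_max + 1)
    j = np.arange(d_max + 1)
    b = exit_rate / theta + 1.0
    # int_0^tau x^j e^{-b x} dx / j! = gammainc(j+1, b*tau) / b^{j+1}
    logk = -math.log(theta) - (j + 1) * math.log(b)
    return gammainc(j + 1, b * tau) * np.exp(logk)


def expected_mismatch(model: str, params: dict, d_max: int) -> MismatchSpectrum:
    """Expected spectrum at classes 0..d_max (renormalized over the window).

    constant: {"theta"}; demographic_expansion: {"tau","theta0","theta1"};
    spatial_expansion: {"tau","theta","M"} (ancestral deme shares theta).
    """
    probs = expected_probs(model, params, d_max)
    total = probs.sum()
    if total <= 0:
        raise ValueError("degenerate expected spectrum")
    return MismatchSpectrum(probs / total)


def expected_probs(model: str, params: dict, d_max: int) -> np.ndarray:
    """Unnormalized class probabilities 0..d_max (sum to <= 1; the deficit
    is the mass beyond d_max)."""
    j = np.arange(d_max + 1)
    if model == "constant":
        theta = params["theta"]
        if theta < 0:
            raise ValueError("theta must be >= 0")
        return _stationary(theta, j)
    if model == "demographic_expansion":
        tau, th0, th1 = params["tau"], params["theta0"], params["theta1"]
        if min(tau, th0, th1) < 0:
            raise ValueError("parameters must be >= 0")
        if th1 == 0:
            return _stationary(th0, j) if tau == 0 else poisson.pmf(j, tau) * 0
        recent = _recent_kernel(tau, th1, 1.0, d_max)
        surv = math.exp(-tau / th1)
        return recent + surv * _ancestral_kernel(tau, th0, d_max)
    if model == "spatial_expansion":
        tau, theta, M = params["tau"], params["theta"], params["M"]
        if min(tau, theta, M) < 0:
            raise ValueError("parameters must be >= 0")
        if theta == 0:
            return poisson.pmf(j, tau)
        exit_rate = 1.0 + M
        recent = _recent_kernel(tau, theta, exit_rate, d_max)
        p_no_exit = math.exp(-exit_rate * tau / theta)
        p_split = (M / exit_rate) * (1.0 - p_no_exit)
        return recent + (p_no_exit + p_split) * _ancestral_kernel(tau, theta, d_max)
    raise ValueError(f"unknown model {model!r}")


def monte_carlo_expected(model: str, params: dict, d_max: int, n_reps: int = 10000,
                         seed: int | None = None, n_demes: int = 30) -> MismatchSpectrum:
    """Pairwise-sample Monte-Carlo expectation from the coalescent simulator;
    agrees with the closed form within MC error (cross-check path)."""
    rng = np.random.default_rng(seed)
    counts = np.zeros(d_max + 1)
    sc = _bootstrap_scenario(model, params, n=2, n_demes=n_demes)
    for r in range(n_reps):
        d = simulate_dataset(sc, seed=int(rng.integers(2 ** 31)))
        mat = d.concatenated()
        k = int((mat[0] != mat[1]).sum())
        if k <= d_max:
            counts[k] += 1
    return MismatchSpectrum(counts / counts.sum(), counts, n_reps)


# ---------------------------------------------------------------------------
# raggedness and fitting
# ---------------------------------------------------------------------------

def raggedness(spec: MismatchSpectrum) -> float:
    """Harpending's raggedness r = sum_{i=1..d+1} (x_i - x_{i-1})^2 with
    x_{d+1} = 0 (that closing term included by convention)."""
    x = np.concatenate([spec.frequencies, [0.0]])
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class MismatchFit:
    model: str
    params: dict
    ssd: float
    raggedness: float
    converged: bool
    p_ssd: float | None = None
    p_rag: float | None = None
    tau_ci: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)


def _ssd(spec: MismatchSpectrum, model: str, params: dict) -> float:
    exp = expected_probs(model, params, spec.d_max)
    return float(np.sum((spec.frequencies - exp) ** 2))


def _grid(model: str, spec: MismatchSpectrum):
    mean = max(spec.mean_differences, 0.1)
    taus = np.arange(0.0, max(50.0, 2 * mean) + 1)
    thetas = np.array([0.01, 0.1, 0.5, 1, 2, 5, 10, 30, 100, 1000, 1e4, 1e5])
    if model == "constant":
        for th in np.concatenate([thetas, [mean]]):
            yield {"theta": th}
    elif model == "demographic_expansion":
        for tau in taus:
            for th0 in [0.0, 0.1, 1.0, mean]:
                for th1 in [mean, 10, 100, 1000, 1e5]:
                    yield {"tau": tau, "theta0": th0, "theta1": th1}
    else:
        for tau in taus:
            for th in [0.1, 1.0, mean, 4 * mean]:
                for M in [0.1, 1.0, 10.0, 100.0]:
                    yield {"tau": tau, "theta": th, "M": M}


_PARAM_ORDER = {
    "constant": ["theta"],
    "demographic_expansion": ["tau", "theta0", "theta1"],
    "spatial_expansion": ["tau", "theta", "M"],
}

THETA1_MAX = 1e5


def fit_mismatch(spec: MismatchSpectrum, model: str,
                 init: dict | None = None) -> MismatchFit:
    """Least-squares fit: coarse grid then Nelder–Mead on sqrt-transformed
    parameters (keeps them >= 0); deterministic.

    ``init`` warm-starts the refinement from known-good parameters (used by
    the parametric bootstrap) and skips the global grid.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if spec.n_pairs and spec.n_pairs < 45:
        import warnings
        warnings.warn("mismatch fit from fewer than 10 sequences is unstable")
    names = _PARAM_ORDER[model]
    best, best_ssd = None, np.inf
    if init is not None:
        cands = [dict(init)]
        # small local grid around the warm start (tau is the key axis)
        for f in (0.0, 0.5, 1.5, 2.0):
            c = dict(init)
            c["tau"] = init.get("tau", spec.mean_differences) * f
            cands.append(c)
        mean = max(spec.mean_differences, 0.1)
        c = dict(init)
        c["tau"] = mean
        cands.append(c)
    else:
        cands = _grid(model, spec)
    for cand in cands:
        s = _ssd(spec, model, cand)
        if s < best_ssd:
            best, best_ssd = cand, s

    def unpack(u):
        params = {nm: float(v ** 2) for nm, v in zip(names, u)}
        if "theta1" in params:
            params["theta1"] = min(params["theta1"], THETA1_MAX)
        return params

    x0 = np.sqrt([best[nm] for nm in names])
    res = minimize(lambda u: _ssd(spec, model, unpack(u)), x0,
                   method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 4000})
    params, converged = best, False
    if res.fun <= best_ssd:
        params, converged = unpack(res.x), bool(res.success)
        best_ssd = float(res.fun)
    return MismatchFit(model, params, best_ssd, raggedness(spec), converged)


# ---------------------------------------------------------------------------
# parametric bootstrap
# ---------------------------------------------------------------------------

def _bootstrap_scenario(model: str, params: dict, n: int,
                        n_demes: int = 30, n_loci: int = 1) -> DemographicScenario:
    """Coalescent scenario matching fitted mismatch parameters.

    The total mutation rate over all loci is u = 1/2 so that mutational time
    equals generations (tau = 2ut = t) and theta = 2Nu = N; ``n_loci``
    matches the genealogical structure of multi-locus data.
    """
    L = 1000
    mu = 0.5 / (L * n_loci)
    loci = [Locus(f"boot{i}", L, mu) for i in range(n_loci)]
    eps = 1e-6
    if model == "constant":
        theta = max(params["theta"], eps)
        return DemographicScenario([Deme("A", theta)], {"A": n}, loci,
                                   label="boot_constant")
    if model == "demographic_expansion":
        th0 = max(params["theta0"], eps)
        th1 = max(params["theta1"], eps)
        tau = max(params["tau"], eps)
        events = [Event(time=tau, kind="size", deme="A", value=th0)]
        return DemographicScenario([Deme("A", th1)], {"A": n}, loci,
                                   events=events, label="boot_demexp")
    if model == "spatial_expansion":
        theta = max(params["theta"], eps)
        tau = max(params["tau"], eps)
        M = max(params["M"], 0.0)
        m = M / (2.0 * theta)  # per-lineage per-generation
        demes = [Deme(f"D{i}", theta) for i in range(n_demes)]
        mig = np.full((n_demes, n_demes), m / (n_demes - 1))
        np.fill_diagonal(mig, 0.0)
        events = [Event(time=tau, kind="merge", deme=f"D{i}", dest="D0")
                  for i in range(1, n_demes)]
        return DemographicScenario(demes, {"D0": n}, loci, events=events,
                                   migration=mig, label="boot_spatial")
    raise ValueError(model)


def bootstrap_gof(spec: MismatchSpectrum, fit: MismatchFit, n: int,
                  B: int = 1000, seed: int | None = None,
                  n_demes: int = 30, n_loci: int = 1,
                  warm_start: bool = True) -> MismatchFit:
    """Parametric bootstrap of SSD/raggedness and the 95% CI of τ.

    Simulates B coalescent datasets of n sequences at the fitted parameters,
    refits each, and reports p_ssd = P(SSD_sim >= SSD_obs), p_rag
    analogous, and the 2.5/97.5 percentiles of refitted τ.  Returns a new
    MismatchFit carrying the bootstrap results.
    """
    if B < 50:
        import warnings
        warnings.warn("fewer than 50 bootstrap replicates is unreliable")
    rng = np.random.default_rng(seed)
    eps = 1e-6
    if fit.model == "spatial_expansion":
        # exact infinite-island sampler (the model the closed form assumes)
        L = 1000
        island_loci = [Locus(f"boot{i}", L, 0.5 / (L * n_loci))
                       for i in range(n_loci)]
        theta = max(fit.params["theta"], eps)
        tau = max(fit.params["tau"], eps)
        M = max(fit.params["M"], 0.0)

        def draw(seed_):
            return simulate_infinite_island_dataset(n, theta, M, tau,
                                                    island_loci, seed=seed_)
    else:
        sc = _bootstrap_scenario(fit.model, fit.params, n, n_demes=n_demes,
                                 n_loci=n_loci)

        def draw(seed_):
            return simulate_dataset(sc, seed=seed_)

    ssd_sims, rag_sims, taus = [], [], []
    for b in range(B):
        sim = draw(int(rng.integers(2 ** 31)))
        sim_spec = _matrix_spectrum(sim.concatenated())
        refit = fit_mismatch(sim_spec, fit.model,
                             init=fit.params if warm_start else None)
        ssd_sims.append(_ssd(sim_spec, fit.model, refit.params))
        rag_sims.append(raggedness(sim_spec))
        taus.append(refit.params.get("tau", 0.0))
    p_ssd = float(np.mean(np.asarray(ssd_sims) >= fit.ssd))
    p_rag = float(np.mean(np.asarray(rag_sims) >= fit.raggedness))
    tau_lo, tau_hi = np.percentile(taus, [2.5, 97.5])
    tau_hat = fit.params.get("tau", 0.0)
    ci = (float(min(tau_lo, tau_hat)), float(max(tau_hi, tau_hat)))
    return MismatchFit(fit.model, fit.params, fit.ssd, fit.raggedness,
                       fit.converged, p_ssd=p_ssd, p_rag=p_rag, tau_ci=ci,
                       meta={"tau_boot": taus,
                             "raggedness_convention": "x_{d+1}=0, sum from i=1"})


# ---------------------------------------------------------------------------
# time conversions
# ---------------------------------------------------------------------------

def tau_to_generations(tau: float, mu_per_site: float, L: float) -> float:
    """t = tau / (2 * mu_per_site * L); tau=0 maps to t=0."""
    if mu_per_site <= 0 or L <= 0:
        raise ValueError("mu and L must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    return tau / (2.0 * mu_per_site * L)


def generations_to_years(g: float, gen_per_year: float = 30.0) -> float:
    if gen_per_year <= 0:
        raise ValueError("gen_per_year must be > 0")
    if g < 0:
        raise ValueError("g must be >= 0")
    return g / gen_per_year
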