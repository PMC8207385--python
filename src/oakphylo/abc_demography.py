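"""Coalescent simulation of microsatellites and ABC scenario inference.

Three single-population demographic scenarios are compared: (1) constant
effective size, (2) a single stepwise expansion, and (3) a bottleneck
followed by a recent expansion.  Loci evolve under a strict stepwise
mutation model (every mutation shifts the allele by +/-1 motif unit).
Scenario choice uses rejection sampling (direct frequencies among the
closest simulations) and multinomial logistic regression on standardized
summary statistics; parameters are estimated with a local-linear
regression adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ScenarioSpec",
    "Priors",
    "SummaryStatVector",
    "STAT_NAMES",
    "simulate_coalescent_msat",
    "summary_stats",
    "generate_reference_table",
    "abc_model_choice",
    "abc_parameter_estimation",
    "scenario_confidence",
    "AbcResult",
]

ANCESTRAL_SIZE = 100  # arbitrary origin in motif units; all stats are shift invariant

STAT_NAMES = [
    "mean_num_alleles",
    "mean_het",
    "mean_size_var",
    "mean_gw_m",
    "var_num_alleles",
    "var_het",
    "var_size_var",
    "var_gw_m",
]


# ----------------------------------------------------------------------
# Scenarios and priors
# ----------------------------------------------------------------------

@dataclass
class Priors:
    """Uniform/log-uniform prior ranges.

    Surrogate defaults: effective sizes log-uniform on [1e2, 1e6], event
    times uniform on [10, 10000] generations, per-locus mutation rate
    log-uniform on [1e-4, 1e-3].
    """

    ne_range: tuple[float, float] = (1e2, 1e6)
    t_range: tuple[float, float] = (10.0, 10_000.0)
    mu_range: tuple[float, float] = (1e-4, 1e-3)

    def validate(self) -> None:
        for name, (lo, hi) in (
            ("ne_range", self.ne_range),
            ("t_range", self.t_range),
            ("mu_range", self.mu_range),
        ):
            if not (0 < lo < hi):
                raise ValueError(f"invalid prior {name}: ({lo}, {hi})")

    def draw_ne(self, rng: np.random.Generator) -> float:
        lo, hi = self.ne_range
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    def draw_t(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(*self.t_range))

    def draw_mu(self, rng: np.random.Generator, size: int) -> np.ndarray:
        lo, hi = self.mu_range
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


@dataclass
class ScenarioSpec:
    """Piecewise-constant demography, epochs ordered backward in time.

    ``epochs`` is a list of ``(start_time_generations, Ne)``; the first
    entry must start at 0 (the present).
    """

    scenario_id: int
    epochs: list[tuple[float, float]]

    def __post_init__(self) -> None:
        times = [t for t, _ in self.epochs]
        if times[0] != 0:
            raise ValueError("first epoch must start at time 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("epoch start times must strictly increase backward")
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("Ne must be positive")

    @property
    def param_dict(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for i, (t, ne) in enumerate(self.epochs):
            out[f"N{i + 1}"] = ne
            if i > 0:
                out[f"t{i}"] = t
        return out


PARAM_COLUMNS = ["N1", "N2", "N3", "t1", "t2"]


def draw_scenario(scenario_id: int, priors: Priors, rng: np.random.Generator) -> ScenarioSpec:
    """Draw scenario parameters from the priors (rejection on order constraints)."""
    if scenario_id == 1:
        return ScenarioSpec(1, [(0.0, priors.draw_ne(rng))])
    if scenario_id == 2:
        # forward-time expansion: ancestral size smaller than current
        for _ in range(10_000):
            n_cur, n_anc = priors.draw_ne(rng), priors.draw_ne(rng)
            if n_anc < n_cur:
                return ScenarioSpec(2, [(0.0, n_cur), (priors.draw_t(rng), n_anc)])
        raise RuntimeError("prior rejection failed for scenario 2")
    if scenario_id == 3:
        # bottleneck (small Nb) between ancestral and current sizes
        for _ in range(10_000):
            n_cur, n_bot, n_anc = (priors.draw_ne(rng) for _ in range(3))
            t1, t2 = sorted((priors.draw_t(rng), priors.draw_t(rng)))
            if n_bot < n_cur and n_bot < n_anc and t1 < t2:
                return ScenarioSpec(3, [(0.0, n_cur), (t1, n_bot), (t2, n_anc)])
        raise RuntimeError("prior rejection failed for scenario 3")
    raise ValueError(f"unknown scenario id {scenario_id}")


# ----------------------------------------------------------------------
# Coalescent SMM simulator (numba core)
# ----------------------------------------------------------------------

@njit(cache=True)
def _sim_tree(n, epoch_t, epoch_n):
    """Kingman coalescent with piecewise-constant Ne.

    Returns (parent, time) arrays over 2n-1 nodes; tips are 0..n-1, the
    root is 2n-2.  Times are in generations.
    """
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=np.int64)
    times = np.zeros(total)
    active = np.empty(n, dtype=np.int64)
    for i in range(n):
        active[i] = i
    k = n
    t = 0.0
    ep = 0
    n_ep = epoch_t.shape[0]
    next_id = n
    while k > 1:
        ne = epoch_n[ep]
        rate = k * (k - 1) / (4.0 * ne)  # diploid-scaled: 2N gene copies
        w = np.random.exponential(1.0 / rate)
        if ep + 1 < n_ep and t + w > epoch_t[ep + 1]:
            t = epoch_t[ep + 1]
            ep += 1
            continue
        t += w
        i = np.random.randint(k)
        j = np.random.randint(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = next_id
        parent[b] = next_id
        times[next_id] = t
        # swap-remove the two children, push the parent
        hi, lo = (i, j) if i > j else (j, i)
        active[hi] = active[k - 1]
        active[lo] = active[k - 2]
        active[k - 2] = next_id
        next_id += 1
        k -= 1
    return parent, times


@njit(cache=True)
def _drop_mutations(parent, times, n, mu, ancestral):
    """Propagate SMM mutations from root to tips; returns tip allele sizes."""
    total = parent.shape[0]
    value = np.empty(total, dtype=np.int64)
    value[total - 1] = ancestral
    for v in range(total - 2, -1, -1):
        bl = times[parent[v]] - times[v]
        m = np.random.poisson(mu * bl)
        step = 0
        for _ in range(m):
            if np.random.random() < 0.5:
                step += 1
            else:
                step -= 1
        value[v] = value[parent[v]] + step
    return value[:n]


@njit(cache=True)
def _sim_sample(n, epoch_t, epoch_n, mus, linked, seed):
    """Simulate ``len(mus)`` loci; linked loci share one genealogy."""
    np.random.seed(seed)
    n_loci = mus.shape[0]
    out = np.empty((n_loci, n), dtype=np.int64)
    if linked:
        parent, times = _sim_tree(n, epoch_t, epoch_n)
        for l in range(n_loci):
            out[l] = _drop_mutations(parent, times, n, mus[l], ANCESTRAL_SIZE)
    else:
        for l in range(n_loci):
            parent, times = _sim_tree(n, epoch_t, epoch_n)
            out[l] = _drop_mutations(parent, times, n, mus[l], ANCESTRAL_SIZE)
    return out


@njit(cache=True)
def _locus_stats(alleles):
    """(num_alleles, unbiased_het, size_variance, GW M) for one locus."""
    n = alleles.shape[0]
    srt = np.sort(alleles)
    k = 1
    for i in range(1, n):
        if srt[i] != srt[i - 1]:
            k += 1
    # unbiased expected heterozygosity
    sum_p2 = 0.0
    run = 1
    for i in range(1, n + 1):
        if i < n and srt[i] == srt[i - 1]:
            run += 1
        else:
            sum_p2 += (run / n) ** 2
            run = 1
    het = n / (n - 1.0) * (1.0 - sum_p2)
    mean = 0.0
    for i in range(n):
        mean += srt[i]
    mean /= n
    var = 0.0
    for i in range(n):
        var += (srt[i] - mean) ** 2
    var /= n
    rng_steps = srt[n - 1] - srt[0]
    m = k / (rng_steps + 1.0)
    return k, het, var, m


@njit(cache=True)
def _sample_stats(alleles):
    """Mean and variance across loci of the four per-locus statistics."""
    n_loci = alleles.shape[0]
    per = np.empty((n_loci, 4))
    for l in range(n_loci):
        a, h, v, m = _locus_stats(alleles[l])
        per[l, 0] = a
        per[l, 1] = h
        per[l, 2] = v
        per[l, 3] = m
    out = np.empty(8)
    for s in range(4):
        mu = 0.0
        for l in range(n_loci):
            mu += per[l, s]
        mu /= n_loci
        va = 0.0
        for l in range(n_loci):
            va += (per[l, s] - mu) ** 2
        va /= n_loci
        out[s] = mu
        out[4 + s] = va
    return out


def simulate_coalescent_msat(
    n_copies: int,
    scenario: ScenarioSpec,
    mu: float | np.ndarray,
    n_loci: int = 10,
    linked: bool = False,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate a microsatellite sample; returns (n_loci, n_copies) allele sizes.

    Waiting times follow the Kingman coalescent with ``2 * Ne`` gene copies
    per epoch; mutations are Poisson along branches with per-generation rate
    ``mu`` and strict +/-1 steps from the ancestral size.
    """
    if n_copies < 2:
        raise ValueError("need >= 2 gene copies")
    epoch_t = np.array([t for t, _ in scenario.epochs], dtype=float)
    epoch_n = np.array([ne for _, ne in scenario.epochs], dtype=float)
    if np.any(np.diff(epoch_t) <= 0):
        raise ValueError("zero-length epoch")
    mus = np.full(n_loci, mu, dtype=float) if np.isscalar(mu) else np.asarray(mu, dtype=float)
    if mus.shape != (n_loci,):
        raise ValueError("mu must be scalar or length n_loci")
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
    return _sim_sample(n_copies, epoch_t, epoch_n, mus, linked, seed)


@dataclass
class SummaryStatVector:
    values: np.ndarray  # length 8, ordered as STAT_NAMES

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=STAT_NAMES)


def summary_stats(sample: np.ndarray) -> SummaryStatVector:
    """DIYABC-style one-population statistics.

    Per locus: number of alleles, unbiased expected heterozygosity,
    allele-size variance (population form), and Garza-Williamson
    ``M = A / (range + 1)``; the vector holds the mean and variance of each
    across loci.
    """
    sample = np.asarray(sample, dtype=np.int64)
    if sample.ndim != 2 or sample.shape[1] < 2:
        raise ValueError("sample must be (n_loci, n_copies>=2)")
    return SummaryStatVector(_sample_stats(sample))


# ----------------------------------------------------------------------
# Reference table
# ----------------------------------------------------------------------

def generate_reference_table(
    n_sims: int,
    n_copies: int,
    n_loci: int = 10,
    scenarios: tuple[int, ...] = (1, 2, 3),
    priors: Priors | None = None,
    seed: int | None = None,
    linked: bool = False,
) -> pd.DataFrame:
    """Simulate ``n_sims`` datasets with equiprobable scenarios.

    Returns a DataFrame with columns ``scenario``, the drawn parameters
    (NaN where a scenario lacks a parameter) and the eight summary
    statistics.  Deterministic given ``seed``.
    """
    priors = priors or Priors()
    priors.validate()
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    rows = np.empty((n_sims, 1 + len(PARAM_COLUMNS) + 8))
    rows[:] = np.nan
    for i in range(n_sims):
        sid = int(rng.choice(scenarios))
        spec = draw_scenario(sid, priors, rng)
        mus = priors.draw_mu(rng, n_loci)
        sample = simulate_coalescent_msat(
            n_copies, spec, mus, n_loci, linked, seed=int(rng.integers(2**31))
        )
        rows[i, 0] = sid
        for k, name in enumerate(PARAM_COLUMNS):
            rows[i, 1 + k] = spec.param_dict.get(name, np.nan)
        rows[i, 1 + len(PARAM_COLUMNS):] = _sample_stats(sample)
    return pd.DataFrame(rows, columns=["scenario"] + PARAM_COLUMNS + STAT_NAMES)


# ----------------------------------------------------------------------
# Model choice
# ----------------------------------------------------------------------

@dataclass
class AbcResult:
    direct_probabilities: dict[int, float]
    direct_ci: dict[int, tuple[float, float]]
    logistic_probabilities: dict[int, float]
    logistic_ci: dict[int, tuple[float, float]]
    best_scenario: int
    n_closest_direct: int
    tolerance: float
    posterior_quantiles: pd.DataFrame | None = None
    error_report: dict | None = None


def _standardize(stats: np.ndarray, ref_stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scale = ref_stats.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return ref_stats / scale, stats / scale


def abc_model_choice(
    ref_table: pd.DataFrame,
    observed_stats: np.ndarray,
    tolerance: float = 0.01,
    n_closest_direct: int = 500,
    n_boot: int = 500,
    seed: int | None = None,
) -> AbcResult:
    """Scenario posterior probabilities by rejection and logistic regression.

    Distances are Euclidean on SD-standardized statistics.  The direct
    estimate is the scenario frequency among the ``n_closest_direct``
    nearest rows; the logistic estimate fits a multinomial regression of
    scenario on statistics over the closest ``tolerance`` fraction and is
    evaluated at the observed vector.  CIs (0.05-0.95) come from a
    nonparametric bootstrap over the retained rows.
    """
    if len(ref_table) == 0:
        raise ValueError("empty reference table")
    scen = ref_table["scenario"].to_numpy().astype(int)
    scenarios = np.unique(scen)
    stats = ref_table[STAT_NAMES].to_numpy()
    obs = np.asarray(observed_stats, dtype=float).ravel()
    z, z_obs = _standardize(obs, stats)
    dist = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
    order = np.argsort(dist, kind="stable")

    n_keep = max(int(np.ceil(tolerance * len(ref_table))), len(scenarios) * 10)
    if n_keep > len(ref_table):
        raise ValueError("reference table too small for the requested tolerance")
    if n_closest_direct > len(ref_table):
        raise ValueError("n_closest_direct exceeds the table size")

    rng = np.random.default_rng(seed)
    near = scen[order[:n_closest_direct]]
    direct = {int(s): float(np.mean(near == s)) for s in scenarios}
    direct_ci: dict[int, tuple[float, float]] = {}
    if n_boot > 0:
        boot = rng.choice(near, size=(n_boot, near.size), replace=True)
        for s in scenarios:
            fr = (boot == s).mean(axis=1)
            direct_ci[int(s)] = tuple(float(q) for q in np.quantile(fr, [0.05, 0.95]))

    kept = order[:n_keep]
    zk, yk = z[kept], scen[kept]
    logistic: dict[int, float] = {}
    logistic_ci: dict[int, tuple[float, float]] = {}
    present = np.unique(yk)
    if present.size == 1:
        for s in scenarios:
            logistic[int(s)] = 1.0 if s == present[0] else 0.0
            logistic_ci[int(s)] = (logistic[int(s)], logistic[int(s)])
    else:
        def fit_predict(zz: np.ndarray, yy: np.ndarray) -> dict[int, float]:
            clf = LogisticRegression(max_iter=2_000)
            clf.fit(zz, yy)
            proba = clf.predict_proba(z_obs.reshape(1, -1))[0]
            out = {int(s): 0.0 for s in scenarios}
            for cls, p in zip(clf.classes_, proba):
                out[int(cls)] = float(p)
            return out

        logistic = fit_predict(zk, yk)
        if n_boot > 0:
            samples = {int(s): [] for s in scenarios}
            for _ in range(n_boot):
                idx = rng.integers(0, n_keep, size=n_keep)
                if np.unique(yk[idx]).size < 2:
                    continue
                pb = fit_predict(zk[idx], yk[idx])
                for s in scenarios:
                    samples[int(s)].append(pb[int(s)])
            for s in scenarios:
                arr = np.array(samples[int(s)]) if samples[int(s)] else np.array([logistic[int(s)]])
                logistic_ci[int(s)] = tuple(float(q) for q in np.quantile(arr, [0.05, 0.95]))

    best = int(max(direct, key=lambda s: direct[s]))
    return AbcResult(direct, direct_ci, logistic, logistic_ci, best, n_closest_direct, tolerance)


# ----------------------------------------------------------------------
# Parameter estimation
# ----------------------------------------------------------------------

def abc_parameter_estimation(
    ref_table: pd.DataFrame,
    observed_stats: np.ndarray,
    scenario: int,
    tolerance: float = 0.01,
    generation_time: float = 100.0,
    adjust: bool = True,
) -> pd.DataFrame:
    """Local-linear regression-adjusted posterior quantiles for one scenario.

    Retains the closest ``tolerance`` fraction of the scenario's rows,
    regresses each parameter on the standardized statistics with
    Epanechnikov weights, shifts the retained draws to the observed point,
    and reports the weighted mean and the 0.05/0.95 quantiles.  Time
    parameters are also reported in years (``generation_time`` years per
    generation).  ``adjust=False`` skips the regression step (plain
    rejection posterior; at tolerance 1.0 this reproduces the prior).
    """
    sub = ref_table[ref_table["scenario"] == scenario]
    stats = sub[STAT_NAMES].to_numpy()
    obs = np.asarray(observed_stats, dtype=float).ravel()
    z, z_obs = _standardize(obs, stats)
    dist = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
    n_keep = max(int(np.ceil(tolerance * len(sub))), 50)
    if len(sub) < 1_000:
        raise ValueError("need >= 1000 rows for the chosen scenario")
    order = np.argsort(dist, kind="stable")[:n_keep]
    d = dist[order]
    d_max = d.max() if d.max() > 0 else 1.0
    if adjust:
        w = np.maximum(1.0 - (d / d_max) ** 2, 1e-8)  # Epanechnikov (unnormalized)
    else:
        w = np.ones_like(d)  # plain rejection: retained draws weighted equally
    X = z[order] - z_obs  # centered at the observed point

    params = [c for c in PARAM_COLUMNS if sub[c].notna().any()]
    records = []
    for p in params:
        y = sub[p].to_numpy()[order]
        if adjust:
            A = np.column_stack([np.ones(len(order)), X])
            W = np.sqrt(w)
            try:
                beta, *_ = np.linalg.lstsq(A * W[:, None], y * W, rcond=None)
                adjusted = y - X @ beta[1:]
            except np.linalg.LinAlgError:
                adjusted = y  # singular design: plain rejection posterior
        else:
            adjusted = y
        mean = float(np.average(adjusted, weights=w))
        q05, q95 = _weighted_quantiles(adjusted, w, (0.05, 0.95))
        rec = {"parameter": p, "mean": mean, "q05": q05, "q95": q95}
        if p.startswith("t"):
            rec.update(
                mean_years=mean * generation_time,
                q05_years=q05 * generation_time,
                q95_years=q95 * generation_time,
            )
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("parameter")


def _weighted_quantiles(values: np.ndarray, weights: np.ndarray, qs) -> tuple[float, ...]:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return tuple(float(np.interp(q, cw, v)) for q in qs)


# ----------------------------------------------------------------------
# Scenario-confidence error rates
# ----------------------------------------------------------------------

def _direct_assign(z_pods: np.ndarray, z_ref: np.ndarray, scen: np.ndarray,
                   n_closest: int, exclude_self: bool) -> np.ndarray:
    """Winning scenario for each pod by the direct method (chunked kNN)."""
    winners = np.empty(z_pods.shape[0], dtype=int)
    scenarios = np.unique(scen)
    chunk = 256
    for start in range(0, z_pods.shape[0], chunk):
        zp = z_pods[start:start + chunk]
        d = np.sqrt(((z_ref[None, :, :] - zp[:, None, :]) ** 2).sum(axis=2))
        k = n_closest + (1 if exclude_self else 0)
        idx = np.argpartition(d, k - 1, axis=1)[:, :k]
        for r in range(zp.shape[0]):
            cols = idx[r]
            if exclude_self:
                cols = cols[np.argsort(d[r, cols])][1:]  # drop the pod itself
            votes = scen[cols]
            counts = [(votes == s).sum() for s in scenarios]
            winners[start + r] = scenarios[int(np.argmax(counts))]
    return winners


def scenario_confidence(
    ref_table: pd.DataFrame,
    observed_stats: np.ndarray | None = None,
    focal_scenario: int = 3,
    n_pods: int = 500,
    n_random_pods: int = 1_000,
    n_closest: int = 500,
    seed: int | None = None,
) -> dict:
    """Posterior error rate and type I/II error rates by pseudo-observed data.

    (i) the ``n_pods`` rows closest to the observed statistics act as pods
    and the posterior error rate is the fraction misassigned (each pod is
    excluded from its own reference); (ii) type I: fraction of
    ``n_random_pods`` focal-scenario pods where the focal scenario loses;
    (iii) type II: fraction of other-scenario pods where it wins.
    """
    if n_pods > len(ref_table) or n_random_pods > len(ref_table):
        raise ValueError("more pods requested than reference rows")
    rng = np.random.default_rng(seed)
    scen = ref_table["scenario"].to_numpy().astype(int)
    stats = ref_table[STAT_NAMES].to_numpy()
    scale = stats.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    z = stats / scale

    report: dict = {}
    if observed_stats is not None:
        z_obs = np.asarray(observed_stats, dtype=float).ravel() / scale
        d_obs = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
        pod_idx = np.argsort(d_obs, kind="stable")[:n_pods]
        winners = _direct_assign(z[pod_idx], z, scen, n_closest, exclude_self=True)
        report["posterior_error_rate"] = float(np.mean(winners != scen[pod_idx]))

    # type I: focal-scenario pods
    focal_rows = np.flatnonzero(scen == focal_scenario)
    pick = rng.choice(focal_rows, size=min(n_random_pods, focal_rows.size), replace=False)
    winners = _direct_assign(z[pick], z, scen, n_closest, exclude_self=True)
    report["type_1"] = float(np.mean(winners != focal_scenario))

    # type II: per other scenario, fraction where the focal scenario wins
    type2: dict[int, float] = {}
    for s in np.unique(scen):
        if s == focal_scenario:
            continue
        rows = np.flatnonzero(scen == s)
        pick = rng.choice(rows, size=min(n_random_pods, rows.size), replace=False)
        winners = _direct_assign(z[pick], z, scen, n_closest, exclude_self=True)
        type2[int(s)] = float(np.mean(winners == focal_scenario))
    report["type_2"] = type2
    report["type_2_overall"] = float(np.mean(list(type2.values()))) if type2 else float("nan")
    report["focal_scenario"] = focal_scenario
    return report
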