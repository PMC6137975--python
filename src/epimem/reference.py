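"""Reference ("base level") methylation means and bimodal mixture fits.

The reference mean for a chromosome/condition pair is the arithmetic mean
of a random probe subset's condition-averaged signals. A two-component
Gaussian mixture fitted by EM characterizes the bimodal signal
distribution; a mixture-weighted mean is available as an alternative
reference estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ReferenceError(ValueError):
    pass


class DegenerateFitError(RuntimeError):
    """A mixture component's variance collapsed; the fit is refused."""


@dataclass(frozen=True)
class MixtureFit:
    """Two-component Gaussian mixture, components in ascending-mean order."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_observations: int = 0
    log_likelihood_single: float = float("nan")
    loglik_trace: tuple[float, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(s <= 0 for s in self.sds):
            raise ValueError("mixture sds must be > 0")
        if self.means[0] > self.means[1]:
            raise ValueError("components must be ordered by mean")

    @property
    def mixture_mean(self) -> float:
        return self.weights[0] * self.means[0] + self.weights[1] * self.means[1]

    @property
    def effectively_unimodal(self) -> bool:
        """True when the two components add nothing over one Gaussian.

        EM on genuinely unimodal data converges to overlapping components
        whose means need not coincide, so the flag also fires when the
        per-observation likelihood gain over the single-Gaussian fit is
        negligible (< 0.01 nats).
        """
        if abs(self.means[1] - self.means[0]) < 0.2:
            return True
        if self.n_observations and math.isfinite(self.log_likelihood_single):
            gain = (self.log_likelihood - self.log_likelihood_single) / self.n_observations
            return gain < 0.01
        return False


@dataclass(frozen=True)
class ReferenceModel:
    chromosome: str
    condition: str
    reference_mean: float
    subset_probe_ids: tuple[str, ...]
    fraction: float
    seed: int
    mixture: MixtureFit | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.reference_mean):
            raise ReferenceError("reference mean must be finite")


def _subset_size(n: int, fraction: float) -> int:
    """Round half away from zero, clamped to [1, n-1]."""
    k = math.floor(fraction * n + 0.5)
    return min(max(k, 1), n - 1)


def split_probes(probes: pd.DataFrame, fraction: float, seed: int,
                 min_per_chromosome: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition probes into (reference subset, analysis subset).

    Sampling is stratified within each chromosome, without replacement,
    deterministic given the seed. Chromosomes are visited in sorted order
    so the draw sequence does not depend on input row order.
    """
    if not 0.0 < fraction < 1.0:
        raise ReferenceError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    ref_idx: list = []
    for chrom in sorted(probes["chrom"].unique()):
        idx = probes.index[probes["chrom"] == chrom]
        if len(idx) < min_per_chromosome:
            raise ReferenceError(
                f"chromosome {chrom} has only {len(idx)} probes (< {min_per_chromosome})")
        k = _subset_size(len(idx), fraction)
        ref_idx.extend(rng.choice(idx.to_numpy(), size=k, replace=False))
    ref_mask = probes.index.isin(ref_idx)
    return probes[ref_mask], probes[~ref_mask]


def estimate_reference_mean(signals) -> float:
    """Arithmetic mean of the reference subset's per-probe signals.

    Missing values are excluded; at least 10 finite values are required.
    """
    arr = np.asarray(signals, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ReferenceError("all reference signals are missing")
    if arr.size < 10:
        raise ReferenceError(f"need >= 10 finite reference signals, got {arr.size}")
    return float(arr.mean())


def _em_once(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray, lam: np.ndarray,
             tol: float, max_iter: int, min_var: float):
    """Run EM to convergence from one starting point.

    Returns (lam, mu, sigma, trace, converged) or raises DegenerateFitError.
    """
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step in log space for stability
        log_dens = np.stack([
            np.log(lam[0]) + stats.norm.logpdf(x, mu[0], sigma[0]),
            np.log(lam[1]) + stats.norm.logpdf(x, mu[1], sigma[1]),
        ])
        log_norm = np.logaddexp(log_dens[0], log_dens[1])
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_dens - log_norm)
        # M step
        nk = resp.sum(axis=1)
        lam = nk / x.size
        mu = resp @ x / nk
        var = np.array([resp[j] @ (x - mu[j]) ** 2 / nk[j] for j in range(2)])
        if np.any(var < min_var):
            raise DegenerateFitError("component variance collapsed below threshold")
        sigma = np.sqrt(var)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
    return lam, mu, sigma, trace, converged


def fit_bimodal_mixture(signals, tol: float = 1e-8, max_iter: int = 500,
                        n_restarts: int = 5, seed: int = 0,
                        min_var: float = 1e-6) -> MixtureFit:
    """Fit a two-component Gaussian mixture by EM.

    The first start assigns initial means to the 10th/90th percentiles;
    the remaining restarts jitter that start. The best-likelihood
    non-degenerate solution is returned with components ordered by
    ascending mean. Raises :class:`DegenerateFitError` if every restart
    collapses a component variance below ``min_var``.
    """
    x = np.asarray(signals, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise ReferenceError(f"need >= 50 finite values for a mixture fit, got {x.size}")
    q10, q90 = np.quantile(x, [0.1, 0.9])
    spread = max(float(np.std(x)), 1e-3)
    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        mu = np.array([q10, q90], dtype=float)
        if restart > 0:
            mu = mu + rng.normal(0.0, 0.25 * spread, size=2)
            mu.sort()
        sigma = np.full(2, max(0.5 * spread, 1e-3))
        lam = np.array([0.5, 0.5])
        try:
            lam, mu, sigma, trace, converged = _em_once(
                x, mu, sigma, lam, tol, max_iter, min_var)
        except DegenerateFitError:
            continue
        ll = trace[-1]
        if best is None or ll > best[0]:
            best = (ll, lam, mu, sigma, trace, converged)
    if best is None:
        raise DegenerateFitError("all EM restarts produced degenerate fits")
    ll, lam, mu, sigma, trace, converged = best
    order = np.argsort(mu)
    lam = lam / lam.sum()  # counter accumulated float drift
    return MixtureFit(
        weights=(float(lam[order[0]]), float(lam[order[1]])),
        means=(float(mu[order[0]]), float(mu[order[1]])),
        sds=(float(sigma[order[0]]), float(sigma[order[1]])),
        log_likelihood=float(ll),
        n_iterations=len(trace),
        converged=bool(converged),
        n_observations=int(x.size),
        log_likelihood_single=single_gaussian_loglik(x),
        loglik_trace=tuple(trace),
    )


def single_gaussian_loglik(signals) -> float:
    """Log-likelihood of the one-component (plain Gaussian MLE) fit."""
    x = np.asarray(signals, dtype=float)
    x = x[np.isfinite(x)]
    return float(stats.norm.logpdf(x, x.mean(), max(x.std(), 1e-12)).sum())


def build_reference_models(ref_probes: pd.DataFrame, condition_means: pd.DataFrame,
                           fraction: float, seed: int,
                           fit_mixture: bool = True,
                           use_mixture_mean: bool = False) -> dict[tuple[str, str], ReferenceModel]:
    """Per (chromosome, condition) reference models from the reference subset.

    ``condition_means`` is indexed by probe_id with one column per
    condition (replicates already averaged). With ``use_mixture_mean`` the
    reference mean is the mixture-weighted mean instead of the subset mean.
    """
    models: dict[tuple[str, str], ReferenceModel] = {}
    for chrom in sorted(ref_probes["chrom"].unique()):
        pids = ref_probes.loc[ref_probes["chrom"] == chrom, "probe_id"]
        sub = condition_means.loc[pids]
        for condition in condition_means.columns:
            values = sub[condition].to_numpy()
            mu_ref = estimate_reference_mean(values)
            mixture = None
            if fit_mixture:
                try:
                    mixture = fit_bimodal_mixture(values, seed=seed)
                except (ReferenceError, DegenerateFitError):
                    mixture = None
            if use_mixture_mean:
                if mixture is None:
                    raise ReferenceError(
                        f"mixture-mean reference requested but no fit for {chrom}/{condition}")
                mu_ref = mixture.mixture_mean
            models[(chrom, condition)] = ReferenceModel(
                chromosome=chrom, condition=condition, reference_mean=mu_ref,
                subset_probe_ids=tuple(pids), fraction=fraction, seed=seed,
                mixture=mixture)
    return models


def reference_table(models: dict[tuple[str, str], ReferenceModel]) -> pd.DataFrame:
    rows = []
    for (chrom, condition), m in sorted(models.items()):
        row = {"chromosome": chrom, "condition": condition,
               "n_subset": len(m.subset_probe_ids), "mu_ref": m.reference_mean,
               "fraction": m.fraction, "seed": m.seed}
        if m.mixture is not None:
            row.update({
                "lambda1": m.mixture.weights[0], "mu1": m.mixture.means[0],
                "sigma1": m.mixture.sds[0], "lambda2": m.mixture.weights[1],
                "mu2": m.mixture.means[1], "sigma2": m.mixture.sds[1],
                "loglik": m.mixture.log_likelihood, "converged": m.mixture.converged,
            })
        rows.append(row)
    return pd.DataFrame(rows)
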