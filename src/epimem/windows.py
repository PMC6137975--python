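"""Window construction, Wilcoxon tests against the reference mean, FDR
adjustment, and ternary methylation scores.

Windows tile each chromosome as ``[0, w), [w, 2w), ...`` with the final
window truncated at the chromosome end; probes are assigned to windows by
midpoint containment under half-open arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class WindowError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicWindow:
    window_id: str
    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


@dataclass
class WindowResult:
    window_id: str
    condition: str
    mean_signal: float
    p_value: float
    mu_ref: float = float("nan")
    q_value: float = float("nan")
    score: int = 0
    testable: bool = True


def window_id_for(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def tile_chromosome(chrom: str, length: int, window_size: int) -> list[tuple[str, int, int]]:
    """Window intervals [(id, start, end), ...] covering [0, length) exactly."""
    out = []
    for start in range(0, length, window_size):
        end = min(start + window_size, length)
        out.append((window_id_for(chrom, start, end), start, end))
    return out


def assign_window_ids(probes: pd.DataFrame, chrom_lengths: dict[str, int],
                      window_size: int) -> pd.Series:
    """Window id of each probe, by midpoint containment (floor division)."""
    mids = (probes["start"].to_numpy() + probes["end"].to_numpy()) // 2
    ids = []
    for chrom, mid in zip(probes["chrom"], mids):
        length = chrom_lengths[chrom]
        if mid >= length:
            raise WindowError(f"probe midpoint {mid} beyond chromosome {chrom} ({length} bp)")
        start = int(mid // window_size) * window_size
        end = min(start + window_size, length)
        ids.append(window_id_for(chrom, start, end))
    return pd.Series(ids, index=probes.index, name="window_id")


def build_windows(probes: pd.DataFrame, chrom_lengths: dict[str, int],
                  window_size: int) -> list[GenomicWindow]:
    """Tile every chromosome and attach probes by midpoint containment.

    Every window of the genome is returned, including probe-free ones, so
    the window set is a pure function of the genome geometry.
    """
    if window_size <= 0:
        raise WindowError("window_size must be > 0")
    wins = assign_window_ids(probes, chrom_lengths, window_size)
    members: dict[str, list[str]] = {}
    for pid, wid in zip(probes["probe_id"], wins):
        members.setdefault(wid, []).append(pid)
    out = []
    for chrom in chrom_lengths:
        for wid, start, end in tile_chromosome(chrom, chrom_lengths[chrom], window_size):
            out.append(GenomicWindow(wid, chrom, start, end, tuple(members.get(wid, ()))))
    return out


def test_window(values, mu_ref: float, min_probes: int = 3) -> tuple[float, bool]:
    """Two-sided one-sample Wilcoxon signed-rank p-value for symmetry about mu_ref.

    Zero differences are dropped before ranking. With n <= 25 distinct
    absolute differences the exact null distribution is used; otherwise the
    normal approximation with tie and continuity corrections. Returns
    ``(p, testable)``; windows with fewer than ``min_probes`` finite values
    are untestable.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < min_probes:
        return float("nan"), False
    d = arr - mu_ref
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all window signals equal the reference mean; p = 1", stacklevel=2)
        return 1.0, True
    abs_d = np.abs(d)
    exact_ok = d.size <= 25 and np.unique(abs_d).size == abs_d.size
    method = "exact" if exact_ok else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(d, alternative="two-sided", method=method,
                             correction=not exact_ok)
    return float(res.pvalue), True


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, >= raw p, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def local_fdr_tail(p_values, censor_quantile: float = 0.75) -> np.ndarray:
    """Tail-area false-discovery estimates from a two-group model.

    P-values are probit-transformed to half-normal scores
    ``y = |Phi^-1(p/2)|``; the null scale is fitted by truncated maximum
    likelihood on scores below the censoring threshold, the null proportion
    eta0 follows from the truncated mass, and the tail-area FDR is
    ``eta0 * m * S_null(y) / #{y_j >= y}``, monotonized in y.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    y = np.abs(stats.norm.ppf(np.clip(p, 1e-300, 1.0) / 2.0))
    y0 = np.quantile(y, censor_quantile)
    if y0 <= 0:
        return np.ones(m)
    trunc = y[y <= y0]

    # Truncated half-normal MLE: maximize sum log f(y; s) - n log F(y0; s).
    def negll(log_s: float) -> float:
        s = float(np.exp(log_s))
        ll = np.sum(stats.halfnorm.logpdf(trunc, scale=s))
        ll -= trunc.size * stats.halfnorm.logcdf(y0, scale=s)
        return -ll

    from scipy.optimize import minimize_scalar
    opt = minimize_scalar(negll, bounds=(np.log(0.05), np.log(20.0)), method="bounded")
    sigma0 = float(np.exp(opt.x))
    mass0 = float(stats.halfnorm.cdf(y0, scale=sigma0))
    eta0 = min(1.0, (trunc.size / m) / max(mass0, 1e-12))

    surv_null = stats.halfnorm.sf(y, scale=sigma0)
    order = np.argsort(y, kind="mergesort")
    sorted_y = y[order]
    # #{y_j >= y_(i)}, tie-aware
    n_ge = m - np.searchsorted(sorted_y, sorted_y, side="left")
    fdr_sorted = np.minimum(1.0, eta0 * m * surv_null[order] / np.maximum(n_ge, 1))
    # monotone non-increasing in y (non-decreasing in p)
    fdr_sorted = np.maximum.accumulate(fdr_sorted[::-1])[::-1]
    out = np.empty(m)
    out[order] = fdr_sorted
    return out


def adjust_fdr(p_values, method: str = "bh", **kwargs) -> np.ndarray:
    """FDR-adjusted values: 'bh' (Benjamini–Hochberg) or 'local' (tail-area
    estimator in the style of fdrtool)."""
    if method == "bh":
        return benjamini_hochberg(p_values)
    if method == "local":
        return local_fdr_tail(p_values, **kwargs)
    raise ValueError(f"unknown FDR method {method!r}")


def score_windows(results: list[WindowResult], alpha: float,
                  method: str = "bh") -> list[WindowResult]:
    """Assign q-values and ternary scores to testable window results.

    The FDR adjustment pools all testable windows of the condition. Each
    result is scored against its own (per-chromosome) reference mean:
    score = 0 when q > alpha, else the sign of (mean - mu_ref); a mean
    exactly at mu_ref scores 0 regardless of q. Untestable windows keep
    score 0 and NaN q.
    """
    testable = [r for r in results if r.testable]
    q = adjust_fdr([r.p_value for r in testable], method=method)
    for r, qv in zip(testable, q):
        r.q_value = float(qv)
        if qv > alpha or r.mean_signal == r.mu_ref:
            r.score = 0
        else:
            r.score = 1 if r.mean_signal > r.mu_ref else -1
    return results
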