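"""Cross-experiment DMR comparison: common DMRs, conserved vs inversed
direction classes, hypergeometric over-representation, and overlap with
differentially expressed gene (DEG) lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from epimem.dmr import DMR, floor_pct


class CompareError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail hypergeometric test: k successes among n draws from a
    population of N containing K successes."""

    N: int
    K: int
    n: int
    k: int
    p_value: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) <= self.N):
            raise CompareError(
                f"invalid hypergeometric arguments N={self.N} K={self.K} n={self.n} k={self.k}")


def _log_hypergeom_pmf(j: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    return (gammaln(K + 1) - gammaln(j + 1) - gammaln(K - j + 1)
            + gammaln(N - K + 1) - gammaln(n - j + 1) - gammaln(N - K - n + j + 1)
            - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)))


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log space."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise CompareError(f"invalid population: N={N}, K={K}, n={n}")
    if k > min(K, n):
        raise CompareError(f"impossible overlap k={k} > min(K={K}, n={n})")
    if k <= max(0, n + K - N):
        return 1.0
    j = np.arange(k, min(K, n) + 1, dtype=float)
    return float(np.exp(logsumexp(_log_hypergeom_pmf(j, N, K, n))))


def _directions(dmrs: Iterable[DMR] | Mapping[str, str]) -> dict[str, str]:
    if isinstance(dmrs, Mapping):
        return dict(dmrs)
    return {d.window_id: d.direction for d in dmrs}


def intersect_dmrs(dmr_sets: Mapping[str, Iterable[DMR] | Mapping[str, str]]
                   ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Common DMRs (windows that are DMRs in >= 2 experiments) and the
    per-experiment exclusive windows.

    The common table has one row per window with per-experiment direction
    columns and a conserved/inversed status (conserved iff every present
    direction agrees). Symmetric in experiment order.
    """
    dirs = {exp: _directions(d) for exp, d in dmr_sets.items()}
    if len(dirs) < 2:
        raise CompareError("need at least two experiments to intersect")
    counts: dict[str, int] = {}
    for d in dirs.values():
        for wid in d:
            counts[wid] = counts.get(wid, 0) + 1
    rows = []
    for wid in sorted(w for w, c in counts.items() if c >= 2):
        present = {exp: d[wid] for exp, d in dirs.items() if wid in d}
        status = "conserved" if len(set(present.values())) == 1 else "inversed"
        row = {"window_id": wid, "n_experiments": len(present), "status": status}
        for exp in dirs:
            row[f"direction_{exp}"] = present.get(exp, "")
        rows.append(row)
    common = pd.DataFrame(rows, columns=["window_id", "n_experiments", "status"]
                          + [f"direction_{e}" for e in dirs])
    exclusive = {exp: sorted(w for w in d if counts[w] == 1) for exp, d in dirs.items()}
    return common, exclusive


def common_fraction(n_common: int, n_dmrs: int) -> float:
    """Share of an experiment's DMRs that are common, floored to one decimal."""
    return floor_pct(n_common, n_dmrs)


def test_overlap_enrichment(dmrs_a: Iterable[str], dmrs_b: Iterable[str],
                            universe: Iterable[str], label: str = "") -> EnrichmentResult:
    """Is the overlap of two DMR sets larger than chance within the shared
    window universe? N = |universe|, K = |A|, n = |B|, k = |A & B|."""
    uni = set(universe)
    if not uni:
        raise CompareError("empty window universe")
    a, b = set(dmrs_a), set(dmrs_b)
    if not a <= uni or not b <= uni:
        raise CompareError("DMR sets must be subsets of the universe")
    k = len(a & b)
    p = hypergeometric_upper_tail(len(uni), len(a), len(b), k)
    return EnrichmentResult(N=len(uni), K=len(a), n=len(b), k=k, p_value=p, label=label)


def test_direction_enrichment(common: pd.DataFrame, experiment: str,
                              label: str = "") -> EnrichmentResult:
    """Are hypermethylated DMRs over-represented among conserved common DMRs?

    N = |common|, K = hypermethylated among common (direction taken in the
    given experiment), n = |conserved|, k = hypermethylated among conserved.
    """
    if common.empty:
        raise CompareError("no common DMRs")
    col = f"direction_{experiment}"
    if col not in common.columns:
        raise CompareError(f"unknown experiment {experiment!r}")
    present = common[common[col] != ""]
    N = len(present)
    K = int((present[col] == "hyper").sum())
    conserved = present[present["status"] == "conserved"]
    n = len(conserved)
    k = int((conserved[col] == "hyper").sum())
    p = hypergeometric_upper_tail(N, K, n, k)
    return EnrichmentResult(N=N, K=K, n=n, k=k, p_value=p, label=label)


def overlap_with_degs(dmr_genes: Mapping[str, str], degs: pd.DataFrame,
                      gene_universe: Iterable[str]
                      ) -> tuple[pd.DataFrame, dict[str, EnrichmentResult], int]:
    """Cross DMR-covered genes with a DEG list.

    ``dmr_genes`` maps gene id to the methylation direction of its DMR
    ('hyper'/'hypo'); ``degs`` has columns (gene_id, direction) with
    direction in {'up', 'down'}. Returns the 2x2 overlap table
    (methylation x expression), one upper-tail hypergeometric result per
    methylation direction, and the count of DEGs dropped for being outside
    the universe.
    """
    uni = set(gene_universe)
    if not set(dmr_genes) <= uni:
        raise CompareError("dmr_genes must be within the gene universe")
    if degs.empty:
        table = pd.DataFrame(0, index=["hyper", "hypo"], columns=["up", "down"])
        return table, {}, 0
    bad = set(degs["direction"]) - {"up", "down"}
    if bad:
        raise CompareError(f"unknown DEG directions {sorted(bad)}")
    in_uni = degs["gene_id"].isin(uni)
    n_dropped = int((~in_uni).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} DEG ids outside the gene universe were excluded",
                      stacklevel=2)
    degs = degs[in_uni].drop_duplicates("gene_id")
    deg_dir = dict(zip(degs["gene_id"], degs["direction"]))

    table = pd.DataFrame(0, index=["hyper", "hypo"], columns=["up", "down"])
    for gene, meth in dmr_genes.items():
        if gene in deg_dir:
            table.loc[meth, deg_dir[gene]] += 1

    results = {}
    n_degs = len(deg_dir)
    for meth in ("hyper", "hypo"):
        K = sum(1 for m in dmr_genes.values() if m == meth)
        k = int(table.loc[meth].sum())
        if K == 0:
            continue
        p = hypergeometric_upper_tail(len(uni), K, n_degs, k)
        results[meth] = EnrichmentResult(N=len(uni), K=K, n=n_degs, k=k,
                                         p_value=p, label=f"deg_overlap_{meth}")
    return table, results, n_dropped


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{"label": r.label, "N": r.N, "K": r.K, "n": r.n,
                          "k": r.k, "p": r.p_value} for r in results])
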