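"""DMR calling from ternary window scores, annotation, and summaries.

A DMR is a window whose score differs between the favorable and
unfavorable conditions; direction is the change from favorable to
unfavorable (hyper = methylation increases under unfavorable conditions),
intensity is strong when the score jumps by two levels (-1 to +1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from epimem.windows import GenomicWindow, WindowResult


class DmrError(ValueError):
    pass


@dataclass
class DMR:
    window_id: str
    chrom: str
    start: int
    end: int
    score_favorable: int
    score_unfavorable: int
    category_counts: dict[str, int] = field(default_factory=dict)
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.score_favorable == self.score_unfavorable:
            raise DmrError(f"{self.window_id}: equal scores do not define a DMR")

    @property
    def direction(self) -> str:
        return "hyper" if self.score_unfavorable > self.score_favorable else "hypo"

    @property
    def intensity(self) -> str:
        return "strong" if abs(self.score_unfavorable - self.score_favorable) == 2 else "mild"


def floor_pct(count: int, total: int) -> float:
    """Display percentage 100*count/total truncated (floored) to one decimal.

    Integer arithmetic keeps the truncation exact: 255/871 -> 29.2, not
    the 29.3 that rounding would give.
    """
    if total <= 0:
        raise DmrError("total must be positive")
    return (count * 1000) // total / 10


def _index_results(results: list[WindowResult]) -> dict[str, WindowResult]:
    return {r.window_id: r for r in results}


def call_dmrs(scored_favorable: list[WindowResult],
              scored_unfavorable: list[WindowResult],
              windows: list[GenomicWindow]) -> list[DMR]:
    """Windows with unequal ternary scores across conditions.

    Both score sets must cover the same windows; windows untestable in
    either condition are excluded.
    """
    fav = _index_results(scored_favorable)
    unf = _index_results(scored_unfavorable)
    if set(fav) != set(unf):
        odd = sorted(set(fav) ^ set(unf))
        raise DmrError(f"window sets differ between conditions: {odd[:10]}")
    geom = {w.window_id: w for w in windows}
    dmrs = []
    for wid in fav:
        rf, ru = fav[wid], unf[wid]
        if not (rf.testable and ru.testable):
            continue
        if rf.score != ru.score:
            w = geom[wid]
            dmrs.append(DMR(window_id=wid, chrom=w.chrom, start=w.start, end=w.end,
                            score_favorable=rf.score, score_unfavorable=ru.score))
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs


def annotate_dmrs(dmrs: list[DMR], probes: pd.DataFrame,
                  genes: pd.DataFrame | None = None,
                  window_members: dict[str, tuple[str, ...]] | None = None) -> list[DMR]:
    """Attach per-category probe counts and overlapping gene ids to DMRs.

    ``window_members`` maps window_id to member probe ids (the analysis
    subset); when omitted, membership is recomputed from probe midpoints.
    A gene overlaps a window when their half-open intervals intersect, so
    a gene spanning a window boundary is listed in both windows.
    """
    by_id = probes.set_index("probe_id")
    for d in dmrs:
        if window_members is not None:
            member_ids = window_members.get(d.window_id, ())
            sub = by_id.loc[list(member_ids)]
        else:
            mids = (probes["start"] + probes["end"]) // 2
            mask = (probes["chrom"] == d.chrom) & (mids >= d.start) & (mids < d.end)
            sub = probes[mask]
        d.category_counts = dict(Counter(sub["category"]))
        if genes is not None and not genes.empty:
            hit = genes[(genes["chrom"] == d.chrom)
                        & (genes["start"] < d.end) & (genes["end"] > d.start)]
            d.gene_ids = sorted(hit["gene_id"].unique())
    return dmrs


def summarize_dmrs(dmrs: list[DMR], n_windows_tested: int) -> dict:
    """Counts, floored display percentage, direction and intensity splits,
    and the per-category probe table summed over DMRs."""
    if n_windows_tested < 1:
        raise DmrError("n_windows_tested must be >= 1")
    n = len(dmrs)
    directions = Counter(d.direction for d in dmrs)
    intensities = Counter(d.intensity for d in dmrs)
    categories: Counter = Counter()
    for d in dmrs:
        categories.update(d.category_counts)
    return {
        "n_dmrs": n,
        "n_windows_tested": n_windows_tested,
        "pct_dmrs": floor_pct(n, n_windows_tested),
        "n_hyper": directions.get("hyper", 0),
        "n_hypo": directions.get("hypo", 0),
        "pct_hyper": floor_pct(directions.get("hyper", 0), n) if n else 0.0,
        "n_mild": intensities.get("mild", 0),
        "n_strong": intensities.get("strong", 0),
        "categories": dict(categories),
    }


def category_direction_table(dmrs: list[DMR]) -> pd.DataFrame:
    """Contingency table of member-probe counts: category x {hyper, hypo}."""
    rows: dict[str, Counter] = {}
    for d in dmrs:
        for cat, cnt in d.category_counts.items():
            rows.setdefault(cat, Counter())[d.direction] += cnt
    table = pd.DataFrame(rows).T.fillna(0).astype(int)
    for col in ("hyper", "hypo"):
        if col not in table.columns:
            table[col] = 0
    return table[["hyper", "hypo"]].sort_index()


def chi_squared_categories(table: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-squared test of independence on a category-by-direction
    contingency table.

    Returns (statistic, p, expected-counts frame); cells with expected
    count < 5 are reported via the expected frame. Degenerate tables (a
    zero margin or a single row/column) are errors.
    """
    arr = table.to_numpy(dtype=float)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DmrError("contingency table needs at least 2 rows and 2 columns")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DmrError("contingency table has a zero margin")
    stat, p, _, expected = stats.chi2_contingency(arr, correction=False)
    exp = pd.DataFrame(expected, index=table.index, columns=table.columns)
    return float(stat), float(p), exp


def genes_in_dmrs(dmrs: list[DMR]) -> list[str]:
    """Distinct gene ids covered by any DMR (the export fed to GO tools)."""
    out: set[str] = set()
    for d in dmrs:
        out.update(d.gene_ids)
    return sorted(out)
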