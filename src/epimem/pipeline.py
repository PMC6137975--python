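"""End-to-end orchestration: probe split, reference models, window tests,
scores, and DMR calls for one experiment, plus planted-DMR recovery and
null false-discovery metrics used for calibration checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from epimem import dmr as dmr_mod
from epimem import simulate
from epimem.config import RunConfig, SimConfig
from epimem.io import SignalMatrix
from epimem.reference import ReferenceModel, build_reference_models, split_probes
from epimem.windows import (GenomicWindow, WindowResult, build_windows,
                            score_windows, test_window)

log = logging.getLogger("epimem")


@dataclass
class ExperimentResult:
    probes_reference: pd.DataFrame
    probes_analysis: pd.DataFrame
    windows: list[GenomicWindow]
    references: dict[tuple[str, str], ReferenceModel]
    results: dict[str, list[WindowResult]]   # condition -> scored window results
    dmrs: list[dmr_mod.DMR]

    @property
    def n_testable(self) -> int:
        any_cond = next(iter(self.results.values()))
        testable = {r.window_id for r in any_cond if r.testable}
        for res in self.results.values():
            testable &= {r.window_id for r in res if r.testable}
        return len(testable)

    def window_table(self) -> pd.DataFrame:
        """Merged per-window frame, one row per window, conditions side by
        side, with the -log10 p columns used for Manhattan plots."""
        geom = {w.window_id: w for w in self.windows}
        frames = []
        for condition, res in self.results.items():
            df = pd.DataFrame([{
                "window_id": r.window_id,
                f"mean_{condition}": r.mean_signal,
                f"p_{condition}": r.p_value,
                f"q_{condition}": r.q_value,
                f"score_{condition}": r.score,
                f"testable_{condition}": r.testable,
                f"neglog10p_{condition}": -np.log10(r.p_value) if r.p_value > 0 else np.inf,
            } for r in res]).set_index("window_id")
            frames.append(df)
        merged = pd.concat(frames, axis=1).reset_index()
        merged.insert(1, "chrom", [geom[w].chrom for w in merged["window_id"]])
        merged.insert(2, "start", [geom[w].start for w in merged["window_id"]])
        merged.insert(3, "end", [geom[w].end for w in merged["window_id"]])
        merged.insert(4, "n_probes", [geom[w].n_probes for w in merged["window_id"]])
        return merged.sort_values(["chrom", "start"]).reset_index(drop=True)


def score_experiment(matrix: SignalMatrix, probes: pd.DataFrame,
                     chrom_lengths: dict[str, int], config: RunConfig,
                     fit_mixture: bool = False,
                     call: bool = True) -> ExperimentResult:
    """Run the full scoring pipeline on one experiment.

    The probe set is split once (20%/80% by default); windows are built
    from the analysis subset geometry but span the whole genome; each
    condition is tested against its own per-chromosome reference mean and
    scored after a condition-wide FDR adjustment.
    """
    cond_means = matrix.condition_means()
    ref_probes, ana_probes = split_probes(probes, config.ref_fraction, config.seed)
    log.info("split probes: %d reference / %d analysis", len(ref_probes), len(ana_probes))
    references = build_reference_models(ref_probes, cond_means, config.ref_fraction,
                                        config.seed, fit_mixture=fit_mixture)
    windows = build_windows(ana_probes, chrom_lengths, config.window_size)
    log.info("built %d windows of %d bp", len(windows), config.window_size)

    results: dict[str, list[WindowResult]] = {}
    for condition in cond_means.columns:
        cond_results = []
        for w in windows:
            mu_ref = references[(w.chrom, condition)].reference_mean
            values = cond_means.loc[list(w.probe_ids), condition].to_numpy() if w.probe_ids \
                else np.empty(0)
            p, testable = test_window(values, mu_ref, config.min_probes_per_window)
            cond_results.append(WindowResult(
                window_id=w.window_id, condition=condition,
                mean_signal=float(np.nanmean(values)) if testable else float("nan"),
                p_value=p, mu_ref=mu_ref, testable=testable))
        score_windows(cond_results, config.alpha, method=config.fdr_method)
        n_sig = sum(1 for r in cond_results if r.score != 0)
        log.info("condition %s: %d/%d windows scored nonzero", condition, n_sig,
                 sum(r.testable for r in cond_results))
        results[condition] = cond_results

    dmrs: list[dmr_mod.DMR] = []
    if call:
        fav, unf = config.condition_favorable, config.condition_unfavorable
        dmrs = dmr_mod.call_dmrs(results[fav], results[unf], windows)
        members = {w.window_id: w.probe_ids for w in windows}
        dmr_mod.annotate_dmrs(dmrs, probes, window_members=members)
        log.info("called %d DMRs", len(dmrs))
    return ExperimentResult(ref_probes, ana_probes, windows, references, results, dmrs)


def simulate_and_score(sim_config: SimConfig, run_config: RunConfig,
                       **kwargs) -> tuple[ExperimentResult, pd.DataFrame]:
    """Convenience: simulate one experiment and score it. Returns the
    experiment result and the ground-truth table."""
    probes, genes = simulate.simulate_probe_design(sim_config)
    matrices, truth = simulate.simulate_signals(probes, sim_config)
    matrix = simulate.combine_matrices(matrices)
    result = score_experiment(matrix, probes, simulate.chromosome_lengths(sim_config),
                              run_config, **kwargs)
    dmr_mod.annotate_dmrs(result.dmrs, probes, genes=genes,
                          window_members={w.window_id: w.probe_ids for w in result.windows})
    return result, truth


def evaluate_recovery(dmrs: list[dmr_mod.DMR], truth: pd.DataFrame) -> dict:
    """Sensitivity and direction accuracy of called DMRs against the
    planted truth, plus the false-discovery proportion."""
    called = {d.window_id: d.direction for d in dmrs}
    planted = truth[truth["is_dmr"]]
    hits = [w for w in planted["window_id"] if w in called]
    correct = [w for w in hits
               if called[w] == planted.set_index("window_id").loc[w, "planted_direction"]]
    n_false = len(set(called) - set(planted["window_id"]))
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "n_recovered": len(hits),
        "sensitivity": len(hits) / len(planted) if len(planted) else float("nan"),
        "direction_accuracy": len(correct) / len(hits) if hits else float("nan"),
        "false_discovery_proportion": n_false / len(called) if called else 0.0,
    }


def null_score_fdp(sim_config: SimConfig, run_config: RunConfig) -> float:
    """False-discovery proportion of nonzero window scores on one fully
    null dataset (delta forced to 0, no planted shifts applied).

    The FDR adjustment runs once per condition, so the FDP is computed per
    condition family with the V/max(R, 1) convention — with no shifted
    windows every nonzero score is false, giving 1 when the condition has
    any nonzero score and 0 otherwise — and averaged across conditions.
    """
    import dataclasses
    null_cfg = dataclasses.replace(sim_config, delta=0.0)
    result, _ = simulate_and_score(null_cfg, run_config, call=False)
    per_condition = [1.0 if any(r.score != 0 for r in res) else 0.0
                     for res in result.results.values()]
    return float(np.mean(per_condition))


def mean_null_fdp(sim_config: SimConfig, run_config: RunConfig,
                  seeds: list[int]) -> float:
    """Average null FDP over seeded replicate simulations (FDR estimate)."""
    import dataclasses
    fdps = []
    for seed in seeds:
        sc = dataclasses.replace(sim_config, seed=seed)
        rc = dataclasses.replace(run_config, seed=seed)
        fdps.append(null_score_fdp(sc, rc))
    return float(np.mean(fdps))
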