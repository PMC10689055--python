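"""Planted-sweep benchmark: simulate, scan, and score against truth.

Ten 250-kb hard sweeps (F_sweep = 0.95) are planted in the focal group on
an F = 0.1 three-group background across 1040 shared 500-kb/125-kb
windows; the scan is scored by window-level recall of truth windows, the
fraction of called windows outside truth, and XP-CLR grid-point coverage
of the planted intervals.
"""

from __future__ import annotations

import numpy as np

from .genomic_io import PopulationMap
from .simulate import simulate_genotypes, sweep_benchmark_config, truth_window_mask
from .sweeps import ScanConfig, ScanResult, scan_matrix, threshold_top_fraction


def popmap_for_matrix(matrix) -> PopulationMap:
    """Population map from the simulator's `<group>_<index>` sample ids."""
    return PopulationMap({s: s.rsplit("_", 1)[0] for s in matrix.samples})


def run_sweep_benchmark(seed: int, methods=("pbs", "piratio", "xpclr")) -> dict:
    """Simulate the benchmark at ``seed``, scan it, and score the calls.

    Returns the metric dict plus the ScanResult and truth table under the
    ``_result`` / ``_truth`` keys for further inspection.
    """
    sim = sweep_benchmark_config(seed)
    matrix, truth = simulate_genotypes(sim)
    pops = popmap_for_matrix(matrix)
    cfg = ScanConfig(
        focal="CG1", baseline="BG", third="G3", methods=tuple(methods),
        min_methods=min(2, len(methods)),
    )
    result = scan_matrix(cfg, matrix, pops, dict(sim.genome))
    metrics = score_scan(result, truth["sweeps"])
    metrics["_result"] = result
    metrics["_truth"] = truth
    return metrics


def score_scan(result: ScanResult, sweeps_truth: list[dict]) -> dict:
    """Window-level recall/false fraction and XP-CLR truth coverage."""
    win = result.windows
    truth_mask = truth_window_mask(win, sweeps_truth)
    called = win["candidate"].to_numpy()
    n_called = int(called.sum())
    metrics = {
        "n_windows": len(win),
        "n_truth_windows": int(truth_mask.sum()),
        "n_called_windows": n_called,
        "recall": float((called & truth_mask).sum() / max(truth_mask.sum(), 1)),
        "false_fraction": float((called & ~truth_mask).sum() / max(n_called, 1)),
        "n_sweeps_called": len(result.sweeps),
        "total_sweep_bp": int(result.sweeps["length_bp"].sum()) if len(result.sweeps) else 0,
    }
    scores = result.xpclr_scores
    if scores is not None:
        sc = scores.dropna(subset=["clr"])
        _, flags = threshold_top_fraction(sc["clr"].to_numpy(), 0.05)
        inside = np.zeros(len(sc), dtype=bool)
        covered = 0
        for s in sweeps_truth:
            in_s = (
                (sc["chrom"] == s["chrom"]).to_numpy()
                & (sc["pos"].to_numpy() >= s["start"])
                & (sc["pos"].to_numpy() < s["end"])
            )
            inside |= in_s
            if (flags & in_s).any():
                covered += 1
        metrics["xpclr_sweep_coverage"] = covered / max(len(sweeps_truth), 1)
        metrics["xpclr_mean_clr_inside"] = float(sc["clr"].to_numpy()[inside].mean())
        metrics["xpclr_mean_clr_outside"] = float(sc["clr"].to_numpy()[~inside].mean())
        metrics["min_clr"] = float(sc["clr"].min())
    return metrics
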