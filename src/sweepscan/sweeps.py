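"""Outlier thresholding, 2-of-3 evidence combination, sweep merging and
gene annotation.

Each statistic is thresholded at its own top fraction over the retained
windows; a window becomes a candidate when at least ``min_methods``
statistics flag it; overlapping or book-ended candidate windows merge into
sweep intervals which are then annotated with overlapping genes.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ParameterError, StageError
from .diversity import POOLED, compute_window_stats
from .genomic_io import (
    GeneModel,
    make_windows,
    read_gff_genes,
    read_population_map,
    read_vcf,
    read_vcf_chrom_lengths,
)
from .xpclr import XpclrParams, map_scores_to_windows, xpclr_scan

VALID_METHODS = ("pbs", "piratio", "xpclr")


@dataclass
class ScanConfig:
    """Configuration of one focal-vs-baseline selective-sweep scan."""

    focal: str
    baseline: str
    third: str = POOLED
    size_bp: int = 500_000
    step_bp: int = 125_000
    min_snps: int = 5
    top_fraction: float = 0.05
    methods: tuple[str, ...] = VALID_METHODS
    min_methods: int = 2
    xpclr: XpclrParams = field(default_factory=XpclrParams)

    def __post_init__(self):
        self.methods = tuple(self.methods)
        if not (0 < self.top_fraction < 1):
            raise ParameterError("top_fraction must be in (0, 1)")
        bad = [m for m in self.methods if m not in VALID_METHODS]
        if bad:
            raise ParameterError(f"unknown methods {bad}; valid: {VALID_METHODS}")
        if self.min_methods > len(self.methods):
            raise ParameterError(
                f"min_methods={self.min_methods} exceeds |methods|={len(self.methods)}"
            )
        if self.size_bp <= 0 or self.step_bp <= 0:
            raise ParameterError("window size/step must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d["xpclr"]["s_grid"] = [float(s) for s in self.xpclr.s_grid]
        return d

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        xp = raw.pop("xpclr", None)
        cfg = cls(**raw)
        if xp:
            if "s_grid" in xp:
                xp["s_grid"] = np.asarray(xp["s_grid"], dtype=float)
            cfg.xpclr = XpclrParams(**xp)
        return cfg


def threshold_top_fraction(values, q: float):
    """Flag the ceil(q * N) largest rankable values, ties at the threshold
    included. NaN values are unrankable; +inf sorts above all finite values.

    Returns (threshold, flags) where threshold is the smallest flagged value.
    """
    values = np.asarray(values, dtype=np.float64)
    rankable = ~np.isnan(values)
    n = int(rankable.sum())
    need = math.ceil(1.0 / q)
    if n < need:
        raise ParameterError(f"{n} finite values; >= {need} required for top {q:g}")
    k = math.ceil(q * n)
    ranked = np.sort(values[rankable])[::-1]
    threshold = ranked[k - 1]
    with np.errstate(invalid="ignore"):
        flags = np.where(rankable, values >= threshold, False)
    if np.isfinite(values[rankable]).any() and ranked[0] == ranked[-1]:
        warnings.warn(
            "degenerate statistic distribution: all values tie at the threshold",
            stacklevel=2,
        )
    return float(threshold), flags


def combine_evidence(flags: dict[str, np.ndarray], min_methods: int) -> pd.DataFrame:
    """Per-window support counts and the >= min_methods candidate flag.

    All methods must be evaluated on the same retained-window set; a length
    mismatch is a hard failure, not a silent intersection.
    """
    lengths = {m: len(f) for m, f in flags.items()}
    if len(set(lengths.values())) > 1:
        raise ParameterError(f"mismatched window sets across methods: {lengths}")
    df = pd.DataFrame({m: np.asarray(f, dtype=bool) for m, f in flags.items()})
    df["support_count"] = df.sum(axis=1)
    df["candidate"] = df["support_count"] >= min_methods
    return df


def merge_candidate_windows(windows: pd.DataFrame, stat_cols=()) -> pd.DataFrame:
    """Merge overlapping/book-ended candidate windows into sweep intervals.

    ``windows`` needs chrom/start/end plus boolean method columns; for each
    column in ``stat_cols`` the merged interval reports its mean and max.
    Returns sorted, non-overlapping intervals with supporting methods
    unioned over the merged windows.
    """
    method_cols = {
        c: (c[5:] if c.startswith("flag_") else c)
        for c in windows.columns
        if c in VALID_METHODS or (c.startswith("flag_") and c[5:] in VALID_METHODS)
    }
    if windows.empty:
        cols = ["chrom", "start", "end", "length_bp", "n_windows", "methods", "support"]
        for c in stat_cols:
            cols += [f"mean_{c}", f"max_{c}"]
        return pd.DataFrame(columns=cols)
    win = windows.sort_values(["chrom", "start"]).reset_index(drop=True)
    out = []
    cur = None
    for row in win.itertuples(index=False):
        r = row._asdict()
        if cur is not None and r["chrom"] == cur["chrom"] and r["start"] <= cur["end"]:
            cur["end"] = max(cur["end"], r["end"])
            cur["rows"].append(r)
        else:
            if cur is not None:
                out.append(cur)
            cur = {"chrom": r["chrom"], "start": r["start"], "end": r["end"], "rows": [r]}
    out.append(cur)

    records = []
    for iv in out:
        rows = pd.DataFrame(iv["rows"])
        methods = sorted({name for c, name in method_cols.items() if rows[c].any()})
        rec = {
            "chrom": iv["chrom"],
            "start": int(iv["start"]),
            "end": int(iv["end"]),
            "length_bp": int(iv["end"] - iv["start"]),
            "n_windows": len(rows),
            "methods": ",".join(methods),
            "support": len(methods),
        }
        for c in stat_cols:
            vals = rows[c].replace([np.inf, -np.inf], np.nan)
            rec[f"mean_{c}"] = vals.mean()
            rec[f"max_{c}"] = vals.max()
        records.append(rec)
    return pd.DataFrame(records)


def annotate_genes(sweeps: pd.DataFrame, genes: list[GeneModel]):
    """Attach overlapping gene ids (>= 1 bp overlap, strand-agnostic).

    Returns (sweeps with a ``genes`` column, flat gene table with one row
    per gene-sweep assignment).
    """
    sweeps = sweeps.copy()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)

    gene_lists, flat = [], []
    for row in sweeps.itertuples(index=False):
        hits = [
            g.gene_id
            for g in by_chrom.get(row.chrom, [])
            if g.start < row.end and g.end > row.start
        ]
        gene_lists.append(",".join(hits))
        for gid in hits:
            flat.append((gid, row.chrom, row.start, row.end))
    sweeps["genes"] = gene_lists
    flat_df = pd.DataFrame(flat, columns=["gene_id", "chrom", "sweep_start", "sweep_end"])
    return sweeps, flat_df


def sweep_overlap(sweeps_a: pd.DataFrame, sweeps_b: pd.DataFrame, genes=None):
    """Shared interval length (bp) between two merged sweep sets, plus the
    genes overlapping both sets when gene models are given."""
    shared_bp = 0
    shared_intervals = []
    for chrom in set(sweeps_a["chrom"]).intersection(sweeps_b["chrom"]):
        a = sweeps_a[sweeps_a["chrom"] == chrom][["start", "end"]].to_numpy()
        b = sweeps_b[sweeps_b["chrom"] == chrom][["start", "end"]].to_numpy()
        for s1, e1 in a:
            for s2, e2 in b:
                lo, hi = max(s1, s2), min(e1, e2)
                if hi > lo:
                    shared_bp += hi - lo
                    shared_intervals.append((chrom, int(lo), int(hi)))
    shared_genes: set[str] = set()
    if genes is not None:
        for g in genes:
            for chrom, lo, hi in shared_intervals:
                if g.chrom == chrom and g.start < hi and g.end > lo:
                    shared_genes.add(g.gene_id)
                    break
    return shared_bp, shared_genes


def _bed6(df: pd.DataFrame, name_col: str, score_col: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int),
            "end": df["end"].astype(int),
            "name": df[name_col],
            "score": df[score_col],
            "strand": ".",
        }
    )


@dataclass
class ScanResult:
    """Everything run_scan computed, before/after file output."""

    config: ScanConfig
    windows: pd.DataFrame            # WindowStatRow table incl. method stats
    thresholds: dict[str, float]
    flags: pd.DataFrame              # per-method boolean + support/candidate
    sweeps: pd.DataFrame             # merged, annotated intervals
    gene_table: pd.DataFrame
    xpclr_scores: pd.DataFrame | None


_METHOD_STAT = {"pbs": "pbs", "piratio": "log2_pi_ratio", "xpclr": "xpclr_score"}


def run_scan(config: ScanConfig, vcf, popmap, gff=None, outdir=None, chrom_lengths=None) -> ScanResult:
    """End-to-end scan: window statistics -> outliers -> sweeps -> genes.

    Deterministic given inputs and config. When ``outdir`` is set, writes
    windows.tsv, outliers.<method>.bed, sweeps.bed, sweep_genes.tsv and
    run.log (config echo + per-stage counts; no timestamps, so reruns are
    byte-identical).
    """
    stage = "read inputs"
    try:
        matrix = read_vcf(vcf)
        pops = read_population_map(popmap)
        genes = read_gff_genes(gff) if gff is not None else []
        if chrom_lengths is None:
            chrom_lengths = read_vcf_chrom_lengths(vcf)
        if not chrom_lengths:
            chrom_lengths = {
                c: int(matrix.pos[sl].max())
                for c, sl in matrix.chrom_slices().items()
            }
    except ParameterError:
        raise
    except Exception as exc:
        raise StageError(f"stage '{stage}' failed: {exc}") from exc
    result = scan_matrix(config, matrix, pops, chrom_lengths, genes=genes)
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def scan_matrix(
    config: ScanConfig,
    matrix,
    pops,
    chrom_lengths: dict[str, int],
    genes: list[GeneModel] | None = None,
) -> ScanResult:
    """The scan on in-memory inputs; run_scan wraps this with file I/O."""
    genes = genes or []
    try:
        stage = "window statistics"
        grid = make_windows(chrom_lengths, config.size_bp, config.step_bp)
        win = compute_window_stats(
            matrix, grid, pops, config.focal, config.baseline, config.third,
            min_snps=config.min_snps,
        )

        stage = "xpclr scan"
        scores = None
        if "xpclr" in config.methods:
            scores = xpclr_scan(
                matrix, pops, chrom_lengths, config.baseline, config.focal, config.xpclr
            )
            win["xpclr_score"] = map_scores_to_windows(
                scores, WindowSubset(win, grid)
            )

        stage = "outlier thresholds"
        thresholds, flags = {}, {}
        for m in config.methods:
            thresholds[m], flags[m] = threshold_top_fraction(
                win[_METHOD_STAT[m]].to_numpy(), config.top_fraction
            )
        evidence = combine_evidence(flags, config.min_methods)
        evidence = evidence.rename(columns={m: f"flag_{m}" for m in config.methods})

        stage = "merge sweeps"
        stat_cols = [_METHOD_STAT[m] for m in config.methods]
        cand = pd.concat(
            [win[["chrom", "start", "end"] + stat_cols].reset_index(drop=True), evidence],
            axis=1,
        )
        sweeps = merge_candidate_windows(
            cand[cand["candidate"]].drop(columns=["support_count", "candidate"]),
            stat_cols=stat_cols,
        )

        stage = "annotate genes"
        sweeps, gene_table = annotate_genes(sweeps, genes)
    except ParameterError:
        raise
    except Exception as exc:
        raise StageError(f"stage '{stage}' failed: {exc}") from exc

    return ScanResult(
        config=config,
        windows=pd.concat([win.reset_index(drop=True), evidence], axis=1),
        thresholds=thresholds,
        flags=evidence,
        sweeps=sweeps,
        gene_table=gene_table,
        xpclr_scores=scores,
    )


class WindowSubset:
    """Adapter exposing the retained-window rows as a WindowGrid-alike."""

    def __init__(self, win: pd.DataFrame, grid):
        self.windows = list(zip(win["chrom"], win["start"], win["end"]))
        self.size_bp = grid.size_bp
        self.step_bp = grid.step_bp

    def __len__(self):
        return len(self.windows)


def _write_bundle(result: ScanResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    result.windows.to_csv(outdir / "windows.tsv", sep="\t", index=False, float_format=fmt)
    for m in result.config.methods:
        flagged = result.windows[result.flags[f"flag_{m}"].to_numpy()]
        bed = _bed6(
            flagged.assign(name=m, score=flagged[_METHOD_STAT[m]]),
            "name",
            "score",
        )
        bed.to_csv(outdir / f"outliers.{m}.bed", sep="\t", index=False, header=False, float_format=fmt)
    sweeps_bed = _bed6(
        result.sweeps.assign(name=result.sweeps["methods"], score=result.sweeps["support"]),
        "name",
        "score",
    ) if len(result.sweeps) else pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    sweeps_bed.to_csv(outdir / "sweeps.bed", sep="\t", index=False, header=False, float_format=fmt)
    result.sweeps.to_csv(outdir / "sweeps.tsv", sep="\t", index=False, float_format=fmt)
    result.gene_table.to_csv(outdir / "sweep_genes.tsv", sep="\t", index=False)
    if result.xpclr_scores is not None:
        result.xpclr_scores.to_csv(
            outdir / "xpclr_scores.tsv", sep="\t", index=False, float_format=fmt
        )

    cfg = result.config.to_dict()
    cfg_yaml = yaml.safe_dump(cfg, sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_yaml.encode()).hexdigest()[:16]
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"sweepscan {__version__}\n")
        fh.write(f"config_sha256 {cfg_hash}\n")
        fh.write("--- config ---\n")
        fh.write(cfg_yaml)
        fh.write("--- counts ---\n")
        fh.write(f"retained_windows\t{len(result.windows)}\n")
        for m, t in result.thresholds.items():
            fh.write(f"threshold_{m}\t{t:.6g}\n")
            fh.write(f"flagged_{m}\t{int(result.flags[f'flag_{m}'].sum())}\n")
        fh.write(f"candidate_windows\t{int(result.flags['candidate'].sum())}\n")
        fh.write(f"sweeps\t{len(result.sweeps)}\n")
        total = int(result.sweeps["length_bp"].sum()) if len(result.sweeps) else 0
        fh.write(f"total_sweep_bp\t{total}\n")
        fh.write(f"sweep_genes\t{result.gene_table['gene_id'].nunique() if len(result.gene_table) else 0}\n")
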