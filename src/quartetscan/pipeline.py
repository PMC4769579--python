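"""Genome-scan orchestration and the candidate-filter cascade.

Runs multi-scale windowed D / f_d / d_xy / F_ST scans with bootstrap
inference, calibrates per-size D thresholds on a reference locus with a
known introgression signal, selects and merges candidate windows, and
applies the d_xy-comparison, depth and FDR filters that grade candidates
into tiers, the top tier being loci supported by every measure.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import popgen
from .genotype_io import ConfigError, GenotypeMatrix, QuartetSpec, iter_windows
from .resampling import (InsufficientDataError, ResamplingConfig, bh_fdr,
                         block_jackknife, moving_block_bootstrap)

PASS_FLAGS = ("significant_D", "significant_fd", "dxy_below_chromosome",
              "dxy_lowest_pair", "depth_ok")


@dataclass
class ScanConfig:
    """Scan geometry, filter thresholds and FDR level.

    ``min_snps_per_5kb`` is a strict lower bound, scaled proportionally
    for larger windows (> 10 per 10 kb, > 50 per 50 kb). Thresholds may
    be given explicitly per window size or calibrated from
    ``reference_region`` — the maximum window D observed over a locus
    with an a-priori introgression signal.
    """

    window_sizes: tuple[int, ...] = (5_000, 10_000, 50_000)
    min_snps_per_5kb: float = 5.0
    q: float = 0.01
    reference_region: tuple | None = None       # (chrom, start, end)
    thresholds: dict | None = None              # size -> min D
    depth_bounds: tuple[float, float] = (5.0, 40.0)
    fst_pair: tuple[str, str] = ("P2", "P3")
    dxy_block_size: int = 100
    chromosome_lengths: dict | None = None

    def __post_init__(self):
        if len(set(self.window_sizes)) != len(self.window_sizes):
            raise ConfigError("window sizes must be distinct")
        if any(s <= 0 for s in self.window_sizes):
            raise ConfigError("window sizes must be positive")
        if not (0 < self.q < 1):
            raise ConfigError("q must lie in (0, 1)")
        lo, hi = self.depth_bounds
        if not lo < hi:
            raise ConfigError("depth bounds must satisfy low < high")

    def min_snps(self, size: int) -> float:
        return self.min_snps_per_5kb * size / 5_000.0


def _window_seed(base_seed: int, size: int, chrom: str, start: int) -> int:
    # zlib.crc32 is stable across processes, unlike the salted str hash
    chrom_digest = zlib.crc32(str(chrom).encode()) & 0x7FFFFFFF
    ss = np.random.SeedSequence([base_seed, size, chrom_digest, start])
    return int(ss.generate_state(1)[0])


def scan_windows(matrix: GenotypeMatrix, quartet: QuartetSpec,
                 config: ScanConfig | None = None,
                 resampling: ResamplingConfig | None = None) -> pd.DataFrame:
    """One row per (window, size class) with all windowed statistics.

    D and f_d carry moving-block-bootstrap SE/z/p (NaN when the window
    has fewer than 8 usable sites or f_d is undefined); d_xy is reported
    for the P2–P3, P1–P3 and P1–P2 pairs; F_ST for ``config.fst_pair``.
    """
    config = config or ScanConfig()
    resampling = resampling or ResamplingConfig()
    idx = quartet.indices(matrix.samples)
    rows = []
    for size in config.window_sizes:
        for w in iter_windows(matrix, size, lengths=config.chromosome_lengths):
            site_idx = matrix.sites_in(w.chrom, w.start, w.end)
            freqs = popgen.site_frequencies(matrix, quartet, site_idx)
            n_snps = popgen.valid_snp_count(freqs)
            row = {
                "chrom": w.chrom, "start": w.start, "end": w.end,
                "size": size, "partial": w.partial, "n_snps": n_snps,
            }
            d = popgen.d_statistic(freqs)
            num, den, _ = popgen.abba_baba_components(freqs)
            row.update(_boot_fields("D", num, den, d, resampling,
                                    _window_seed(resampling.seed, size,
                                                 w.chrom, w.start)))
            fd = popgen.f_d_statistic(freqs)
            fnum, fden, _ = popgen.f_d_components(freqs)
            if np.isfinite(fd):
                row.update(_boot_fields("fd", fnum, fden, fd, resampling,
                                        _window_seed(resampling.seed, size,
                                                     w.chrom, w.start + 1)))
            else:
                row.update({"fd": fd, "fd_se": np.nan, "fd_z": np.nan,
                            "fd_p": np.nan})
            for a, b in (("P2", "P3"), ("P1", "P3"), ("P1", "P2")):
                row[f"dxy_{a}{b}"] = popgen.dxy(freqs, a, b)
            row["fst"] = popgen.fst_weir_cockerham(
                matrix,
                [matrix.samples[i] for i in idx[config.fst_pair[0]]],
                [matrix.samples[i] for i in idx[config.fst_pair[1]]],
                site_idx)
            depth = popgen.window_depth_summary(matrix, quartet, site_idx) \
                if matrix.depths is not None else {r: np.nan for r in
                                                   ("P1", "P2", "P3", "O")}
            for r in ("P1", "P2", "P3", "O"):
                row[f"depth_{r}"] = depth[r]
            rows.append(row)
    return pd.DataFrame(rows)


def _boot_fields(name, num, den, estimate, resampling, seed):
    out = {name: estimate, f"{name}_se": np.nan, f"{name}_z": np.nan,
           f"{name}_p": np.nan}
    if len(num) >= 8 and np.isfinite(estimate):
        tr = moving_block_bootstrap(num, resampling.n_bootstrap, seed, den)
        out.update({f"{name}_se": tr.se, f"{name}_z": tr.z, f"{name}_p": tr.p})
    return out


def chromosome_summary(matrix: GenotypeMatrix, quartet: QuartetSpec,
                       resampling: ResamplingConfig | None = None) -> pd.DataFrame:
    """Chromosome-level D with 50-kb block-jackknife SE, z and p.

    Accepts arbitrary quartets, so swapping taxa in the QuartetSpec
    reproduces sex-chromosome-style analyses by quartet rotation.
    Chromosomes with fewer than two jackknife blocks are skipped.
    """
    resampling = resampling or ResamplingConfig()
    rows = []
    seen = []
    for c in matrix.chroms:
        if c not in seen:
            seen.append(c)
    for chrom in seen:
        on = np.flatnonzero(matrix.chroms == chrom)
        if matrix.unplaced is not None and matrix.unplaced[on].any():
            continue
        freqs = popgen.site_frequencies(matrix, quartet, on)
        num, den, pos = popgen.abba_baba_components(freqs)
        try:
            tr = block_jackknife(num, pos, resampling.jackknife_block_size, den)
        except InsufficientDataError:
            continue
        rows.append({"chrom": chrom, "D": tr.estimate, "D_se": tr.se,
                     "D_z": tr.z, "D_p": tr.p, "n_blocks": tr.n_units,
                     "n_snps": int(freqs.valid.sum())})
    return pd.DataFrame(rows)


def calibrate_reference_threshold(stats: pd.DataFrame, region: tuple,
                                  size: int) -> float:
    """Maximum window D of the given size class overlapping the region."""
    chrom, start, end = region
    sub = stats[(stats["size"] == size) & (stats["chrom"] == chrom)
                & (stats["end"] > start) & (stats["start"] < end)]
    if len(sub) == 0:
        raise ConfigError(f"no {size}-bp windows overlap reference region {region}")
    d = sub["D"].to_numpy(float)
    if not np.isfinite(d).any():
        raise ConfigError("all windows in the reference region have undefined D")
    return float(np.nanmax(d))


def resolve_thresholds(stats: pd.DataFrame, config: ScanConfig) -> dict:
    """Per-size minimum D, from overrides or reference-locus calibration."""
    if config.thresholds is not None:
        missing = [s for s in config.window_sizes if s not in config.thresholds]
        if missing:
            raise ConfigError(f"no D threshold for window sizes {missing}")
        return dict(config.thresholds)
    if config.reference_region is None:
        raise ConfigError("need either explicit thresholds or a reference region")
    return {s: calibrate_reference_threshold(stats, config.reference_region, s)
            for s in config.window_sizes}


def select_candidates(stats: pd.DataFrame, thresholds: dict,
                      config: ScanConfig) -> pd.DataFrame:
    """Windows with D at or above the size threshold and enough valid SNPs."""
    keep = np.zeros(len(stats), dtype=bool)
    for size, thr in thresholds.items():
        sub = (stats["size"] == size) & (stats["D"] >= thr) \
            & (stats["n_snps"] > config.min_snps(size))
        keep |= sub.to_numpy()
    return stats[keep].reset_index(drop=True)


def merge_candidate_loci(candidates: pd.DataFrame) -> pd.DataFrame:
    """Merge multi-scale candidate windows into unique loci.

    A window that strictly contains a smaller selected window is folded
    into that smaller locus (its size class recorded in ``sizes``);
    windows containing no smaller candidate become loci themselves.
    """
    if len(candidates) == 0:
        out = candidates.copy()
        out["sizes"] = pd.Series(dtype=object)
        return out
    cand = candidates.sort_values(["chrom", "size", "start"]).reset_index(drop=True)
    n = len(cand)
    is_locus = np.ones(n, dtype=bool)
    sizes: list[set] = [set([int(cand.loc[i, "size"])]) for i in range(n)]
    for i in range(n):
        for j in range(n):
            if i == j or cand.loc[i, "chrom"] != cand.loc[j, "chrom"]:
                continue
            nested = (cand.loc[j, "start"] >= cand.loc[i, "start"]
                      and cand.loc[j, "end"] <= cand.loc[i, "end"]
                      and cand.loc[j, "size"] < cand.loc[i, "size"])
            if nested:
                is_locus[i] = False
                sizes[j].add(int(cand.loc[i, "size"]))
    # propagate container sizes to the loci they were folded into
    loci = cand[is_locus].reset_index(drop=True)
    loci["sizes"] = [tuple(sorted(sizes[i])) for i in range(n) if is_locus[i]]
    return loci


def dxy_block_values(matrix: GenotypeMatrix, quartet: QuartetSpec, chrom: str,
                     block_size: int = 100, pair=("P2", "P3")):
    """Per-block d_xy values over a chromosome, with block start positions."""
    on = np.flatnonzero(matrix.chroms == chrom)
    freqs = popgen.site_frequencies(matrix, quartet, on)
    terms, pos = popgen.dxy_site_terms(freqs, *pair)
    if len(terms) == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    blocks = pos // block_size
    uniq, inv = np.unique(blocks, return_inverse=True)
    sums = np.bincount(inv, weights=terms)
    counts = np.bincount(inv)
    return sums / counts, (uniq * block_size).astype(np.int64)


def dxy_comparison_filter(locus: pd.Series, block_values: np.ndarray,
                          block_starts: np.ndarray,
                          min_blocks: int = 5) -> dict:
    """The two d_xy-based candidate filters for one locus.

    Flag A compares the locus's 100-bp-block P2–P3 d_xy values against
    the chromosome-wide blocks (one-sided Mann–Whitney U, locus lower),
    flag B requires the locus P2–P3 d_xy to be the lowest of the three
    pairwise comparisons. The U test uses the exact null for fewer than
    20 locus blocks and the tie-corrected normal approximation otherwise.
    """
    inside = (block_starts >= locus["start"]) & (block_starts < locus["end"])
    loc_blocks = block_values[inside]
    out = {"dxy_locus_mean": float(np.mean(loc_blocks)) if len(loc_blocks) else np.nan,
           "dxy_chrom_mean": float(np.mean(block_values)) if len(block_values) else np.nan,
           "n_dxy_blocks": int(len(loc_blocks)),
           "dxy_mwu_p": np.nan, "dxy_below_mean": None, "dxy_lowest_pair": None}
    if len(loc_blocks) < min_blocks:
        return out
    method = "exact" if len(loc_blocks) < 20 else "asymptotic"
    try:
        mwu = sps.mannwhitneyu(loc_blocks, block_values, alternative="less",
                               method=method)
    except ValueError:
        mwu = sps.mannwhitneyu(loc_blocks, block_values, alternative="less",
                               method="asymptotic")
    out["dxy_mwu_p"] = float(mwu.pvalue)
    out["dxy_below_mean"] = bool(out["dxy_locus_mean"] < out["dxy_chrom_mean"])
    trio = (locus["dxy_P2P3"], locus["dxy_P1P3"], locus["dxy_P1P2"])
    if all(np.isfinite(v) for v in trio):
        out["dxy_lowest_pair"] = bool(trio[0] < trio[1] and trio[0] < trio[2])
    return out


def depth_filter(locus: pd.Series, bounds=(5.0, 40.0)):
    """True iff every taxon's mean locus depth lies within [low, high]."""
    lo, hi = bounds
    depths = [locus[f"depth_{r}"] for r in ("P1", "P2", "P3", "O")]
    if any(not np.isfinite(d) for d in depths):
        return None
    return bool(all(lo <= d <= hi for d in depths))


def finalize_tiers(loci: pd.DataFrame, q: float = 0.01) -> tuple[pd.DataFrame, dict]:
    """Apply per-family BH FDR and grade loci into tiers.

    The D, f_d and d_xy (Mann–Whitney) p-value families are adjusted
    separately over the candidate set. A locus is "well-supported" when
    all five pass flags hold; otherwise its tier lists the failed
    filters. Undefined flags (missing depth, too few blocks) demote the
    locus. Returns the graded table and the per-filter bookkeeping
    counts.
    """
    out = loci.copy()
    n = len(out)
    if n == 0:
        for f in PASS_FLAGS:
            out[f] = pd.Series(dtype=object)
        out["tier"] = pd.Series(dtype=object)
        return out, {"n_candidates": 0, "n_well_supported": 0}

    bh_d = bh_fdr(out["D_p"].to_numpy(float), q)
    bh_fd = bh_fdr(out["fd_p"].to_numpy(float), q)
    bh_dxy = bh_fdr(out["dxy_mwu_p"].to_numpy(float), q)
    out["significant_D"] = bh_d.reject
    out["significant_fd"] = bh_fd.reject
    below = out["dxy_below_mean"].to_numpy(object)
    out["dxy_below_chromosome"] = [
        bool(b) and bool(r) if b is not None else None
        for b, r in zip(below, bh_dxy.reject)]
    # dxy_lowest_pair, depth_ok already present
    tiers = []
    for _, row in out.iterrows():
        failed = [f for f in PASS_FLAGS if row[f] is not True]
        tiers.append("well-supported" if not failed
                     else "filtered: " + ",".join(failed))
    out["tier"] = tiers
    counts = {
        "n_candidates": n,
        "n_significant_D": int(out["significant_D"].sum()),
        "n_significant_fd": int(out["significant_fd"].sum()),
        "n_significant_D_and_fd": int((out["significant_D"]
                                       & out["significant_fd"]).sum()),
        "n_dxy_below_chromosome": int(sum(bool(v) for v in
                                          out["dxy_below_chromosome"])),
        "n_dxy_lowest_pair": int(sum(bool(v) for v in out["dxy_lowest_pair"])),
        "n_depth_ok": int(sum(bool(v) for v in out["depth_ok"])),
        "n_well_supported": int(sum(t == "well-supported" for t in tiers)),
        "bh_critical_D": bh_d.critical_value,
        "bh_critical_fd": bh_fd.critical_value,
        "bh_critical_dxy": bh_dxy.critical_value,
    }
    return out, counts


def run_scan(matrix: GenotypeMatrix, quartet: QuartetSpec,
             config: ScanConfig | None = None,
             resampling: ResamplingConfig | None = None) -> dict:
    """Full cascade: scan → calibrate → select → merge → filter → tier.

    Returns a dict with the windows table, chromosome summaries, the
    graded candidate table and the bookkeeping counts.
    """
    config = config or ScanConfig()
    resampling = resampling or ResamplingConfig()
    windows = scan_windows(matrix, quartet, config, resampling)
    chroms = chromosome_summary(matrix, quartet, resampling)
    thresholds = resolve_thresholds(windows, config)
    cand = select_candidates(windows, thresholds, config)
    loci = merge_candidate_loci(cand)

    block_cache: dict[str, tuple] = {}
    extra_rows = []
    for _, locus in loci.iterrows():
        chrom = locus["chrom"]
        if chrom not in block_cache:
            block_cache[chrom] = dxy_block_values(
                matrix, quartet, chrom, config.dxy_block_size)
        vals, starts = block_cache[chrom]
        extra = dxy_comparison_filter(locus, vals, starts)
        extra["depth_ok"] = depth_filter(locus, config.depth_bounds)
        extra_rows.append(extra)
    if extra_rows:
        loci = pd.concat([loci, pd.DataFrame(extra_rows, index=loci.index)],
                         axis=1)
    else:
        for col in ("dxy_locus_mean", "dxy_chrom_mean", "n_dxy_blocks",
                    "dxy_mwu_p", "dxy_below_mean", "dxy_lowest_pair",
                    "depth_ok"):
            loci[col] = pd.Series(dtype=object)
    graded, counts = finalize_tiers(loci, config.q)
    return {"windows": windows, "chromosomes": chroms,
            "candidates": graded, "counts": counts,
            "thresholds": thresholds}


def write_bed_track(windows: pd.DataFrame, column: str, path: str,
                    size: int | None = None) -> None:
    """Export one statistic column of the windows table as a BED track.

    Rows with an undefined value are skipped; ``size`` restricts the
    export to one window size class when the table mixes several.
    """
    if column not in windows.columns:
        raise ConfigError(f"no column {column!r} in windows table")
    sub = windows if size is None else windows[windows["size"] == size]
    with open(path, "w") as fh:
        for _, row in sub.iterrows():
            val = row[column]
            if isinstance(val, float) and not np.isfinite(val):
                continue
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}"
                     f"\t{val:.6g}\n" if isinstance(val, float) else
                     f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}"
                     f"\t{val}\n")


def write_outputs(result: dict, outdir: str, float_format: str = "%.6g") -> None:
    """Write windows.tsv, chromosomes.tsv, candidates.tsv and candidates.bed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result["windows"].to_csv(out / "windows.tsv", sep="\t", index=False,
                             float_format=float_format)
    result["chromosomes"].to_csv(out / "chromosomes.tsv", sep="\t", index=False,
                                 float_format=float_format)
    cand = result["candidates"].copy()
    if "sizes" in cand:
        cand["sizes"] = [";".join(str(s) for s in v) if isinstance(v, tuple)
                         else v for v in cand["sizes"]]
    cand.to_csv(out / "candidates.tsv", sep="\t", index=False,
                float_format=float_format)
    with open(out / "candidates.bed", "w") as fh:
        for _, row in cand.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}"
                     f"\t{row['tier']}\n")
    with open(out / "counts.tsv", "w") as fh:
        for k, v in result["counts"].items():
            fh.write(f"{k}\t{v}\n")
    with open(out / "thresholds.tsv", "w") as fh:
        for k, v in result["thresholds"].items():
            fh.write(f"{k}\t{v}\n")
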