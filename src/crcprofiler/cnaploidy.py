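"""Tumor cell content (TCC), ploidy and allele-specific copy number.

The model relates the observed tumor/normal coverage ratio ``r`` of a
segment with total tumor copy number ``ct`` to purity and ploidy through

    r = (tcc * ct + 2 * (1 - tcc)) / (tcc * ploidy + 2 * (1 - tcc))

so for a candidate (tcc, ploidy) the implied real-valued total copy number is

    ct = (r * D - 2 * (1 - tcc)) / tcc,      D = tcc * ploidy + 2 * (1 - tcc)

and for an allelically imbalanced segment the observed decrease of
heterozygosity dh_obs = 2 * mean_BAF - 1 maps to the major/minor split via

    dh_obs = tcc * (cA - cB) / (tcc * ct + 2 * (1 - tcc)).

Segments are classified from the distribution of germline-heterozygous SNP
allele fractions: a global density maximum inside [0.45, 0.55] is balanced,
one peak outside that interval is ambiguous (dropped), two peaks is
imbalanced. A grid over tcc in [0.05, 1] and ploidy in [1, 6.5] scores each
candidate by the segment-length-weighted mean distance of the implied real
copy numbers to their nearest allowed integer states (even total states only
for balanced segments); cells forcing negative copy numbers or tumor DH > 1
anywhere are infeasible, and local minima of the surface are the reported
solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .config import GridConfig

BALANCED = "balanced"
IMBALANCED = "imbalanced"
AMBIGUOUS = "ambiguous"
UNCLASSIFIED = "unclassified"


@dataclass
class SegmentObservation:
    """One genomic segment with its coverage ratio and het-SNP evidence."""

    chrom: str
    start: int  # 0-based half-open internally
    end: int
    log2ratio: float
    afs: np.ndarray = field(default_factory=lambda: np.empty(0))  # unfolded
    klass: str = UNCLASSIFIED
    mean_baf: float = np.nan  # folded, >= 0.5; set for imbalanced segments

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def n_het_snps(self) -> int:
        return len(self.afs)

    @property
    def bafs(self) -> np.ndarray:
        """Folded B-allele fractions (higher-count allele as B-allele)."""
        return np.maximum(self.afs, 1.0 - self.afs)


@dataclass
class TccPloidyGrid:
    tcc_values: np.ndarray
    ploidy_values: np.ndarray
    distance: np.ndarray  # shape (n_tcc, n_ploidy), nan where infeasible
    feasible: np.ndarray


@dataclass
class TccPloidySolution:
    tcc: float
    ploidy: float
    distance: float
    per_segment: pd.DataFrame  # columns: chrom,start,end,klass,ct,cA,cB,dh


# ---------------------------------------------------------------------------
# Het-SNP calling and segment classification
# ---------------------------------------------------------------------------

def call_het_snps(normal_af: np.ndarray | pd.Series,
                  low: float = 0.3, high: float = 0.7) -> np.ndarray:
    """Boolean mask of germline-heterozygous SNPs: normal AF in [low, high]."""
    af = np.asarray(normal_af, dtype=float)
    if ((af < 0) | (af > 1)).any():
        raise ValueError("allele fractions must lie in [0, 1]")
    return (af >= low) & (af <= high)


def _density_peaks(afs: np.ndarray, n_grid: int = 512,
                   prominence_frac: float = 0.1) -> np.ndarray:
    """Locations of the AF density peaks (Gaussian KDE, Silverman bandwidth).

    Peaks are local maxima of the density on a fine grid over [0, 1] with
    prominence at least ``prominence_frac`` of the global maximum. Degenerate
    samples (near-zero spread) are treated as a single peak at the mean.
    """
    afs = np.asarray(afs, dtype=float)
    if np.ptp(afs) < 1e-9:
        return np.array([afs.mean()])
    kde = gaussian_kde(afs, bw_method="silverman")
    # evaluate beyond [0, 1]: modes near the boundary would otherwise lose
    # prominence against the truncated tail and go undetected
    pad = 4.0 * np.sqrt(float(kde.covariance[0, 0]))
    grid = np.linspace(0.0 - pad, 1.0 + pad, n_grid)
    dens = kde(grid)
    idx, _ = find_peaks(dens, prominence=prominence_frac * dens.max())
    if len(idx) == 0:  # monotone density: take the global maximum
        idx = np.array([int(np.argmax(dens))])
    return grid[idx]


def classify_segment(afs: np.ndarray, n_min: int = 20,
                     balanced_low: float = 0.45,
                     balanced_high: float = 0.55) -> tuple[str, float]:
    """Classify a segment from its unfolded het-SNP allele fractions.

    Returns (class, mean folded BAF). Segments with fewer than ``n_min``
    SNPs are unclassified; a global density maximum in
    [balanced_low, balanced_high] is balanced; one peak outside is
    ambiguous; two or more peaks is imbalanced. The mean folded BAF (using
    the higher-count allele as B-allele) is reported for imbalanced
    segments.
    """
    afs = np.asarray(afs, dtype=float)
    if len(afs) < n_min:
        return UNCLASSIFIED, np.nan
    peaks = _density_peaks(afs)
    # global maximum = highest-density peak
    if np.ptp(afs) < 1e-9:
        global_peak = afs.mean()
    else:
        kde = gaussian_kde(afs, bw_method="silverman")
        global_peak = peaks[int(np.argmax(kde(peaks)))]
    if balanced_low - 1e-9 <= global_peak <= balanced_high + 1e-9:
        return BALANCED, np.nan
    if len(peaks) == 1:
        return AMBIGUOUS, np.nan
    mean_baf = float(np.maximum(afs, 1 - afs).mean())
    return IMBALANCED, mean_baf


def classify_segments(segments: list[SegmentObservation],
                      n_min: int = 20,
                      balanced_low: float = 0.45,
                      balanced_high: float = 0.55) -> list[SegmentObservation]:
    """Classify every segment in place and return the list."""
    for seg in segments:
        seg.klass, seg.mean_baf = classify_segment(
            seg.afs, n_min=n_min,
            balanced_low=balanced_low, balanced_high=balanced_high)
    return segments


# ---------------------------------------------------------------------------
# Copy-number model
# ---------------------------------------------------------------------------

def expected_copy_numbers(log2ratio: float, mean_baf: float | None,
                          tcc: float, ploidy: float,
                          ) -> tuple[float, float, float, float]:
    """Real-valued (ct, cA, cB, dh_tumor) implied by one (tcc, ploidy) cell.

    ``mean_baf`` is the folded BAF of an imbalanced segment, or ``None`` for
    a balanced segment (then cA = cB = ct / 2 and dh = 0).
    """
    if not (0 < tcc <= 1):
        raise ValueError("tcc must lie in (0, 1]")
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    r = 2.0 ** log2ratio
    denom = tcc * ploidy + 2 * (1 - tcc)
    ct = (r * denom - 2 * (1 - tcc)) / tcc
    if mean_baf is None or not np.isfinite(mean_baf):
        cA = cB = ct / 2.0
        dh = 0.0
    else:
        dh_obs = 2 * mean_baf - 1
        diff = dh_obs * (tcc * ct + 2 * (1 - tcc)) / tcc
        cA = (ct + diff) / 2.0
        cB = ct - cA
        dh = diff / ct if ct > 0 else np.inf
    return ct, cA, cB, dh


def expected_baf(cA: float, cB: float, tcc: float) -> float:
    """Folded B-allele fraction of a (cA, cB) segment at purity ``tcc``."""
    ct = cA + cB
    return (tcc * cA + (1 - tcc)) / (tcc * ct + 2 * (1 - tcc))


def expected_log2ratio(ct: float, tcc: float, ploidy: float) -> float:
    """Coverage log-ratio of a segment with total copy number ``ct``."""
    r = (tcc * ct + 2 * (1 - tcc)) / (tcc * ploidy + 2 * (1 - tcc))
    return float(np.log2(r))


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def _usable(segments: list[SegmentObservation]) -> list[SegmentObservation]:
    return [s for s in segments if s.klass in (BALANCED, IMBALANCED)]


def grid_search(segments: list[SegmentObservation],
                grid: GridConfig | None = None) -> TccPloidyGrid:
    """Weighted mean distance-to-integer-state surface over (tcc, ploidy).

    For each cell the real-valued total (and, for imbalanced segments,
    allele-specific) copy numbers are computed per segment; the distance is
    |ct - nearest allowed integer| plus, for imbalanced segments,
    |cA - round(cA)| + |cB - round(cB)|. Balanced segments may only occupy
    even total states. The cell distance is the segment-length-weighted
    mean. Cells implying a negative copy number or tumor DH > 1 (negative
    minor allele) on any segment are infeasible.
    """
    grid = grid or GridConfig()
    segs = _usable(segments)
    if not segs:
        raise ValueError("no balanced or imbalanced segments to fit "
                         "(ambiguous/unclassified segments are excluded)")
    tcc = np.round(np.arange(grid.tcc_min, grid.tcc_max + 1e-9, grid.tcc_step), 10)
    ploidy = np.round(np.arange(grid.ploidy_min, grid.ploidy_max + 1e-9,
                                grid.ploidy_step), 10)
    T = tcc[:, None]                      # (n_tcc, 1)
    D = T * ploidy[None, :] + 2 * (1 - T)  # (n_tcc, n_ploidy)

    weights = np.array([s.length_bp for s in segs], dtype=float)
    total_w = weights.sum()
    dist = np.zeros_like(D)
    infeasible = np.zeros(D.shape, dtype=bool)

    for seg, w in zip(segs, weights):
        r = 2.0 ** seg.log2ratio
        ct = (r * D - 2 * (1 - T)) / T
        infeasible |= ct < -1e-9
        if seg.klass == BALANCED:
            state = np.round(ct / 2.0) * 2.0
            state = np.maximum(state, 0.0)
            d = np.abs(ct - state)
        else:
            dh_obs = 2 * seg.mean_baf - 1
            diff = dh_obs * (T * ct + 2 * (1 - T)) / T
            cA = (ct + diff) / 2.0
            cB = ct - cA
            # tumor DH materially above 1: the nearest minor-allele state
            # would be negative (a small overshoot of a noisy BAF around a
            # pure-LOH state only counts as distance, not exclusion)
            infeasible |= cB < -0.5
            sA = np.maximum(np.round(cA), 0.0)
            sB = np.maximum(np.round(cB), 0.0)
            d = (np.abs(ct - np.round(np.maximum(ct, 0)))
                 + np.abs(cA - sA) + np.abs(cB - sB))
        dist += w * d
    dist /= total_w
    dist[infeasible] = np.nan
    return TccPloidyGrid(tcc_values=tcc, ploidy_values=ploidy,
                         distance=dist, feasible=~infeasible)


def _solution_states(segments: list[SegmentObservation],
                     tcc: float, ploidy: float) -> pd.DataFrame:
    rows = []
    for seg in _usable(segments):
        ct, cA, cB, _ = expected_copy_numbers(
            seg.log2ratio,
            seg.mean_baf if seg.klass == IMBALANCED else None,
            tcc, ploidy)
        if seg.klass == BALANCED:
            ct_i = max(int(round(ct / 2.0)) * 2, 0)
            cA_i = cB_i = ct_i // 2
        else:
            cA_i = max(int(round(cA)), 0)
            cB_i = max(int(round(cB)), 0)
            ct_i = cA_i + cB_i
        dh = (cA_i - cB_i) / ct_i if ct_i > 0 else 0.0
        rows.append(dict(chrom=seg.chrom, start=seg.start, end=seg.end,
                         klass=seg.klass, ct=ct_i, cA=cA_i, cB=cB_i,
                         dh=dh))
    return pd.DataFrame(rows)


def find_solutions(grid: TccPloidyGrid,
                   segments: list[SegmentObservation],
                   max_solutions: int | None = None) -> list[TccPloidySolution]:
    """Local minima of the distance surface, ranked as candidate solutions.

    A feasible cell is a local minimum when no feasible 8-neighbor has a
    strictly smaller distance. Candidates are ranked by ascending distance,
    ties broken toward lower ploidy then higher tumor cell content.
    """
    dist = grid.distance
    feas = grid.feasible
    if not feas.any():
        raise ValueError("no feasible (tcc, ploidy) cell in the grid")
    n_t, n_p = dist.shape
    padded = np.full((n_t + 2, n_p + 2), np.inf)
    padded[1:-1, 1:-1] = np.where(feas, dist, np.inf)
    neigh_min = np.full_like(dist, np.inf)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neigh_min = np.minimum(
                neigh_min, padded[1 + di:1 + di + n_t, 1 + dj:1 + dj + n_p])
    is_min = feas & (dist <= neigh_min + 1e-12)

    ti, pi = np.nonzero(is_min)
    # numerically tied distances (e.g. several exact fits related by a
    # purity/ploidy degeneracy) break toward lower ploidy, then higher TCC
    order = sorted(
        range(len(ti)),
        key=lambda k: (round(float(dist[ti[k], pi[k]]), 9),
                       grid.ploidy_values[pi[k]],
                       -grid.tcc_values[ti[k]]))
    solutions = []
    for k in order[: (max_solutions or len(order))]:
        tcc = float(grid.tcc_values[ti[k]])
        ploidy = float(grid.ploidy_values[pi[k]])
        solutions.append(TccPloidySolution(
            tcc=tcc, ploidy=ploidy,
            distance=float(dist[ti[k], pi[k]]),
            per_segment=_solution_states(segments, tcc, ploidy)))
    return solutions


def estimate_purity_ploidy(segments: list[SegmentObservation],
                           grid: GridConfig | None = None,
                           n_min: int = 20,
                           max_solutions: int = 10,
                           ) -> list[TccPloidySolution]:
    """Classify segments, run the grid search and rank local-minimum solutions."""
    classify_segments(segments, n_min=n_min)
    g = grid_search(segments, grid=grid)
    return find_solutions(g, segments, max_solutions=max_solutions)


def plot_grid(grid: TccPloidyGrid, path: str | None = None,
              solutions: list[TccPloidySolution] | None = None,
              ax=None):
    """Heatmap of the distance surface, infeasible cells masked.

    The ranked-solution replacement for eyeballing the fit: local minima can
    be overplotted (best solution as a star, runners-up as circles).
    """
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    masked = np.ma.masked_invalid(grid.distance)
    mesh = ax.pcolormesh(grid.ploidy_values, grid.tcc_values, masked,
                         shading="nearest", cmap="viridis")
    ax.figure.colorbar(mesh, ax=ax, label="weighted mean distance")
    if solutions:
        ax.plot(solutions[0].ploidy, solutions[0].tcc, "r*", ms=14,
                label=f"best: TCC={solutions[0].tcc:.2f}, "
                      f"ploidy={solutions[0].ploidy:.2f}")
        for sol in solutions[1:]:
            ax.plot(sol.ploidy, sol.tcc, "wo", mfc="none", ms=8)
        ax.legend(loc="upper right")
    ax.set_xlabel("ploidy")
    ax.set_ylabel("tumor cell content")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


# ---------------------------------------------------------------------------
# Table ingest
# ---------------------------------------------------------------------------

def segments_from_tables(seg_df: pd.DataFrame,
                         snp_df: pd.DataFrame) -> list[SegmentObservation]:
    """Build :class:`SegmentObservation` objects from segment + SNP tables.

    ``seg_df`` needs chrom, start, end (1-based inclusive), log2ratio;
    ``snp_df`` needs chrom, pos, af_tumor (unfolded tumor allele fraction),
    optionally af_normal for het-SNP calling.
    """
    for col in ("chrom", "start", "end", "log2ratio"):
        if col not in seg_df.columns:
            raise KeyError(f"segment table lacks column {col!r}")
    for col in ("chrom", "pos", "af_tumor"):
        if col not in snp_df.columns:
            raise KeyError(f"SNP table lacks column {col!r}")
    if "af_normal" in snp_df.columns:
        snp_df = snp_df.loc[call_het_snps(snp_df["af_normal"])]
    out = []
    for _, row in seg_df.iterrows():
        start0 = int(row["start"]) - 1  # 1-based inclusive -> 0-based half-open
        end0 = int(row["end"])
        in_seg = ((snp_df["chrom"] == row["chrom"])
                  & (snp_df["pos"] >= row["start"])
                  & (snp_df["pos"] <= row["end"]))
        out.append(SegmentObservation(
            chrom=str(row["chrom"]), start=start0, end=end0,
            log2ratio=float(row["log2ratio"]),
            afs=snp_df.loc[in_seg, "af_tumor"].to_numpy(dtype=float)))
    return out
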