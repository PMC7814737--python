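"""Windowed methylation features around transcription start sites.

Per-CpG methylation counts are converted to M-values (log2 methylation
odds with a pseudocount, clamped to +/- log2(65), coverage-filtered).
Around each TSS, two grids of 20 contiguous windows (250 bp and 2500 bp
wide) summarize the M-values into three channels per window:

* ``Mave`` — window mean,
* ``Mvar`` — window variance (population divisor ``n``),
* ``Mfssd`` — the window's share of the region-level sum of squared
  deviations from the region mean (a spatial-heterogeneity feature;
  the shares over a grid sum to at most 1).

The per-sample tensor has shape ``(n_promoters, 2 scales, 20 windows,
3 channels)``.  Each feature column is min-max scaled to [0.1, 1] within
the sample; windows without methylation data are set to 0 after scaling,
so 0 always means "missing".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

DEFAULT_SCALES = (250, 2500)
N_WINDOWS = 20
N_CHANNELS = 3
SCALED_MIN = 0.1
SCALED_MAX = 1.0


def compute_m_values(
    sites: pd.DataFrame,
    offset: float = 0.5,
    cap: float = 65.0,
    min_cov: int = 5,
) -> pd.DataFrame:
    """Convert per-CpG counts to coverage-filtered, clamped M-values.

    ``sites`` needs columns ``chrom, pos, meth, unmeth``.  Sites with
    fewer than ``min_cov`` total reads are dropped;
    ``mval = log2((meth + offset) / (unmeth + offset))`` clamped to
    ``[-log2(cap), log2(cap)]``.
    """
    meth = sites["meth"].to_numpy(dtype=float)
    unmeth = sites["unmeth"].to_numpy(dtype=float)
    if (meth < 0).any() or (unmeth < 0).any():
        raise ValueError("negative methylation counts")
    keep = meth + unmeth >= min_cov
    out = sites.loc[keep, ["chrom", "pos"]].copy()
    limit = np.log2(cap)
    mval = np.log2((meth[keep] + offset) / (unmeth[keep] + offset))
    out["mval"] = np.clip(mval, -limit, limit)
    return out.reset_index(drop=True)


def make_window_grid(
    tss: int,
    strand: str = "+",
    scale: int = 250,
    ordering: str = "transcriptional",
) -> np.ndarray:
    """Return the 20 half-open window intervals for one TSS and scale.

    Windows tile ``[tss - 10*scale, tss + 10*scale)`` contiguously;
    window 10 ends at the TSS and window 11 starts at it.  Under
    ``transcriptional`` ordering the index order is reversed for
    minus-strand promoters so window 1 is always the far upstream end.
    """
    if ordering not in ("transcriptional", "genomic"):
        raise ValueError(f"unknown ordering {ordering!r}")
    edges = tss + scale * np.arange(-N_WINDOWS // 2, N_WINDOWS // 2 + 1)
    grid = np.stack([edges[:-1], edges[1:]], axis=1)
    if ordering == "transcriptional" and strand == "-":
        grid = grid[::-1].copy()
    return grid


def summarize_windows(mvalues: np.ndarray, positions: np.ndarray, grid: np.ndarray):
    """Windowed mean/variance/FSSD for one promoter and one scale.

    Returns ``(values, missing)`` where ``values`` is (20, 3) and
    ``missing`` a boolean mask; the whole window is missing when it holds
    no CpG (or extends past the chromosome start), and the FSSD channel
    is missing grid-wide when the region-level SSD denominator is 0.
    """
    values = np.zeros((N_WINDOWS, N_CHANNELS))
    missing = np.ones((N_WINDOWS, N_CHANNELS), dtype=bool)
    lo = grid.min()
    hi = grid.max()
    sel = (positions >= lo) & (positions < hi)
    mv = mvalues[sel]
    pos = positions[sel]
    n_i = mv.size
    if n_i:
        region_mean = mv.mean()
        total_ssd = float(((mv - region_mean) ** 2).sum())
    else:
        total_ssd = 0.0
    fssd_ok = n_i > 1 and total_ssd > 0.0
    for j in range(N_WINDOWS):
        w_lo, w_hi = grid[j]
        if w_lo < 0:
            continue  # truncated at the chromosome start: keep missing
        in_w = (pos >= w_lo) & (pos < w_hi)
        x = mv[in_w]
        if x.size == 0:
            continue
        mean = x.mean()
        var = float(((x - mean) ** 2).mean())
        values[j, 0] = mean
        values[j, 1] = var
        missing[j, 0] = missing[j, 1] = False
        if fssd_ok:
            values[j, 2] = float(((x - mean) ** 2).sum()) / total_ssd
            missing[j, 2] = False
    return values, missing


def scale_features(raw: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Min-max scale each feature column to [0.1, 1] within the sample.

    ``raw``/``missing`` have shape (N, 2, 20, 3).  The affine map is fit
    per column over non-missing entries; zero-range columns map to 0.1;
    missing entries become exactly 0.
    """
    n = raw.shape[0]
    flat = raw.reshape(n, -1).astype(float)
    miss = missing.reshape(n, -1)
    out = np.zeros_like(flat)
    masked = np.where(miss, np.nan, flat)
    with np.errstate(invalid="ignore"):
        col_min = np.nanmin(masked, axis=0)
        col_max = np.nanmax(masked, axis=0)
    all_missing = miss.all(axis=0)
    if all_missing.any():
        logger.warning("%d feature columns have no data in this sample", int(all_missing.sum()))
    rng = col_max - col_min
    safe_rng = np.where(rng > 0, rng, 1.0)
    scaled = SCALED_MIN + (flat - col_min) / safe_rng * (SCALED_MAX - SCALED_MIN)
    scaled = np.where(rng > 0, scaled, SCALED_MIN)
    out = np.where(miss | all_missing[None, :], 0.0, scaled)
    return out.reshape(raw.shape)


@dataclass
class FeatureTensor:
    """Scaled per-promoter feature array aligned to a promoter catalog."""

    values: np.ndarray  # (N, 2, 20, 3), {0} union [0.1, 1]
    transcript_ids: np.ndarray
    sample_id: str = ""
    ordering: str = "transcriptional"
    scales: tuple = DEFAULT_SCALES


class PromoterFeaturizer(TransformerMixin, BaseEstimator):
    """Transform a per-CpG methylation table into the model's input tensor.

    Parameters
    ----------
    catalog : DataFrame
        Promoter catalog (``promact.catalog.build_catalog`` output).
    scales : tuple of int
        Window widths in bp; 20 windows per scale.
    ordering : {"transcriptional", "genomic"}
        Whether minus-strand window order is flipped so that index runs
        5'->3' along the transcript (default) or left-to-right on the
        genome.
    offset, cap, min_cov
        M-value pseudocount, odds clamp, and minimum read coverage.
    """

    def __init__(self, catalog=None, scales=DEFAULT_SCALES, ordering="transcriptional",
                 offset=0.5, cap=65.0, min_cov=5):
        self.catalog = catalog
        self.scales = scales
        self.ordering = ordering
        self.offset = offset
        self.cap = cap
        self.min_cov = min_cov

    def fit(self, X=None, y=None):
        if self.catalog is None or len(self.catalog) == 0:
            raise ValueError("a non-empty promoter catalog is required")
        self.transcript_ids_ = self.catalog["transcript_id"].to_numpy()
        return self

    def transform(self, X: pd.DataFrame, sample_id: str = "") -> FeatureTensor:
        """``X`` is a methylation table (chrom, pos, meth, unmeth)."""
        if not hasattr(self, "transcript_ids_"):
            self.fit()
        raw, missing = self.raw_features(X)
        values = scale_features(raw, missing)
        return FeatureTensor(
            values=values,
            transcript_ids=self.transcript_ids_,
            sample_id=sample_id,
            ordering=self.ordering,
            scales=tuple(self.scales),
        )

    def raw_features(self, X: pd.DataFrame):
        """Unscaled (N, 2, 20, 3) feature matrix plus its missing mask."""
        self.fit()
        mvals = compute_m_values(X, offset=self.offset, cap=self.cap, min_cov=self.min_cov)
        by_chrom = {}
        for chrom, sub in mvals.groupby("chrom", sort=False):
            sub = sub.sort_values("pos", kind="mergesort")
            by_chrom[chrom] = (sub["pos"].to_numpy(), sub["mval"].to_numpy())
        cat = self.catalog
        n = len(cat)
        n_scales = len(self.scales)
        raw = np.zeros((n, n_scales, N_WINDOWS, N_CHANNELS))
        missing = np.ones((n, n_scales, N_WINDOWS, N_CHANNELS), dtype=bool)
        chroms = cat["chrom"].to_numpy()
        strands = cat["strand"].to_numpy()
        tsss = cat["tss"].to_numpy()
        for i in range(n):
            entry = by_chrom.get(chroms[i])
            if entry is None:
                continue
            pos, mv = entry
            for s_idx, scale in enumerate(self.scales):
                grid = make_window_grid(int(tsss[i]), strands[i], scale, self.ordering)
                lo, hi = grid.min(), grid.max()
                a, b = np.searchsorted(pos, [lo, hi])
                vals, miss = summarize_windows(mv[a:b], pos[a:b], grid)
                raw[i, s_idx] = vals
                missing[i, s_idx] = miss
        return raw, missing
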