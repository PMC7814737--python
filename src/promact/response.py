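"""Per-promoter histone-modification enrichment from coverage tracks.

The response the model is trained against is, for each 2-kb promoter
region, ``HM_i = log2((sum ChIP_i + alpha) / (sum Input_i + alpha))``
where the sums are per-base signal over the region and ``alpha`` is the
25th percentile of the input sums across the catalog — a sample-level
pseudocount that stabilizes low-coverage promoters.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph (0-based half-open), plain or gzip."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith(("#", "track", "browser"))]
    from io import StringIO

    df = pd.read_csv(
        StringIO("".join(lines)), sep="\t", header=None,
        names=["chrom", "start", "end", "value"],
    )
    return df


def _validate_track(track: pd.DataFrame) -> dict:
    """Index a coverage track by chromosome; enforce sorted, disjoint intervals."""
    by_chrom = {}
    for chrom, sub in track.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts, kind="mergesort")
        starts, ends = starts[order], ends[order]
        vals = sub["value"].to_numpy()[order]
        if (ends <= starts).any():
            raise ValueError(f"empty or inverted interval on {chrom}")
        if (starts[1:] < ends[:-1]).any():
            raise ValueError(f"overlapping coverage intervals on {chrom}")
        by_chrom[chrom] = (starts, ends, vals)
    return by_chrom


def promoter_signal_sums(track: pd.DataFrame, catalog: pd.DataFrame) -> np.ndarray:
    """Sum of per-base signal over each catalog promoter region.

    Regions on chromosomes absent from the track contribute 0 (counted
    and logged).  Intervals are clipped to the region, so the sum is the
    integral of the step function over [start, end).
    """
    by_chrom = _validate_track(track)
    n = len(catalog)
    sums = np.zeros(n)
    n_uncovered = 0
    chroms = catalog["chrom"].to_numpy()
    starts = catalog["start"].to_numpy()
    ends = catalog["end"].to_numpy()
    for i in range(n):
        entry = by_chrom.get(chroms[i])
        if entry is None:
            n_uncovered += 1
            continue
        t_start, t_end, t_val = entry
        a = np.searchsorted(t_end, starts[i], side="right")
        b = np.searchsorted(t_start, ends[i], side="left")
        if a >= b:
            continue
        widths = np.minimum(t_end[a:b], ends[i]) - np.maximum(t_start[a:b], starts[i])
        sums[i] = float(np.dot(widths, t_val[a:b]))
    if n_uncovered:
        logger.info("%d promoter regions on chromosomes absent from the track", n_uncovered)
    return sums


@dataclass
class EnrichmentVector:
    """Per-promoter log2 ChIP/input enrichment for one mark in one sample."""

    values: np.ndarray
    transcript_ids: np.ndarray
    sample_id: str = ""
    mark: str = ""
    alpha: float = 0.0


def compute_enrichment(
    chip_sums: np.ndarray,
    input_sums: np.ndarray,
    transcript_ids: np.ndarray,
    sample_id: str = "",
    mark: str = "",
    depth_normalize: bool = False,
) -> EnrichmentVector:
    """log2 enrichment of ChIP over input with a percentile pseudocount.

    ``alpha`` is the 25th percentile (linear interpolation) of the input
    sums over all catalog promoters.  With ``depth_normalize`` the input
    sums are rescaled by total ChIP depth / total input depth first, for
    tracks that are raw counts at unequal sequencing depths.
    """
    chip_sums = np.asarray(chip_sums, dtype=float)
    input_sums = np.asarray(input_sums, dtype=float)
    if chip_sums.shape != input_sums.shape:
        raise ValueError("chip and input sums are not aligned")
    if depth_normalize and input_sums.sum() > 0:
        input_sums = input_sums * (chip_sums.sum() / input_sums.sum())
    alpha = float(np.percentile(input_sums, 25))
    if alpha == 0.0 and (input_sums == 0).any():
        raise ValueError("alpha is 0 with zero input sums present; enrichment undefined")
    values = np.log2((chip_sums + alpha) / (input_sums + alpha))
    return EnrichmentVector(
        values=values,
        transcript_ids=np.asarray(transcript_ids),
        sample_id=sample_id,
        mark=mark,
        alpha=alpha,
    )


def write_enrichment(vec: EnrichmentVector, path) -> None:
    with open(path, "wt") as fh:
        fh.write(f"# sample_id={vec.sample_id} mark={vec.mark} alpha={vec.alpha!r}\n")
        pd.DataFrame({"transcript_id": vec.transcript_ids, "hm": vec.values}).to_csv(
            fh, sep="\t", index=False
        )


def read_enrichment(path) -> EnrichmentVector:
    with open(path, "rt") as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=", 1) for kv in header)
        df = pd.read_csv(fh, sep="\t")
    return EnrichmentVector(
        values=df["hm"].to_numpy(),
        transcript_ids=df["transcript_id"].to_numpy(),
        sample_id=meta.get("sample_id", ""),
        mark=meta.get("mark", ""),
        alpha=float(meta.get("alpha", 0.0)),
    )
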