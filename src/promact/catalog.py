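"""Promoter catalogs from transcript annotation.

A promoter is the 2-kb interval centered on a transcription start site
(TSS).  Two catalogs are supported:

``deduped``
    Unique-TSS promoters with sex chromosomes removed and same-strand
    regions sharing >= 50% of their span collapsed to one representative.
    This is the catalog used for model training and evaluation, where
    near-identical regions in train and test would leak information.
``all_protein_coding``
    Every autosomal protein-coding promoter, without overlap collapsing;
    used for gene-level expression comparisons where each gene is later
    summarized by its most active promoter.

Coordinates are 0-based half-open internally; GTF input is 1-based
inclusive.  The TSS of a minus-strand transcript is the annotated *end*
coordinate.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROMOTER_HALF_WIDTH = 1000
PROMOTER_WIDTH = 2 * PROMOTER_HALF_WIDTH
#: minimum shared span (bp) for two same-strand promoters to count as overlapping
OVERLAP_BP = PROMOTER_WIDTH // 2

_PRIMARY_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}
_SEX_CHROMS = {"X", "Y"}

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GTFParseError(ValueError):
    """Raised for a structurally malformed GTF line (names the line number)."""


def _chrom_key(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _open_text(source) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    if str(source).endswith(".gz"):
        return gzip.open(source, "rt")
    return open(source, "rt")


def parse_annotation(source, gene_types: Iterable[str] | None = None) -> pd.DataFrame:
    """Extract one TSS record per transcript from a GTF stream.

    Parameters
    ----------
    source
        Path (plain or ``.gz``) or open text handle of a GTF file.
    gene_types
        Optional whitelist of ``gene_type`` values (e.g. ``["protein_coding"]``).

    Returns
    -------
    DataFrame with columns ``transcript_id, gene_id, gene_type, chrom,
    strand, tss`` (0-based), one row per transcript.  Transcripts sharing
    (chrom, strand, tss) are collapsed to the lexicographically smallest
    transcript_id.  Non-primary contigs and records missing required
    attributes are skipped with a logged count.
    """
    wanted = set(gene_types) if gene_types is not None else None
    rows = []
    n_skipped_attr = 0
    n_skipped_contig = 0
    handle = _open_text(source)
    for lineno, line in enumerate(handle, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise GTFParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
        if feature != "transcript":
            continue
        try:
            start = int(start_s)
            end = int(end_s)
        except ValueError as exc:
            raise GTFParseError(f"line {lineno}: non-integer coordinates") from exc
        if strand not in ("+", "-"):
            raise GTFParseError(f"line {lineno}: bad strand {strand!r}")
        if _chrom_key(chrom) not in _PRIMARY_CHROMS:
            n_skipped_contig += 1
            continue
        attr = dict(_ATTR_RE.findall(attrs))
        tid = attr.get("transcript_id")
        gid = attr.get("gene_id")
        if not tid or not gid:
            n_skipped_attr += 1
            continue
        gtype = attr.get("gene_type", attr.get("gene_biotype", ""))
        if wanted is not None and gtype not in wanted:
            continue
        # GTF is 1-based inclusive; TSS is the first transcribed base.
        tss = start - 1 if strand == "+" else end - 1
        rows.append((tid, gid, gtype, chrom, strand, tss))
    if n_skipped_attr:
        logger.warning("skipped %d records missing transcript_id/gene_id", n_skipped_attr)
    if n_skipped_contig:
        logger.info("skipped %d records on non-primary contigs", n_skipped_contig)
    df = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "gene_type", "chrom", "strand", "tss"])
    if df.empty:
        return df
    # collapse duplicate TSS positions, keeping the smallest transcript_id
    df = df.sort_values(["chrom", "strand", "tss", "transcript_id"], kind="mergesort")
    df = df.drop_duplicates(subset=["chrom", "strand", "tss"], keep="first")
    return df.reset_index(drop=True)


def build_catalog(tss_table: pd.DataFrame, mode: str = "deduped") -> pd.DataFrame:
    """Build the promoter-region catalog from a TSS table.

    ``deduped`` mode removes chrX/chrY, sorts by (chrom, start), and runs a
    greedy left-to-right scan retaining a region unless it shares >= 1000 bp
    with an already-retained region *on the same strand*; opposite-strand
    overlap never removes a region.  ``all_protein_coding`` keeps every
    autosomal protein-coding promoter with no overlap collapsing.
    """
    if mode not in ("deduped", "all_protein_coding"):
        raise ValueError(f"unknown catalog mode {mode!r}")
    if tss_table.empty:
        logger.warning("empty TSS table; returning empty catalog")
        return _empty_catalog(mode)

    df = tss_table.copy()
    df["start"] = df["tss"] - PROMOTER_HALF_WIDTH
    df["end"] = df["tss"] + PROMOTER_HALF_WIDTH
    df["_ckey"] = df["chrom"].map(_chrom_key)

    if mode == "all_protein_coding":
        keep = (df["gene_type"] == "protein_coding") & ~df["_ckey"].isin(_SEX_CHROMS)
        out = df.loc[keep]
    else:
        df = df.loc[~df["_ckey"].isin(_SEX_CHROMS)]
        df = df.sort_values(["chrom", "start", "transcript_id"], kind="mergesort")
        retained = np.zeros(len(df), dtype=bool)
        # most recent retained end per (chrom, strand); regions are equal
        # width so only the latest retained region can overlap the next one
        last_end: dict[tuple[str, str], int] = {}
        chroms = df["chrom"].to_numpy()
        strands = df["strand"].to_numpy()
        starts = df["start"].to_numpy()
        ends = df["end"].to_numpy()
        for i in range(len(df)):
            key = (chroms[i], strands[i])
            prev_end = last_end.get(key)
            overlap = 0 if prev_end is None else prev_end - starts[i]
            if overlap < OVERLAP_BP:
                retained[i] = True
                last_end[key] = ends[i]
        out = df.loc[retained]
        n_dropped = len(df) - int(retained.sum())
        if n_dropped:
            logger.info("dedup removed %d overlapping same-strand promoters", n_dropped)

    out = out.drop(columns="_ckey").sort_values(["chrom", "start", "transcript_id"], kind="mergesort")
    out = out.reset_index(drop=True)
    out["catalog_mode"] = mode
    if out.empty:
        logger.warning("catalog is empty after filtering")
    return out[["transcript_id", "gene_id", "gene_type", "chrom", "strand", "start", "end", "tss", "catalog_mode"]]


def _empty_catalog(mode: str) -> pd.DataFrame:
    return pd.DataFrame(
        columns=["transcript_id", "gene_id", "gene_type", "chrom", "strand", "start", "end", "tss", "catalog_mode"]
    )


def write_catalog(catalog: pd.DataFrame, bed_path, sidecar_path=None) -> None:
    """Write the catalog as BED6 plus a TSV sidecar with gene metadata."""
    bed = catalog[["chrom", "start", "end", "transcript_id"]].copy()
    bed["score"] = 0
    bed["strand"] = catalog["strand"]
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    if sidecar_path is not None:
        catalog[["transcript_id", "gene_id", "gene_type", "catalog_mode"]].to_csv(
            sidecar_path, sep="\t", index=False
        )


def read_catalog(bed_path, sidecar_path) -> pd.DataFrame:
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start", "end", "transcript_id", "score", "strand"],
    )
    side = pd.read_csv(sidecar_path, sep="\t")
    df = bed.merge(side, on="transcript_id")
    df["tss"] = df["start"] + PROMOTER_HALF_WIDTH
    return df[["transcript_id", "gene_id", "gene_type", "chrom", "strand", "start", "end", "tss", "catalog_mode"]]
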