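"""Synthetic annotation, methylomes, and ChIP coverage with planted truth.

The generator emulates the data a promoter-activity study observes:

* a transcript annotation whose promoters are far enough apart that
  their 25-kb feature neighborhoods are independent;
* a per-CpG methylation table in which active promoters carry a deep
  hypomethylated canyon around the TSS, poised promoters a shallow one,
  and inactive promoters uniformly high methylation, with beta noise on
  per-site methylation levels, negative-binomial read coverage, and
  binomial methylated-read counts;
* ChIP and input coverage tracks constructed so that recomputing the
  log2 enrichment from the tracks recovers the planted per-state
  enrichment target plus Gaussian noise (the generator verifies this by
  calling the response module itself);
* an expression table on an exponential scale of the planted H3K27ac
  enrichment.

A cohort shares a configurable fraction of promoter states across
samples; an optional domain shift distorts the methylation profiles and
replaces the state-to-enrichment map to emulate a new tumor type for
transfer-learning experiments.  Everything is deterministic under the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import catalog as _catalog
from . import response as _response

STATES = ("active", "poised", "inactive")


@dataclass
class SimConfig:
    """All knobs of the generator; nothing else is hard-coded."""

    n_promoters: int = 2000
    spacing: int = 52_000  # >= 2000 + 2 * 25000 keeps feature windows independent
    chrom: str = "chr1"
    first_tss: int = 30_000
    state_priors: dict = field(
        default_factory=lambda: {"active": 0.3, "poised": 0.2, "inactive": 0.5}
    )
    # spatial methylation profile: p(d) = flank - depth * exp(-(d / width)^2)
    flank_level: float = 0.85
    canyon_depth: dict = field(
        default_factory=lambda: {"active": 0.80, "poised": 0.50, "inactive": 0.0}
    )
    canyon_width: dict = field(
        default_factory=lambda: {"active": 1000.0, "poised": 600.0, "inactive": 800.0}
    )
    beta_concentration: float = 30.0  # per-site noise; larger = tighter
    # CpG density (per bp): dense within +/- near_span of the TSS
    cpg_rate_near: float = 0.05
    cpg_rate_far: float = 1.0 / 150.0
    near_span: int = 1000
    far_span: int = 25_000
    # read counts
    coverage_mean: float = 30.0
    coverage_dispersion: float = 10.0
    # ChIP/input tracks
    input_depth: float = 1.0
    input_noise_cv: float = 0.05
    enrichment_map: dict = field(
        default_factory=lambda: {
            "H3K27ac": {"active": 3.0, "poised": 0.0, "inactive": -1.0},
            "H3K4me3": {"active": 3.0, "poised": 2.0, "inactive": -1.0},
        }
    )
    enrichment_noise_sd: float = 0.3
    # expression
    expression_noise_sd: float = 0.25
    # domain shift (new tumor type): profile distortion + new enrichment map
    shift_depth_scale: float = 0.85
    shift_width_scale: float = 0.8
    shift_enrichment_map: dict = field(
        default_factory=lambda: {
            "H3K27ac": {"active": 1.5, "poised": 1.5, "inactive": -0.9},
            "H3K4me3": {"active": 2.0, "poised": 2.0, "inactive": -0.9},
        }
    )
    seed: int = 0


@dataclass
class SimSample:
    """One synthetic sample: inputs for the pipeline plus planted truth."""

    sample_id: str
    annotation: pd.DataFrame  # transcript table (also writable as GTF)
    catalog: pd.DataFrame
    methylation: pd.DataFrame  # chrom, pos, meth, unmeth
    chip_tracks: dict  # mark -> bedGraph-like DataFrame
    input_track: pd.DataFrame
    truth: pd.DataFrame  # transcript_id, state, hm_<mark>, fpkm


# ----------------------------------------------------------------------
def simulate_annotation(config: SimConfig) -> pd.DataFrame:
    """Transcript table with alternating strands on one chromosome."""
    n = config.n_promoters
    idx = np.arange(n)
    tss = config.first_tss + idx * config.spacing
    strand = np.where(idx % 2 == 0, "+", "-")
    return pd.DataFrame(
        {
            "transcript_id": [f"T{i:05d}" for i in idx],
            "gene_id": [f"G{i:05d}" for i in idx],
            "gene_type": "protein_coding",
            "chrom": config.chrom,
            "strand": strand,
            "tss": tss,
        }
    )


def annotation_to_gtf(annotation: pd.DataFrame, path, transcript_length: int = 1500) -> None:
    """Write the transcript table as a minimal GTF (1-based inclusive)."""
    with open(path, "wt") as fh:
        for row in annotation.itertuples(index=False):
            if row.strand == "+":
                start = row.tss + 1
                end = row.tss + transcript_length
            else:
                end = row.tss + 1
                start = max(1, end - transcript_length + 1)
            attrs = (
                f'gene_id "{row.gene_id}"; transcript_id "{row.transcript_id}"; '
                f'gene_type "{row.gene_type}";'
            )
            fh.write(
                f"{row.chrom}\tsim\ttranscript\t{start}\t{end}\t.\t{row.strand}\t.\t{attrs}\n"
            )


def draw_states(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    priors = np.array([config.state_priors[s] for s in STATES])
    priors = priors / priors.sum()
    return rng.choice(np.array(STATES), size=config.n_promoters, p=priors)


# ----------------------------------------------------------------------
def _profile(dist: np.ndarray, state: str, config: SimConfig, shifted: bool) -> np.ndarray:
    depth = config.canyon_depth[state]
    width = config.canyon_width[state]
    if shifted:
        depth *= config.shift_depth_scale
        width *= config.shift_width_scale
    p = config.flank_level - depth * np.exp(-((dist / width) ** 2))
    return np.clip(p, 0.01, 0.99)


def simulate_methylome(
    config: SimConfig,
    annotation: pd.DataFrame,
    states: np.ndarray,
    rng: np.random.Generator,
    shifted: bool = False,
) -> pd.DataFrame:
    """Per-CpG methylation counts with state-dependent spatial profiles."""
    chroms, positions, meths, unmeths = [], [], [], []
    tss_arr = annotation["tss"].to_numpy()
    for i in range(len(annotation)):
        tss = int(tss_arr[i])
        state = states[i]
        # CpG positions: dense near the TSS, sparse in the 25-kb flanks
        n_near = rng.poisson(config.cpg_rate_near * 2 * config.near_span)
        n_far = rng.poisson(config.cpg_rate_far * 2 * (config.far_span - config.near_span))
        near = rng.integers(tss - config.near_span, tss + config.near_span, size=n_near)
        far_off = rng.integers(config.near_span, config.far_span, size=n_far)
        far_sign = rng.choice([-1, 1], size=n_far)
        far = tss + far_sign * far_off
        pos = np.unique(np.concatenate([near, far]))
        pos = pos[pos >= 0]
        if pos.size == 0:
            continue
        p_mean = _profile(pos - tss, state, config, shifted)
        k = config.beta_concentration
        p_site = rng.beta(np.maximum(p_mean * k, 1e-3), np.maximum((1 - p_mean) * k, 1e-3))
        r = config.coverage_dispersion
        cov = rng.negative_binomial(r, r / (r + config.coverage_mean), size=pos.size)
        meth = rng.binomial(cov, p_site)
        chroms.append(np.full(pos.size, config.chrom, dtype=object))
        positions.append(pos)
        meths.append(meth)
        unmeths.append(cov - meth)
    return pd.DataFrame(
        {
            "chrom": np.concatenate(chroms),
            "pos": np.concatenate(positions),
            "meth": np.concatenate(meths),
            "unmeth": np.concatenate(unmeths),
        }
    )


# ----------------------------------------------------------------------
def simulate_chip(
    config: SimConfig,
    cat: pd.DataFrame,
    states: np.ndarray,
    rng: np.random.Generator,
    shifted: bool = False,
):
    """Input and per-mark ChIP tracks whose recomputed enrichment equals
    the state target plus Gaussian noise (clipped at zero ChIP signal).

    Returns ``(input_track, chip_tracks, truth_hm)`` where ``truth_hm``
    maps mark -> the enrichment recomputed from the emitted tracks via
    the response module (exact self-consistency by construction).
    """
    width = (cat["end"] - cat["start"]).to_numpy()
    n = len(cat)
    if config.input_noise_cv > 0:
        cv2 = config.input_noise_cv ** 2
        level = config.input_depth * rng.gamma(1.0 / cv2, cv2, size=n)
    else:
        level = np.full(n, config.input_depth)
    input_sums = level * width
    alpha = float(np.percentile(input_sums, 25))

    gmap = config.shift_enrichment_map if shifted else config.enrichment_map
    chip_tracks = {}
    truth_hm = {}
    base = cat[["chrom", "start", "end"]].reset_index(drop=True)
    input_track = base.copy()
    input_track["value"] = level
    for mark, state_map in gmap.items():
        target = np.array([state_map[s] for s in states], dtype=float)
        if config.enrichment_noise_sd > 0:
            target = target + rng.normal(0.0, config.enrichment_noise_sd, size=n)
        chip_sums = np.maximum((input_sums + alpha) * 2.0 ** target - alpha, 0.0)
        track = base.copy()
        track["value"] = chip_sums / width
        chip_tracks[mark] = track
        # self-consistency: planted truth is the enrichment the pipeline recovers
        rec_chip = _response.promoter_signal_sums(track, cat)
        rec_input = _response.promoter_signal_sums(input_track, cat)
        vec = _response.compute_enrichment(
            rec_chip, rec_input, cat["transcript_id"].to_numpy(), mark=mark
        )
        truth_hm[mark] = vec.values
    return input_track, chip_tracks, truth_hm


def simulate_expression(
    config: SimConfig, truth_k27: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """FPKM as an exponential-scale transform of true H3K27ac enrichment."""
    noise = rng.normal(0.0, config.expression_noise_sd, size=truth_k27.size)
    return np.maximum(2.0 ** (truth_k27 + noise) - 1.0, 0.0)


# ----------------------------------------------------------------------
def simulate_sample(
    config: SimConfig,
    annotation: pd.DataFrame,
    states: np.ndarray,
    rng: np.random.Generator,
    sample_id: str = "S0",
    shifted: bool = False,
) -> SimSample:
    cat = _catalog.build_catalog(annotation.assign(gene_type="protein_coding"), mode="deduped")
    # align states to the catalog (dedup may drop promoters)
    state_by_tid = pd.Series(states, index=annotation["transcript_id"])
    cat_states = state_by_tid.loc[cat["transcript_id"]].to_numpy()
    methylation = simulate_methylome(config, cat, cat_states, rng, shifted=shifted)
    input_track, chip_tracks, truth_hm = simulate_chip(config, cat, cat_states, rng, shifted=shifted)
    fpkm = simulate_expression(config, truth_hm.get("H3K27ac", np.zeros(len(cat))), rng)
    truth = pd.DataFrame(
        {
            "transcript_id": cat["transcript_id"].to_numpy(),
            "gene_id": cat["gene_id"].to_numpy(),
            "state": cat_states,
            "fpkm": fpkm,
        }
    )
    for mark, hm in truth_hm.items():
        truth[f"hm_{mark}"] = hm
    return SimSample(
        sample_id=sample_id,
        annotation=annotation,
        catalog=cat,
        methylation=methylation,
        chip_tracks=chip_tracks,
        input_track=input_track,
        truth=truth,
    )


def simulate_cohort(
    config: SimConfig,
    n_samples: int,
    shared_fraction: float = 1.0,
    domain_shift: bool = False,
    seed: int | None = None,
) -> list[SimSample]:
    """Samples sharing a fraction of promoter states.

    A ``shared_fraction`` of promoters keep one cohort-wide state; the
    remainder re-draw a state per sample.  With ``domain_shift`` the
    methylation profiles are distorted and the shifted enrichment map
    is used, emulating a new tumor type.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    seqs = root.spawn(n_samples + 1)
    rng0 = np.random.default_rng(seqs[0])
    annotation = simulate_annotation(config)
    shared_states = draw_states(config, rng0)
    is_shared = rng0.random(config.n_promoters) < shared_fraction
    samples = []
    for s in range(n_samples):
        rng = np.random.default_rng(seqs[s + 1])
        states = draw_states(config, rng)
        states[is_shared] = shared_states[is_shared]
        samples.append(
            simulate_sample(
                config, annotation, states, rng,
                sample_id=f"{'D' if domain_shift else 'S'}{s}",
                shifted=domain_shift,
            )
        )
    return samples


# ----------------------------------------------------------------------
def write_sample(sample: SimSample, outdir) -> dict:
    """Write a sample's files (GTF, methylation TSV, bedGraphs, truth TSV)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    gtf = outdir / f"{sample.sample_id}.annotation.gtf"
    annotation_to_gtf(sample.annotation, gtf)
    paths["annotation"] = gtf
    meth = outdir / f"{sample.sample_id}.methylation.tsv"
    out = sample.methylation.copy()
    out["pos"] = out["pos"] + 1  # methylation TSV convention is 1-based
    out.to_csv(meth, sep="\t", header=False, index=False)
    paths["methylation"] = meth
    inp = outdir / f"{sample.sample_id}.input.bedGraph"
    sample.input_track.to_csv(inp, sep="\t", header=False, index=False)
    paths["input"] = inp
    for mark, track in sample.chip_tracks.items():
        p = outdir / f"{sample.sample_id}.{mark}.bedGraph"
        track.to_csv(p, sep="\t", header=False, index=False)
        paths[mark] = p
    truth = outdir / f"{sample.sample_id}.truth.tsv"
    sample.truth.to_csv(truth, sep="\t", index=False)
    paths["truth"] = truth
    return paths
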