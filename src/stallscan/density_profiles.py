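"""Metagene density profiles in 61-nt windows around codon occurrences.

Every in-frame occurrence of a query codon whose +-30 nt window fits inside
the CDS defines a codon-region; 5'-end counts of footprints are collected
per position, normalised so each region has mean density 1 (total/61 per
position), smoothed with a width-3 rectangular kernel of height 1/3, and
averaged across regions. The elementwise difference of the two samples'
mean profiles is the density shift; a stalled codon shows a peak at the
position where A-site-decoding footprints place their 5' ends (offset
-a_site_offset from the codon's first nucleotide).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import is_sense
from .rpf_io import GeneAnnotation

logger = logging.getLogger(__name__)

WINDOW = 61
FLANK = 30  # window = FLANK + codon first nt + FLANK
DEFAULT_MIN_REGION_COUNT = 50
DEFAULT_MIN_WINDOWS_COMMON = 1000
THRESHOLD_FLOOR = 10
THRESHOLD_STEP = 10


@dataclass
class CodonRegion:
    """A 61-nt window centred on one in-frame occurrence of a codon."""

    region_id: str
    gene_id: str
    transcript_id: str
    codon: str
    codon_pos: int  # CDS coordinate of the codon's first nucleotide
    start: int  # window start in CDS coordinates (codon_pos - FLANK)
    genomic_key: tuple  # (seqname, strand, genomic position of codon start)


@dataclass
class RegionProfiles:
    """Per-region raw/normalised/smoothed density matrices for one sample."""

    codon: str
    region_ids: list[str]
    raw_counts: np.ndarray  # (n_regions, 61)
    normalized: np.ndarray
    smoothed: np.ndarray
    threshold_used: int
    threshold_schedule: list[int] = field(default_factory=list)


@dataclass
class DensityShiftResult:
    codon: str
    mean_condition: np.ndarray  # (61,)
    mean_control: np.ndarray
    density_shift: np.ndarray  # condition - control, elementwise
    n_regions_used: int


def extract_codon_regions(
    annotation: list[GeneAnnotation],
    sequences: dict[str, str],
    codon: str,
) -> list[CodonRegion]:
    """All in-frame occurrences of ``codon`` with a full 61-nt window.

    Occurrences whose window would extend past either CDS end are excluded.
    Regions from different transcripts that map to identical genomic
    coordinates are collapsed to one; overlapping-but-distinct regions are
    all retained. ``sequences`` are reference sequences keyed by seqname
    (for synthetic transcript-space data, the transcript FASTA).
    """
    codon = codon.upper()
    if not is_sense(codon):
        raise ValueError(f"{codon!r} is not a sense codon")
    regions: list[CodonRegion] = []
    seen: set[tuple] = set()
    for ann in annotation:
        cds = ann.cds_sequence(sequences)
        n = len(cds)
        for pos in range(0, n - 2, 3):
            if cds[pos : pos + 3] != codon:
                continue
            start = pos - FLANK
            if start < 0 or start + WINDOW > n:
                continue
            key = (ann.seqname, ann.strand, ann.unproject(pos))
            if key in seen:
                continue
            seen.add(key)
            regions.append(
                CodonRegion(
                    region_id=f"{ann.transcript_id}:{pos}",
                    gene_id=ann.gene_id,
                    transcript_id=ann.transcript_id,
                    codon=codon,
                    codon_pos=pos,
                    start=start,
                    genomic_key=key,
                )
            )
    return regions


def _region_count_matrix(rpfs: pd.DataFrame, regions: list[CodonRegion]) -> np.ndarray:
    """5'-end counts per window position, one row per region."""
    match_col = "transcript_id" if "transcript_id" in rpfs.columns else "gene_id"
    out = np.zeros((len(regions), WINDOW), dtype=np.int64)
    if rpfs.empty or not regions:
        return out
    per_key: dict[str, np.ndarray] = {}
    for key, sub in rpfs.groupby(match_col):
        pos = sub["cds_relative_5p"].to_numpy()
        pos = pos[pos >= 0]
        per_key[key] = np.bincount(pos) if pos.size else np.zeros(1, dtype=np.int64)
    for i, region in enumerate(regions):
        key = region.transcript_id if match_col == "transcript_id" else region.gene_id
        vec = per_key.get(key)
        if vec is None:
            continue
        a, b = region.start, region.start + WINDOW
        sl = vec[max(a, 0) : min(b, vec.size)]
        out[i, max(a, 0) - a : max(a, 0) - a + sl.size] = sl
    return out


def smooth_profile(x: np.ndarray) -> np.ndarray:
    """Width-3, height-1/3 rectangular smoothing with edge replication.

    Edges reuse their own value for the missing neighbour, which makes the
    kernel exactly mean-preserving over the window.
    """
    x = np.asarray(x, dtype=float)
    padded = np.concatenate([x[..., :1], x, x[..., -1:]], axis=-1)
    return (padded[..., :-2] + padded[..., 1:-1] + padded[..., 2:]) / 3.0


def profile_regions(
    rpfs_by_sample: dict[str, pd.DataFrame],
    regions: list[CodonRegion],
    min_region_count: int = DEFAULT_MIN_REGION_COUNT,
    min_windows_common: int = DEFAULT_MIN_WINDOWS_COMMON,
) -> dict[str, RegionProfiles]:
    """Jointly filter, normalise and smooth codon-region profiles per sample.

    A region survives only if its total 5'-end count reaches the threshold in
    *every* sample. If fewer than ``min_windows_common`` regions survive for
    a codon that has more candidate regions available, the threshold is
    lowered stepwise (e.g. 50 -> 40 -> 30 -> 20 -> 10) until enough regions
    survive or the floor of 10 is reached; the schedule actually walked is
    recorded on the result.
    """
    if not regions:
        raise ValueError("no candidate codon-regions supplied")
    codon = regions[0].codon
    counts = {s: _region_count_matrix(df, regions) for s, df in rpfs_by_sample.items()}
    totals = {s: m.sum(axis=1) for s, m in counts.items()}

    schedule = []
    thr = min_region_count
    while True:
        schedule.append(thr)
        kept = np.ones(len(regions), dtype=bool)
        for tot in totals.values():
            kept &= tot >= thr
        n_kept = int(kept.sum())
        if n_kept >= min_windows_common or thr - THRESHOLD_STEP < THRESHOLD_FLOOR:
            break
        if n_kept >= len(regions):
            break
        thr -= THRESHOLD_STEP
    if n_kept == 0:
        raise ValueError(
            f"no codon-region for {codon} reaches {schedule[-1]} counts in all "
            f"samples (schedule tried: {schedule})"
        )
    logger.info(
        "codon %s: kept %d/%d regions at threshold %d", codon, n_kept, len(regions), thr
    )

    kept_idx = np.flatnonzero(kept)
    kept_ids = [regions[i].region_id for i in kept_idx]
    out: dict[str, RegionProfiles] = {}
    for sample, mat in counts.items():
        raw = mat[kept_idx]
        tot = raw.sum(axis=1, keepdims=True).astype(float)
        normalized = raw / (tot / WINDOW)
        smoothed = smooth_profile(normalized)
        out[sample] = RegionProfiles(
            codon=codon,
            region_ids=kept_ids,
            raw_counts=raw,
            normalized=normalized,
            smoothed=smoothed,
            threshold_used=thr,
            threshold_schedule=schedule,
        )
    return out


def density_shift(
    profiles_condition: RegionProfiles, profiles_control: RegionProfiles
) -> DensityShiftResult:
    """Difference of cross-region mean smoothed densities (condition - control)."""
    if profiles_condition.region_ids != profiles_control.region_ids:
        raise ValueError("region sets differ between samples; joint filter required")
    mean_c = profiles_condition.smoothed.mean(axis=0)
    mean_k = profiles_control.smoothed.mean(axis=0)
    return DensityShiftResult(
        codon=profiles_condition.codon,
        mean_condition=mean_c,
        mean_control=mean_k,
        density_shift=mean_c - mean_k,
        n_regions_used=len(profiles_condition.region_ids),
    )


def write_profile_matrix(profiles: RegionProfiles, path) -> None:
    df = pd.DataFrame(
        profiles.smoothed,
        index=pd.Index(profiles.region_ids, name="region_id"),
        columns=[f"pos{p:+d}" for p in range(-FLANK, FLANK + 1)],
    )
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_density_shift(result: DensityShiftResult, path) -> None:
    df = pd.DataFrame(
        {
            "position": np.arange(-FLANK, FLANK + 1),
            "mean_condition": result.mean_condition,
            "mean_control": result.mean_control,
            "density_shift": result.density_shift,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
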