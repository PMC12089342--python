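"""Synthetic transcriptomes and ribosome-footprint libraries with known stalling.

The generator emulates the data a ribosome-profiling (Ribo-seq) experiment
produces after alignment: 20-34 nt ribosome-protected fragments (RPFs) whose
5' ends sit a fixed offset upstream of the codon being decoded in the
ribosomal A site (15 nt here; 12 nt for the P site). Elevated dwell time at
user-chosen codons — the signature of a limiting amino acid — is modelled as
a per-codon multiplier on the probability that a footprint's A site occupies
that codon.

Sampling model, per read:

1. choose a transcript with probability proportional to its expression weight;
2. choose an A-site codon within that CDS with probability proportional to
   its dwell multiplier (uniform base dwell), restricted to codons far enough
   from both CDS ends that no read can overhang;
3. place the 5' end ``a_site_offset`` nt upstream, displaced by +-1 nt with
   probability ``offset_jitter_prob`` (split evenly) to mimic imperfect
   nuclease trimming;
4. draw the read length from the configured length distribution.

Because A-site candidates are kept clear of the CDS ends, the per-codon
A-site probability has an exact closed form (`analytic_asite_distribution`),
which downstream tests use as the ground-truth oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import (
    SENSE_CODONS,
    STOP_CODONS,
    codon_ids_per_position,
    decode_codon,
    encode_codon,
    encode_sequence,
)

MIN_READ_LEN = 20
MAX_READ_LEN = 34
MIN_CDS_LEN = 90


def default_read_length_distribution() -> dict[int, float]:
    """Triangular length distribution over 20-34 nt with mode 30 nt."""
    lengths = np.arange(MIN_READ_LEN, MAX_READ_LEN + 1)
    w = np.where(lengths <= 30, lengths - 19.0, 11.0 * (35.0 - lengths) / 5.0)
    w /= w.sum()
    return {int(l): float(p) for l, p in zip(lengths, w)}


@dataclass
class TranscriptModel:
    """A single-isoform protein-coding transcript (sequence == CDS)."""

    transcript_id: str
    cds_sequence: str
    expression_weight: float = 1.0
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            self.gene_id = self.transcript_id
        seq = self.cds_sequence.upper()
        self.cds_sequence = seq
        n = len(seq)
        if n < MIN_CDS_LEN or n % 3:
            raise ValueError(
                f"{self.transcript_id}: CDS must be >= {MIN_CDS_LEN} nt and a "
                f"multiple of 3, got {n}"
            )
        if seq[:3] != "ATG":
            raise ValueError(f"{self.transcript_id}: CDS must start with ATG")
        if seq[-3:] not in STOP_CODONS:
            raise ValueError(f"{self.transcript_id}: CDS must end with a stop codon")
        internal = {seq[i : i + 3] for i in range(3, n - 3, 3)}
        if internal & STOP_CODONS:
            raise ValueError(f"{self.transcript_id}: internal stop codon in frame 0")
        if not self.expression_weight > 0:
            raise ValueError(f"{self.transcript_id}: expression_weight must be > 0")

    def __len__(self) -> int:
        return len(self.cds_sequence)


@dataclass
class StallingProfile:
    """Per-codon dwell-time multipliers; 1.0 everywhere = no stalling."""

    dwell_multiplier: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for codon, mult in self.dwell_multiplier.items():
            c = codon.upper()
            if c not in SENSE_CODONS:
                raise ValueError(f"not a sense codon: {codon!r}")
            if not mult > 0:
                raise ValueError(f"dwell multiplier for {c} must be > 0, got {mult}")
            clean[c] = float(mult)
        self.dwell_multiplier = clean

    def as_array(self) -> np.ndarray:
        """Dwell multipliers indexed by codon id; stop codons get 0."""
        arr = np.ones(64)
        for stop in STOP_CODONS:
            arr[encode_codon(stop)] = 0.0
        for codon, mult in self.dwell_multiplier.items():
            arr[encode_codon(codon)] = mult
        return arr


@dataclass
class SimulationConfig:
    n_reads: int = 100_000
    seed: int = 0
    read_length_distribution: dict[int, float] = field(
        default_factory=default_read_length_distribution
    )
    a_site_offset: int = 15
    offset_jitter_prob: float = 0.0
    ligation_bias: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        lengths = sorted(self.read_length_distribution)
        if not lengths:
            raise ValueError("read_length_distribution is empty")
        if lengths[0] < MIN_READ_LEN or lengths[-1] > MAX_READ_LEN:
            raise ValueError(
                f"read lengths must lie in [{MIN_READ_LEN}, {MAX_READ_LEN}] nt"
            )
        total = sum(self.read_length_distribution.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"read-length probabilities sum to {total}, not 1")
        if not 0.0 <= self.offset_jitter_prob <= 1.0:
            raise ValueError("offset_jitter_prob must be in [0, 1]")

    @property
    def max_read_length(self) -> int:
        return max(self.read_length_distribution)

    def bias_array(self) -> np.ndarray:
        arr = np.ones(64)
        if self.ligation_bias:
            for codon, b in self.ligation_bias.items():
                if not b > 0:
                    raise ValueError(f"ligation bias for {codon} must be > 0")
                arr[encode_codon(codon)] = float(b)
        return arr


# ---------------------------------------------------------------------------
# Transcriptome generation
# ---------------------------------------------------------------------------

def generate_transcriptome(
    n_genes: int,
    length_range: tuple[int, int] = (300, 1800),
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> list[TranscriptModel]:
    """Random protein-coding transcripts with a target GC content.

    Lengths are drawn uniformly from ``length_range`` and snapped down to a
    multiple of 3 (>= 90 nt). Internal codons are built from bases sampled
    i.i.d. at the requested GC fraction, rejecting stop codons in frame;
    every CDS starts with ATG and ends with a stop codon. Expression weights
    are log-normal (sigma = 1), a realistic bulk mRNA abundance spread.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < MIN_CDS_LEN:
        raise ValueError(f"length_range minimum must be >= {MIN_CDS_LEN} nt")
    if hi < lo:
        raise ValueError("length_range must be (min, max) with min <= max")
    if (lo // 3) * 3 < MIN_CDS_LEN:
        raise ValueError("length_range collapses below 90 nt after snapping to codons")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    base_p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    stop_ids = {encode_codon(c) for c in STOP_CODONS}
    bases = np.array(list("ACGT"))
    width = len(str(n_genes))

    transcripts: list[TranscriptModel] = []
    for i in range(n_genes):
        length = (int(rng.integers(lo, hi + 1)) // 3) * 3
        n_internal = length // 3 - 2
        codons = rng.choice(4, size=(n_internal, 3), p=base_p)
        ids = 16 * codons[:, 0] + 4 * codons[:, 1] + codons[:, 2]
        while True:
            bad = np.isin(ids, list(stop_ids))
            if not bad.any():
                break
            redraw = rng.choice(4, size=(int(bad.sum()), 3), p=base_p)
            codons[bad] = redraw
            ids[bad] = 16 * redraw[:, 0] + 4 * redraw[:, 1] + redraw[:, 2]
        body = "".join(bases[codons.ravel()])
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
        seq = "ATG" + body + stop
        gid = f"gene{i + 1:0{width}d}"
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gid}.t1",
                cds_sequence=seq,
                expression_weight=float(rng.lognormal(0.0, 1.0)),
                gene_id=gid,
            )
        )
    return transcripts


def write_fasta(transcripts: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            fh.write(f">{tx.transcript_id}\n")
            seq = tx.cds_sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    """CDS features in transcript coordinates (seqname = transcript id)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
            for feature in ("exon", "CDS"):
                fh.write(
                    f"{tx.transcript_id}\tstallscan\t{feature}\t1\t{len(tx)}\t.\t+\t0\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Footprint simulation
# ---------------------------------------------------------------------------

def _candidate_asites(
    tx: TranscriptModel, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray]:
    """A-site candidate positions (nt) and their codon ids for one transcript.

    Candidates are in-frame codon starts at least ``a_site_offset`` nt from the
    CDS start and ``max_read_length - a_site_offset`` nt from the CDS end
    (one extra nt on each side when jitter is enabled), so no sampled read can
    overhang the transcript. The start codon and the stop codon are never
    candidates.
    """
    pad = 1 if config.offset_jitter_prob > 0 else 0
    lo_nt = config.a_site_offset + pad
    hi_nt = len(tx) - (config.max_read_length - config.a_site_offset) - pad
    k_min = max(1, -(-lo_nt // 3))  # ceil division; k >= 1 excludes start codon
    k_max = min(len(tx) // 3 - 2, hi_nt // 3)  # excludes stop codon
    if k_max < k_min:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint8)
    positions = 3 * np.arange(k_min, k_max + 1)
    per_pos = codon_ids_per_position(encode_sequence(tx.cds_sequence))
    return positions, per_pos[positions]


def simulate_footprints(
    transcriptome: list[TranscriptModel],
    profile: StallingProfile,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate aligned RPFs; deterministic for a fixed config seed.

    Returns a DataFrame sorted by (transcript_id, position) with columns
    ``read_id, transcript_id, gene_id, pos5, length, a_site_pos,
    a_site_codon`` — ``pos5`` is the 0-based transcript coordinate of the
    read 5' end.
    """
    if not transcriptome:
        raise ValueError("transcriptome is empty")
    rng = np.random.default_rng(config.seed)
    weight = profile.as_array() * config.bias_array()

    cand_pos: list[np.ndarray] = []
    cand_p: list[np.ndarray] = []
    cand_cid: list[np.ndarray] = []
    tx_weight = np.zeros(len(transcriptome))
    for i, tx in enumerate(transcriptome):
        pos, cids = _candidate_asites(tx, config)
        w = weight[cids] if cids.size else np.empty(0)
        tot = w.sum()
        if tot > 0:
            tx_weight[i] = tx.expression_weight
            cand_p.append(w / tot)
        else:
            cand_p.append(w)
        cand_pos.append(pos)
        cand_cid.append(cids)
    if tx_weight.sum() == 0:
        raise ValueError(
            "no transcript offers a feasible A-site for the configured offsets "
            "(transcripts too short)"
        )

    n = config.n_reads
    tx_idx = rng.choice(len(transcriptome), size=n, p=tx_weight / tx_weight.sum())

    a_pos = np.zeros(n, dtype=np.int64)
    a_cid = np.zeros(n, dtype=np.uint8)
    for i in range(len(transcriptome)):
        mask = tx_idx == i
        m = int(mask.sum())
        if m == 0:
            continue
        picks = rng.choice(cand_pos[i].size, size=m, p=cand_p[i])
        a_pos[mask] = cand_pos[i][picks]
        a_cid[mask] = cand_cid[i][picks]

    lengths_avail = np.array(sorted(config.read_length_distribution))
    length_p = np.array(
        [config.read_length_distribution[int(l)] for l in lengths_avail], dtype=float
    )
    length_p /= length_p.sum()
    read_len = rng.choice(lengths_avail, size=n, p=length_p)

    shift = np.zeros(n, dtype=np.int64)
    if config.offset_jitter_prob > 0:
        u = rng.random(n)
        jp = config.offset_jitter_prob
        shift[u < jp / 2] = -1
        shift[(u >= jp / 2) & (u < jp)] = 1

    pos5 = a_pos - config.a_site_offset + shift
    tx_len = np.array([len(t) for t in transcriptome])

    # Candidate padding guarantees reads never overhang; redraw defensively
    # if a configuration ever violates that.
    for _ in range(100):
        bad = (pos5 < 0) | (pos5 + read_len > tx_len[tx_idx])
        if not bad.any():
            break
        nb = int(bad.sum())
        read_len[bad] = rng.choice(lengths_avail, size=nb, p=length_p)
        if config.offset_jitter_prob > 0:
            u = rng.random(nb)
            s = np.zeros(nb, dtype=np.int64)
            s[u < jp / 2] = -1
            s[(u >= jp / 2) & (u < jp)] = 1
            pos5[bad] = a_pos[bad] - config.a_site_offset + s
    else:
        raise RuntimeError("could not place reads inside transcripts")

    tids = np.array([t.transcript_id for t in transcriptome])
    gids = np.array([t.gene_id for t in transcriptome])
    df = pd.DataFrame(
        {
            "transcript_id": tids[tx_idx],
            "gene_id": gids[tx_idx],
            "pos5": pos5,
            "length": read_len.astype(np.int64),
            "a_site_pos": a_pos,
            "a_site_codon": np.array([decode_codon(c) for c in range(64)])[a_cid],
        }
    )
    df = df.sort_values(["transcript_id", "pos5"], kind="mergesort").reset_index(drop=True)
    df.insert(0, "read_id", [f"r{i:08d}" for i in range(len(df))])
    return df


def analytic_asite_distribution(
    transcriptome: list[TranscriptModel],
    profile: StallingProfile,
    config: SimulationConfig,
) -> dict[str, float]:
    """Exact per-codon A-site probability under the sampling model.

    Sums transcript weight x within-transcript candidate weight over every
    feasible A-site position; this is the distribution the empirical codon
    occupancy of `simulate_footprints` converges to.
    """
    weight = profile.as_array() * config.bias_array()
    totals = np.zeros(64)
    tx_w = []
    per_tx = []
    for tx in transcriptome:
        _, cids = _candidate_asites(tx, config)
        w = weight[cids] if cids.size else np.empty(0)
        tot = w.sum()
        if tot > 0:
            contrib = np.bincount(cids, weights=weight[cids], minlength=64) / tot
            per_tx.append(contrib)
            tx_w.append(tx.expression_weight)
    if not per_tx:
        raise ValueError("no feasible A-sites in any transcript")
    tx_w = np.asarray(tx_w)
    tx_w = tx_w / tx_w.sum()
    for wt, contrib in zip(tx_w, per_tx):
        totals += wt * contrib
    return {decode_codon(i): float(totals[i]) for i in range(64) if totals[i] > 0}


def to_aligned_rpfs(reads: pd.DataFrame, min_length: int = 27) -> pd.DataFrame:
    """Simulated reads as an AlignedRPF table, bypassing SAM round-trip.

    Synthetic transcripts are CDS-only with one isoform per gene, so the
    transcript coordinate *is* the CDS-relative coordinate and gene/frame
    assignment is unambiguous; only the length filter applies. Equivalent to
    writing a SAM and running `stallscan.rpf_io.assign_rpfs` on it.
    """
    kept = reads[reads["length"] >= min_length]
    out = kept[["read_id", "gene_id", "transcript_id", "pos5", "length"]].rename(
        columns={"pos5": "cds_relative_5p"}
    )
    out["frame"] = out["cds_relative_5p"].to_numpy() % 3
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_sam(
    reads: pd.DataFrame, transcriptome: list[TranscriptModel], path
) -> None:
    """One alignment per footprint, transcript coordinates, MAPQ 255, no mismatches."""
    import pysam

    by_id = {t.transcript_id: t for t in transcriptome}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": t.transcript_id, "LN": len(t)}
            for t in sorted(transcriptome, key=lambda t: t.transcript_id)
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in reads.itertuples(index=False):
            a = pysam.AlignedSegment(out.header)
            a.query_name = row.read_id
            a.reference_name = row.transcript_id
            a.reference_start = int(row.pos5)
            a.mapping_quality = 255
            a.cigarstring = f"{int(row.length)}M"
            a.flag = 0
            seq = by_id[row.transcript_id].cds_sequence
            a.query_sequence = seq[int(row.pos5) : int(row.pos5) + int(row.length)]
            out.write(a)


def write_truth_table(reads: pd.DataFrame, path) -> None:
    reads[["read_id", "transcript_id", "a_site_pos", "a_site_codon"]].to_csv(
        path, sep="\t", index=False
    )
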