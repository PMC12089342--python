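"""Annotation/alignment ingest: gene and reading-frame assignment of RPFs.

A ribosome-protected fragment is usable for codon-level analysis only when it
can be placed unambiguously: it must be long enough (> 26 nt), its 5' end
must fall inside a valid coding sequence (allowing a 15-nt 5' overhang
upstream of the start codon, where initiating ribosomes protect sequence
before the CDS), and it must be attributable to exactly one gene and one
reading frame. Everything else is excluded, and the exclusions are
book-kept in a `FilterReport` whose counts always reconcile with the input.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_right
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 27  # "> 26 nt" read as a strict inequality
DEFAULT_OVERHANG_5P = 15


@dataclass
class GeneAnnotation:
    """CDS model of one transcript in reference coordinates.

    ``cds_intervals`` are 0-based half-open, sorted by ascending reference
    coordinate; for minus-strand transcripts the 5' end of the CDS is the
    *last* interval's right edge.
    """

    gene_id: str
    transcript_id: str
    seqname: str
    strand: str
    cds_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.cds_intervals = sorted((int(a), int(b)) for a, b in self.cds_intervals)
        if any(b <= a for a, b in self.cds_intervals):
            raise ValueError(f"{self.transcript_id}: empty CDS interval")
        for (_, b1), (a2, _) in zip(self.cds_intervals, self.cds_intervals[1:]):
            if a2 < b1:
                raise ValueError(f"{self.transcript_id}: overlapping CDS intervals")
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        # cumulative CDS length before each interval, walking 5'->3'
        lens = [b - a for a, b in self.cds_intervals]
        order = lens if self.strand == "+" else lens[::-1]
        self._cum = np.concatenate([[0], np.cumsum(order)])

    @property
    def cds_length(self) -> int:
        return int(self._cum[-1])

    def project(self, pos: int, overhang_5p: int = 0) -> int | None:
        """Map a reference coordinate to a CDS-relative one (0 = first CDS nt).

        Positions up to ``overhang_5p`` nt upstream of the CDS start map to
        negative coordinates; intronic or out-of-range positions return None.
        """
        ivs = self.cds_intervals if self.strand == "+" else self.cds_intervals[::-1]
        for i, (a, b) in enumerate(ivs):
            if a <= pos < b:
                within = (pos - a) if self.strand == "+" else (b - 1 - pos)
                return int(self._cum[i]) + within
        start = ivs[0][0] if self.strand == "+" else ivs[0][1] - 1
        if self.strand == "+" and start - overhang_5p <= pos < start:
            return pos - start
        if self.strand == "-" and start < pos <= start + overhang_5p:
            return start - pos
        return None

    def unproject(self, cds_pos: int) -> int:
        """Inverse of `project` for in-CDS coordinates."""
        if not 0 <= cds_pos < self.cds_length:
            raise ValueError(f"CDS position {cds_pos} outside [0, {self.cds_length})")
        ivs = self.cds_intervals if self.strand == "+" else self.cds_intervals[::-1]
        i = bisect_right(self._cum, cds_pos) - 1
        within = cds_pos - int(self._cum[i])
        a, b = ivs[i]
        return a + within if self.strand == "+" else b - 1 - within

    def cds_sequence(self, ref_sequences: dict[str, str]) -> str:
        """Spliced CDS nucleotide sequence, 5'->3'."""
        seq = ref_sequences[self.seqname]
        parts = [seq[a:b] for a, b in self.cds_intervals]
        cds = "".join(parts)
        if self.strand == "-":
            cds = _revcomp(cds)
        return cds.upper()


_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class FilterReport:
    """Per-category read accounting for `assign_rpfs`.

    Unmapped reads count as outside-CDS; secondary/supplementary alignments
    (multi-mappers) count as gene-ambiguous.
    """

    n_input: int = 0
    n_short: int = 0
    n_outside_cds: int = 0
    n_ambiguous_gene: int = 0
    n_ambiguous_frame: int = 0
    n_retained: int = 0

    def reconciles(self) -> bool:
        return self.n_input == (
            self.n_short
            + self.n_outside_cds
            + self.n_ambiguous_gene
            + self.n_ambiguous_frame
            + self.n_retained
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# Annotation and sequence loading
# ---------------------------------------------------------------------------

def load_annotation(gtf_path) -> list[GeneAnnotation]:
    """Parse CDS features from a GTF/GFF into per-transcript annotations.

    Transcripts whose total CDS length is not a multiple of 3 are dropped
    with a warning (they cannot define a reading frame).
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            force=True,
            keep_order=False,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - gffutils error classes vary
        raise ValueError(f"could not parse annotation {gtf_path}: {exc}") from exc

    per_tx: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        tid = feat.attributes.get("transcript_id", [feat.id])[0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        rec = per_tx.setdefault(
            tid,
            {"gene_id": gid, "seqname": feat.seqid, "strand": feat.strand, "ivs": []},
        )
        rec["ivs"].append((feat.start - 1, feat.end))  # GTF is 1-based inclusive

    if not per_tx:
        raise ValueError(f"no CDS features found in {gtf_path}")

    annotations = []
    for tid, rec in sorted(per_tx.items()):
        ann = GeneAnnotation(
            gene_id=rec["gene_id"],
            transcript_id=tid,
            seqname=rec["seqname"],
            strand=rec["strand"],
            cds_intervals=rec["ivs"],
        )
        if ann.cds_length % 3:
            logger.warning(
                "dropping transcript %s: CDS length %d not divisible by 3",
                tid,
                ann.cds_length,
            )
            continue
        annotations.append(ann)
    return annotations


def load_sequences(fasta_path) -> dict[str, str]:
    """Reference sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}


def cds_sequences(
    annotations: list[GeneAnnotation], ref_sequences: dict[str, str]
) -> dict[str, str]:
    """Spliced CDS sequence per transcript_id (and per gene_id when unique)."""
    out: dict[str, str] = {}
    gene_seen: dict[str, str | None] = {}
    for ann in annotations:
        seq = ann.cds_sequence(ref_sequences)
        out[ann.transcript_id] = seq
        if ann.gene_id in gene_seen:
            gene_seen[ann.gene_id] = None  # ambiguous: multiple isoforms
        else:
            gene_seen[ann.gene_id] = seq
    for gid, seq in gene_seen.items():
        if seq is not None and gid not in out:
            out[gid] = seq
    return out


# ---------------------------------------------------------------------------
# Read assignment
# ---------------------------------------------------------------------------

def _read_5p_positions(aln) -> list[int]:
    """Reference coordinate(s) of the biological 5' end, soft clips excluded."""
    if aln.is_reverse:
        return [aln.reference_end - 1]
    return [aln.reference_start]


def assign_rpfs(
    alignments,
    annotation: list[GeneAnnotation],
    min_length: int = DEFAULT_MIN_LENGTH,
    overhang_5p: int = DEFAULT_OVERHANG_5P,
) -> tuple[pd.DataFrame, FilterReport]:
    """Assign each alignment a gene id and reading frame, or reject it.

    ``alignments`` is a SAM/BAM path or an open ``pysam.AlignmentFile``.
    A read is retained when its aligned length is >= ``min_length``, its 5'
    end projects into [CDS_start - overhang_5p, CDS_end - min_length] of at
    least one transcript on the matching strand, all such transcripts belong
    to one gene, and they agree on the reading frame. Frames of overhang
    positions are reduced mod 3 into {0,1,2} so downstream offset arithmetic
    stays in-frame.

    Returns an ``AlignedRPF`` table (read_id, gene_id, transcript_id,
    cds_relative_5p, length, frame) and the `FilterReport`.
    """
    import pysam

    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for ann in annotation:
        by_chrom.setdefault(ann.seqname, []).append(ann)

    own_handle = False
    if not hasattr(alignments, "fetch"):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own_handle = True

    report = FilterReport()
    rows: list[tuple] = []
    try:
        for aln in alignments:
            report.n_input += 1
            if aln.is_unmapped:
                report.n_outside_cds += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                report.n_ambiguous_gene += 1
                continue
            length = aln.query_alignment_length or 0
            if length < min_length:
                report.n_short += 1
                continue
            strand = "-" if aln.is_reverse else "+"
            pos5 = _read_5p_positions(aln)[0]
            candidates: list[tuple[GeneAnnotation, int]] = []
            for ann in by_chrom.get(aln.reference_name, []):
                if ann.strand != strand:
                    continue
                rel = ann.project(pos5, overhang_5p=overhang_5p)
                if rel is None:
                    continue
                if rel > ann.cds_length - min_length:
                    continue
                candidates.append((ann, rel))
            if not candidates:
                report.n_outside_cds += 1
                continue
            genes = {ann.gene_id for ann, _ in candidates}
            if len(genes) > 1:
                report.n_ambiguous_gene += 1
                continue
            frames = {rel % 3 for _, rel in candidates}
            if len(frames) > 1:
                report.n_ambiguous_frame += 1
                continue
            # deterministic representative: longest CDS, then transcript id
            ann, rel = max(candidates, key=lambda c: (c[0].cds_length, c[0].transcript_id))
            report.n_retained += 1
            rows.append(
                (aln.query_name, ann.gene_id, ann.transcript_id, rel, length, rel % 3)
            )
    finally:
        if own_handle:
            alignments.close()

    rpfs = pd.DataFrame(
        rows,
        columns=["read_id", "gene_id", "transcript_id", "cds_relative_5p", "length", "frame"],
    )
    assert report.reconciles(), "FilterReport counts do not reconcile"
    return rpfs, report


# ---------------------------------------------------------------------------
# Periodicity / metagene QC
# ---------------------------------------------------------------------------

METAGENE_WINDOW = (-30, 60)


def periodicity_qc(rpfs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3-nt periodicity and start-codon metagene QC on retained RPFs.

    Returns ``(frame_table, metagene)``: per-read-length fractions of 5' ends
    in each frame (rows sum to 1; final row 'all' pools lengths), and summed
    5'-end counts at each offset in [-30, +60] nt around CDS starts.
    """
    if rpfs.empty:
        raise ValueError("periodicity_qc requires at least one retained RPF")
    tab = (
        rpfs.groupby(["length", "frame"]).size().unstack("frame", fill_value=0)
    )
    for f in (0, 1, 2):
        if f not in tab.columns:
            tab[f] = 0
    tab = tab[[0, 1, 2]].astype(float)
    tab.loc["all"] = tab.sum(axis=0)
    frame_table = tab.div(tab.sum(axis=1), axis=0)
    frame_table.columns = [f"frame{f}" for f in (0, 1, 2)]

    lo, hi = METAGENE_WINDOW
    pos = rpfs["cds_relative_5p"].to_numpy()
    sel = pos[(pos >= lo) & (pos <= hi)]
    counts = np.bincount(sel - lo, minlength=hi - lo + 1)
    metagene = pd.DataFrame(
        {"offset_from_start": np.arange(lo, hi + 1), "count": counts}
    )
    return frame_table, metagene


def write_rpf_table(rpfs: pd.DataFrame, path) -> None:
    rpfs.to_csv(path, sep="\t", index=False)


def read_rpf_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
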