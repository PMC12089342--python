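"""Shared fixtures: small synthetic transcriptomes and footprint libraries."""

import numpy as np
import pandas as pd
import pytest

import stallscan as ss

ALA_CODONS = ("GCA", "GCC", "GCG", "GCT")


def make_cds(codons: list[str]) -> str:
    """CDS string from a codon list; caller supplies ATG ... stop."""
    return "".join(codons)


def simulate_rpfs(
    transcriptome,
    profile: dict[str, float],
    seed: int,
    n_reads: int = 100_000,
    **cfg,
) -> pd.DataFrame:
    """Simulate and convert to an AlignedRPF table in one step."""
    config = ss.SimulationConfig(n_reads=n_reads, seed=seed, **cfg)
    reads = ss.simulate_footprints(transcriptome, ss.StallingProfile(profile), config)
    return ss.to_aligned_rpfs(reads)


@pytest.fixture(scope="session")
def small_transcriptome():
    """10 genes, 300-900 nt, balanced GC."""
    return ss.generate_transcriptome(10, (300, 900), 0.5, seed=42)


@pytest.fixture(scope="session")
def medium_transcriptome():
    """100 genes for shift/background statistics."""
    return ss.generate_transcriptome(100, (300, 900), 0.5, seed=7)


@pytest.fixture(scope="session")
def medium_seqs(medium_transcriptome):
    return {t.gene_id: t.cds_sequence for t in medium_transcriptome}


@pytest.fixture(scope="session")
def small_seqs(small_transcriptome):
    return {t.gene_id: t.cds_sequence for t in small_transcriptome}


@pytest.fixture(scope="session")
def sim_files(small_transcriptome, tmp_path_factory):
    """FASTA + GTF + SAM + truth table for the small transcriptome."""
    out = tmp_path_factory.mktemp("simfiles")
    fasta, gtf, sam, truth = (
        out / "tx.fa",
        out / "tx.gtf",
        out / "reads.sam",
        out / "truth.tsv",
    )
    ss.write_fasta(small_transcriptome, fasta)
    ss.write_gtf(small_transcriptome, gtf)
    config = ss.SimulationConfig(n_reads=1000, seed=5)
    reads = ss.simulate_footprints(small_transcriptome, ss.StallingProfile({}), config)
    ss.write_sam(reads, small_transcriptome, sam)
    ss.write_truth_table(reads, truth)
    return {
        "fasta": fasta,
        "gtf": gtf,
        "sam": sam,
        "truth": truth,
        "reads": reads,
        "config": config,
    }
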