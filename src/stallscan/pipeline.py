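"""End-to-end orchestration: simulate -> qc -> shift -> density -> ooftest.

A run is described by a single declarative YAML/dict config; every effective
parameter, derived seed and output checksum is echoed into a machine-readable
``manifest.json`` so a rerun with the same config reproduces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import density_profiles, outofframe, rpf_io, subsequence_shift, synthetic_ribo

logger = logging.getLogger(__name__)

_DEFAULT_THRESHOLDS = {
    "min_gene_count": 100,
    "min_region_count": 50,
    "min_windows_common": 1000,
    "min_length": 27,
    "overhang_5p": 15,
}
_DEFAULT_OFFSETS = {"a_site": 15, "p_site": 12}


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    simulate: dict | None = None  # synthetic experiment description
    samples: dict | None = None  # pre-aligned inputs: annotation/sequences/condition/control
    offsets: dict = field(default_factory=lambda: dict(_DEFAULT_OFFSETS))
    thresholds: dict = field(default_factory=lambda: dict(_DEFAULT_THRESHOLDS))
    density_codons: list[str] = field(default_factory=list)
    oof_codons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.offsets = {**_DEFAULT_OFFSETS, **(self.offsets or {})}
        self.thresholds = {**_DEFAULT_THRESHOLDS, **(self.thresholds or {})}
        for key, val in self.thresholds.items():
            if val <= 0:
                raise ValueError(f"threshold {key} must be positive, got {val}")
        if (self.simulate is None) == (self.samples is None):
            raise ValueError("config needs exactly one of 'simulate' or 'samples'")
        if self.samples is not None:
            for key in ("annotation", "sequences"):
                if key not in self.samples:
                    raise ValueError(f"samples config missing {key!r}")
                if not Path(self.samples[key]).exists():
                    raise FileNotFoundError(self.samples[key])
            for arm in ("condition", "control"):
                paths = self.samples.get(arm) or []
                if not paths:
                    raise ValueError(f"samples config lists no {arm} alignments")
                for p in paths:
                    if not Path(p).exists():
                        raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _derived_seed(base: int, replicate: int, arm: int) -> int:
    return (base * 100_003 + replicate * 101 + arm) % (2**31 - 1)


def simulate_experiment(config: RunConfig, outdir: Path) -> dict:
    """Materialise the synthetic experiment described by ``config.simulate``.

    Writes FASTA/GTF for the shared transcriptome and, per replicate and arm,
    a SAM file plus a truth table. Returns a ``samples``-style mapping that
    the rest of the pipeline consumes exactly like real inputs.
    """
    sim = dict(config.simulate)
    n_reps = int(sim.get("replicates", 1))
    transcriptome = synthetic_ribo.generate_transcriptome(
        n_genes=int(sim.get("n_genes", 200)),
        length_range=tuple(sim.get("length_range", (300, 1800))),
        gc_fraction=float(sim.get("gc_fraction", 0.5)),
        seed=config.seed,
    )
    fasta = outdir / "transcriptome.fa"
    gtf = outdir / "transcriptome.gtf"
    synthetic_ribo.write_fasta(transcriptome, fasta)
    synthetic_ribo.write_gtf(transcriptome, gtf)

    profiles = {
        "condition": synthetic_ribo.StallingProfile(sim.get("condition_stalling", {})),
        "control": synthetic_ribo.StallingProfile(sim.get("control_stalling", {})),
    }
    out = {"annotation": str(gtf), "sequences": str(fasta), "condition": [], "control": []}
    for rep in range(1, n_reps + 1):
        for arm_idx, arm in enumerate(("condition", "control")):
            cfg = synthetic_ribo.SimulationConfig(
                n_reads=int(sim.get("n_reads", 100_000)),
                seed=_derived_seed(config.seed, rep, arm_idx),
                a_site_offset=int(config.offsets["a_site"]),
                offset_jitter_prob=float(sim.get("offset_jitter_prob", 0.0)),
            )
            reads = synthetic_ribo.simulate_footprints(
                transcriptome, profiles[arm], cfg
            )
            sam = outdir / f"{arm}_rep{rep}.sam"
            synthetic_ribo.write_sam(reads, transcriptome, sam)
            synthetic_ribo.write_truth_table(reads, outdir / f"{arm}_rep{rep}.truth.tsv")
            out[arm].append(str(sam))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            "seed": config.seed,
            "offsets": config.offsets,
            "thresholds": config.thresholds,
            "density_codons": config.density_codons,
            "oof_codons": config.oof_codons,
            "simulate": config.simulate,
        },
        "stages": [],
        "outputs": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s done: %s", stage, info)

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    try:
        if config.simulate is not None:
            samples = simulate_experiment(config, outdir)
            record("simulate", replicates=len(samples["condition"]))
        else:
            samples = config.samples
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        annotation = rpf_io.load_annotation(samples["annotation"])
        refs = rpf_io.load_sequences(samples["sequences"])
        seqs = rpf_io.cds_sequences(annotation, refs)
        record("load", n_transcripts=len(annotation))
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    thr = config.thresholds
    rpfs: dict[str, list[pd.DataFrame]] = {"condition": [], "control": []}
    try:
        for arm in ("condition", "control"):
            for i, path in enumerate(samples[arm], start=1):
                table, rep = rpf_io.assign_rpfs(
                    path,
                    annotation,
                    min_length=int(thr["min_length"]),
                    overhang_5p=int(thr["overhang_5p"]),
                )
                rpfs[arm].append(table)
                name = f"{arm}_rep{i}"
                rpf_io.write_rpf_table(table, outdir / f"{name}.rpfs.tsv")
                rep.to_json(outdir / f"{name}.filter_report.json")
                emit(f"{name}.rpfs", outdir / f"{name}.rpfs.tsv")
                emit(f"{name}.filter_report", outdir / f"{name}.filter_report.json")
                frame_tab, metagene = rpf_io.periodicity_qc(table)
                frame_tab.to_csv(outdir / f"{name}.frames.tsv", sep="\t", float_format="%.10g")
                metagene.to_csv(outdir / f"{name}.metagene.tsv", sep="\t", index=False)
                emit(f"{name}.frames", outdir / f"{name}.frames.tsv")
                emit(f"{name}.metagene", outdir / f"{name}.metagene.tsv")
                record("qc", sample=name, n_input=rep.n_input, n_retained=rep.n_retained)
    except Exception as exc:
        raise RuntimeError(f"stage 'qc' failed: {exc}") from exc

    try:
        n_pairs = min(len(rpfs["condition"]), len(rpfs["control"]))
        replicate_shifts: dict[str, pd.DataFrame] = {}
        for i in range(n_pairs):
            tab_c = subsequence_shift.count_codons_at_offset(
                rpfs["condition"][i], seqs, offset=int(config.offsets["a_site"])
            )
            tab_k = subsequence_shift.count_codons_at_offset(
                rpfs["control"][i], seqs, offset=int(config.offsets["a_site"])
            )
            shifts = subsequence_shift.compute_shifts(
                tab_c, tab_k, min_gene_count=int(thr["min_gene_count"])
            )
            replicate_shifts[f"rep{i + 1}"] = shifts
            subsequence_shift.write_shift_table(shifts, outdir / f"shifts_rep{i + 1}.tsv")
            emit(f"shifts_rep{i + 1}", outdir / f"shifts_rep{i + 1}.tsv")
        record("shift", n_replicate_pairs=n_pairs)
        if n_pairs >= 2:
            aa = subsequence_shift.test_amino_acids(replicate_shifts)
            subsequence_shift.write_aa_test_table(aa, outdir / "amino_acid_tests.tsv")
            emit("amino_acid_tests", outdir / "amino_acid_tests.tsv")
            record("aa_test", n_amino_acids=len(aa))
    except Exception as exc:
        raise RuntimeError(f"stage 'shift' failed: {exc}") from exc

    pooled = {
        arm: pd.concat(tables, ignore_index=True) for arm, tables in rpfs.items()
    }

    try:
        for codon in config.density_codons:
            regions = density_profiles.extract_codon_regions(annotation, refs, codon)
            prof = density_profiles.profile_regions(
                pooled,
                regions,
                min_region_count=int(thr["min_region_count"]),
                min_windows_common=int(thr["min_windows_common"]),
            )
            result = density_profiles.density_shift(prof["condition"], prof["control"])
            density_profiles.write_density_shift(
                result, outdir / f"density_shift_{codon}.tsv"
            )
            emit(f"density_shift_{codon}", outdir / f"density_shift_{codon}.tsv")
            record("density", codon=codon, n_regions=result.n_regions_used,
                   threshold=prof["condition"].threshold_used,
                   schedule=prof["condition"].threshold_schedule)
    except Exception as exc:
        raise RuntimeError(f"stage 'density' failed: {exc}") from exc

    try:
        results = []
        if config.oof_codons:
            results = outofframe.oof_tests(
                pooled["condition"],
                pooled["control"],
                seqs,
                config.oof_codons,
                target_offset=int(config.offsets["a_site"]),
                min_gene_count=int(thr["min_gene_count"]),
            )
        if results:
            outofframe.write_oof_table(results, outdir / "oof_tests.tsv")
            emit("oof_tests", outdir / "oof_tests.tsv")
            record("ooftest", n_codons=len(results))
    except Exception as exc:
        raise RuntimeError(f"stage 'ooftest' failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
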