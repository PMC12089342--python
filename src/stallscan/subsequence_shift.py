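"""Subsequence-shift (diricore-style) codon occupancy comparison.

For every retained footprint the triplet a fixed distance from its 5' end is
tallied: 15 nt reaches the ribosomal A site, 12 nt the P site. Counts are
normalised within each gene (counts / gene total), so expression differences
between samples cancel, then averaged across genes passing a minimum-count
threshold in *both* samples. The per-codon statistic is the relative shift

    shift(c) = (mean_freq_condition(c) - mean_freq_control(c)) / mean_freq_control(c)

and amino-acid-level inference pools replicate-level codon shifts in a
linear mixed model with fixed effects for the 20 amino acids and a random
intercept per codon, testing each amino acid against the grand mean (Wald t,
REML fit) with Benjamini-Hochberg correction across the 20 tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codons import (
    ALL_CODONS,
    CODON_TO_AA,
    STOP_IDS,
    codon_ids_per_position,
    encode_sequence,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENE_COUNT = 100


@dataclass
class CodonFrequencyTable:
    """Per-gene triplet counts at a fixed 5'-end offset.

    ``counts`` has one row per gene and one column per triplet (lexicographic
    over the 64); ``offset`` records the distance from the read 5' end at
    which the triplets were read.
    """

    offset: int
    counts: pd.DataFrame  # index: gene_id, columns: 64 codon strings

    @property
    def gene_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def frequencies(self) -> pd.DataFrame:
        """Within-gene normalized frequencies (rows sum to 1)."""
        totals = self.gene_totals
        return self.counts.div(totals.where(totals > 0, np.nan), axis=0)


def count_codons_at_offset(
    rpfs: pd.DataFrame,
    sequences: dict[str, str],
    offset: int = 15,
    *,
    selection_offset: int | None = None,
    in_frame_only: bool = True,
    drop_stops: bool = True,
) -> CodonFrequencyTable:
    """Tally the triplet ``offset`` nt from each RPF 5' end, per gene.

    With the defaults, only reads whose triplet at ``offset`` is in-frame
    contribute (out-of-frame reads contribute nothing) and stop-codon
    triplets are dropped, which is the configuration for A-site (15 nt) and
    P-site (12 nt) codon counting. The out-of-frame background instead
    selects reads by frame at ``selection_offset`` while reading the triplet
    at ``offset`` = selection_offset +- 1, keeping all 64 triplets.

    Sequences are keyed by gene_id or transcript_id (CDS nucleotides,
    frame 0 at index 0); a gene with no sequence aborts with its name.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    sel = offset if selection_offset is None else selection_offset

    key_col = "gene_id"
    genes = pd.Index(sorted(rpfs["gene_id"].unique()))
    seq_key = {}
    for _, row in rpfs.drop_duplicates("gene_id").iterrows():
        gid = row["gene_id"]
        if gid in sequences:
            seq_key[gid] = gid
        elif "transcript_id" in rpfs.columns and row["transcript_id"] in sequences:
            seq_key[gid] = row["transcript_id"]
        else:
            raise KeyError(f"no CDS sequence available for gene {gid!r}")

    # concatenated per-position codon ids with per-gene offsets for one gather
    gene_pos = {}
    chunks = []
    cursor = 0
    for gid in genes:
        enc = encode_sequence(sequences[seq_key[gid]])
        chunks.append(codon_ids_per_position(enc))
        gene_pos[gid] = (cursor, enc.size)
        cursor += enc.size
    big = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint8)

    gidx = rpfs[key_col].map({g: i for i, g in enumerate(genes)}).to_numpy()
    starts = rpfs[key_col].map({g: gene_pos[g][0] for g in genes}).to_numpy()
    lens = rpfs[key_col].map({g: gene_pos[g][1] for g in genes}).to_numpy()
    rel = rpfs["cds_relative_5p"].to_numpy()

    p = rel + offset
    valid = (p >= 0) & (p + 3 <= lens)
    if in_frame_only:
        valid &= (rel + sel) % 3 == 0
    cid = np.zeros(len(rpfs), dtype=np.int64)
    cid[valid] = big[(starts + p)[valid]]
    valid &= np.where(valid, cid != 255, False)
    if drop_stops:
        valid &= ~np.isin(cid, list(STOP_IDS))

    flat = np.bincount(
        gidx[valid] * 64 + cid[valid], minlength=len(genes) * 64
    ).reshape(len(genes), 64)
    counts = pd.DataFrame(flat, index=genes, columns=list(ALL_CODONS))
    return CodonFrequencyTable(offset=offset, counts=counts)


def compute_shifts(
    table_condition: CodonFrequencyTable,
    table_control: CodonFrequencyTable,
    min_gene_count: int = DEFAULT_MIN_GENE_COUNT,
    weight_by_counts: bool = False,
) -> pd.DataFrame:
    """Per-codon relative occupancy shift between condition and control.

    Genes must reach ``min_gene_count`` total counts in *both* samples to
    enter the across-gene average — unweighted by default (one gene, one
    vote); ``weight_by_counts=True`` weights each gene's frequencies by its
    total counts instead. Triplets never observed in either sample are
    omitted; triplets with zero control mean but non-zero condition mean
    are reported with ``defined = False`` and NaN shift.

    Returns a DataFrame with columns codon, amino_acid, shift,
    mean_freq_condition, mean_freq_control, n_genes_used, defined.
    """
    if table_condition.offset != table_control.offset:
        raise ValueError("condition and control tables use different offsets")
    tc, tk = table_condition, table_control
    common = tc.counts.index.intersection(tk.counts.index)
    ok = (tc.gene_totals.reindex(common, fill_value=0) >= min_gene_count) & (
        tk.gene_totals.reindex(common, fill_value=0) >= min_gene_count
    )
    genes = common[ok]
    if genes.empty:
        raise ValueError(
            f"no gene reaches {min_gene_count} counts in both samples; "
            "lower min_gene_count"
        )
    if weight_by_counts:
        wc = tc.gene_totals.loc[genes]
        wk = tk.gene_totals.loc[genes]
        mean_c = tc.frequencies().loc[genes].mul(wc, axis=0).sum(axis=0) / wc.sum()
        mean_k = tk.frequencies().loc[genes].mul(wk, axis=0).sum(axis=0) / wk.sum()
    else:
        mean_c = tc.frequencies().loc[genes].mean(axis=0)
        mean_k = tk.frequencies().loc[genes].mean(axis=0)

    rows = []
    for codon in ALL_CODONS:
        mc, mk = float(mean_c[codon]), float(mean_k[codon])
        if mc == 0.0 and mk == 0.0:
            continue
        defined = mk > 0.0
        shift = (mc - mk) / mk if defined else np.nan
        rows.append(
            {
                "codon": codon,
                "amino_acid": CODON_TO_AA[codon],
                "shift": shift,
                "mean_freq_condition": mc,
                "mean_freq_control": mk,
                "n_genes_used": len(genes),
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Amino-acid-level mixed-model test
# ---------------------------------------------------------------------------

def test_amino_acids(
    replicate_shifts: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Mixed-model test for amino-acid-level occupancy shifts across replicates.

    Stacks replicate-level codon shifts and fits
    ``shift ~ 0 + amino_acid`` with a random intercept per codon (REML).
    Each amino acid is contrasted against the grand mean of the amino-acid
    effects (Wald t). A singular random-effect fit falls back to the
    fixed-effects-only linear model with a logged warning. p-values are
    Benjamini-Hochberg adjusted across the amino acids tested.
    """
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    if len(replicate_shifts) < 2:
        raise ValueError("at least 2 replicates are required")
    frames = []
    for rep, df in replicate_shifts.items():
        sub = df[df["defined"] & df["amino_acid"].ne("*")][
            ["codon", "amino_acid", "shift"]
        ].copy()
        sub["replicate"] = rep
        frames.append(sub)
    data = pd.concat(frames, ignore_index=True).dropna(subset=["shift"])
    if data.empty:
        raise ValueError("no defined codon shifts to test")

    aa_levels = sorted(data["amino_acid"].unique())
    exog = pd.get_dummies(data["amino_acid"], dtype=float)[aa_levels]
    endog = data["shift"].to_numpy(dtype=float)
    k = len(aa_levels)
    contrasts = np.eye(k) - np.full((k, k), 1.0 / k)

    if np.allclose(endog, endog[0]):
        # degenerate: identical shifts everywhere -> no effect, by construction
        result = pd.DataFrame(
            {
                "amino_acid": aa_levels,
                "t_value": 0.0,
                "p_value": 1.0,
            }
        )
    else:
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)  # "covariance is singular"
            try:
                model = sm.MixedLM(
                    endog, exog.to_numpy(), groups=data["codon"].to_numpy()
                )
                fit = model.fit(reml=True)
                # singular when the codon variance is negligible relative to
                # the residual variance (lme4-style relative tolerance)
                if np.isfinite(fit.bse_fe).all() and (
                    float(np.min(np.diag(fit.cov_re))) > 1e-4 * float(fit.scale)
                ):
                    res = fit
                else:
                    logger.warning(
                        "singular random-effect fit (codon variance ~ 0); "
                        "falling back to fixed-effects-only model"
                    )
            except Exception:
                logger.warning(
                    "mixed-model fit failed; falling back to fixed-effects-only model"
                )
        if res is None:
            res = sm.OLS(endog, exog.to_numpy()).fit()
        tt = res.t_test(contrasts)
        result = pd.DataFrame(
            {
                "amino_acid": aa_levels,
                "t_value": np.asarray(tt.tvalue, dtype=float),
                "p_value": np.asarray(tt.pvalue, dtype=float),
            }
        )

    result["p_adjusted"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result.sort_values("amino_acid").reset_index(drop=True)


def write_shift_table(shifts: pd.DataFrame, path) -> None:
    shifts.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_aa_test_table(tests: pd.DataFrame, path) -> None:
    tests.to_csv(path, sep="\t", index=False, float_format="%.10g")
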