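"""Out-of-frame background Z-test for codon-specific occupancy shifts.

The null distribution for a codon's subsequence shift is built from the
shifts of nucleotide triplets read one position to either side of the codon
under analysis (offsets target-1 and target+1 from the read 5' end), using
the identical gene-normalisation machinery as the in-frame statistic. These
off-frame triplets are not decoded by the ribosome, so their shifts capture
the technical and compositional noise floor. Triplets that physically
overlap the target codon by two bases would carry its true signal and are
excluded: for target b0 b1 b2, pattern N-b0-b1 on the -1 side and b1-b2-N
on the +1 side (for GCA: NGC and CAN). The observed in-frame shift is then
scored against this background with a two-tailed Z-test, with
Anderson-Darling / Shapiro-Wilk normality diagnostics attached (diagnostics
only — they never suppress a result).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codons import is_sense
from .subsequence_shift import (
    DEFAULT_MIN_GENE_COUNT,
    compute_shifts,
    count_codons_at_offset,
)

MIN_BACKGROUND_VALUES = 8


@dataclass
class BackgroundDistribution:
    target_codon: str
    target_offset: int
    background_values: np.ndarray  # shifts of kept off-frame triplets
    background_triplets: list[tuple[int, str]]  # (offset_side, triplet) kept
    excluded_patterns: list[tuple[int, str]]
    excluded_triplets: list[tuple[int, str]] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.background_values))

    @property
    def sd(self) -> float:
        # n-1 denominator: background samples are small (<= ~120 triplets)
        return float(np.std(self.background_values, ddof=1))


@dataclass
class OofTestResult:
    target_codon: str
    observed_shift: float
    background_mean: float
    background_sd: float
    n_background: int
    z: float | None
    p_two_tailed: float | None
    degenerate: bool
    anderson_darling_stat: float | None
    shapiro_wilk_p: float | None
    normality_flag: bool
    qq_points: np.ndarray | None  # (n, 2): theoretical vs ordered sample quantiles

    def p_one_tailed(self) -> float | None:
        """Upper-tail p, for callers that want a directional test."""
        if self.z is None:
            return None
        return float(stats.norm.sf(self.z))


def exclusion_patterns(target_codon: str) -> list[tuple[int, str]]:
    """Triplet patterns at +-1 nt that overlap the target codon by two bases.

    Returns ``[(-1, 'N'+b0+b1), (+1, b1+b2+'N')]`` — e.g. GCA gives
    (-1, NGC) and (+1, CAN).
    """
    c = target_codon.upper()
    if not is_sense(c):
        raise ValueError(f"{target_codon!r} is not a sense codon")
    return [(-1, "N" + c[0] + c[1]), (+1, c[1] + c[2] + "N")]


def _matches(pattern: str, triplet: str) -> bool:
    return all(p == "N" or p == t for p, t in zip(pattern, triplet))


def offframe_shift_tables(
    rpfs_condition: pd.DataFrame,
    rpfs_control: pd.DataFrame,
    sequences: dict[str, str],
    target_offset: int = 15,
    min_gene_count: int = DEFAULT_MIN_GENE_COUNT,
) -> dict[int, pd.DataFrame]:
    """Subsequence shifts of the triplets at target_offset -1 and +1 nt.

    Reads are selected exactly as for the in-frame statistic (frame anchored
    at ``target_offset``) but the tallied triplet sits one nucleotide to the
    side. These tables do not depend on the codon under test, so they are
    computed once and shared across targets.
    """
    tables: dict[int, pd.DataFrame] = {}
    for side in (-1, +1):
        tab_c = count_codons_at_offset(
            rpfs_condition,
            sequences,
            offset=target_offset + side,
            selection_offset=target_offset,
            drop_stops=False,
        )
        tab_k = count_codons_at_offset(
            rpfs_control,
            sequences,
            offset=target_offset + side,
            selection_offset=target_offset,
            drop_stops=False,
        )
        tables[side] = compute_shifts(tab_c, tab_k, min_gene_count=min_gene_count)
    return tables


def build_background(
    rpfs_condition: pd.DataFrame,
    rpfs_control: pd.DataFrame,
    sequences: dict[str, str],
    target_codon: str,
    target_offset: int = 15,
    min_gene_count: int = DEFAULT_MIN_GENE_COUNT,
    side_shifts: dict[int, pd.DataFrame] | None = None,
) -> BackgroundDistribution:
    """Background distribution: off-frame triplet shifts minus overlaps.

    All 64 triplets observed at target_offset +- 1 nt enter, apart from the
    overlap-excluded patterns for the target codon. Pass precomputed
    ``side_shifts`` (from `offframe_shift_tables`) when testing several
    codons on the same samples. Fewer than 8 surviving values aborts.
    """
    patterns = exclusion_patterns(target_codon)
    if side_shifts is None:
        side_shifts = offframe_shift_tables(
            rpfs_condition,
            rpfs_control,
            sequences,
            target_offset=target_offset,
            min_gene_count=min_gene_count,
        )
    values: list[float] = []
    kept: list[tuple[int, str]] = []
    excluded: list[tuple[int, str]] = []
    for side in (-1, +1):
        side_patterns = [p for s, p in patterns if s == side]
        for row in side_shifts[side].itertuples(index=False):
            if not row.defined or not np.isfinite(row.shift):
                continue
            if any(_matches(p, row.codon) for p in side_patterns):
                excluded.append((side, row.codon))
                continue
            kept.append((side, row.codon))
            values.append(float(row.shift))
    if len(values) < MIN_BACKGROUND_VALUES:
        raise ValueError(
            f"only {len(values)} background values for {target_codon} at offset "
            f"{target_offset} (need >= {MIN_BACKGROUND_VALUES}); more reads or a "
            "lower min_gene_count are required"
        )
    return BackgroundDistribution(
        target_codon=target_codon.upper(),
        target_offset=target_offset,
        background_values=np.asarray(values, dtype=float),
        background_triplets=kept,
        excluded_patterns=patterns,
        excluded_triplets=excluded,
    )


def z_test(background: BackgroundDistribution, observed_shift: float) -> OofTestResult:
    """Two-tailed Z-test of the observed shift against the off-frame background.

    A zero-variance background (e.g. condition == control) yields a
    degenerate result with no z or p rather than an error from downstream
    arithmetic. Shapiro-Wilk p < 0.05 sets ``normality_flag`` but the test
    result is still reported.
    """
    vals = background.background_values
    mean, sd = background.mean, background.sd
    if sd == 0.0:
        return OofTestResult(
            target_codon=background.target_codon,
            observed_shift=float(observed_shift),
            background_mean=mean,
            background_sd=0.0,
            n_background=vals.size,
            z=None,
            p_two_tailed=None,
            degenerate=True,
            anderson_darling_stat=None,
            shapiro_wilk_p=None,
            normality_flag=False,
            qq_points=None,
        )
    z = (float(observed_shift) - mean) / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    ad_stat = float(stats.anderson(vals, dist="norm", method="interpolate").statistic)
    sw_p = float(stats.shapiro(vals).pvalue)
    (theo, ordered), _ = stats.probplot(vals, dist="norm")
    return OofTestResult(
        target_codon=background.target_codon,
        observed_shift=float(observed_shift),
        background_mean=mean,
        background_sd=sd,
        n_background=vals.size,
        z=float(z),
        p_two_tailed=p,
        degenerate=False,
        anderson_darling_stat=ad_stat,
        shapiro_wilk_p=sw_p,
        normality_flag=sw_p < 0.05,
        qq_points=np.column_stack([theo, ordered]),
    )


def oof_tests(
    rpfs_condition: pd.DataFrame,
    rpfs_control: pd.DataFrame,
    sequences: dict[str, str],
    target_codons: list[str],
    target_offset: int = 15,
    min_gene_count: int = DEFAULT_MIN_GENE_COUNT,
) -> list[OofTestResult]:
    """Out-of-frame tests for several codons, sharing the shift tables."""
    tab_c = count_codons_at_offset(rpfs_condition, sequences, offset=target_offset)
    tab_k = count_codons_at_offset(rpfs_control, sequences, offset=target_offset)
    shifts = compute_shifts(tab_c, tab_k, min_gene_count=min_gene_count).set_index(
        "codon"
    )
    side_shifts = offframe_shift_tables(
        rpfs_condition,
        rpfs_control,
        sequences,
        target_offset=target_offset,
        min_gene_count=min_gene_count,
    )
    results = []
    for codon in target_codons:
        c = codon.upper()
        if c not in shifts.index or not bool(shifts.loc[c, "defined"]):
            raise ValueError(f"no defined in-frame shift for {codon}")
        background = build_background(
            rpfs_condition,
            rpfs_control,
            sequences,
            c,
            target_offset=target_offset,
            min_gene_count=min_gene_count,
            side_shifts=side_shifts,
        )
        results.append(z_test(background, float(shifts.loc[c, "shift"])))
    return results


def oof_test(
    rpfs_condition: pd.DataFrame,
    rpfs_control: pd.DataFrame,
    sequences: dict[str, str],
    target_codon: str,
    target_offset: int = 15,
    min_gene_count: int = DEFAULT_MIN_GENE_COUNT,
) -> OofTestResult:
    """End-to-end out-of-frame test: observed in-frame shift vs background."""
    return oof_tests(
        rpfs_condition,
        rpfs_control,
        sequences,
        [target_codon],
        target_offset=target_offset,
        min_gene_count=min_gene_count,
    )[0]


def write_oof_table(results: list[OofTestResult], path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "codon": r.target_codon,
                "observed_shift": r.observed_shift,
                "background_n": r.n_background,
                "background_mean": r.background_mean,
                "background_sd": r.background_sd,
                "z": r.z if r.z is not None else "",
                "p_two_tailed": r.p_two_tailed if r.p_two_tailed is not None else "",
                "degenerate": r.degenerate,
                "anderson_darling_stat": r.anderson_darling_stat,
                "shapiro_wilk_p": r.shapiro_wilk_p,
                "normality_flag": r.normality_flag,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")
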