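"""Cis-window genome scan: pair enumeration, per-pair testing, ranking.

The scan pairs every SNP with every CpG mapped within a fixed genomic
window on the same chromosome (10 kb by default, boundary inclusive),
calibrates the W-test null once per cohort, tests all pairs, optionally
runs both logistic-regression benchmarks, and ranks results by p-value
with a Bonferroni family-wise threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .benchmarks import DegenerateDesignError, lr_interaction_test
from .data_io import GenotypeMatrix, MarkerMap, MethylationMatrix
from .preprocess import binarize_methylation, encode_additive
from .wtest import (
    DEFAULT_BOOT_REPS,
    DEFAULT_SAMPLE_FLOOR,
    CalibrationTable,
    bootstrap_null_samples,
    estimate_hf,
    wtest_pair,
)

__all__ = [
    "PairResult",
    "ScanConfig",
    "ScanSummary",
    "QQResult",
    "enumerate_cis_pairs",
    "bonferroni_threshold",
    "genome_scan",
    "qq_points",
]

logger = logging.getLogger(__name__)


@dataclass
class PairResult:
    """One tested SNP-CpG pair."""

    snp_id: str
    cpg_id: str
    distance_bp: int
    snp_maf: float
    k: int
    S: float
    W: float
    p_value: float
    lr_m1_p: float = np.nan
    lr_m2_p: float = np.nan
    correction_applied: bool = False
    lr_converged: bool = True


@dataclass
class ScanConfig:
    window_bp: int = 10_000
    alpha: float = 0.05
    boot_reps: int = DEFAULT_BOOT_REPS
    subsample_size: int | None = None
    sample_floor: int = DEFAULT_SAMPLE_FLOOR
    seed: int = 0
    run_benchmarks: bool = True

    def __post_init__(self) -> None:
        if self.window_bp < 0:
            raise ValueError("window_bp must be non-negative")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class ScanSummary:
    n_enumerated: int
    n_tested: int
    skipped: dict[str, int]
    bonferroni_alpha: float
    n_significant: int
    calibration: CalibrationTable
    n_subjects: int


@dataclass
class QQResult:
    expected: np.ndarray  # -log10 expected quantiles
    observed: np.ndarray  # -log10 observed p-values, ascending p
    lambda_gc: float

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.expected.tolist(), self.observed.tolist()))


def enumerate_cis_pairs(
    snp_map: MarkerMap,
    cpg_map: MarkerMap,
    window_bp: int = 10_000,
) -> list[tuple[str, str, int]]:
    """All same-chromosome SNP-CpG pairs within the window, inclusive.

    Output is ordered by chromosome, then SNP position, then CpG position
    (marker id breaks coordinate ties) so the scan order is deterministic.
    """
    out: list[tuple[str, str, int]] = []
    cpg_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for cid, chrom, pos in zip(cpg_map.marker_ids, cpg_map.chromosomes, cpg_map.positions):
        cpg_by_chrom.setdefault(chrom, []).append((int(pos), cid))
    for chrom in cpg_by_chrom:
        cpg_by_chrom[chrom].sort()
    snps = sorted(
        zip(snp_map.chromosomes, snp_map.positions, snp_map.marker_ids),
        key=lambda t: (t[0], int(t[1]), t[2]),
    )
    for chrom, spos, sid in snps:
        cpgs = cpg_by_chrom.get(chrom)
        if not cpgs:
            continue
        positions = np.array([p for p, _ in cpgs])
        lo = int(np.searchsorted(positions, int(spos) - window_bp, side="left"))
        hi = int(np.searchsorted(positions, int(spos) + window_bp, side="right"))
        for cpos, cid in cpgs[lo:hi]:
            out.append((sid, cid, abs(int(spos) - cpos)))
    logger.info("enumerated %d cis pair(s) within %d bp", len(out), window_bp)
    return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / m controlling the FWER over m tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def genome_scan(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    snp_map: MarkerMap,
    cpg_map: MarkerMap,
    phenotype,
    config: ScanConfig | None = None,
) -> tuple[list[PairResult], ScanSummary]:
    """Test every cis SNP-CpG pair on an aligned complete-case cohort.

    The chi-squared calibration (h, f per k) is fitted once from bootstrap
    null samples drawn over the candidate pairs, then applied to each pair.
    Monomorphic SNPs and constant CpGs are skipped with logged reasons.
    Results come back sorted by W-test p-value ascending (ties by ids).
    """
    config = config or ScanConfig()
    y = np.asarray(phenotype)
    if genotypes.subject_ids != methylation.subject_ids or len(y) != genotypes.n_subjects:
        raise ValueError("genotype, methylation and phenotype must be subject-aligned")

    pairs = enumerate_cis_pairs(snp_map, cpg_map, config.window_bp)
    if not pairs:
        raise ValueError("no cis pairs within the window")

    snp_col = {s: i for i, s in enumerate(genotypes.snp_ids)}
    cpg_col = {c: i for i, c in enumerate(methylation.cpg_ids)}
    skipped = {
        "snp_not_in_genotypes": 0,
        "cpg_not_in_methylation": 0,
        "monomorphic_snp": 0,
        "constant_cpg": 0,
        "degenerate_table": 0,
    }

    encoded: dict[int, object] = {}
    binarized: dict[int, object] = {}

    def _enc(j: int):
        if j not in encoded:
            enc = encode_additive(genotypes.values[:, j])
            encoded[j] = None if enc.monomorphic else enc
        return encoded[j]

    def _bin(j: int):
        if j not in binarized:
            try:
                binarized[j] = binarize_methylation(methylation.values[:, j])
            except ValueError:
                binarized[j] = None
        return binarized[j]

    testable: list[tuple[str, str, int, int, int]] = []
    for sid, cid, dist in pairs:
        if sid not in snp_col:
            skipped["snp_not_in_genotypes"] += 1
            continue
        if cid not in cpg_col:
            skipped["cpg_not_in_methylation"] += 1
            continue
        sj, cj = snp_col[sid], cpg_col[cid]
        if _enc(sj) is None:
            skipped["monomorphic_snp"] += 1
            continue
        if _bin(cj) is None:
            skipped["constant_cpg"] += 1
            continue
        testable.append((sid, cid, dist, sj, cj))
    if not testable:
        raise ValueError("no polymorphic cis pairs to test")

    codes = np.column_stack([encoded[sj].codes for _, _, _, sj, _ in testable])
    labels = np.column_stack([binarized[cj].labels for _, _, _, _, cj in testable])
    cal_pairs = [(i, i) for i in range(len(testable))]
    calibration = estimate_hf(
        bootstrap_null_samples(
            codes,
            labels,
            y,
            cal_pairs,
            B=config.boot_reps,
            subsample_size=config.subsample_size,
            seed=np.random.default_rng([29, config.seed]),
        ),
        floor=config.sample_floor,
    )

    results: list[PairResult] = []
    for i, (sid, cid, dist, sj, cj) in enumerate(testable):
        g = codes[:, i]
        m = labels[:, i]
        try:
            res = wtest_pair(g, m, y, calibration)
        except ValueError:
            skipped["degenerate_table"] += 1
            continue
        pr = PairResult(
            snp_id=sid,
            cpg_id=cid,
            distance_bp=dist,
            snp_maf=encoded[sj].maf,
            k=res.k,
            S=res.S,
            W=res.W,
            p_value=res.p_value,
            correction_applied=any(c.corrected for c in res.per_cell),
        )
        if config.run_benchmarks:
            try:
                m1 = lr_interaction_test(g, m.astype(float), y, cpg_mode="binary")
                m2 = lr_interaction_test(
                    g, methylation.values[:, cj], y, cpg_mode="continuous"
                )
                pr.lr_m1_p = m1.p_value
                pr.lr_m2_p = m2.p_value
                pr.lr_converged = m1.converged and m2.converged
            except DegenerateDesignError:
                pr.lr_converged = False
        results.append(pr)

    results.sort(key=lambda r: (r.p_value, r.snp_id, r.cpg_id))
    thr = bonferroni_threshold(config.alpha, len(results))
    n_sig = sum(r.p_value <= thr for r in results)
    summary = ScanSummary(
        n_enumerated=len(pairs),
        n_tested=len(results),
        skipped=skipped,
        bonferroni_alpha=thr,
        n_significant=n_sig,
        calibration=calibration,
        n_subjects=len(y),
    )
    logger.info(
        "scan: %d enumerated, %d tested, %d significant at %.3g",
        len(pairs),
        len(results),
        n_sig,
        thr,
    )
    return results, summary


def qq_points(p_values) -> QQResult:
    """Expected-vs-observed -log10 p quantiles plus a genomic inflation factor.

    lambda is the ratio of the median 1-df chi-squared quantile of the
    observed p-values to the theoretical null median (~0.4549); values
    near 1 indicate a well-calibrated test.
    """
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]; floor underflowed values upstream")
    obs = np.sort(p)
    m = len(obs)
    exp = (np.arange(1, m + 1) - 0.5) / m
    lam = float(np.median(stats.chi2.isf(p, 1)) / stats.chi2.ppf(0.5, 1))
    return QQResult(
        expected=-np.log10(exp),
        observed=-np.log10(obs),
        lambda_gc=lam,
    )
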