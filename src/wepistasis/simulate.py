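"""Synthetic lipid-trial cohorts and the simulation studies run on them.

The generator emulates a fenofibrate pharmacogenomics cohort: ~680
unrelated subjects, biallelic SNPs in Hardy-Weinberg proportions with MAF
drawn from [0.05, 0.5], bimodal beta-mixture methylation values as produced
by array-based methylation profiling, markers placed so that cis SNP-CpG
pairs within 10 kb exist, and a binary drug-response phenotype from a
logistic model with optional main and interaction effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import expit

from .benchmarks import lr_interaction_test
from .data_io import GenotypeMatrix, MarkerMap, MethylationMatrix
from .preprocess import binarize_methylation, encode_additive
from .wtest import (
    DEFAULT_BOOT_REPS,
    bootstrap_null_samples,
    estimate_hf,
    wtest_pair,
)

__all__ = [
    "SimConfig",
    "SimStudyResult",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_positions",
    "simulate_phenotype",
    "type_i_error_experiment",
    "power_experiment",
    "load_sim_config",
    "save_sim_config",
]

# fixed stream tags keep the per-component generators independent of each
# other while remaining pure functions of the user seed
_TAG_GENO, _TAG_METH, _TAG_POS, _TAG_PHENO, _TAG_EXPT = 11, 13, 17, 19, 23

CIS_WINDOW_BP = 10_000


@dataclass
class SimConfig:
    """Knobs of the synthetic cohort generator.

    Defaults follow the emulated study: 680 subjects, MAF uniform on
    [0.05, 0.5], Beta(2,8)/Beta(8,2) half-half methylation mixture, a
    baseline log-odds of 0 (balanced responders), and a null effect model.
    """

    n_subjects: int = 680
    n_snps: int = 1
    n_cpgs: int = 1
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_low_shapes: tuple[float, float] = (2.0, 8.0)
    beta_high_shapes: tuple[float, float] = (8.0, 2.0)
    high_proportion: float = 0.5
    chrom_length: int = 1_000_000
    chromosome: str = "11"
    effect_model: str = "null"  # null | main | interaction
    beta0: float = 0.0
    beta_snp: float = 0.0
    beta_cpg: float = 0.0
    beta_int: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        for shapes in (self.beta_low_shapes, self.beta_high_shapes):
            if min(shapes) <= 0:
                raise ValueError(f"beta mixture shapes must be positive, got {shapes}")
        if not (0.0 < self.high_proportion <= 1.0):
            raise ValueError("high_proportion must be in (0, 1]")
        if self.effect_model not in ("null", "main", "interaction"):
            raise ValueError(f"unknown effect_model {self.effect_model!r}")


@dataclass
class SimStudyResult:
    """Rejection-rate summary of one simulation study arm."""

    test_id: str
    n_replicates: int
    alpha: float
    rejections: int
    extra: dict = field(default_factory=dict)

    @property
    def rate(self) -> float:
        return self.rejections / self.n_replicates

    @property
    def mc_se(self) -> float:
        r = self.rate
        return float(np.sqrt(r * (1.0 - r) / self.n_replicates))


def _rng(tag: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([tag, seed])


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw genotypes in Hardy-Weinberg proportions with per-SNP uniform MAF."""
    rng = rng or _rng(_TAG_GENO, config.seed)
    n, p = config.n_subjects, config.n_snps
    maf = rng.uniform(*config.maf_range, size=p)
    u = rng.random((n, p))
    p_aa = (1.0 - maf) ** 2  # homozygous major
    p_ab = 2.0 * maf * (1.0 - maf)
    geno = (u >= p_aa).astype(float) + (u >= p_aa + p_ab)
    return GenotypeMatrix(
        subject_ids=[f"S{i + 1:05d}" for i in range(n)],
        snp_ids=[f"snp{j + 1:05d}" for j in range(p)],
        values=geno,
    )


def simulate_methylation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> MethylationMatrix:
    """Draw bimodal beta values from a two-state beta mixture."""
    rng = rng or _rng(_TAG_METH, config.seed)
    n, p = config.n_subjects, config.n_cpgs
    high = rng.random((n, p)) < config.high_proportion
    a_lo, b_lo = config.beta_low_shapes
    a_hi, b_hi = config.beta_high_shapes
    betas = np.where(
        high,
        rng.beta(a_hi, b_hi, size=(n, p)),
        rng.beta(a_lo, b_lo, size=(n, p)),
    )
    return MethylationMatrix(
        subject_ids=[f"S{i + 1:05d}" for i in range(n)],
        cpg_ids=[f"cg{j + 1:05d}" for j in range(p)],
        values=betas,
    )


def simulate_positions(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[MarkerMap, MarkerMap]:
    """Place SNPs uniformly and anchor most CpGs within 10 kb of a SNP.

    Each CpG lands within the cis window of a randomly chosen SNP with
    probability 0.8 (guaranteeing cis pairs exist), otherwise uniformly on
    the chromosome.
    """
    if config.chrom_length < 2 * CIS_WINDOW_BP + 1:
        raise ValueError(f"chrom_length must be at least {2 * CIS_WINDOW_BP + 1} bp")
    rng = rng or _rng(_TAG_POS, config.seed)
    snp_pos = rng.integers(1, config.chrom_length + 1, size=config.n_snps)
    anchored = rng.random(config.n_cpgs) < 0.8
    anchor_snp = rng.integers(0, config.n_snps, size=config.n_cpgs)
    offset = rng.integers(-CIS_WINDOW_BP, CIS_WINDOW_BP + 1, size=config.n_cpgs)
    cpg_pos = np.where(
        anchored,
        np.clip(snp_pos[anchor_snp] + offset, 1, config.chrom_length),
        rng.integers(1, config.chrom_length + 1, size=config.n_cpgs),
    )
    chrom = config.chromosome
    snp_map = MarkerMap(
        "SNP",
        [f"snp{j + 1:05d}" for j in range(config.n_snps)],
        [chrom] * config.n_snps,
        snp_pos,
    )
    cpg_map = MarkerMap(
        "CpG",
        [f"cg{j + 1:05d}" for j in range(config.n_cpgs)],
        [chrom] * config.n_cpgs,
        cpg_pos,
    )
    return snp_map, cpg_map


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    config: SimConfig,
    causal_snp: int = 0,
    causal_cpg: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw a binary response from a logistic model on one causal pair.

    P(Y=1) = logistic(beta0 + beta_snp*G + beta_cpg*M + beta_int*G*M) with G
    the additive genotype code and M the raw beta value; the null model
    zeroes all three effects.
    """
    rng = rng or _rng(_TAG_PHENO, config.seed)
    n = genotypes.n_subjects
    eta = np.full(n, config.beta0)
    if config.effect_model != "null":
        try:
            g = genotypes.values[:, causal_snp]
            m = methylation.values[:, causal_cpg]
        except IndexError:
            raise ValueError("designated causal pair is outside the simulated markers") from None
        eta = eta + config.beta_snp * g + config.beta_cpg * m
        if config.effect_model == "interaction":
            eta = eta + config.beta_int * g * m
    return (rng.random(n) < expit(eta)).astype(np.int8)


def _prepare_cohort(config: SimConfig):
    """Generate and encode a cohort; returns analysis-ready arrays."""
    geno = simulate_genotypes(config)
    meth = simulate_methylation(config)
    codes = np.column_stack(
        [encode_additive(geno.values[:, j]).codes for j in range(geno.n_snps)]
    )
    labels = np.column_stack(
        [binarize_methylation(meth.values[:, j]).labels for j in range(meth.n_cpgs)]
    )
    return geno, meth, codes, labels


def type_i_error_experiment(
    config: SimConfig,
    n_replicates: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
    include_lr: bool = False,
    boot_reps: int = DEFAULT_BOOT_REPS,
    subsample_size: int | None = None,
    average_over_pairs: bool = False,
    recalibrate_each: bool = False,
) -> dict[str, SimStudyResult]:
    """Empirical type-I error of the tests under permuted phenotypes.

    One cohort is generated and the chi-squared calibration (h, f) fitted
    once; each replicate permutes the phenotype and tests one SNP-CpG pair
    (the first, or a rotating pair when ``average_over_pairs``), counting
    p <= alpha as a false positive.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    seed = config.seed if seed is None else seed
    rng = _rng(_TAG_EXPT, seed)
    geno, meth, codes, labels = _prepare_cohort(config)
    y = simulate_phenotype(geno, meth, replace(config, effect_model="null"), rng=rng)
    if y.min() == y.max():  # pragma: no cover - beta0=0 makes this vanishing
        raise RuntimeError("degenerate phenotype draw: single class")

    pairs = (
        [(i % geno.n_snps, i % meth.n_cpgs) for i in range(max(geno.n_snps, meth.n_cpgs))]
        if average_over_pairs
        else [(0, 0)]
    )
    calib = estimate_hf(
        bootstrap_null_samples(
            codes, labels, y, pairs, B=boot_reps, subsample_size=subsample_size, seed=rng
        )
    )

    counts = {"wtest": 0}
    if include_lr:
        counts.update(lr_m1=0, lr_m2=0)
    pvals = {t: [] for t in counts}
    for r in range(n_replicates):
        yp = rng.permutation(y)
        si, ci = pairs[r % len(pairs)]
        if recalibrate_each:
            calib = estimate_hf(
                bootstrap_null_samples(
                    codes, labels, yp, pairs, B=boot_reps,
                    subsample_size=subsample_size, seed=rng,
                )
            )
        res = wtest_pair(codes[:, si], labels[:, ci], yp, calib)
        pvals["wtest"].append(res.p_value)
        if res.p_value <= alpha:
            counts["wtest"] += 1
        if include_lr:
            for tid, mode, vals in (
                ("lr_m1", "binary", labels[:, ci].astype(float)),
                ("lr_m2", "continuous", meth.values[:, ci]),
            ):
                lr = lr_interaction_test(codes[:, si], vals, yp, cpg_mode=mode)
                pvals[tid].append(lr.p_value)
                if lr.converged and lr.p_value <= alpha:
                    counts[tid] += 1
    return {
        tid: SimStudyResult(
            test_id=tid,
            n_replicates=n_replicates,
            alpha=alpha,
            rejections=c,
            extra={"p_values": np.asarray(pvals[tid])},
        )
        for tid, c in counts.items()
    }


def power_experiment(
    config: SimConfig,
    n_replicates: int = 500,
    alpha: float = 0.05,
    effect_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0),
    seed: int | None = None,
    boot_reps: int = DEFAULT_BOOT_REPS,
) -> dict[float, SimStudyResult]:
    """Rejection rate on the causal pair across interaction effect sizes.

    For each interaction log-odds in ``effect_grid`` the phenotype is
    redrawn per replicate from the interaction model on a fixed cohort; the
    calibration is fitted once per effect setting from permuted-phenotype
    bootstrap samples (a valid null regardless of the generating effect).
    """
    if not effect_grid:
        raise ValueError("effect_grid must be non-empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    seed = config.seed if seed is None else seed
    geno, meth, codes, labels = _prepare_cohort(config)
    out: dict[float, SimStudyResult] = {}
    for b_int in effect_grid:
        cfg = replace(config, effect_model="interaction", beta_int=float(b_int))
        rng = _rng(_TAG_EXPT, seed)
        y0 = simulate_phenotype(geno, meth, cfg, rng=rng)
        calib = estimate_hf(
            bootstrap_null_samples(codes, labels, y0, [(0, 0)], B=boot_reps, seed=rng)
        )
        rejections = 0
        for _ in range(n_replicates):
            y = simulate_phenotype(geno, meth, cfg, rng=rng)
            if y.min() == y.max():
                continue
            res = wtest_pair(codes[:, 0], labels[:, 0], y, calib)
            if res.p_value <= alpha:
                rejections += 1
        out[float(b_int)] = SimStudyResult(
            test_id="wtest",
            n_replicates=n_replicates,
            alpha=alpha,
            rejections=rejections,
            extra={"beta_int": float(b_int)},
        )
    return out


# ---------------------------------------------------------------------------
# flat key=value config round-trip (CLI surface)

_FLOAT_FIELDS = {
    "high_proportion", "beta0", "beta_snp", "beta_cpg", "beta_int",
}
_INT_FIELDS = {"n_subjects", "n_snps", "n_cpgs", "chrom_length", "seed"}
_PAIR_FIELDS = {"maf_range", "beta_low_shapes", "beta_high_shapes"}


def save_sim_config(config: SimConfig, path) -> None:
    with Path(path).open("w") as fh:
        for name in config.__dataclass_fields__:
            value = getattr(config, name)
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            fh.write(f"{name}={value}\n")


def load_sim_config(path) -> SimConfig:
    kwargs = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}: line {lineno}: expected key=value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in SimConfig.__dataclass_fields__:
            raise ValueError(f"{path}: unknown config key {key!r}")
        if key in _INT_FIELDS:
            kwargs[key] = int(value)
        elif key in _FLOAT_FIELDS:
            kwargs[key] = float(value)
        elif key in _PAIR_FIELDS:
            parts = [float(v) for v in value.split(",")]
            if len(parts) != 2:
                raise ValueError(f"{path}: {key} needs two comma-separated numbers")
            kwargs[key] = tuple(parts)
        else:
            kwargs[key] = value
    return SimConfig(**kwargs)
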