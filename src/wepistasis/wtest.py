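"""The W-test for SNP-CpG epistasis and its adaptive chi-squared calibration.

For one SNP (additively coded 0/1/2) and one CpG (binarized low/high) the
subjects fall into at most six joint categories. Within each retained
category i the case/control contrast is summarized by the log odds ratio of
the category-versus-rest 2x2 table, standardized by its standard error:

    z_i = log[ (p1_i / (1 - p1_i)) / (p0_i / (1 - p0_i)) ] / SE_i

where p1_i and p0_i are the proportions of cases and controls falling in
category i and SE_i = sqrt(1/n1_i + 1/(n1 - n1_i) + 1/n0_i + 1/(n0 - n0_i)).
The raw statistic S = sum(z_i^2) is rescaled as W = h * S, which follows a
chi-squared distribution with f degrees of freedom; h and f are estimated
from the working data by moment matching against bootstrapped null
statistics (subjects resampled, phenotype permuted), making the reference
distribution data-set adaptive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "CellStat",
    "CalibrationEntry",
    "CalibrationTable",
    "WResult",
    "build_pair_categories",
    "tabulate_cells",
    "raw_statistic",
    "bootstrap_null_samples",
    "estimate_hf",
    "wtest_pvalue",
    "wtest_pair",
    "N_CATEGORIES",
    "DEFAULT_BOOT_REPS",
    "DEFAULT_SAMPLE_FLOOR",
]

#: 3 genotype levels x 2 methylation levels
N_CATEGORIES = 6
DEFAULT_BOOT_REPS = 400
DEFAULT_SAMPLE_FLOOR = 50

#: joint category order: (snp_level, cpg_level) -> index
CATEGORY_LABELS = [(s, m) for s in (0, 1, 2) for m in (0, 1)]


@dataclass
class ContingencyTable:
    """Per-category case/control counts for one SNP-CpG pair.

    Categories empty in both groups are dropped; ``k`` counts the retained
    categories. ``cell_corrected`` marks cells whose category-versus-rest
    2x2 collapse contains a zero and therefore receives the
    Haldane-Anscombe 0.5 continuity correction when the log odds ratio is
    computed.
    """

    k: int
    case_counts: np.ndarray  # int, length k
    control_counts: np.ndarray  # int, length k
    n1: int
    n0: int
    category_labels: list[tuple[int, int]]
    cell_corrected: np.ndarray  # bool, length k

    @property
    def correction_applied(self) -> bool:
        return bool(self.cell_corrected.any())


@dataclass
class CellStat:
    log_or: float
    se: float
    z2: float
    corrected: bool


@dataclass
class CalibrationEntry:
    h: float
    f: float
    m_boot: float
    v_boot: float
    n_samples: int
    pooled_fallback: bool = False


@dataclass
class CalibrationTable:
    """(h, f) estimates keyed by number of non-empty categories k."""

    entries: dict[int, CalibrationEntry]
    pooled: CalibrationEntry

    def lookup(self, k: int) -> CalibrationEntry:
        return self.entries.get(k, self.pooled)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "k": k,
                "h": e.h,
                "f": e.f,
                "m_boot": e.m_boot,
                "v_boot": e.v_boot,
                "n_samples": e.n_samples,
                "pooled_fallback": int(e.pooled_fallback),
            }
            for k, e in sorted(self.entries.items())
        ]
        rows.append(
            {
                "k": 0,  # k = 0 row stores the pooled estimate
                "h": self.pooled.h,
                "f": self.pooled.f,
                "m_boot": self.pooled.m_boot,
                "v_boot": self.pooled.v_boot,
                "n_samples": self.pooled.n_samples,
                "pooled_fallback": 0,
            }
        )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CalibrationTable":
        df = pd.read_csv(Path(path), sep="\t")
        entries: dict[int, CalibrationEntry] = {}
        pooled = None
        for _, row in df.iterrows():
            entry = CalibrationEntry(
                h=float(row["h"]),
                f=float(row["f"]),
                m_boot=float(row["m_boot"]),
                v_boot=float(row["v_boot"]),
                n_samples=int(row["n_samples"]),
                pooled_fallback=bool(row["pooled_fallback"]),
            )
            if int(row["k"]) == 0:
                pooled = entry
            else:
                entries[int(row["k"])] = entry
        if pooled is None:
            raise ValueError(f"{path}: calibration file lacks the pooled (k=0) row")
        return cls(entries=entries, pooled=pooled)


@dataclass
class WResult:
    """Calibrated W statistic and p-value for one pair."""

    S: float
    W: float
    h: float
    f: float
    k: int
    p_value: float
    per_cell: list[CellStat] = field(default_factory=list)


def build_pair_categories(snp_coded, cpg_binary) -> np.ndarray:
    """Map (genotype level, methylation level) to a stable index 0..5.

    Order is (0,low),(0,high),(1,low),(1,high),(2,low),(2,high).
    """
    g = np.asarray(snp_coded)
    m = np.asarray(cpg_binary)
    if g.shape != m.shape:
        raise ValueError(f"length mismatch: {g.shape} genotypes vs {m.shape} CpG labels")
    if np.isnan(np.asarray(g, dtype=float)).any() or np.isnan(np.asarray(m, dtype=float)).any():
        raise ValueError("missing values in pair variables; complete cases required")
    return (2 * g + m).astype(np.intp)


def tabulate_cells(categories, phenotype) -> ContingencyTable:
    """Count cases and controls per joint category, dropping empty categories."""
    cats = np.asarray(categories, dtype=np.intp)
    y = np.asarray(phenotype)
    if cats.shape != y.shape:
        raise ValueError("categories and phenotype differ in length")
    uniq = np.unique(y)
    if not np.isin(uniq, (0, 1)).all() or uniq.size != 2:
        raise ValueError("phenotype must be binary with both classes present")
    case_counts = np.bincount(cats[y == 1], minlength=N_CATEGORIES)
    control_counts = np.bincount(cats[y == 0], minlength=N_CATEGORIES)
    occupied = (case_counts + control_counts) > 0
    case_counts = case_counts[occupied]
    control_counts = control_counts[occupied]
    labels = [CATEGORY_LABELS[i] for i in np.nonzero(occupied)[0]]
    n1 = int(case_counts.sum())
    n0 = int(control_counts.sum())
    corrected = (
        (case_counts == 0)
        | (case_counts == n1)
        | (control_counts == 0)
        | (control_counts == n0)
    )
    return ContingencyTable(
        k=int(occupied.sum()),
        case_counts=case_counts.astype(np.int64),
        control_counts=control_counts.astype(np.int64),
        n1=n1,
        n0=n0,
        category_labels=labels,
        cell_corrected=corrected,
    )


def raw_statistic(table: ContingencyTable) -> tuple[float, list[CellStat]]:
    """Sum of squared standardized log odds ratios over retained categories.

    Each category is collapsed against the rest into a 2x2 table
    (category vs rest) x (case vs control); cells flagged for continuity
    correction get 0.5 added to all four entries of their collapse.
    """
    if table.k < 2:
        raise ValueError("degenerate table: fewer than 2 non-empty categories")
    cells: list[CellStat] = []
    s = 0.0
    for i in range(table.k):
        a = float(table.case_counts[i])
        b = float(table.n1 - table.case_counts[i])
        c = float(table.control_counts[i])
        d = float(table.n0 - table.control_counts[i])
        corrected = bool(table.cell_corrected[i])
        if corrected:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        log_or = np.log(a / b) - np.log(c / d)
        se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
        z2 = (log_or / se) ** 2
        s += z2
        cells.append(CellStat(log_or=log_or, se=se, z2=z2, corrected=corrected))
    return s, cells


def bootstrap_null_samples(
    snp_codes: np.ndarray,
    cpg_labels: np.ndarray,
    phenotype: np.ndarray,
    pairs: list[tuple[int, int]],
    B: int = DEFAULT_BOOT_REPS,
    subsample_size: int | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[int, np.ndarray]:
    """Draw null raw statistics for calibration, grouped by observed k.

    Each replicate resamples subjects with replacement, permutes the
    phenotype within the draw (enforcing the null of no SNP/CpG association)
    and evaluates S on a randomly chosen candidate pair.

    Parameters
    ----------
    snp_codes : (n, n_snps) additive codes, no missing
    cpg_labels : (n, n_cpgs) binary methylation labels
    phenotype : (n,) binary vector
    pairs : candidate (snp_index, cpg_index) list the scan will test
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if not pairs:
        raise ValueError("no candidate pairs for calibration")
    snp_codes = np.atleast_2d(np.asarray(snp_codes))
    cpg_labels = np.atleast_2d(np.asarray(cpg_labels))
    y = np.asarray(phenotype)
    n = len(y)
    if subsample_size is None:
        subsample_size = min(n, 1000)
    if not 1 <= subsample_size <= n:
        raise ValueError("subsample_size must be in [1, n]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    samples: dict[int, list[float]] = {}
    attempts = 0
    collected = 0
    max_attempts = 50 * B
    while collected < B and attempts < max_attempts:
        attempts += 1
        idx = rng.integers(0, n, size=subsample_size)
        yb = rng.permutation(y[idx])
        if yb.min() == yb.max():
            continue  # single-class draw carries no case/control contrast
        si, ci = pairs[rng.integers(len(pairs))]
        cats = build_pair_categories(snp_codes[idx, si], cpg_labels[idx, ci])
        tab = tabulate_cells(cats, yb)
        if tab.k < 2:
            continue
        s, _ = raw_statistic(tab)
        samples.setdefault(tab.k, []).append(s)
        collected += 1
    if collected < B:
        raise RuntimeError(
            f"calibration bootstrap produced only {collected}/{B} usable replicates"
        )
    return {k: np.asarray(v) for k, v in sorted(samples.items())}


def _moment_match(s: np.ndarray) -> tuple[float, float, float, float]:
    """Match h*S to a chi-squared by mean/variance: E = f, Var = 2f."""
    m = float(np.mean(s))
    v = float(np.var(s, ddof=1))
    if v <= 0:
        raise ValueError("degenerate null samples: zero variance")
    return 2 * m / v, 2 * m * m / v, m, v


def estimate_hf(
    null_samples: dict[int, np.ndarray],
    floor: int = DEFAULT_SAMPLE_FLOOR,
) -> CalibrationTable:
    """Estimate the scaling constant h and degrees of freedom f per k.

    ``h = 2m/v`` and ``f = 2m^2/v`` with m, v the mean and variance of the
    bootstrapped null statistics. Groups with fewer than ``floor`` samples
    fall back to the pooled estimate over all k.
    """
    if not null_samples:
        raise ValueError("no null samples")
    all_s = np.concatenate(list(null_samples.values()))
    if len(all_s) < 2:
        raise ValueError("need at least 2 null samples")
    h, f, m, v = _moment_match(all_s)
    pooled = CalibrationEntry(h=h, f=f, m_boot=m, v_boot=v, n_samples=len(all_s))
    entries: dict[int, CalibrationEntry] = {}
    for k, s in null_samples.items():
        if len(s) >= floor:
            h, f, m, v = _moment_match(s)
            entries[k] = CalibrationEntry(h=h, f=f, m_boot=m, v_boot=v, n_samples=len(s))
        else:
            entries[k] = CalibrationEntry(
                h=pooled.h,
                f=pooled.f,
                m_boot=pooled.m_boot,
                v_boot=pooled.v_boot,
                n_samples=len(s),
                pooled_fallback=True,
            )
    return CalibrationTable(entries=entries, pooled=pooled)


def wtest_pvalue(S: float, calibration: CalibrationTable, k: int) -> WResult:
    """Calibrated statistic W = h*S and its upper-tail chi-squared p-value."""
    if S < 0:
        raise ValueError("raw statistic must be non-negative")
    entry = calibration.lookup(k)
    w = entry.h * S
    p = float(stats.chi2.sf(w, entry.f))
    return WResult(S=S, W=w, h=entry.h, f=entry.f, k=k, p_value=p)


def wtest_pair(
    snp_coded,
    cpg_binary,
    phenotype,
    calibration: CalibrationTable,
) -> WResult:
    """End-to-end W-test for one SNP-CpG pair on complete-case vectors."""
    cats = build_pair_categories(snp_coded, cpg_binary)
    tab = tabulate_cells(cats, phenotype)
    s, cells = raw_statistic(tab)
    res = wtest_pvalue(s, calibration, tab.k)
    res.per_cell = cells
    return res
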