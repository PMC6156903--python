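"""Analysis-ready variables from raw tables.

Covers additive minor-allele coding, two-mean binarization of methylation
beta values, triglyceride-based drug-response labels, and complete-case
cohort alignment. Subject alignment is always by id, never by row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GenotypeMatrix, MethylationMatrix, PhenotypeTable

__all__ = [
    "EncodedSNP",
    "BinarizedCpG",
    "Cohort",
    "encode_additive",
    "binarize_methylation",
    "define_drug_response",
    "complete_case_filter",
    "RESPONDER_DELTA_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: fractional TG decrease above which treatment counts as effective
RESPONDER_DELTA_THRESHOLD = 0.30


@dataclass
class EncodedSNP:
    """Additive coding of one SNP, polarized to the dataset minor allele."""

    codes: np.ndarray  # {0,1,2} with nan for missing
    maf: float
    flipped: bool
    monomorphic: bool


@dataclass
class BinarizedCpG:
    """Low/high methylation split of one CpG by two-mean clustering."""

    labels: np.ndarray  # int8, 0 = low, 1 = high
    center_low: float
    center_high: float
    n_iterations: int

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.center_low + self.center_high)


def encode_additive(genotypes) -> EncodedSNP:
    """Polarize a dosage vector so codes count the dataset minor allele.

    If the counted allele's observed frequency exceeds 0.5 the codes are
    flipped (g -> 2 - g); ``maf`` is the counted-allele frequency after
    flipping. Missing entries (nan) are preserved.
    """
    g = np.asarray(genotypes, dtype=float).copy()
    obs = ~np.isnan(g)
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("monomorphic/empty SNP: no observed genotypes")
    freq = float(g[obs].sum()) / (2 * n_obs)
    flipped = freq > 0.5
    if flipped:
        g[obs] = 2.0 - g[obs]
        freq = 1.0 - freq
    monomorphic = np.unique(g[obs]).size == 1
    if monomorphic:
        logger.debug("monomorphic SNP (maf=%.4f)", freq)
    return EncodedSNP(codes=g, maf=freq, flipped=flipped, monomorphic=monomorphic)


def _threshold_scan(x: np.ndarray) -> np.ndarray:
    """Exhaustive 1-D two-cluster split minimizing within-cluster SSE.

    Returns the boolean high-cluster mask. Every two-cluster partition of
    1-D data that minimizes SSE is a threshold partition of the sorted
    values, so scanning thresholds is exact.
    """
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(xs)
    best_sse, best_split = np.inf, 1
    csum = np.cumsum(xs)
    csq = np.cumsum(xs**2)
    for split in range(1, n):
        if xs[split] == xs[split - 1]:
            continue  # identical values must share a cluster
        s1, q1 = csum[split - 1], csq[split - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        sse = (q1 - s1**2 / split) + (q2 - s2**2 / (n - split))
        if sse < best_sse - 1e-12:
            best_sse, best_split = sse, split
    high = np.zeros(n, dtype=bool)
    high[order[best_split:]] = True
    return high


def binarize_methylation(betas, max_iter: int = 100) -> BinarizedCpG:
    """Split beta values into low/high states with deterministic 1-D k-means.

    Lloyd iterations start from centers at the min and max value, so the
    procedure involves no randomness. Because min/max-initialized Lloyd can
    stall in a local optimum (e.g. on [0, 0, 0.5, 1]), the converged split
    is replaced by the exhaustive threshold scan whenever n <= 1000,
    guaranteeing the globally SSE-optimal two-cluster partition; for larger
    n the Lloyd solution stands.
    """
    x = np.asarray(betas, dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing beta values: apply complete-case filtering first")
    if np.unique(x).size < 2:
        raise ValueError("constant CpG, cannot binarize")
    c_low, c_high = float(x.min()), float(x.max())
    labels = x > 0.5 * (c_low + c_high)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        c_low = float(x[~labels].mean())
        c_high = float(x[labels].mean())
        new_labels = x > 0.5 * (c_low + c_high)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    if len(x) <= 1000:
        exact = _threshold_scan(x)
        if not np.array_equal(exact, labels):
            labels = exact
        c_low = float(x[~labels].mean())
        c_high = float(x[labels].mean())
    return BinarizedCpG(
        labels=labels.astype(np.int8),
        center_low=c_low,
        center_high=c_high,
        n_iterations=n_iter,
    )


def define_drug_response(phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Derive responder labels from the four TG visits.

    TG_pre averages visits 1-2, TG_post visits 3-4, and the fractional
    change is (TG_pre - TG_post) / TG_pre. A subject is a responder only
    when the decrease strictly exceeds 30%. Subjects carrying a precomputed
    response are passed through unchanged; subjects with neither complete
    TG visits nor a response get ``responder = nan``.
    """
    ids = phenotypes.subject_ids
    tg = phenotypes.tg
    out = pd.DataFrame(index=pd.Index(ids, name="subject_id"))
    has_tg = ~np.isnan(tg).any(axis=1)
    tg_pre = np.where(has_tg, tg[:, :2].mean(axis=1), np.nan)
    tg_post = np.where(has_tg, tg[:, 2:].mean(axis=1), np.nan)
    with np.errstate(invalid="ignore"):
        delta = (tg_pre - tg_post) / tg_pre
    responder = phenotypes.response.copy()
    derive = np.isnan(responder) & has_tg
    responder[derive] = (delta[derive] > RESPONDER_DELTA_THRESHOLD).astype(float)
    out["tg_pre"] = tg_pre
    out["tg_post"] = tg_post
    out["delta_pct"] = delta
    out["responder"] = responder
    return out


@dataclass
class Cohort:
    """Aligned complete-case analysis set."""

    subject_ids: list[str]
    genotypes: GenotypeMatrix
    methylation: MethylationMatrix
    response: np.ndarray  # int8 {0,1}
    removal_log: dict[str, int]


def complete_case_filter(
    genotypes: GenotypeMatrix,
    methylation: MethylationMatrix,
    phenotypes: PhenotypeTable,
) -> Cohort:
    """Intersect the three tables on subject id and drop incomplete records.

    Returned subjects are in sorted-id order so downstream statistics do not
    depend on input row order. The removal log counts subjects dropped per
    reason (not in all tables, missing genotype, missing methylation,
    missing phenotype).
    """
    gid = set(genotypes.subject_ids)
    mid = set(methylation.subject_ids)
    pid = set(phenotypes.subject_ids)
    union = gid | mid | pid
    common = sorted(gid & mid & pid)
    log = {"not_in_all_tables": len(union) - len(common)}
    if not common:
        raise ValueError("no subjects shared by genotype, methylation and phenotype tables")

    g_idx = {s: i for i, s in enumerate(genotypes.subject_ids)}
    m_idx = {s: i for i, s in enumerate(methylation.subject_ids)}
    resp = define_drug_response(phenotypes)["responder"]

    keep: list[str] = []
    log.update(missing_genotype=0, missing_methylation=0, missing_phenotype=0)
    for s in common:
        if np.isnan(genotypes.values[g_idx[s]]).any():
            log["missing_genotype"] += 1
        elif np.isnan(methylation.values[m_idx[s]]).any():
            log["missing_methylation"] += 1
        elif np.isnan(resp.loc[s]):
            log["missing_phenotype"] += 1
        else:
            keep.append(s)
    if not keep:
        raise ValueError("no complete-case subjects remain after filtering")
    for reason, n in log.items():
        if n:
            logger.info("complete-case filter removed %d subject(s): %s", n, reason)

    g_rows = [g_idx[s] for s in keep]
    m_rows = [m_idx[s] for s in keep]
    return Cohort(
        subject_ids=keep,
        genotypes=GenotypeMatrix(keep, list(genotypes.snp_ids), genotypes.values[g_rows]),
        methylation=MethylationMatrix(
            keep, list(methylation.cpg_ids), methylation.values[m_rows]
        ),
        response=resp.loc[keep].to_numpy().astype(np.int8),
        removal_log=log,
    )
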