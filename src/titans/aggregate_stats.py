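"""Cross-cohort aggregation: meta-analysis, multiple testing, PRS, and pTDT."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import expression_models as em


@dataclass
class MetaResult:
    beta: float
    se: float
    z: float
    p: float
    n_studies: int


def ivw_meta(betas: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    w_i = 1/se_i^2, combined beta = sum(w b)/sum(w), SE = sum(w)^(-1/2).
    Records with non-positive SE are excluded with a warning.  A single
    usable record is returned unchanged.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    ok = np.isfinite(b) & np.isfinite(s) & (s > 0)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} records with non-positive or missing "
                      "SE excluded from IVW meta-analysis")
    b, s = b[ok], s[ok]
    if b.size == 0:
        raise ValueError("no usable records for IVW meta-analysis")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    return MetaResult(beta, se, z, float(2 * stats.norm.sf(abs(z))), int(b.size))


def stouffer_meta(zs: Sequence[float], ns: Sequence[float]) -> tuple[float, float]:
    """Sample-size-weighted z-score meta-analysis.

    Weights are sqrt(N_i); combined z = sum(w z) / sqrt(sum w^2).  For trio
    cohorts N is the number of informative families.
    """
    z = np.asarray(zs, dtype=float)
    n = np.asarray(ns, dtype=float)
    if (n <= 0).any():
        raise ValueError("sample sizes must be positive")
    w = np.sqrt(n)
    zc = float((w * z).sum() / np.sqrt((w**2).sum()))
    return zc, float(2 * stats.norm.sf(abs(zc)))


def two_stage_meta(
    stage1: pd.DataFrame, replication_z: float, replication_n: float
) -> tuple[float, float]:
    """IVW across trio cohorts, then z-based combination with a replication z.

    ``stage1`` needs columns beta, se, n.  Used when the replication stage
    reports only z-scores (no effect sizes).
    """
    m = ivw_meta(stage1["beta"], stage1["se"])
    n1 = float(stage1["n"].sum())
    return stouffer_meta([m.z, replication_z], [n1, replication_n])


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_tiers(
    records: pd.DataFrame,
    alpha: float = 0.05,
    n_total_tests: Optional[int] = None,
) -> pd.DataFrame:
    """Flag per-tissue FDR significance and cross-tissue Bonferroni significance.

    Per tissue, BH-adjusted p <= alpha; across tissues, p below
    alpha / n_total_tests where the total test count defaults to the number
    of rows (it is a configuration input when the table is a subset of the
    full scan; e.g. 125,000 tests at alpha 0.05 give a 4.0e-7 cutoff).
    """
    out = records.copy()
    if len(out) == 0:
        out["tissue_fdr_significant"] = pd.Series(dtype=bool)
        out["crosstissue_significant"] = pd.Series(dtype=bool)
        return out
    out["p_adjusted"] = np.nan
    for _, idx in out.groupby("tissue").groups.items():
        sub = out.loc[idx, "p"]
        mask = sub.notna()
        if mask.any():
            out.loc[sub.index[mask], "p_adjusted"] = bh_adjust(sub[mask].to_numpy())
    out["tissue_fdr_significant"] = out["p_adjusted"] <= alpha
    total = n_total_tests if n_total_tests is not None else int(out["p"].notna().sum())
    cutoff = alpha / total
    out["crosstissue_significant"] = out["p"] <= cutoff
    out.attrs["crosstissue_cutoff"] = cutoff
    return out


def prs_score(
    aligned: em.AlignedModel, matrix, samples: Optional[Sequence[str]] = None
) -> pd.Series:
    """Polygenic score per sample: sum of effect weights times dosage.

    Reuses the harmonized-model scoring path (a PRS is the same linear
    predictor as an expression model).  Missing variants were already
    dropped and counted during harmonization.
    """
    if aligned.n_predictors == 0:
        raise ValueError("no overlapping variants between weights and genotypes")
    if samples is None:
        samples = matrix.samples
    idx = [matrix.sample_index(s) for s in samples]
    dos = matrix.haplotypes[idx][:, aligned.col_idx, :].sum(axis=2)
    return pd.Series(em.impute_expression(aligned, dos), index=list(samples))


@dataclass
class PTDTResult:
    mean_deviation: float
    se: float
    t: float
    df: int
    p: float
    n_families: int


def ptdt(
    proband_prs: Sequence[float],
    father_prs: Sequence[float],
    mother_prs: Sequence[float],
) -> PTDTResult:
    """Polygenic transmission disequilibrium test.

    Deviations (proband - midparent) / SD(midparent), with the sample SD
    (n - 1) of the midparent scores, are tested against zero with a
    one-sample two-sided t-test (df = n - 1).  Invariant to adding a
    constant to every individual's PRS.
    """
    pp = np.asarray(proband_prs, dtype=float)
    fp = np.asarray(father_prs, dtype=float)
    mp_ = np.asarray(mother_prs, dtype=float)
    if not (pp.size == fp.size == mp_.size):
        raise ValueError("PRS vectors must have equal length")
    if pp.size < 2:
        raise ValueError("pTDT needs at least 2 families")
    midparent = (fp + mp_) / 2.0
    sd_mp = midparent.std(ddof=1)
    if sd_mp == 0:
        raise ValueError("zero SD of midparent scores")
    dev = (pp - midparent) / sd_mp
    n = pp.size
    if dev.std(ddof=1) == 0:
        # degenerate: identical deviations (e.g. proband == midparent everywhere)
        t = 0.0 if dev.mean() == 0 else math.copysign(math.inf, dev.mean())
        p = 1.0 if t == 0 else 0.0
    else:
        t, p = stats.ttest_1samp(dev, 0.0)
    return PTDTResult(float(dev.mean()), float(dev.std(ddof=1) / np.sqrt(n)),
                      float(t), n - 1, float(p), n)
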