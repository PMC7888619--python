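"""Gene-set and de novo mutation enrichment statistics.

Covers four tests used to corroborate association hits: hypergeometric
over-representation of nominal hits in curated gene sets, Poisson enrichment
of de novo mutations against mutability-based expected counts, a
permutation test for coexpression with a focal gene, and a permutation test
for elevated prenatal expression across brain regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

# controlled annotation vocabulary -> consequence classes
LOF_LABELS = {
    "frameshift", "stop-gained", "splice-donor", "stop-gained-near-splice",
    "frameshift-near-splice", "stop-lost", "splice-acceptor",
}
MISSENSE_LABELS = {"missense", "missense-near-splice"}
SYNONYMOUS_LABELS = {"synonymous", "synonymous-near-splice"}

MPC_DELETERIOUS_THRESHOLD = 2.0  # strictly greater than


def _norm_label(label: str) -> str:
    return label.strip().lower().replace("_", "-").replace(" ", "-")


@dataclass(frozen=True)
class DeNovoRecord:
    sample_id: str
    group: str  # "proband" | "sibling"
    gene: str
    label: str
    mpc: Optional[float] = None


def classify_mutation(record: DeNovoRecord) -> set[str]:
    """Map an annotation label (plus optional MPC score) to mutation classes.

    Returns the set of classes the record belongs to: one of
    {"lof", "missense", "synonymous", "other"} plus "deleterious_missense"
    for missense records with MPC strictly greater than 2, and "all" for any
    classified (non-"other") record.
    """
    lab = _norm_label(record.label)
    if lab in LOF_LABELS:
        base = "lof"
    elif lab in MISSENSE_LABELS:
        base = "missense"
    elif lab in SYNONYMOUS_LABELS:
        base = "synonymous"
    else:
        return {"other"}
    classes = {base, "all"}
    if base == "missense" and record.mpc is not None and record.mpc > MPC_DELETERIOUS_THRESHOLD:
        classes.add("deleterious_missense")
    return classes


def hypergeom_enrichment(
    hit_set: Iterable[str], gene_set: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Over-representation of hits in a gene set, upper-tail hypergeometric.

    The gene set is first intersected with the universe (genes actually
    tested); fold = observed / expected with expected =
    |hits| * |set ∩ universe| / |universe|; p = P(X >= observed) with
    X ~ Hypergeom(|universe|, |set ∩ universe|, |hits|).  Symbols are
    matched case-insensitively.
    """
    uni = {g.upper() for g in universe}
    hits = {g.upper() for g in hit_set} & uni
    gset = {g.upper() for g in gene_set} & uni
    if not uni or not gset:
        return np.nan, np.nan
    observed = len(hits & gset)
    expected = len(hits) * len(gset) / len(uni)
    fold = observed / expected if expected > 0 else np.nan
    # P(X >= observed): sf(k-1) with M=|universe|, n=|set|, N=|hits|
    p = float(stats.hypergeom.sf(observed - 1, len(uni), len(gset), len(hits)))
    return fold, p


def expected_denovo_count(
    mutability: pd.DataFrame,
    gene_set: Iterable[str],
    n_individuals: int,
    mutation_class: str,
    scaling_factor: float = 2.0,
) -> float:
    """Expected de novo count in a gene set from per-gene mutability.

    ``mutability`` has columns (gene, class, mu) with mu the per-offspring
    per-chromosome de novo probability; expected = scaling_factor *
    n_individuals * sum of mu over the set.  The default factor 2 accounts
    for the two chromosome copies per offspring.  Genes absent from the
    table are reported and skipped.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    tab = mutability[mutability["class"] == mutation_class]
    mu = dict(zip(tab["gene"].str.upper(), tab["mu"]))
    genes = {g.upper() for g in gene_set}
    missing = sorted(genes - mu.keys())
    if missing:
        warnings.warn(f"{len(missing)} genes missing from mutability table: "
                      + ", ".join(missing[:5]))
    return float(scaling_factor * n_individuals * sum(mu[g] for g in genes & mu.keys()))


def poisson_enrichment(observed: int, expected: float) -> tuple[float, float]:
    """Fold enrichment and one-sided upper-tail Poisson p-value.

    p = P(X >= observed | lambda = expected), exact tail.  Non-positive
    expected counts yield NA.
    """
    if expected <= 0:
        return np.nan, np.nan
    fold = observed / expected
    p = float(stats.poisson.sf(observed - 1, expected))
    return fold, p


@dataclass
class CoexpressionResult:
    per_gene: pd.DataFrame  # gene, r, p, significant
    n_significant: int
    permutation_p: float
    n_permutations: int


def _pearson_with_p(focal: np.ndarray, mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of a focal vector against each matrix column, with t-test p."""
    n = focal.size
    f = focal - focal.mean()
    m = mat - mat.mean(axis=0)
    fss = (f**2).sum()
    mss = (m**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (f @ m) / np.sqrt(fss * mss)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    bad = (mss == 0) | (fss == 0)
    r[bad], p[bad] = np.nan, np.nan
    return r, p


def coexpression_test(
    expr: pd.DataFrame,
    focal_gene: str,
    gene_set: Sequence[str],
    alpha: float = 0.05,
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
    plus_one: bool = True,
) -> CoexpressionResult:
    """Permutation test for coexpression of a gene set with a focal gene.

    ``expr`` is genes x samples.  Per set gene: Pearson r with the focal
    gene and its t-test p-value; the count of genes significant after
    Bonferroni correction (alpha / |set|) is the statistic.  The null
    shuffles the focal gene's sample labels; permutation p = (r + 1)/(B + 1)
    (the uncorrected proportion is available with ``plus_one=False``).
    """
    if n_permutations < 1:
        raise ValueError("need >= 1 permutation")
    genes_upper = {g.upper(): g for g in expr.index}
    if focal_gene.upper() not in genes_upper:
        raise KeyError(f"focal gene {focal_gene!r} not in expression matrix")
    set_present = [genes_upper[g.upper()] for g in gene_set if g.upper() in genes_upper]
    if not set_present:
        raise ValueError("no gene-set members present in the expression matrix")
    focal = expr.loc[genes_upper[focal_gene.upper()]].to_numpy(dtype=float)
    if focal.size < 3:
        raise ValueError("need >= 3 samples")
    mat = expr.loc[set_present].to_numpy(dtype=float).T  # samples x genes

    cutoff = alpha / len(set_present)
    r, p = _pearson_with_p(focal, mat)
    sig = (p <= cutoff) & np.isfinite(p)
    n_sig = int(sig.sum())

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        rp, pp = _pearson_with_p(rng.permutation(focal), mat)
        if int(((pp <= cutoff) & np.isfinite(pp)).sum()) >= n_sig:
            exceed += 1
    perm_p = (exceed + 1) / (n_permutations + 1) if plus_one else exceed / n_permutations
    per_gene = pd.DataFrame({"gene": set_present, "r": r, "p": p, "significant": sig})
    return CoexpressionResult(per_gene, n_sig, float(perm_p), n_permutations)


def spatiotemporal_elevation_test(
    expr_by_sample: pd.Series,
    stage_labels: pd.Series,
    region_labels: pd.Series,
    stage_ages: pd.Series,
    boundary: float = 0.0,
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Permutation test for prenatal-vs-postnatal expression elevation.

    Inputs are aligned per-sample series: expression on the log2(RPKM+1)
    scale, a developmental-stage label, a brain-region label, and a numeric
    age per sample (same units as ``boundary``; the default boundary 0
    separates fetal from postnatal stages at birth).  Samples in the same
    (region, stage) are first averaged; the statistic is the mean over
    regions of (mean prenatal stage-average - mean postnatal stage-average).
    The null permutes stage labels (and their ages) within region; one-sided
    p = (r + 1)/(B + 1).  Regions lacking either side of the boundary are
    dropped with a warning.
    """
    if n_permutations < 1:
        raise ValueError("need >= 1 permutation")
    df = pd.DataFrame({
        "expr": np.asarray(expr_by_sample, dtype=float),
        "stage": np.asarray(stage_labels),
        "region": np.asarray(region_labels),
        "age": np.asarray(stage_ages, dtype=float),
    })

    def statistic(frame: pd.DataFrame) -> float:
        diffs = []
        for region, sub in frame.groupby("region"):
            stage_avg = sub.groupby("stage").agg(expr=("expr", "mean"),
                                                 age=("age", "first"))
            pre = stage_avg[stage_avg.age < boundary]["expr"]
            post = stage_avg[stage_avg.age >= boundary]["expr"]
            if len(pre) == 0 or len(post) == 0:
                continue
            diffs.append(pre.mean() - post.mean())
        if not diffs:
            raise ValueError("no region has samples on both sides of the boundary")
        return float(np.mean(diffs))

    dropped = [
        region for region, sub in df.groupby("region")
        if (sub.age < boundary).all() or (sub.age >= boundary).all()
    ]
    if dropped:
        warnings.warn(f"regions dropped (one-sided sampling): {dropped}")

    obs = statistic(df)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = df.copy()
        for _, idx in df.groupby("region").groups.items():
            order = rng.permutation(len(idx))
            perm.loc[idx, ["stage", "age"]] = df.loc[idx, ["stage", "age"]].to_numpy()[order]
        if statistic(perm) >= obs:
            exceed += 1
    return obs, (exceed + 1) / (n_permutations + 1)


def load_gene_set(path: str, name: Optional[str] = None) -> set[str]:
    """Read a gene set from a plain-text file, one symbol per line."""
    with open(path) as fh:
        genes = {line.strip().upper() for line in fh if line.strip()}
    if not genes:
        raise ValueError(f"empty gene set in {path}")
    return genes
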