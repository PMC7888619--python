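"""Linear SNP-weight expression models and genetically imputed expression.

A model predicts a molecular trait (gene expression or intron usage) as a
weighted sum of cis-SNP dosages, x = sum_j w_j * d_j, with weights trained
elsewhere (e.g. cross-tissue penalized regression or BSLMM/elastic-net
pipelines).  This module loads a canonical tab-delimited weight dialect,
harmonizes effect alleles against a phased genotype matrix, and scores
probands, parents, and pseudo siblings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .trio_genotypes import PhasedGenotypeMatrix, PseudoSibSet

WEIGHT_COLUMNS = [
    "gene", "tissue", "feature_type", "cluster",
    "chrom", "pos", "ref", "alt", "effect_allele", "weight",
]


@dataclass
class ExpressionModel:
    """Per-gene/tissue linear predictor of expression or intron usage."""

    gene: str
    tissue: str
    feature_type: str = "expression"  # or "intron_usage"
    cluster: Optional[str] = None
    predictors: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: chrom, pos, ref, alt, effect_allele, weight

    def __post_init__(self) -> None:
        if len(self.predictors) == 0:
            raise ValueError(f"model {self.gene}/{self.tissue}: no predictors")
        if not np.isfinite(self.predictors["weight"]).all():
            raise ValueError(f"model {self.gene}/{self.tissue}: non-finite weight")
        keys = list(zip(self.predictors.chrom, self.predictors.pos,
                        self.predictors.ref, self.predictors.alt))
        if len(set(keys)) != len(keys):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"model {self.gene}/{self.tissue}: duplicate predictor {dup}")

    @property
    def key(self) -> tuple[str, str, str, Optional[str]]:
        return (self.gene, self.tissue, self.feature_type, self.cluster)


@dataclass
class AlignedModel:
    """An expression model aligned to a genotype matrix.

    ``flip`` marks predictors whose effect allele is the reference allele;
    their dosage is complemented (d -> 2 - d) at scoring time.  ``col_idx``
    indexes the matrix variant list.
    """

    model: ExpressionModel
    col_idx: np.ndarray
    weights: np.ndarray
    flip: np.ndarray
    dropped: pd.DataFrame
    weight_mass_retained: float

    @property
    def n_predictors(self) -> int:
        return self.col_idx.size


def load_weight_table(path: str) -> list[ExpressionModel]:
    """Load expression models from the canonical tab-delimited weight dialect.

    One model is built per (gene, tissue, feature_type, cluster) group.
    Zero-weight predictors are dropped; rows whose effect allele matches
    neither ref nor alt are rejected with a warning; models left without
    predictors are skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "cluster": str})
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    bad = (df.effect_allele != df.ref) & (df.effect_allele != df.alt)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} weight rows rejected: effect allele "
                      "matches neither ref nor alt")
        df = df[~bad]
    df = df[df.weight != 0]

    models = []
    for (gene, tissue, ftype, cluster), grp in df.groupby(
        ["gene", "tissue", "feature_type", "cluster"], dropna=False, sort=True
    ):
        if len(grp) == 0:
            continue
        cl = None if pd.isna(cluster) else str(cluster)
        models.append(ExpressionModel(gene, tissue, ftype, cl, grp.reset_index(drop=True)))
    return models


def harmonize(
    model: ExpressionModel,
    matrix: PhasedGenotypeMatrix,
    keep_ambiguous: bool = False,
) -> AlignedModel:
    """Align a model's predictors with a genotype matrix.

    Predictors are matched on (chrom, pos, ref, alt).  When the effect allele
    is the alternate allele the weight applies to the dosage directly; when it
    is the reference allele the dosage is complemented at scoring time.
    Strand-ambiguous (A/T, C/G) predictors are dropped unless
    ``keep_ambiguous``.  Predictors absent from the matrix are dropped and
    reported.  Harmonizing twice is a no-op (matching is by exact key).
    """
    cols, weights, flips, dropped = [], [], [], []
    for row in model.predictors.itertuples(index=False):
        ambiguous = {row.ref.upper(), row.alt.upper()} in ({"A", "T"}, {"C", "G"})
        if ambiguous and not keep_ambiguous:
            dropped.append((*_rowkey(row), "strand_ambiguous"))
            continue
        vi = matrix.variant_index((str(row.chrom), int(row.pos), row.ref, row.alt))
        if vi is None:
            dropped.append((*_rowkey(row), "absent_from_matrix"))
            continue
        cols.append(vi)
        weights.append(float(row.weight))
        flips.append(row.effect_allele == row.ref)
    total_mass = float(np.abs(model.predictors.weight).sum())
    retained_mass = float(np.abs(weights).sum()) if weights else 0.0
    dropped_df = pd.DataFrame(dropped, columns=["chrom", "pos", "ref", "alt", "reason"])
    if not cols:
        warnings.warn(f"model {model.gene}/{model.tissue}: all predictors dropped")
    return AlignedModel(
        model,
        np.asarray(cols, dtype=int),
        np.asarray(weights, dtype=float),
        np.asarray(flips, dtype=bool),
        dropped_df,
        retained_mass / total_mass if total_mass > 0 else 0.0,
    )


def _rowkey(row) -> tuple[str, int, str, str]:
    return (str(row.chrom), int(row.pos), row.ref, row.alt)


def impute_expression(aligned: AlignedModel, dosages: np.ndarray) -> np.ndarray:
    """Score dosages with the aligned model: sum_j w_j d_j.

    ``dosages`` is aligned to the model's retained predictors along the last
    axis (any number of leading axes); flipped predictors are complemented
    before weighting.  Linear in the dosages.
    """
    d = np.asarray(dosages, dtype=float)
    if d.shape[-1] != aligned.n_predictors:
        raise ValueError(
            f"dosage length {d.shape[-1]} != {aligned.n_predictors} model predictors"
        )
    eff = np.where(aligned.flip, 2.0 - d, d)
    return eff @ aligned.weights


def haplotype_values(aligned: AlignedModel, haplotypes: np.ndarray) -> np.ndarray:
    """Per-haplotype contribution to imputed expression.

    ``haplotypes``: (..., m, 2) alleles in {0,1}.  Returns (..., 2) values
    such that their sum equals ``impute_expression`` of the dosage.  Allele
    complementation for flipped predictors happens per haplotype (1 - h).
    """
    h = np.asarray(haplotypes, dtype=float)
    eff = np.where(aligned.flip[..., None], 1.0 - h, h)
    return np.einsum("...mh,m->...h", eff, aligned.weights)


def one_sibling_expression(father_value, mother_value, proband_value):
    """Expression of the single non-transmitted pseudo sibling.

    The pseudo sibling carries exactly the parental haplotypes the proband
    did not receive, so by linearity its expression is the sum of parental
    expressions minus the proband's.
    """
    return father_value + mother_value - proband_value


def impute_family_table(
    aligned: AlignedModel,
    matrix: PhasedGenotypeMatrix,
    trio,
    sib_set: PseudoSibSet,
) -> pd.DataFrame:
    """Imputed expression for proband, parents, and the four configurations.

    Rows are keyed by (family, gene, tissue, member).  The four configuration
    values sum to 2 x (father + mother) by construction.
    """
    idx = sib_set.variant_idx
    rows = []
    for member, sample in (("proband", trio.proband_id), ("father", trio.father_id),
                           ("mother", trio.mother_id)):
        val = float(impute_expression(aligned, matrix.dosage(sample, idx)))
        rows.append((trio.family_id, aligned.model.gene, aligned.model.tissue, member, val))
    for lab, dos in zip(sib_set.labels, sib_set.config_dosages):
        val = float(impute_expression(aligned, dos))
        rows.append((trio.family_id, aligned.model.gene, aligned.model.tissue,
                     f"config({lab[0]},{lab[1]})", val))
    return pd.DataFrame(rows, columns=["family", "gene", "tissue", "member", "value"])


def standardize_exposures(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Z-score exposures with the population-SD convention (divide by n).

    Applied within one gene/tissue/cohort group over probands and retained
    pseudo siblings; effect sizes downstream are then per SD of imputed
    expression.  A zero-variance group yields all zeros and an
    "uninformative" flag (second return value False).
    """
    v = np.asarray(values, dtype=float)
    sd = v.std()  # ddof=0
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(v), False
    return (v - v.mean()) / sd, True
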