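"""Phased trio genotypes and pseudo-sibling construction.

In a proband-parent trio with phased parental genotypes, the proband carries
one paternal and one maternal haplotype.  Over a cis-window (where we assume
no crossover, since expression predictors are local), the four possible
pairings of a whole paternal haplotype with a whole maternal haplotype give
four "recombined" pseudo-offspring genotypes.  One of the four should be
identical to the proband when phasing is correct; the others serve as
within-family matched controls for transmission-disequilibrium testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: the fixed order of pseudo-offspring configurations:
#: (paternal haplotype index, maternal haplotype index), 1-based.
CONFIG_LABELS: tuple[tuple[int, int], ...] = ((1, 1), (1, 2), (2, 1), (2, 2))


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant; ``(chrom, pos, ref, alt)`` is the identity key."""

    chrom: str
    pos: int  # 1-based
    id: str
    ref: str
    alt: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def is_strand_ambiguous(self) -> bool:
        """A/T and C/G pairs cannot be disambiguated across strand flips."""
        return {self.ref.upper(), self.alt.upper()} in ({"A", "T"}, {"C", "G"})


@dataclass
class PhasedGenotypeMatrix:
    """Fully phased biallelic genotypes for a set of samples.

    ``haplotypes`` has shape ``(n_samples, n_variants, 2)`` with alleles in
    {0, 1}; dosage is the sum over the last axis.
    """

    variants: list[VariantRecord]
    samples: list[str]
    haplotypes: np.ndarray
    skipped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._variant_index = {v.key: i for i, v in enumerate(self.variants)}
        if len(self._variant_index) != len(self.variants):
            raise ValueError("duplicate variant keys in matrix")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in genotype matrix") from None

    def variant_index(self, key: tuple[str, int, str, str]) -> Optional[int]:
        return self._variant_index.get(key)

    def dosage(self, sample: str, variant_idx: Optional[Sequence[int]] = None) -> np.ndarray:
        """Allele-count dosage (0/1/2) for one sample, optionally subset."""
        h = self.haplotypes[self.sample_index(sample)]
        if variant_idx is not None:
            h = h[np.asarray(variant_idx, dtype=int)]
        return h.sum(axis=1)

    def sample_haplotypes(self, sample: str, variant_idx: Optional[Sequence[int]] = None) -> np.ndarray:
        h = self.haplotypes[self.sample_index(sample)]
        if variant_idx is not None:
            h = h[np.asarray(variant_idx, dtype=int)]
        return h


@dataclass(frozen=True)
class Trio:
    """One proband-parent trio from a pedigree."""

    family_id: str
    proband_id: str
    father_id: str
    mother_id: str
    sex: Optional[int] = None
    affected: Optional[int] = None

    def __post_init__(self) -> None:
        ids = {self.proband_id, self.father_id, self.mother_id}
        if len(ids) != 3:
            raise ValueError(
                f"family {self.family_id}: proband/father/mother ids must be distinct"
            )


@dataclass
class PseudoSibSet:
    """The four recombined pseudo-offspring genotypes for one family/window.

    ``config_dosages`` has shape ``(4, m)``; row ``k`` pairs paternal
    haplotype ``CONFIG_LABELS[k][0]`` with maternal haplotype
    ``CONFIG_LABELS[k][1]``.  ``proband_match_index`` is the label of the
    (lowest-indexed) configuration whose dosage vector equals the proband's
    everywhere, or ``None``.
    """

    family_id: str
    labels: tuple[tuple[int, int], ...]
    config_dosages: np.ndarray
    proband_dosage: np.ndarray
    proband_match_index: Optional[tuple[int, int]]
    variant_idx: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (family, config, variant index, dosage) for debugging."""
        rows = []
        for lab, dos in zip(self.labels, self.config_dosages):
            for vi, d in zip(self.variant_idx, dos):
                rows.append((self.family_id, f"{lab[0]},{lab[1]}", int(vi), int(d)))
        return pd.DataFrame(rows, columns=["family", "config", "variant_idx", "dosage"])


def parse_region(region: str) -> tuple[str, Optional[int], Optional[int]]:
    """Parse ``chrom`` or ``chrom:start-end`` (1-based inclusive)."""
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    start_s, end_s = span.split("-", 1)
    start, end = int(start_s.replace(",", "")), int(end_s.replace(",", ""))
    if start < 1 or end < start:
        raise ValueError(f"invalid region {region!r}")
    return chrom, start, end


def load_phased_vcf(
    path: str,
    region: Optional[str] = None,
    sample_subset: Optional[Sequence[str]] = None,
) -> PhasedGenotypeMatrix:
    """Read fully phased biallelic variants from a VCF into a matrix.

    Multiallelic records, records with any unphased or missing call in the
    requested samples, and calls with alleles outside {0, 1} are skipped and
    counted in ``matrix.skipped``.  A region with zero retained variants
    yields an empty matrix with a warning, not an error.
    """
    vcf = VCF(path)
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in vcf.samples]
        if missing:
            raise KeyError(f"samples not found in VCF: {', '.join(missing)}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    chrom = start = end = None
    if region is not None:
        chrom, start, end = parse_region(region)

    skipped = {"multiallelic": 0, "unphased": 0, "missing": 0, "non_biallelic_allele": 0}
    variants: list[VariantRecord] = []
    hap_rows: list[np.ndarray] = []
    for rec in vcf:
        if chrom is not None:
            if rec.CHROM != chrom:
                continue
            if start is not None and not (start <= rec.POS <= end):
                continue
        if len(rec.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        gts = rec.genotypes  # per sample: [allele0, allele1, phased]
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=np.int8)
        phased = np.array([bool(g[2]) for g in gts])
        if (alleles < 0).any():
            skipped["missing"] += 1
            continue
        if not phased.all():
            skipped["unphased"] += 1
            continue
        if (alleles > 1).any():
            skipped["non_biallelic_allele"] += 1
            continue
        variants.append(
            VariantRecord(rec.CHROM, rec.POS, rec.ID or ".", rec.REF, rec.ALT[0])
        )
        hap_rows.append(alleles)

    if not variants:
        warnings.warn(f"no phased biallelic variants retained from {path}"
                      + (f" in region {region}" if region else ""))
        haps = np.zeros((len(samples), 0, 2), dtype=np.int8)
    else:
        haps = np.stack(hap_rows, axis=1)  # (n_samples, n_variants, 2)
    return PhasedGenotypeMatrix(variants, samples, haps, skipped)


def load_fam(path: str) -> list[Trio]:
    """Read a 6-column pedigree (FID IID father mother sex phenotype).

    Trios are the rows whose father and mother ids are both non-zero.
    """
    ped = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    trios = []
    for row in ped.itertuples(index=False):
        if row.father in ("0", "", None) or row.mother in ("0", "", None):
            continue
        sex = int(row.sex) if row.sex not in (None, "", "NA") else None
        aff = int(float(row.phenotype)) if row.phenotype not in (None, "", "NA", "-9") else None
        trios.append(Trio(row.fid, row.iid, row.father, row.mother, sex, aff))
    return trios


def generate_pseudo_siblings(
    matrix: PhasedGenotypeMatrix,
    trio: Trio,
    variant_subset: Optional[Sequence[int]] = None,
) -> PseudoSibSet:
    """Build the four whole-haplotype recombinants for one family.

    Each configuration joins one entire paternal haplotype with one entire
    maternal haplotype over the window (no within-window crossover).  Variants
    with a missing parental call are dropped from the window with a warning;
    an empty window after dropping is an error.
    """
    if variant_subset is None:
        variant_subset = np.arange(matrix.n_variants)
    idx = np.asarray(variant_subset, dtype=int)
    fh = matrix.sample_haplotypes(trio.father_id, idx)  # (m, 2)
    mh = matrix.sample_haplotypes(trio.mother_id, idx)
    ph = matrix.sample_haplotypes(trio.proband_id, idx)

    ok = (fh >= 0).all(axis=1) & (mh >= 0).all(axis=1)
    if not ok.all():
        warnings.warn(
            f"family {trio.family_id}: dropped {(~ok).sum()} variants with "
            "missing parental calls"
        )
        idx, fh, mh, ph = idx[ok], fh[ok], mh[ok], ph[ok]
    if idx.size == 0:
        raise ValueError(f"family {trio.family_id}: no usable variants in window")

    config_dosages = np.stack(
        [fh[:, f - 1] + mh[:, m - 1] for f, m in CONFIG_LABELS]
    ).astype(np.int8)  # (4, m)
    proband_dosage = ph.sum(axis=1).astype(np.int8)

    match = None
    for lab, dos in zip(CONFIG_LABELS, config_dosages):
        if np.array_equal(dos, proband_dosage):
            match = lab
            break
    return PseudoSibSet(trio.family_id, CONFIG_LABELS, config_dosages, proband_dosage, match, idx)


def check_mendelian_consistency(sib_sets: Sequence[PseudoSibSet]) -> pd.DataFrame:
    """Report, per family, whether a configuration matches the proband exactly.

    The best configuration's mismatching-variant count is reported; a nonzero
    count indicates a phasing error or a crossover within the window.
    """
    rows = []
    for s in sib_sets:
        mism = (s.config_dosages != s.proband_dosage[None, :]).sum(axis=1)
        rows.append((s.family_id, s.proband_match_index is not None, int(mism.min())))
    return pd.DataFrame(rows, columns=["family", "consistent", "best_mismatch_count"])


@dataclass
class SnpPseudoControls:
    """A1 counts for the proband and its three per-variant pseudo-controls."""

    family_id: str
    proband_count: int
    control_counts: np.ndarray  # (3,)
    excluded_label: Optional[tuple[int, int]]
    consistent: bool


def snp_pseudo_controls(
    matrix: PhasedGenotypeMatrix, trio: Trio, variant_idx: int
) -> SnpPseudoControls:
    """Per-variant pseudo-controls for trio GWAS.

    Enumerate the four recombined genotypes at one variant, remove exactly one
    configuration equal to the proband's count (lowest configuration index on
    ties), and return the remaining three counts.  If no configuration matches
    the proband, the family is flagged inconsistent and should be excluded
    from this variant's test.
    """
    sset = generate_pseudo_siblings(matrix, trio, [variant_idx])
    counts = sset.config_dosages[:, 0]
    pcount = int(sset.proband_dosage[0])
    matches = np.nonzero(counts == pcount)[0]
    if matches.size == 0:
        return SnpPseudoControls(trio.family_id, pcount, counts.copy(), None, False)
    drop = int(matches[0])  # CONFIG_LABELS is in lexicographic order
    keep = np.ones(4, dtype=bool)
    keep[drop] = False
    return SnpPseudoControls(
        trio.family_id, pcount, counts[keep].astype(int), CONFIG_LABELS[drop], True
    )


def write_pseudo_sib_table(sib_sets: Sequence[PseudoSibSet], path: str) -> None:
    """Serialize pseudo-sibling sets as a tab-delimited long-format table."""
    pd.concat([s.to_frame() for s in sib_sets], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
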