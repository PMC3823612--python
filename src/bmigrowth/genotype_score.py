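"""The 32-SNP adult-BMI allelic score.

The score for an individual is the sum over 32 established adult-BMI
loci of the imputed dosage of the BMI-increasing allele, so it ranges
over [0, 64].  A sensitivity variant weights each dosage by the published
per-allele GWAS effect on adult BMI (kg/m^2).  The SNP set, effect
alleles, published effects and reference effect-allele frequencies ship
with the package (``data/bmi_snps_32.csv``).

Dosage panels must count the reference effect allele.  When user-supplied
allele labels disagree with the reference, dosages are flipped (d -> 2-d)
if the labels are simply swapped; strand-ambiguous A/T and C/G sites with
mismatching labels are an error because a silent sign flip cannot be
ruled out there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "DosagePanel",
    "load_snp_metadata",
    "compute_allelic_score",
    "effect_allele_frequency",
    "published_weights",
    "harmonise_effect_alleles",
    "N_SNPS",
]

log = logging.getLogger(__name__)

N_SNPS = 32
_AMBIGUOUS = {frozenset("AT"), frozenset("CG")}


def load_snp_metadata() -> pd.DataFrame:
    """Reference metadata for the 32 score SNPs, indexed by rsid."""
    with resources.files("bmigrowth.data").joinpath("bmi_snps_32.csv").open() as fh:
        meta = pd.read_csv(fh)
    return meta.set_index("rsid")


@dataclass
class DosagePanel:
    """Individuals x SNPs effect-allele dosage matrix with SNP metadata.

    Missing dosages are replaced by the SNP-wise mean (logged); any value
    outside [0, 2] after imputation is an error.
    """

    individual_ids: list
    snp_ids: list
    dosages: np.ndarray
    metadata: pd.DataFrame = field(default_factory=load_snp_metadata)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, s = self.dosages.shape
        if n != len(self.individual_ids) or s != len(self.snp_ids):
            raise ValueError("dosage matrix shape does not match id lists")
        missing = ~np.isfinite(self.dosages)
        if missing.any():
            log.info("imputing %d missing dosages with SNP-wise means",
                     int(missing.sum()))
            means = np.nanmean(self.dosages, axis=0)
            self.dosages = np.where(missing, means[None, :], self.dosages)
        if (self.dosages < 0).any() or (self.dosages > 2).any():
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages,
                            index=pd.Index(self.individual_ids,
                                           name="individual_id"),
                            columns=self.snp_ids)

    def dosage_of(self, snp: str) -> pd.Series:
        return self.to_frame()[snp]


def compute_allelic_score(panel: DosagePanel, weights=None) -> pd.Series:
    """Per-individual allelic score: (weighted) row sum of dosages.

    ``weights=None`` gives the unweighted score (range [0, 2 * n_snps]);
    otherwise one weight per SNP, in panel column order.
    """
    if weights is None:
        score = panel.dosages.sum(axis=1)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (panel.n_snps,):
            raise ValueError(
                f"expected {panel.n_snps} weights, got shape {w.shape}")
        score = panel.dosages @ w
    return pd.Series(score, index=pd.Index(panel.individual_ids,
                                           name="individual_id"),
                     name="allelic_score")


def published_weights(panel: DosagePanel) -> np.ndarray:
    """Published adult-BMI effect sizes aligned to the panel's SNP order."""
    return panel.metadata.loc[panel.snp_ids, "gwas_beta"].to_numpy(dtype=float)


def effect_allele_frequency(panel: DosagePanel, snp: str) -> float:
    """Sample effect-allele frequency of one SNP: mean dosage / 2."""
    if snp not in panel.snp_ids:
        raise KeyError(f"unknown SNP {snp!r}")
    j = panel.snp_ids.index(snp)
    return float(panel.dosages[:, j].mean() / 2.0)


def harmonise_effect_alleles(panel: DosagePanel,
                             effect_alleles: dict) -> DosagePanel:
    """Align user dosages to the reference effect alleles.

    ``effect_alleles`` maps rsid -> the allele the user's dosages count.
    A swapped label pair flips the dosage to 2-d; a mismatch at a
    strand-ambiguous (A/T or C/G) site raises, as do labels matching
    neither reference allele.
    """
    dos = panel.dosages.copy()
    for j, snp in enumerate(panel.snp_ids):
        if snp not in effect_alleles or snp not in panel.metadata.index:
            continue
        user = str(effect_alleles[snp]).upper()
        ref_eff = str(panel.metadata.loc[snp, "effect_allele"]).upper()
        ref_oth = str(panel.metadata.loc[snp, "other_allele"]).upper()
        if user == ref_eff:
            continue
        if frozenset((ref_eff, ref_oth)) in _AMBIGUOUS:
            raise ValueError(
                f"{snp}: effect-allele mismatch at strand-ambiguous "
                f"{ref_eff}/{ref_oth} site")
        if user == ref_oth:
            log.info("%s: flipping dosage to count %s", snp, ref_eff)
            dos[:, j] = 2.0 - dos[:, j]
        else:
            raise ValueError(
                f"{snp}: allele {user} matches neither {ref_eff} nor {ref_oth}")
    return DosagePanel(panel.individual_ids, list(panel.snp_ids), dos,
                       metadata=panel.metadata)
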