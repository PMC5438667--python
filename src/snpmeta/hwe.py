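"""Pearson chi-square test for Hardy-Weinberg equilibrium.

Under random mating a biallelic locus with reference-allele frequency p has
genotype proportions p^2, 2p(1-p), (1-p)^2.  Departure in *controls*
signals genotyping error or sampling bias, so control groups are tested
(1 df: three genotype classes minus one estimated allele frequency minus
one).  No continuity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError
from .study_io import GenotypeCounts

__all__ = ["HweResult", "hwe_test"]


@dataclass(frozen=True)
class HweResult:
    """chi2 statistic (1 df), upper-tail p, and the equilibrium verdict."""

    chi2: float
    p_value: float
    in_hwe: bool
    monomorphic: bool = False


def hwe_test(genotypes: GenotypeCounts, threshold: float = 0.05) -> HweResult:
    """Test genotype counts for Hardy-Weinberg equilibrium.

    Expected counts come from the estimated reference-allele frequency
    p = (2*cc + ct) / 2n.  A monomorphic group (p = 0 or 1) fits the
    equilibrium proportions trivially: chi2 = 0 and the group is flagged.
    ``in_hwe`` is True when the p-value exceeds ``threshold``.
    """
    n = genotypes.n
    if n == 0:
        raise ValidationError("cannot test an empty group for HWE")
    p = genotypes.c_alleles / (2 * n)
    if p in (0.0, 1.0):
        return HweResult(chi2=0.0, p_value=1.0, in_hwe=True, monomorphic=True)
    q = 1.0 - p
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    observed = (genotypes.cc, genotypes.ct, genotypes.tt)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(chi2=chi2, p_value=p_value, in_hwe=p_value > threshold)
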