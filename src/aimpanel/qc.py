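"""Genotype quality control: call-rate, MAF and Hardy-Weinberg filters.

Filters are applied in a fixed order, each on the already-filtered data:

1. sample call rate >= ``sample_call_rate_min``
2. SNP call rate >= ``snp_call_rate_min`` (over retained samples)
3. minor allele frequency >= ``maf_min`` (non-missing calls only)
4. exact Hardy-Weinberg p-value >= ``hwe_p_min``

All thresholds are inclusive.  The Hardy-Weinberg test is the exact
conditional test: given the observed allele counts, the p-value sums the
probabilities of every heterozygote count whose conditional probability does
not exceed that of the observed count.  Monomorphic sites return 1 by
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .io_formats import MISSING, GenotypeDataset, ValidationError


@dataclass(frozen=True)
class QcThresholds:
    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 1.0e-3

    def __post_init__(self):
        for name, v in vars(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass
class QcReport:
    """Per-step removal counts, in application order."""

    n_samples_in: int
    n_snps_in: int
    samples_removed_call_rate: int = 0
    snps_removed_call_rate: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0

    @property
    def n_samples_retained(self) -> int:
        return self.n_samples_in - self.samples_removed_call_rate

    @property
    def n_snps_retained(self) -> int:
        return (self.n_snps_in - self.snps_removed_call_rate
                - self.snps_removed_maf - self.snps_removed_hwe)


def _hwe_log_probs(n_a: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional log-probabilities of each feasible heterozygote count.

    ``n_a`` is the minor-allele count and ``n`` the number of diploid
    individuals.  Feasible heterozygote counts share the parity of ``n_a``.
    """
    hets = np.arange(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)
    hom_a = (n_a - hets) // 2
    hom_b = n - hom_a - hets
    logp = (hets * np.log(2)
            - gammaln(hom_a + 1) - gammaln(hets + 1) - gammaln(hom_b + 1))
    logp -= logp.max()
    p = np.exp(logp)
    return hets, p / p.sum()


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts."""
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValidationError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValidationError("empty genotype table")
    n_alt = 2 * n_hom_alt + n_het
    n_a = min(n_alt, 2 * n - n_alt)  # minor allele count
    if n_a == 0:
        return 1.0
    hets, probs = _hwe_log_probs(n_a, n)
    p_obs = probs[hets == n_het][0]
    # tolerance guards ties between float-equal configurations
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _sample_call_rates(calls: np.ndarray) -> np.ndarray:
    return (calls != MISSING).mean(axis=1) if calls.shape[1] else np.ones(calls.shape[0])


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())


def apply_qc(dataset: GenotypeDataset,
             thresholds: QcThresholds = QcThresholds()
             ) -> tuple[GenotypeDataset, QcReport]:
    """Apply the four inclusion criteria in order; return the filtered
    dataset and a per-step report."""
    report = QcReport(dataset.n_samples, dataset.n_snps)
    t = thresholds

    # 1. sample call rate
    keep_samples = _sample_call_rates(dataset.calls) >= t.sample_call_rate_min
    report.samples_removed_call_rate = int((~keep_samples).sum())
    samples = [s for s, k in zip(dataset.samples, keep_samples) if k]
    calls = dataset.calls[keep_samples]

    n_samples = calls.shape[0]
    keep = np.ones(dataset.n_snps, dtype=bool)

    # 2. SNP call rate on retained samples
    if n_samples:
        call_rate = (calls != MISSING).mean(axis=0)
    else:
        call_rate = np.zeros(dataset.n_snps)
    fail = keep & (call_rate < t.snp_call_rate_min)
    report.snps_removed_call_rate = int(fail.sum())
    keep &= ~fail

    # 3. MAF over non-missing calls
    masked = np.ma.masked_equal(calls, MISSING)
    with np.errstate(invalid="ignore"):
        freq = masked.mean(axis=0).filled(np.nan) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    fail = keep & ~(maf >= t.maf_min)  # NaN frequency fails
    report.snps_removed_maf = int(fail.sum())
    keep &= ~fail

    # 4. exact HWE
    fail = np.zeros(dataset.n_snps, dtype=bool)
    for j in np.flatnonzero(keep):
        col = calls[:, j]
        n0, n1, n2 = _genotype_counts(col)
        if n0 + n1 + n2 == 0:
            continue
        fail[j] = hwe_exact_p(n0, n1, n2) < t.hwe_p_min
    report.snps_removed_hwe = int(fail.sum())
    keep &= ~fail

    filtered = GenotypeDataset(
        samples=samples,
        snps=dataset.snps.loc[keep].reset_index(drop=True),
        calls=calls[:, keep],
        population_label=dataset.population_label)
    return filtered, report
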