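"""Synthetic parental panels and admixed cohorts with known truth.

The generator implements exactly the demographic model the inference
assumes (hybrid isolation): each admixed individual draws a European
admixture proportion ``m_j`` from a Beta distribution; each haplotype starts
in a Bernoulli(m_j) ancestry, acquires Poisson(lambda_gen per Morgan)
breakpoints along each chromosome, and redraws its ancestry Bernoulli(m_j)
at every breakpoint.  Alleles are sampled from the ancestry-specific
frequencies, so fitting the admixture HMM to simulated data is a clean
parameter-recovery oracle.

Parental allele-frequency pairs come from one of two presets:

- ``"aims"``: strongly differentiated markers, delta ~ Uniform(0.6, 0.8)
  with the mean frequency uniform over the feasible range — the profile of
  a selected AIM panel;
- ``"random"``: a genome-wide spectrum from a Balding-Nichols model with
  F_ST = 0.075 (the CEU-YRI scale of differentiation), giving mean delta of
  about 0.14.

Parental populations are simulated in linkage equilibrium unless
``ld_block_size > 1``, which plants blocks of correlated SNPs (shared block
frequency; each haplotype copies the previous SNP's allele with probability
``ld_block_rho``) solely to exercise LD pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import (MISSING, GenotypeDataset, SnpRecord, ValidationError,
                         make_snp_table)

#: Balding-Nichols differentiation for the "random" preset
_RANDOM_PRESET_FST = 0.075
_CM_PER_MB = 1.0  # simulated map: 1 cM == 1 Mb

#: approximate sex-averaged genetic lengths of the 22 human autosomes (cM);
#: individual admixture proportions are genome-wide averages, so a
#: realistic total map length (~35 Morgans) matters for their variance
HUMAN_AUTOSOME_CM = (286.0, 269.0, 223.0, 214.0, 204.0, 192.0, 187.0, 168.0,
                     166.0, 181.0, 158.0, 175.0, 126.0, 120.0, 141.0, 134.0,
                     128.0, 117.0, 108.0, 108.0, 62.0, 74.0)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic cohorts.

    Defaults describe an African-American-like cohort: mean European
    admixture 0.2 (Beta(2, 8)), seven generations since a single admixture
    event, and AIM-grade marker differentiation.
    """

    n_individuals: int = 100
    n_snps: int = 500
    chromosome_lengths_cm: tuple[float, ...] = HUMAN_AUTOSOME_CM
    delta_preset: str = "aims"          # "aims" or "random"
    m_beta: tuple[float, float] = (2.0, 8.0)
    lambda_gen: float = 7.0
    missing_rate: float = 0.0
    risk_locus: Optional[tuple[str, float, float]] = None  # (chrom, cM, psi2)
    seed: int = 0
    n_ref: Optional[int] = None         # parental sample size (default: n_individuals)
    ld_block_size: int = 1
    ld_block_rho: float = 0.95

    def __post_init__(self):
        if self.delta_preset not in ("aims", "random"):
            raise ValidationError("delta_preset must be 'aims' or 'random'")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValidationError("missing_rate outside [0, 1]")
        if self.lambda_gen < 0:
            raise ValidationError("lambda_gen must be >= 0")
        if any(l <= 0 for l in self.chromosome_lengths_cm):
            raise ValidationError("chromosome lengths must be positive")
        if self.ld_block_size < 1:
            raise ValidationError("ld_block_size must be >= 1")

    @property
    def n_ref_effective(self) -> int:
        return self.n_ref if self.n_ref is not None else self.n_individuals


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated admixed cohort."""

    m: np.ndarray                        # per-individual European proportion
    k_euro: np.ndarray                   # (n_ind, n_snps) true European allele count
    breakpoints: list                    # [ind][chrom][hap] -> cM positions
    snps: pd.DataFrame
    seed: int

    def k_african(self) -> np.ndarray:
        return 2 - self.k_euro


def _snp_positions(config: SimConfig) -> pd.DataFrame:
    """Place n_snps uniformly at random across chromosomes, proportional to
    genetic length."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    lengths = np.asarray(config.chromosome_lengths_cm, float)
    n_per = np.floor(config.n_snps * lengths / lengths.sum()).astype(int)
    for i in range(config.n_snps - n_per.sum()):
        n_per[i % len(n_per)] += 1
    records = []
    counter = 0
    for c, (n_c, length) in enumerate(zip(n_per, lengths), start=1):
        cm = np.sort(rng.uniform(0.0, length, size=n_c))
        bp = np.unique((cm / _CM_PER_MB * 1e6).astype(np.int64) + 1)
        while len(bp) < n_c:  # resolve bp collisions by re-jittering
            cm = np.sort(rng.uniform(0.0, length, size=n_c))
            bp = np.unique((cm / _CM_PER_MB * 1e6).astype(np.int64) + 1)
        cm = (bp - 1) / 1e6 * _CM_PER_MB
        for j in range(n_c):
            counter += 1
            records.append(SnpRecord(f"snp{counter:06d}", str(c), int(bp[j]),
                                     "A", "C", float(cm[j])))
    return make_snp_table(records)


def _draw_frequencies(config: SimConfig, n_snps: int,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if config.delta_preset == "aims":
        delta = rng.uniform(0.6, 0.8, size=n_snps)
        p_bar = rng.uniform(delta / 2, 1 - delta / 2)
        sign = rng.choice([-1.0, 1.0], size=n_snps)
        p_ceu = p_bar + sign * delta / 2
        p_yri = p_bar - sign * delta / 2
    else:
        f = _RANDOM_PRESET_FST
        p_anc = rng.uniform(0.05, 0.95, size=n_snps)
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_ceu = rng.beta(a, b)
        p_yri = rng.beta(a, b)
    return np.clip(p_ceu, 0.01, 0.99), np.clip(p_yri, 0.01, 0.99)


def _parental_genotypes(p: np.ndarray, n_ind: int, config: SimConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """Binomial(2, p) genotypes, optionally with planted LD blocks."""
    n_snps = len(p)
    if config.ld_block_size <= 1:
        return rng.binomial(2, p, size=(n_ind, n_snps)).astype(np.int8)
    haps = np.empty((2 * n_ind, n_snps), dtype=np.int8)
    block_starts = np.arange(0, n_snps, config.ld_block_size)
    for start in block_starts:
        stop = min(start + config.ld_block_size, n_snps)
        haps[:, start] = rng.random(2 * n_ind) < p[start]
        for j in range(start + 1, stop):
            copy = rng.random(2 * n_ind) < config.ld_block_rho
            fresh = (rng.random(2 * n_ind) < p[j]).astype(np.int8)
            haps[:, j] = np.where(copy, haps[:, j - 1], fresh)
    return (haps[0::2] + haps[1::2]).astype(np.int8)


def simulate_parental(config: SimConfig
                      ) -> tuple[GenotypeDataset, GenotypeDataset, pd.DataFrame]:
    """Simulate two parental reference panels and the true frequency table.

    With ``ld_block_size > 1`` all SNPs inside a block share one frequency,
    so the copy mechanism preserves marginal frequencies exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    snps = _snp_positions(config)
    n_snps = len(snps)
    p_ceu, p_yri = _draw_frequencies(config, n_snps, rng)
    if config.ld_block_size > 1:
        for start in range(0, n_snps, config.ld_block_size):
            stop = min(start + config.ld_block_size, n_snps)
            p_ceu[start:stop] = p_ceu[start]
            p_yri[start:stop] = p_yri[start]
    n_ref = config.n_ref_effective
    calls1 = _parental_genotypes(p_ceu, n_ref, config, rng)
    calls2 = _parental_genotypes(p_yri, n_ref, config, rng)
    pop1 = GenotypeDataset([f"ceu{i:04d}" for i in range(n_ref)], snps.copy(),
                           calls1, "CEU-like")
    pop2 = GenotypeDataset([f"yri{i:04d}" for i in range(n_ref)], snps.copy(),
                           calls2, "YRI-like")
    freq_table = pd.DataFrame({"snp_id": snps["snp_id"],
                               "p_ceu": p_ceu, "p_yri": p_yri})
    return pop1, pop2, freq_table


def _haplotype_ancestry(cm: np.ndarray, length: float, m: float,
                        lam: float, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Ancestry (0 African / 1 European) of one haplotype at marker
    positions, plus the breakpoint list."""
    n_bp = rng.poisson(lam * length / 100.0)
    bps = np.sort(rng.uniform(0.0, length, size=n_bp))
    anc_segments = rng.random(n_bp + 1) < m
    seg_of_marker = np.searchsorted(bps, cm, side="right")
    return anc_segments[seg_of_marker].astype(np.int8), bps


def simulate_admixed(config: SimConfig, freq_table: pd.DataFrame
                     ) -> tuple[GenotypeDataset, TruthSet]:
    """Simulate an admixed cohort under hybrid isolation with recorded truth."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    snps = _snp_positions(config)
    missing_freqs = set(snps["snp_id"]) - set(freq_table["snp_id"])
    if missing_freqs:
        raise ValidationError(
            f"freq_table does not cover {len(missing_freqs)} SNPs")
    freqs = freq_table.set_index("snp_id").loc[snps["snp_id"]]
    p = np.stack([freqs["p_yri"].to_numpy(), freqs["p_ceu"].to_numpy()])

    alpha, beta = config.m_beta
    m = rng.beta(alpha, beta, size=config.n_individuals)
    n_ind, n_snps = config.n_individuals, len(snps)
    calls = np.zeros((n_ind, n_snps), dtype=np.int8)
    k_euro = np.zeros((n_ind, n_snps), dtype=np.int8)
    breakpoints: list = []

    length_of = {str(c): l for c, l in
                 enumerate(config.chromosome_lengths_cm, start=1)}
    chrom_groups = [(str(c), grp.index.to_numpy(),
                     grp["position_cm"].to_numpy(float), length_of[str(c)])
                    for c, grp in snps.groupby("chromosome", sort=False)]
    for i in range(n_ind):
        per_chrom = []
        for chrom, cols, cm, length in chrom_groups:
            haps = []
            for _ in range(2):
                anc, bps = _haplotype_ancestry(cm, length, m[i],
                                               config.lambda_gen, rng)
                allele = rng.random(len(cols)) < p[anc, cols]
                calls[i, cols] += allele.astype(np.int8)
                k_euro[i, cols] += anc
                haps.append(bps)
            per_chrom.append(haps)
        breakpoints.append(per_chrom)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    dataset = GenotypeDataset([f"adm{i:04d}" for i in range(n_ind)],
                              snps.copy(), calls, "admixed")
    truth = TruthSet(m=m, k_euro=k_euro, breakpoints=breakpoints,
                     snps=snps.copy(), seed=config.seed)
    return dataset, truth


def assign_phenotypes(truth: TruthSet,
                      risk_locus: Optional[tuple[str, float, float]],
                      n_cases: int, n_controls: int, seed: int) -> pd.Series:
    """Sample case/control labels from an ancestry relative-risk model.

    With a risk locus (chrom, position_cm, psi2), the probability of being
    sampled as a case is proportional to ``psi2 ** (k_african / 2)`` at the
    SNP nearest the locus; cases are drawn without replacement by those
    weights and controls uniformly from the remainder.  Without a risk
    locus, labels are assigned at random.
    """
    n_ind = len(truth.m)
    if n_cases + n_controls > n_ind:
        raise ValidationError(
            f"requested {n_cases}+{n_controls} labels from {n_ind} individuals")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    ids = np.array([f"adm{i:04d}" for i in range(n_ind)])

    if risk_locus is None or risk_locus[2] == 1.0:
        perm = rng.permutation(n_ind)
    else:
        chrom, pos_cm, psi2 = risk_locus
        on_chrom = truth.snps[truth.snps["chromosome"].astype(str) == str(chrom)]
        if on_chrom.empty:
            raise ValidationError(f"no simulated SNPs on chromosome {chrom}")
        nearest = (on_chrom["position_cm"] - pos_cm).abs().idxmin()
        col = truth.snps.index.get_loc(nearest)
        k_afr = truth.k_african()[:, col].astype(float)
        weights = psi2 ** (k_afr / 2.0)
        case_part = rng.choice(n_ind, size=n_cases, replace=False,
                               p=weights / weights.sum())
        rest = np.setdiff1d(np.arange(n_ind), case_part)
        ctrl_part = rng.choice(rest, size=n_controls, replace=False)
        perm = np.concatenate([case_part, ctrl_part])
    status = {}
    for rank, idx in enumerate(perm[:n_cases + n_controls]):
        status[ids[idx]] = "case" if rank < n_cases else "control"
    return pd.Series(status, name="status")


def write_truth(truth: TruthSet, path) -> None:
    """Write per-individual admixture truth as TSV (id, m, mean ancestry)."""
    ids = [f"adm{i:04d}" for i in range(len(truth.m))]
    pd.DataFrame({
        "sample_id": ids,
        "m_true": truth.m,
        "mean_k_euro": truth.k_euro.mean(axis=1),
    }).to_csv(path, sep="\t", index=False)
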