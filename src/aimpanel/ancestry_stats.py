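"""Per-SNP ancestry-differentiation statistics for two parental populations.

For a biallelic SNP with alt-allele frequencies ``p1`` and ``p2`` in the two
parental populations:

- delta = |p1 - p2|, the allele-frequency differential;
- F_ST is Wright's variance-standardized fixation index for K = 2
  populations, ``s2 / (p_bar * (1 - p_bar))`` with ``p_bar = (p1 + p2)/2``
  and ``s2 = ((p1 - p_bar)**2 + (p2 - p_bar)**2) / 2``; the two-population
  identity ``s2 = delta**2 / 4`` holds exactly;
- SIC (Shannon information content) is the mutual information, in bits,
  between a marker allele and the ancestral origin of the chromosome
  carrying it, given a European admixture proportion ``m``.

With delta fixed, F_ST ranges over [delta**2, delta/(2-delta)]; with F_ST
fixed, delta ranges over [2*F/(1+F), sqrt(F)].  Both relationships are
exposed analytically and by grid search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeDataset, ValidationError

logger = logging.getLogger(__name__)

FST_CATEGORIES = ("little", "moderate", "large", "very_large")


def _check_freq(name: str, p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError(f"{name} outside [0, 1]")
    return p


def compute_delta(p1, p2):
    """Absolute allele-frequency difference |p1 - p2|."""
    p1 = _check_freq("p1", p1)
    p2 = _check_freq("p2", p2)
    out = np.abs(p1 - p2)
    return float(out) if out.ndim == 0 else out


def compute_fst(p1, p2):
    """Wright's two-population F_ST = s2 / (p_bar (1 - p_bar)).

    Sites fixed for the same allele in both populations (p_bar in {0, 1})
    are undifferentiated and return 0.
    """
    p1 = _check_freq("p1", p1)
    p2 = _check_freq("p2", p2)
    p_bar = (p1 + p2) / 2.0
    s2 = ((p1 - p_bar) ** 2 + (p2 - p_bar) ** 2) / 2.0
    denom = p_bar * (1.0 - p_bar)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(denom > 0, s2 / np.where(denom > 0, denom, 1.0), 0.0)
    if np.any(denom == 0):
        logger.debug("compute_fst: fixed undifferentiated site(s), F_ST := 0")
    return float(fst) if fst.ndim == 0 else fst


def fst_bounds_given_delta(delta: float, method: str = "closed_form",
                           step: float = 1e-4) -> tuple[float, float]:
    """Range of attainable F_ST over all frequency pairs with fixed delta.

    ``method='closed_form'`` returns (delta**2, delta/(2-delta)); the
    minimum sits at symmetric frequencies p_bar = 1/2, the maximum at the
    boundary p1 = 0.  ``method='grid'`` scans p1 in [0, 1-delta] at
    resolution ``step`` and evaluates :func:`compute_fst` directly.
    """
    delta = float(delta)
    if not 0.0 <= delta <= 1.0:
        raise ValidationError("delta outside [0, 1]")
    if method == "closed_form":
        if delta == 0.0:
            return 0.0, 0.0
        return delta ** 2, delta / (2.0 - delta)
    if method == "grid":
        p1 = np.arange(0.0, 1.0 - delta + step / 2, step)
        fst = compute_fst(p1, p1 + delta)
        fst = np.atleast_1d(fst)
        return float(fst.min()), float(fst.max())
    raise ValueError(f"unknown method {method!r}")


def delta_bounds_given_fst(fst: float, method: str = "closed_form",
                           step: float = 1e-4) -> tuple[float, float]:
    """Range of attainable delta over all frequency pairs with fixed F_ST.

    Closed form inverts the delta bounds: min = 2F/(1+F) (from
    delta/(2-delta) = F) and max = sqrt(F) (from delta**2 = F).
    """
    fst = float(fst)
    if not 0.0 <= fst <= 1.0:
        raise ValidationError("fst outside [0, 1]")
    if method == "closed_form":
        if fst == 0.0:
            return 0.0, 0.0
        return 2.0 * fst / (1.0 + fst), float(np.sqrt(fst))
    if method == "grid":
        deltas = np.arange(0.0, 1.0 + step / 2, step)
        lo, hi = 1.0, 0.0
        for d in deltas:
            fmin, fmax = fst_bounds_given_delta(float(d))
            if fmin <= fst <= fmax:
                lo, hi = min(lo, d), max(hi, d)
        if lo > hi:
            return 0.0, 0.0
        return float(lo), float(hi)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class SicCells:
    """Joint allele x ancestry cell probabilities at admixture proportion m.

    a00 = (1-m) p_yri, a01 = m p_ceu, a10 = (1-m)(1-p_yri),
    a11 = m (1-p_ceu); the first index is the allele, the second the
    ancestral origin (0 = African, 1 = European).
    """

    m: float
    a00: float
    a01: float
    a10: float
    a11: float

    def __post_init__(self):
        total = self.a00 + self.a01 + self.a10 + self.a11
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(f"cells sum to {total}, not 1")
        if min(self.a00, self.a01, self.a10, self.a11) < 0:
            raise ValidationError("negative cell probability")

    @classmethod
    def from_frequencies(cls, p_ceu: float, p_yri: float, m: float) -> "SicCells":
        p_ceu = float(_check_freq("p_ceu", p_ceu))
        p_yri = float(_check_freq("p_yri", p_yri))
        m = float(_check_freq("m", m))
        return cls(m=m,
                   a00=(1 - m) * p_yri, a01=m * p_ceu,
                   a10=(1 - m) * (1 - p_yri), a11=m * (1 - p_ceu))


def compute_sic(p_ceu, p_yri, m, base: float = 2.0):
    """Shannon information content of a marker for ancestry, in bits.

    Mutual information of the allele x ancestry joint table built from the
    parental frequencies and admixture proportion ``m``; zero when the
    frequencies coincide or when ``m`` is 0 or 1.
    """
    p_ceu = _check_freq("p_ceu", p_ceu)
    p_yri = _check_freq("p_yri", p_yri)
    m = _check_freq("m", m)
    cells = np.stack(np.broadcast_arrays(
        (1 - m) * p_yri, m * p_ceu,
        (1 - m) * (1 - p_yri), m * (1 - p_ceu)), axis=-1)
    # marginals: ancestry (columns 0/1 of each allele row), allele
    anc = np.stack([cells[..., 0] + cells[..., 2],
                    cells[..., 1] + cells[..., 3]], axis=-1)
    allele = np.stack([cells[..., 0] + cells[..., 1],
                       cells[..., 2] + cells[..., 3]], axis=-1)
    prod = np.stack([anc[..., 0] * allele[..., 0],
                     anc[..., 1] * allele[..., 0],
                     anc[..., 0] * allele[..., 1],
                     anc[..., 1] * allele[..., 1]], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        terms = np.where(cells > 0,
                         cells * np.log(np.where(cells > 0, cells, 1.0)
                                        / np.where(prod > 0, prod, 1.0)),
                         0.0)
    sic = np.maximum(terms.sum(axis=-1) / np.log(base), 0.0)
    sic = np.where(sic < 1e-14, 0.0, sic)  # clean float noise at MI = 0
    return float(sic) if sic.ndim == 0 else sic


def classify_fst(fst: float) -> str:
    """Qualitative differentiation category for an F_ST value.

    [0, 0.05) little, [0.05, 0.15) moderate, [0.15, 0.25) large,
    [0.25, 1] very large.
    """
    fst = float(fst)
    if not 0.0 <= fst <= 1.0:
        raise ValidationError("fst outside [0, 1]")
    if fst < 0.05:
        return "little"
    if fst < 0.15:
        return "moderate"
    if fst < 0.25:
        return "large"
    return "very_large"


@dataclass(frozen=True)
class HetSummary:
    observed: float
    expected: float

    def __post_init__(self):
        for v in (self.observed, self.expected):
            if not 0.0 <= v <= 1.0:
                raise ValidationError("heterozygosity outside [0, 1]")


def heterozygosity_summary(dataset: GenotypeDataset,
                           snp_subset: list[str]) -> HetSummary:
    """Observed and expected (2p(1-p)) heterozygosity averaged over SNPs.

    SNPs in the subset with zero non-missing calls are excluded with a log
    note.
    """
    if not snp_subset:
        raise ValidationError("empty SNP subset")
    missing_ids = set(snp_subset) - set(dataset.snps["snp_id"])
    if missing_ids:
        raise ValidationError(f"SNPs absent from dataset: {sorted(missing_ids)[:5]}")
    sub = dataset.subset_snps(snp_subset)
    calls = sub.calls
    n_called = (calls != MISSING).sum(axis=0)
    usable = n_called > 0
    if not usable.all():
        logger.info("heterozygosity_summary: excluded %d SNPs with no calls",
                    int((~usable).sum()))
    if not usable.any():
        raise ValidationError("no SNPs with non-missing calls")
    het_obs = (calls == 1).sum(axis=0)[usable] / n_called[usable]
    freqs = sub.allele_frequencies()[usable]
    het_exp = 2.0 * freqs * (1.0 - freqs)
    return HetSummary(float(het_obs.mean()), float(het_exp.mean()))


def differentiation_table(pop1: GenotypeDataset, pop2: GenotypeDataset,
                          m: float = 0.2) -> pd.DataFrame:
    """Per-SNP differentiation statistics between two harmonized parental
    datasets.

    ``pop1`` is treated as the European-ancestry reference (CEU-like) and
    ``pop2`` as the African-ancestry reference (YRI-like) for the SIC
    computation at admixture proportion ``m``.
    """
    if pop1.snp_ids != pop2.snp_ids:
        raise ValidationError("datasets are not harmonized (SNP lists differ)")
    p1 = pop1.allele_frequencies()
    p2 = pop2.allele_frequencies()
    p_bar = (p1 + p2) / 2.0
    delta = np.abs(p1 - p2)
    df = pd.DataFrame({
        "snp_id": pop1.snps["snp_id"],
        "p_pop1": p1,
        "p_pop2": p2,
        "delta": delta,
        "p_bar": p_bar,
        "s2": delta ** 2 / 4.0,
        "fst": compute_fst(p1, p2),
        "sic": compute_sic(p1, p2, m),
    })
    return df
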