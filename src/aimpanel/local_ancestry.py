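"""Two-ancestry local-ancestry HMM under the hybrid-isolation model.

Each of an admixed individual's two haplotypes carries an ancestry label
(European or African) that switches along the chromosome at recombination
breakpoints laid down since a single admixture event ``lambda_gen``
generations ago.  Under hybrid isolation the breakpoints form a Poisson
process with rate ``lambda_gen`` per Morgan and the ancestry after each
breakpoint is redrawn Bernoulli(m), where ``m`` is the individual's European
admixture proportion.  Over a genetic distance of ``d`` Morgans the haploid
transition is therefore

    P(next = European) = (1 - exp(-lambda d)) m + exp(-lambda d) [cur = European]

with stationary start Bernoulli(m).  The diploid chain is the product of two
independent haploid chains (4 ordered states); an unphased genotype is
emitted from ancestry-specific allele frequencies, one Bernoulli draw per
haplotype.  Posteriors are computed by forward-backward and marginalized to
the unordered European-allele count k in {0, 1, 2}.  Grid points between
markers are handled by augmenting the chain with emission-free loci.

The model-fitting surface follows the statsmodels convention: build an
:class:`AdmixtureHMM` from data, call :meth:`~AdmixtureHMM.fit`, and read
estimates off the returned :class:`AdmixtureResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .io_formats import GenotypeDataset, MISSING, ValidationError

logger = logging.getLogger(__name__)

_FREQ_CLAMP = 1e-4
_M_CLAMP = 1e-6
LAMBDA_BOUNDS = (0.5, 50.0)
#: European allele count of each ordered diploid state (A/E per haplotype)
_K_OF_STATE = np.array([0, 1, 1, 2])


@dataclass
class AdmixtureModelParams:
    """Hybrid-isolation model parameters.

    ``m`` holds one European admixture proportion per individual (clamped
    away from 0 and 1); ``lambda_gen`` is the shared number of generations
    since admixture; ``parental_freqs`` gives per-SNP alt-allele frequencies
    (p_ceu, p_yri) aligned to the dataset's SNP order.
    """

    m: np.ndarray
    lambda_gen: float
    parental_freqs: pd.DataFrame  # columns: snp_id, p_ceu, p_yri

    def __post_init__(self):
        self.m = np.clip(np.atleast_1d(np.asarray(self.m, float)),
                         _M_CLAMP, 1.0 - _M_CLAMP)
        if not LAMBDA_BOUNDS[0] <= self.lambda_gen <= LAMBDA_BOUNDS[1]:
            raise ValidationError(
                f"lambda_gen {self.lambda_gen} outside {LAMBDA_BOUNDS}")

    def prior_k(self) -> np.ndarray:
        """Per-individual prior over European allele count, shape (n, 3)."""
        m = self.m
        return np.stack([(1 - m) ** 2, 2 * m * (1 - m), m ** 2], axis=1)


@dataclass
class AncestryPosteriorField:
    """Per-individual, per-locus posterior over European allele counts.

    ``q`` has shape (n_individuals, n_loci, 3) and each row sums to 1;
    ``grid`` lists the evaluation loci as (chromosome, position_cm).
    """

    individuals: list[str]
    grid: pd.DataFrame  # columns: chromosome, position_cm
    q: np.ndarray

    def __post_init__(self):
        if self.q.shape != (len(self.individuals), len(self.grid), 3):
            raise ValidationError("posterior array shape mismatch")
        if np.any(self.q < -1e-12):
            raise ValidationError("negative posterior probability")
        sums = self.q.sum(axis=2)
        if np.max(np.abs(sums - 1.0)) > 1e-9:
            raise ValidationError("posteriors do not sum to 1")

    def mean_k(self) -> np.ndarray:
        """Posterior mean European allele count, shape (n_ind, n_loci)."""
        return self.q @ np.array([0.0, 1.0, 2.0])


# ---------------------------------------------------------------------------
# core forward-backward machinery
# ---------------------------------------------------------------------------

def _clamped_freqs(parental_freqs: pd.DataFrame,
                   snp_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    freqs = parental_freqs.set_index("snp_id").loc[list(snp_ids)]
    p_ceu = freqs["p_ceu"].to_numpy(float)
    p_yri = freqs["p_yri"].to_numpy(float)
    n_clamped = int(((p_ceu <= 0) | (p_ceu >= 1)
                     | (p_yri <= 0) | (p_yri >= 1)).sum())
    if n_clamped:
        logger.debug("clamping %d boundary parental frequencies", n_clamped)
    return (np.clip(p_ceu, _FREQ_CLAMP, 1 - _FREQ_CLAMP),
            np.clip(p_yri, _FREQ_CLAMP, 1 - _FREQ_CLAMP))


def _emission_table(genotypes: np.ndarray, p_ceu: float,
                    p_yri: float) -> np.ndarray:
    """P(genotype | diploid state) for one SNP; shape (n_ind, 4).

    State order is (hap1, hap2) in {A, E}^2: AA, AE, EA, EE.  Missing
    genotypes emit 1 in every state.
    """
    p = np.array([p_yri, p_ceu])  # allele prob by haploid ancestry
    p1 = p[[0, 0, 1, 1]]
    p2 = p[[0, 1, 0, 1]]
    table = np.stack([
        (1 - p1) * (1 - p2),
        p1 * (1 - p2) + (1 - p1) * p2,
        p1 * p2,
        np.ones(4),  # missing
    ])
    idx = np.where(genotypes == MISSING, 3, genotypes)
    return table[idx]


def _transition_tensors(m: np.ndarray, lam: float,
                        d_morgans: np.ndarray) -> list[np.ndarray]:
    """Per-gap diploid transition matrices, each shape (n_ind, 4, 4)."""
    n = len(m)
    out = []
    stay = np.exp(-lam * np.asarray(d_morgans, float))
    for e in stay:
        th = np.empty((n, 2, 2))
        th[:, 0, 0] = e + (1 - e) * (1 - m)
        th[:, 0, 1] = (1 - e) * m
        th[:, 1, 0] = (1 - e) * (1 - m)
        th[:, 1, 1] = e + (1 - e) * m
        t4 = np.einsum("nab,ncd->nacbd", th, th).reshape(n, 4, 4)
        out.append(t4)
    return out


def _chain_loci(snps: pd.DataFrame, chrom: str,
                grid_cm: Optional[np.ndarray]) -> tuple[np.ndarray, np.ndarray,
                                                        np.ndarray]:
    """Merge marker and grid positions on one chromosome.

    Returns (cm_sorted, marker_index_into_chain, grid_index_into_chain).
    Markers and grid points at identical cM get distinct chain slots
    (zero-length gap between them), which keeps bookkeeping trivial.
    """
    marker_cm = snps["position_cm"].to_numpy(float)
    if np.isnan(marker_cm).any():
        raise ValidationError(f"chromosome {chrom}: markers lack cM positions")
    cms = [marker_cm]
    tags = [np.zeros(len(marker_cm), dtype=int)]
    if grid_cm is not None and len(grid_cm):
        cms.append(np.asarray(grid_cm, float))
        tags.append(np.ones(len(grid_cm), dtype=int))
    cm_all = np.concatenate(cms)
    tag_all = np.concatenate(tags)
    within = np.concatenate([np.arange(len(c)) for c in cms])
    order = np.lexsort((tag_all, cm_all))
    cm_sorted = cm_all[order]
    marker_idx = np.empty(len(marker_cm), dtype=int)
    grid_idx = np.empty(0 if grid_cm is None else len(grid_cm), dtype=int)
    for chain_pos, orig in enumerate(order):
        if tag_all[orig] == 0:
            marker_idx[within[orig]] = chain_pos
        else:
            grid_idx[within[orig]] = chain_pos
    return cm_sorted, marker_idx, grid_idx


def _forward_backward_chrom(calls: np.ndarray, snps: pd.DataFrame,
                            params: AdmixtureModelParams,
                            grid_cm: Optional[np.ndarray]
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Forward-backward on one chromosome for all individuals at once.

    Returns (gamma_markers, gamma_grid, loglik_per_individual, total_loglik)
    where the gammas are posteriors over k in {0,1,2} with shapes
    (n_ind, n_markers, 3) and (n_ind, n_grid, 3).
    """
    n_ind = calls.shape[0]
    m = params.m
    p_ceu, p_yri = _clamped_freqs(params.parental_freqs, snps["snp_id"])
    cm_sorted, marker_idx, grid_idx = _chain_loci(snps, str(snps["chromosome"].iloc[0]),
                                                  grid_cm)
    n_loci = len(cm_sorted)

    # emissions: ones at grid (silent) loci
    emis = np.ones((n_loci, n_ind, 4))
    for j, chain_pos in enumerate(marker_idx):
        emis[chain_pos] = _emission_table(calls[:, j], p_ceu[j], p_yri[j])

    d = np.diff(cm_sorted) / 100.0  # Morgans
    trans = _transition_tensors(m, params.lambda_gen, d)

    pi_h = np.stack([1 - m, m], axis=1)
    init = np.einsum("na,nb->nab", pi_h, pi_h).reshape(n_ind, 4)

    alpha = np.empty((n_loci, n_ind, 4))
    scale = np.empty((n_loci, n_ind))
    a = init * emis[0]
    scale[0] = a.sum(axis=1)
    alpha[0] = a / scale[0][:, None]
    for t in range(1, n_loci):
        a = np.einsum("ni,nij->nj", alpha[t - 1], trans[t - 1]) * emis[t]
        scale[t] = a.sum(axis=1)
        alpha[t] = a / scale[t][:, None]

    beta = np.empty((n_loci, n_ind, 4))
    beta[-1] = 1.0
    for t in range(n_loci - 2, -1, -1):
        b = np.einsum("nij,nj->ni", trans[t], emis[t + 1] * beta[t + 1])
        beta[t] = b / b.sum(axis=1)[:, None]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)

    # marginalize ordered diploid states to unordered k
    gk = np.zeros((n_loci, n_ind, 3))
    for s, k in enumerate(_K_OF_STATE):
        gk[:, :, k] += gamma[:, :, s]
    loglik_ind = np.log(scale).sum(axis=0)
    return (np.transpose(gk[marker_idx], (1, 0, 2)),
            np.transpose(gk[grid_idx], (1, 0, 2)) if len(grid_idx)
            else np.empty((n_ind, 0, 3)),
            loglik_ind, float(loglik_ind.sum()))


def _split_chromosomes(dataset: GenotypeDataset):
    for chrom, grp in dataset.snps.groupby("chromosome", sort=False):
        cols = grp.index.to_numpy()
        yield str(chrom), grp.reset_index(drop=True), dataset.calls[:, cols]


def make_grid(dataset: GenotypeDataset,
              grid_spacing_cm: float = 1.0) -> pd.DataFrame:
    """Uniform evaluation grid spanning each chromosome's marker range."""
    rows = []
    for chrom, grp in dataset.snps.groupby("chromosome", sort=False):
        cm = grp["position_cm"].to_numpy(float)
        lo, hi = float(np.min(cm)), float(np.max(cm))
        pts = np.arange(lo, hi + grid_spacing_cm / 2, grid_spacing_cm)
        rows.append(pd.DataFrame({"chromosome": str(chrom),
                                  "position_cm": pts}))
    return pd.concat(rows, ignore_index=True)


def posterior_field(dataset: GenotypeDataset, params: AdmixtureModelParams,
                    grid_spacing_cm: float = 1.0,
                    grid: Optional[pd.DataFrame] = None
                    ) -> AncestryPosteriorField:
    """Local-ancestry posteriors on an evaluation grid.

    ``grid`` may supply explicit (chromosome, position_cm) points; otherwise
    a uniform grid at ``grid_spacing_cm`` over each chromosome's marker span
    is used.  Grid points are inserted into the chain as emission-free loci,
    so their posteriors interpolate the hidden chain exactly rather than the
    marker posteriors linearly.
    """
    if grid is None:
        grid = make_grid(dataset, grid_spacing_cm)
    blocks, grid_rows = [], []
    for chrom, snps, calls in _split_chromosomes(dataset):
        gcm = grid.loc[grid["chromosome"].astype(str) == chrom,
                       "position_cm"].to_numpy(float)
        _, gamma_grid, _, _ = _forward_backward_chrom(calls, snps, params, gcm)
        blocks.append(gamma_grid)
        grid_rows.append(pd.DataFrame({"chromosome": chrom,
                                       "position_cm": gcm}))
    q = np.concatenate(blocks, axis=1)
    return AncestryPosteriorField(list(dataset.samples),
                                  pd.concat(grid_rows, ignore_index=True), q)


def marker_posteriors(dataset: GenotypeDataset,
                      params: AdmixtureModelParams) -> AncestryPosteriorField:
    """Posteriors evaluated at the marker loci themselves."""
    blocks, rows = [], []
    for chrom, snps, calls in _split_chromosomes(dataset):
        gm, _, _, _ = _forward_backward_chrom(calls, snps, params, None)
        blocks.append(gm)
        rows.append(snps[["chromosome", "position_cm"]])
    return AncestryPosteriorField(
        list(dataset.samples), pd.concat(rows, ignore_index=True),
        np.concatenate(blocks, axis=1))


def _total_loglik(dataset: GenotypeDataset,
                  params: AdmixtureModelParams) -> float:
    total = 0.0
    for _, snps, calls in _split_chromosomes(dataset):
        _, _, _, ll = _forward_backward_chrom(calls, snps, params, None)
        total += ll
    return total


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class AdmixtureHMM:
    """Hybrid-isolation admixture model for an admixed genotype dataset.

    Parameters
    ----------
    dataset
        Admixed cohort with cM positions on every SNP.
    parental_freqs
        DataFrame (snp_id, p_ceu, p_yri) of parental alt-allele frequencies
        covering every SNP in the dataset.
    lambda_init
        Starting value for the generations-since-admixture parameter.
    """

    def __init__(self, dataset: GenotypeDataset, parental_freqs: pd.DataFrame,
                 lambda_init: float = 7.0):
        if dataset.n_samples < 1:
            raise ValidationError("need at least one individual")
        if dataset.n_snps < 2:
            raise ValidationError("need at least two markers")
        if dataset.snps["position_cm"].isna().any():
            raise ValidationError("dataset lacks cM positions")
        missing = set(dataset.snps["snp_id"]) - set(parental_freqs["snp_id"])
        if missing:
            raise ValidationError(
                f"parental frequencies missing for {len(missing)} SNPs")
        self.dataset = dataset
        self.parental_freqs = parental_freqs.reset_index(drop=True)
        self.lambda_init = float(lambda_init)

    @classmethod
    def from_datasets(cls, admixed: GenotypeDataset, parent_ceu: GenotypeDataset,
                      parent_yri: GenotypeDataset,
                      lambda_init: float = 7.0) -> "AdmixtureHMM":
        """Build the model with frequencies estimated from two harmonized
        parental reference panels."""
        if parent_ceu.snp_ids != parent_yri.snp_ids:
            raise ValidationError("parental datasets are not harmonized")
        freqs = pd.DataFrame({
            "snp_id": parent_ceu.snps["snp_id"],
            "p_ceu": parent_ceu.allele_frequencies(),
            "p_yri": parent_yri.allele_frequencies()})
        return cls(admixed, freqs, lambda_init)

    # -- initialization ------------------------------------------------
    def _initial_m(self) -> np.ndarray:
        """Least-squares moment estimator of m from mean dosages."""
        p_ceu, p_yri = _clamped_freqs(self.parental_freqs,
                                      self.dataset.snps["snp_id"])
        diff = p_ceu - p_yri
        calls = self.dataset.calls.astype(float)
        calls[calls == MISSING] = np.nan
        num = np.nansum((calls / 2.0 - p_yri) * diff, axis=1)
        den = np.nansum(np.where(np.isnan(calls), 0.0, diff ** 2), axis=1)
        den = np.where(den > 0, den, 1.0)
        return np.clip(num / den, 0.01, 0.99)

    def fit(self, tol: float = 1e-4, max_iter: int = 100,
            fit_lambda: bool = True, n_alternations: int = 2
            ) -> "AdmixtureResults":
        """Estimate per-individual m and shared lambda.

        Each alternation runs the m fixed-point (set m to the posterior mean
        European haplotype fraction at the markers, iterated to ``tol``)
        followed, when ``fit_lambda``, by a bounded 1-D likelihood search
        for lambda on [0.5, 50].
        """
        m = self._initial_m()
        lam = float(np.clip(self.lambda_init, *LAMBDA_BOUNDS))
        loglik_path: list[float] = []
        converged = False
        for _ in range(n_alternations):
            for _ in range(max_iter):
                params = AdmixtureModelParams(m, lam, self.parental_freqs)
                post = marker_posteriors(self.dataset, params)
                ll = _total_loglik(self.dataset, params)
                loglik_path.append(ll)
                m_new = np.clip(post.mean_k().mean(axis=1) / 2.0,
                                _M_CLAMP, 1 - _M_CLAMP)
                delta = float(np.max(np.abs(m_new - m)))
                m = m_new
                if delta < tol:
                    converged = True
                    break
            else:
                converged = False
            if fit_lambda:
                res = minimize_scalar(
                    lambda lg: -_total_loglik(
                        self.dataset,
                        AdmixtureModelParams(m, lg, self.parental_freqs)),
                    bounds=LAMBDA_BOUNDS, method="bounded",
                    options={"xatol": 0.02})
                lam = float(res.x)
        params = AdmixtureModelParams(m, lam, self.parental_freqs)
        final_ll = _total_loglik(self.dataset, params)
        loglik_path.append(final_ll)
        if not converged:
            logger.warning("fit_admixture: m fixed-point not converged "
                           "within max_iter=%d", max_iter)
        return AdmixtureResults(self, params, final_ll, converged,
                                loglik_path)


@dataclass
class AdmixtureResults:
    """Fitted hybrid-isolation admixture model.

    Carries the per-individual admixture estimates, the shared
    generations-since-admixture estimate, the final log-likelihood and the
    likelihood path of the m fixed-point iterations.
    """

    model: AdmixtureHMM
    params: AdmixtureModelParams
    loglik: float
    converged: bool
    loglik_path: list[float] = field(default_factory=list)

    @property
    def m_hat(self) -> np.ndarray:
        return self.params.m

    @property
    def lambda_hat(self) -> float:
        return self.params.lambda_gen

    @property
    def african_ancestry(self) -> np.ndarray:
        return 1.0 - self.params.m

    def m_summary(self) -> tuple[float, float]:
        """(mean, across-individual SD) of the European admixture
        proportion."""
        sd = float(self.m_hat.std(ddof=1)) if len(self.m_hat) > 1 else 0.0
        return float(self.m_hat.mean()), sd

    def posterior_field(self, grid_spacing_cm: float = 1.0,
                        grid: Optional[pd.DataFrame] = None
                        ) -> AncestryPosteriorField:
        return posterior_field(self.model.dataset, self.params,
                               grid_spacing_cm, grid)

    def map_power(self, grid_spacing_cm: float = 1.0) -> "MapPowerResult":
        return map_power(self.posterior_field(grid_spacing_cm), self.params)

    def summary(self) -> str:
        mean_m, sd_m = float(self.m_hat.mean()), (
            float(self.m_hat.std(ddof=1)) if len(self.m_hat) > 1 else 0.0)
        lines = [
            "Hybrid-isolation admixture model",
            "=" * 40,
            f"individuals:            {self.model.dataset.n_samples}",
            f"markers:                {self.model.dataset.n_snps}",
            f"European ancestry m:    {mean_m:.3f} +/- {sd_m:.3f}",
            f"African ancestry 1-m:   {1 - mean_m:.3f}",
            f"generations (lambda):   {self.lambda_hat:.2f}",
            f"log-likelihood:         {self.loglik:.2f}",
            f"converged:              {self.converged}",
        ]
        return "\n".join(lines)


def fit_admixture(dataset: GenotypeDataset, parental_freqs: pd.DataFrame,
                  lambda_init: float = 7.0, tol: float = 1e-4,
                  max_iter: int = 100,
                  fit_lambda: bool = True) -> AdmixtureResults:
    """Functional wrapper: fit the admixture HMM and return its results."""
    return AdmixtureHMM(dataset, parental_freqs, lambda_init).fit(
        tol=tol, max_iter=max_iter, fit_lambda=fit_lambda)


# ---------------------------------------------------------------------------
# map power
# ---------------------------------------------------------------------------

@dataclass
class MapPowerResult:
    """Entropy-based relative map power per grid locus.

    ``r_i = 1 - sum_j X_ij / sum_j G_j`` with X the posterior entropy and G
    the prior (genome-wide) ancestry entropy; r_i is 0 when the panel adds
    nothing beyond genome-wide ancestry and 1 under perfect local-ancestry
    information.
    """

    grid: pd.DataFrame
    r_i: np.ndarray
    g_j: np.ndarray

    @property
    def r_avg(self) -> float:
        return float(self.r_i.mean())


def _entropy_bits(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=-1)


def map_power(field: AncestryPosteriorField,
              params: AdmixtureModelParams) -> MapPowerResult:
    """Relative power r_i at each grid locus and its average."""
    x = _entropy_bits(field.q)            # (n_ind, n_loci)
    g = _entropy_bits(params.prior_k())   # (n_ind,)
    g_total = g.sum()
    if g_total <= 0:
        raise ValidationError(
            "map power undefined: all individuals have boundary admixture")
    r = 1.0 - x.sum(axis=0) / g_total
    return MapPowerResult(field.grid.copy(), np.clip(r, 0.0, 1.0), g)


def effective_sample_factor(r_avg: float) -> float:
    """Sample-size inflation 1 / r_avg versus perfect local-ancestry
    information, rounded to 2 decimals."""
    if not 0.0 < r_avg <= 1.0:
        raise ValidationError("r_avg must lie in (0, 1]")
    return round(1.0 / r_avg, 2)


def power_threshold_fractions(result: MapPowerResult,
                              thresholds: Sequence[float] = (0.50, 0.75, 0.80)
                              ) -> dict[float, float]:
    """Fraction of grid loci with r_i >= each threshold."""
    return {float(t): float((result.r_i >= t).mean()) for t in thresholds}
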