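"""Admixture-mapping test statistics from local-ancestry posteriors.

Two scan statistics are computed at every grid locus:

- the **locus-genome LOD** (case-only): each case contributes the log10
  ratio of the probability of its local ancestry under an ancestry
  relative-risk model to the probability under its genome-wide ancestry
  prior.  With ``k`` the African-origin allele count, risk weights are
  ``rho = (1, psi1, psi2)`` for ``k = (0, 1, 2)`` with ``psi1 = sqrt(psi2)``
  under the default multiplicative model.  The genome-wide significance
  threshold is LOD >= 2.

- the **case-control z**: per individual, the deviation of posterior-mean
  local African ancestry from the genome-wide estimate; the statistic is the
  Welch-type standardized difference of mean deviations between cases and
  controls, approximately standard normal under the null.  Thresholds of
  |z| >= 4.2 (AIM panels) or 4.7 (random panels) control genome-wide error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import ValidationError
from .local_ancestry import AdmixtureModelParams, AncestryPosteriorField

#: genome-wide z thresholds by panel type
Z_THRESHOLD_AIMS = 4.2
Z_THRESHOLD_RANDOM = 4.7
LOD_THRESHOLD = 2.0


@dataclass(frozen=True)
class RiskModel:
    """Ancestry relative-risk model for African-origin alleles.

    ``psi2`` is the risk of carrying 2 African-origin alleles relative to 0;
    ``psi1`` defaults to sqrt(psi2) (multiplicative per-allele risk).
    """

    psi2: float = 2.80
    psi1: Optional[float] = None

    def __post_init__(self):
        if self.psi2 <= 0:
            raise ValidationError("psi2 must be positive")
        if self.psi1 is None:
            object.__setattr__(self, "psi1", float(np.sqrt(self.psi2)))
        if self.psi1 <= 0:
            raise ValidationError("psi1 must be positive")

    @property
    def rho(self) -> np.ndarray:
        """Risk weights indexed by African allele count (0, 1, 2)."""
        return np.array([1.0, self.psi1, self.psi2])


def _as_status_series(phen, individuals: list[str]) -> pd.Series:
    phen = pd.Series(phen)
    missing = set(individuals) - set(phen.index)
    extra = set(phen.index) - set(individuals)
    if extra:
        raise ValidationError(
            f"phenotype table has samples absent from posteriors: "
            f"{sorted(extra)[:5]}")
    bad = set(phen.unique()) - {"case", "control"}
    if bad:
        raise ValidationError(f"phenotype status must be case/control, got {bad}")
    return phen


def _african_posteriors(field: AncestryPosteriorField) -> np.ndarray:
    """Reindex posteriors from European to African allele count."""
    return field.q[:, :, ::-1]


def _african_priors(params: AdmixtureModelParams) -> np.ndarray:
    return params.prior_k()[:, ::-1]


def locus_genome_lod(field: AncestryPosteriorField,
                     params: AdmixtureModelParams, phen,
                     risk: RiskModel = RiskModel()) -> np.ndarray:
    """Case-only locus-genome LOD score at every grid locus.

    Individuals whose posterior equals their prior contribute 0; the null
    risk model (psi1 = psi2 = 1) gives an identically zero scan.
    """
    phen = _as_status_series(phen, field.individuals)
    case_ids = [s for s in field.individuals if phen.get(s) == "case"]
    if not case_ids:
        raise ValidationError("locus-genome statistic requires >= 1 case")
    idx = [field.individuals.index(s) for s in case_ids]
    q_afr = _african_posteriors(field)[idx]        # (n_case, n_loci, 3)
    pi_afr = _african_priors(params)[idx]          # (n_case, 3)
    rho = risk.rho
    num = q_afr @ rho                              # (n_case, n_loci)
    den = (pi_afr @ rho)[:, None]
    return np.log10(num / den).sum(axis=0)


def case_control_z(field: AncestryPosteriorField,
                   params: AdmixtureModelParams, phen) -> np.ndarray:
    """Case-control z statistic at every grid locus.

    Per-individual deviation: posterior-mean African ancestry fraction at
    the locus minus the genome-wide African ancestry 1 - m_hat.  The z score
    is the Welch-standardized difference of group means; with zero variance
    in both groups the statistic is defined as 0.
    """
    phen = _as_status_series(phen, field.individuals)
    case_idx = [i for i, s in enumerate(field.individuals)
                if phen.get(s) == "case"]
    ctrl_idx = [i for i, s in enumerate(field.individuals)
                if phen.get(s) == "control"]
    if len(case_idx) < 2 or len(ctrl_idx) < 2:
        raise ValidationError("need >= 2 cases and >= 2 controls")
    k_afr = _african_posteriors(field) @ np.array([0.0, 1.0, 2.0])
    dev = k_afr / 2.0 - (1.0 - params.m)[:, None]  # (n_ind, n_loci)
    d_case, d_ctrl = dev[case_idx], dev[ctrl_idx]
    se2 = (d_case.var(axis=0, ddof=1) / len(case_idx)
           + d_ctrl.var(axis=0, ddof=1) / len(ctrl_idx))
    diff = d_case.mean(axis=0) - d_ctrl.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se2 > 0, diff / np.sqrt(np.where(se2 > 0, se2, 1.0)), 0.0)
    return z


@dataclass
class MappingStatistics:
    """Per-locus mapping statistics with significance flags."""

    table: pd.DataFrame  # chromosome, position_cm, lod, z, lod_flag, z_flag
    lod_threshold: float
    z_threshold: float

    def flagged(self) -> pd.DataFrame:
        t = self.table
        return t[t["lod_flag"] | t["z_flag"]].reset_index(drop=True)


def mapping_scan(field: AncestryPosteriorField, params: AdmixtureModelParams,
                 phen, risk: RiskModel = RiskModel(),
                 lod_threshold: float = LOD_THRESHOLD,
                 z_threshold: float = Z_THRESHOLD_AIMS) -> MappingStatistics:
    """Run both statistics over the grid and attach significance flags."""
    lod = locus_genome_lod(field, params, phen, risk)
    z = case_control_z(field, params, phen)
    return significance_calls(field.grid, lod, z, lod_threshold, z_threshold)


def significance_calls(grid: pd.DataFrame, lod: np.ndarray, z: np.ndarray,
                       lod_threshold: float = LOD_THRESHOLD,
                       z_threshold: float = Z_THRESHOLD_AIMS
                       ) -> MappingStatistics:
    """Flag loci exceeding the genome-wide significance thresholds."""
    if lod_threshold <= 0 or z_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    table = grid.copy()
    table["lod"] = lod
    table["z"] = z
    table["lod_flag"] = table["lod"] >= lod_threshold
    table["z_flag"] = table["z"].abs() >= z_threshold
    return MappingStatistics(table, lod_threshold, z_threshold)
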