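"""Ancestry-informative-marker panel construction.

The selection algorithm builds a panel with roughly one marker per 1-Mb bin
while keeping the panel in approximate linkage equilibrium in both parental
reference samples:

1. drop SNPs with minor allele frequency < ``maf_min`` in either parent;
2. keep SNPs whose criterion (delta or F_ST) is >= ``threshold``;
3. assign each chromosome's SNPs to consecutive non-overlapping bins of
   ``bin_size_bp`` and sort each bin by descending criterion;
4. per chromosome, compute pairwise genotype r^2 between the current
   bin-top SNPs in each parental dataset;
5. for any pair with r^2 >= ``r2_max`` in either parent, discard the member
   with the smaller criterion value from its bin (ties at four decimal
   places discard the SNP with the larger bp coordinate) and promote that
   bin's next SNP;
6. iterate 4-5 until no conflicting pair remains.

Conflicting pairs are resolved highest-r^2 first, which makes the outcome
independent of input ordering.  Bins left without a qualifying SNP simply
contribute no marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import (MISSING, GeneticMapTable, GenotypeDataset,
                         ValidationError, chrom_sort_key)
from . import ancestry_stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    criterion: str = "delta"          # "delta" or "fst"
    threshold: Optional[float] = None  # defaults: 0.6 (delta) / 0.4 (fst)
    bin_size_bp: int = 1_000_000
    r2_max: float = 0.4
    maf_min: float = 0.01

    def __post_init__(self):
        if self.criterion not in ("delta", "fst"):
            raise ValidationError("criterion must be 'delta' or 'fst'")
        if self.threshold is None:
            object.__setattr__(
                self, "threshold", 0.6 if self.criterion == "delta" else 0.4)
        if not 0.0 < self.threshold <= 1.0:
            raise ValidationError("threshold outside (0, 1]")
        if not 0.0 < self.r2_max <= 1.0:
            raise ValidationError("r2_max outside (0, 1]")
        if self.bin_size_bp <= 0:
            raise ValidationError("bin_size_bp must be positive")


@dataclass
class AimPanel:
    """Selected markers with their statistics and selection provenance.

    ``table`` columns: snp_id, chromosome, position_bp, position_cm,
    allele_ref, allele_alt, p_pop1, p_pop2, delta, fst, sic, bin_index.
    """

    table: pd.DataFrame
    criterion: str
    threshold: float
    n_iterations: int = 0
    discarded: list[dict] = field(default_factory=list)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def genotype_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete entries (both non-missing); a constant
    vector yields 0 by convention.  This is composite (unphased genotype)
    LD, not haplotype r^2.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1 or len(g1) < 2:
        raise ValidationError("dosage vectors must be equal-length, >= 2")
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        raise ValidationError("fewer than 2 pairwise-complete genotypes")
    x, y = g1[ok], g2[ok]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def _bin_index(position_bp: np.ndarray, bin_size: int) -> np.ndarray:
    # 1-based coordinates: bp 1..bin_size fall in bin 0
    return (np.asarray(position_bp, dtype=np.int64) - 1) // bin_size


def select_aims(parent1: GenotypeDataset, parent2: GenotypeDataset,
                config: SelectionConfig = SelectionConfig(),
                m_for_sic: float = 0.2) -> AimPanel:
    """Run the six-step iterative selection on two harmonized parental
    datasets and return the resulting panel."""
    if parent1.snp_ids != parent2.snp_ids:
        raise ValidationError("parental datasets are not harmonized")
    stats = ancestry_stats.differentiation_table(parent1, parent2, m=m_for_sic)
    crit = stats[config.criterion].to_numpy()

    # steps 1-2: MAF in both parents, criterion threshold
    maf1 = np.minimum(stats["p_pop1"], 1 - stats["p_pop1"])
    maf2 = np.minimum(stats["p_pop2"], 1 - stats["p_pop2"])
    eligible = ((maf1 >= config.maf_min) & (maf2 >= config.maf_min)
                & (crit >= config.threshold)).to_numpy()
    if not eligible.any():
        logger.warning("select_aims: no SNP passes MAF/threshold; empty panel")
        return AimPanel(table=_empty_panel_table(), criterion=config.criterion,
                        threshold=config.threshold)

    snps = parent1.snps
    info = pd.DataFrame({
        "snp_id": snps["snp_id"],
        "chromosome": snps["chromosome"],
        "position_bp": snps["position_bp"],
        "crit": crit,
        "col": np.arange(len(snps)),
    }).loc[eligible]
    info["bin_index"] = _bin_index(info["position_bp"].to_numpy(),
                                   config.bin_size_bp)

    # step 3: per-bin stacks sorted by descending criterion (proximal first
    # on exact float ties, for determinism)
    bins: dict[tuple[str, int], list[dict]] = {}
    for key, grp in info.groupby(["chromosome", "bin_index"], sort=False):
        grp = grp.sort_values(["crit", "position_bp"],
                              ascending=[False, True], kind="stable")
        bins[(str(key[0]), int(key[1]))] = grp.to_dict("records")

    calls1, calls2 = parent1.calls, parent2.calls
    r2_cache: dict[tuple[int, int], tuple[float, float]] = {}

    def pair_r2(ci: int, cj: int) -> tuple[float, float]:
        key = (ci, cj) if ci < cj else (cj, ci)
        if key not in r2_cache:
            r2_cache[key] = (genotype_r2(calls1[:, key[0]], calls1[:, key[1]]),
                             genotype_r2(calls2[:, key[0]], calls2[:, key[1]]))
        return r2_cache[key]

    discarded: list[dict] = []
    n_iter = 0
    while True:
        # step 4: all pairs of current bin-top SNPs within each chromosome
        tops: dict[str, list[tuple[tuple[str, int], dict]]] = {}
        for key, stack in bins.items():
            if stack:
                tops.setdefault(key[0], []).append((key, stack[0]))
        worst = None  # (score, bin_key_a, bin_key_b)
        for chrom, entries in tops.items():
            for (ka, a), (kb, b) in combinations(entries, 2):
                r2a, r2b = pair_r2(a["col"], b["col"])
                score = max(r2a, r2b)
                if score >= config.r2_max:
                    tie_key = (score, min(a["snp_id"], b["snp_id"]),
                               max(a["snp_id"], b["snp_id"]))
                    if worst is None or tie_key > worst[0]:
                        worst = (tie_key, (ka, a), (kb, b))
        if worst is None:
            break
        # step 5: discard the smaller-criterion member (4-dp comparison;
        # ties discard the distal SNP), promote within its bin
        n_iter += 1
        (_, (ka, a), (kb, b)) = worst
        ca, cb = round(a["crit"], 4), round(b["crit"], 4)
        if ca < cb:
            loser_key, loser, partner = ka, a, b
        elif cb < ca:
            loser_key, loser, partner = kb, b, a
        elif a["position_bp"] > b["position_bp"]:
            loser_key, loser, partner = ka, a, b
        else:
            loser_key, loser, partner = kb, b, a
        bins[loser_key].pop(0)
        discarded.append({"snp_id": loser["snp_id"],
                          "partner": partner["snp_id"],
                          "criterion_value": loser["crit"],
                          "reason": "r2_conflict"})

    chosen = [stack[0] for stack in bins.values() if stack]
    cols = [c["col"] for c in chosen]
    table = snps.iloc[cols].reset_index(drop=True).copy()
    srows = stats.iloc[cols].reset_index(drop=True)
    table["p_pop1"] = srows["p_pop1"].to_numpy()
    table["p_pop2"] = srows["p_pop2"].to_numpy()
    table["delta"] = srows["delta"].to_numpy()
    table["fst"] = srows["fst"].to_numpy()
    table["sic"] = srows["sic"].to_numpy()
    table["bin_index"] = [c["bin_index"] for c in chosen]
    order = np.lexsort((table["position_bp"],
                        table["chromosome"].map(chrom_sort_key)))
    table = table.iloc[order].reset_index(drop=True)
    return AimPanel(table=table, criterion=config.criterion,
                    threshold=config.threshold, n_iterations=n_iter,
                    discarded=discarded)


def _empty_panel_table() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "snp_id", "chromosome", "position_bp", "position_cm", "allele_ref",
        "allele_alt", "p_pop1", "p_pop2", "delta", "fst", "sic", "bin_index"])


# ---------------------------------------------------------------------------
# VIF pruning and random panels
# ---------------------------------------------------------------------------

def _window_vifs(X: np.ndarray) -> np.ndarray:
    """VIF = 1/(1-R^2) of each column regressed on the remaining columns.

    Columns are mean-imputed and centered; the regression uses a plain
    least-squares pseudoinverse, so exactly collinear columns give infinite
    VIF rather than an error.  Constant columns have VIF 1.
    """
    n, k = X.shape
    vifs = np.ones(k)
    if k < 2:
        return vifs
    Xc = X - X.mean(axis=0)
    for i in range(k):
        y = Xc[:, i]
        sst = float(y @ y)
        if sst == 0.0:
            continue
        others = np.delete(Xc, i, axis=1)
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        r2 = 1.0 - float(resid @ resid) / sst
        r2 = min(max(r2, 0.0), 1.0)
        vifs[i] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_prune(dataset: GenotypeDataset, window_snps: int = 50,
              slide_snps: int = 5, vif_max: float = 1.1) -> list[str]:
    """Sliding-window LD pruning by variance inflation factor.

    Within each window of ``window_snps`` consecutive (currently retained)
    SNPs, while any SNP's VIF exceeds ``vif_max`` the SNP with the largest
    VIF is removed (the distal one on exact ties, so duplicate columns lose
    exactly one copy); the window then slides by ``slide_snps``.  Windows do
    not span chromosomes.  Returns retained SNP ids in dataset order.
    """
    if window_snps < 2:
        raise ValidationError("window must span at least 2 SNPs")
    snps = dataset.snps
    removed = np.zeros(dataset.n_snps, dtype=bool)
    calls = dataset.calls.astype(float)
    calls[calls == MISSING] = np.nan
    col_means = np.nanmean(np.where(np.isnan(calls), np.nan, calls), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    imputed = np.where(np.isnan(calls), col_means, calls)

    for chrom, grp in snps.groupby("chromosome", sort=False):
        idx = grp.index.to_numpy()
        start = 0
        while start < len(idx):
            window_idx = [i for i in idx[start:start + window_snps]
                          if not removed[i]]
            while len(window_idx) >= 2:
                vifs = _window_vifs(imputed[:, window_idx])
                worst = vifs.max()
                if worst <= vif_max:
                    break
                # largest VIF; distal member on ties
                cand = np.flatnonzero(vifs == worst)
                drop_pos = cand[-1]
                removed[window_idx[drop_pos]] = True
                window_idx.pop(drop_pos)
            start += slide_snps
    return snps.loc[~removed, "snp_id"].tolist()


def random_panel(snp_ids: list[str], fraction: float, seed: int) -> list[str]:
    """Uniform sample without replacement of round(fraction * N) SNP ids,
    reproducible by seed; output preserves input order."""
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("fraction outside (0, 1]")
    n_pick = round(fraction * len(snp_ids))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(snp_ids), size=n_pick, replace=False)
    chosen_set = set(chosen.tolist())
    return [s for i, s in enumerate(snp_ids) if i in chosen_set]


# ---------------------------------------------------------------------------
# panel summary
# ---------------------------------------------------------------------------

@dataclass
class PanelSummary:
    per_chromosome: pd.DataFrame  # chromosome, n_markers, bp_start, bp_end
    n_markers: int
    mean_gap_cm: Optional[float]  # None when no gap escapes a centromere
    n_gaps_included: int
    mean_delta: float
    mean_fst: float
    mean_sic: float
    centromeres_available: bool


def panel_summary(panel: AimPanel,
                  map_table: Optional[GeneticMapTable] = None,
                  centromeres: Optional[pd.DataFrame] = None) -> PanelSummary:
    """Marker counts, spans and mean inter-marker cM distance for a panel.

    Adjacent-marker gaps whose physical interval overlaps a centromere are
    excluded from the mean gap.  Without a centromere table all gaps are
    included and the summary is flagged accordingly.
    """
    table = panel.table
    if table.empty:
        raise ValidationError("cannot summarize an empty panel")
    if map_table is not None:
        from .io_formats import interpolate_cm
        table = interpolate_cm(table, map_table)
    if table["position_cm"].isna().any():
        raise ValidationError("panel lacks cM positions; supply a map table")

    rows = []
    gaps = []
    for chrom, grp in table.groupby("chromosome", sort=False):
        grp = grp.sort_values("position_bp")
        rows.append({"chromosome": chrom, "n_markers": len(grp),
                     "bp_start": int(grp["position_bp"].iloc[0]),
                     "bp_end": int(grp["position_bp"].iloc[-1])})
        bp = grp["position_bp"].to_numpy()
        cm = grp["position_cm"].to_numpy()
        for i in range(len(grp) - 1):
            blocked = False
            if centromeres is not None:
                cen = centromeres[centromeres["chrom"].astype(str) == str(chrom)]
                for c in cen.itertuples():
                    if bp[i] < c.end and bp[i + 1] > c.start:
                        blocked = True
                        break
            if not blocked:
                gaps.append(cm[i + 1] - cm[i])
    if centromeres is None:
        logger.warning("panel_summary: no centromere table; all gaps included")
    return PanelSummary(
        per_chromosome=pd.DataFrame(rows),
        n_markers=len(table),
        mean_gap_cm=float(np.mean(gaps)) if gaps else None,
        n_gaps_included=len(gaps),
        mean_delta=float(table["delta"].mean()),
        mean_fst=float(table["fst"].mean()),
        mean_sic=float(table["sic"].mean()),
        centromeres_available=centromeres is not None)
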