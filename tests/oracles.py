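"""Independent reference implementations used as test oracles.

Everything here is deliberately written from the statistic definitions, not
from the package's code paths: exhaustive enumeration for the HMM, exact
rational arithmetic for the Hardy-Weinberg test, and a plain re-coding of
the published selection rules for the panel algorithms.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test by exact rational enumeration
# ---------------------------------------------------------------------------

def hwe_exact_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE p-value via Fraction arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_a = min(n_alt, 2 * n - n_alt)
    if n_a == 0:
        return 1.0
    f = math.factorial

    def weight(het: int) -> Fraction:
        hom_a = (n_a - het) // 2
        hom_b = n - hom_a - het
        return Fraction(f(n) * 2 ** het, f(hom_a) * f(het) * f(hom_b))

    hets = list(range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2))
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    p_obs = weights[n_het]
    p = sum(w for w in weights.values() if w <= p_obs) / total
    return float(p)


# ---------------------------------------------------------------------------
# exhaustive hidden-path enumeration for the diploid ancestry HMM
# ---------------------------------------------------------------------------

def enumerate_posteriors(genotypes: np.ndarray, cm: np.ndarray,
                         p_ceu: np.ndarray, p_yri: np.ndarray,
                         m: float, lam: float,
                         clamp: float = 1e-4) -> np.ndarray:
    """Posterior P(k European alleles) at each locus by summing all
    4^L ordered hidden-state paths.  Loci with genotype -1 act as silent
    (emission-free) positions."""
    pc = np.clip(np.asarray(p_ceu, float), clamp, 1 - clamp)
    py = np.clip(np.asarray(p_yri, float), clamp, 1 - clamp)
    L = len(cm)
    states = list(itertools.product((0, 1), repeat=2))  # 1 = European

    def emission(g: int, state, j: int) -> float:
        if g == -1:
            return 1.0
        p1 = pc[j] if state[0] else py[j]
        p2 = pc[j] if state[1] else py[j]
        return [(1 - p1) * (1 - p2),
                p1 * (1 - p2) + (1 - p1) * p2,
                p1 * p2][g]

    def haploid_step(h_from: int, h_to: int, d: float) -> float:
        e = math.exp(-lam * d)
        redraw = (1 - e) * (m if h_to else 1 - m)
        return e + redraw if h_from == h_to else redraw

    post = np.zeros((L, 3))
    total = 0.0
    for path in itertools.product(states, repeat=L):
        pr = ((m if path[0][0] else 1 - m)
              * (m if path[0][1] else 1 - m))
        for t in range(1, L):
            d = (cm[t] - cm[t - 1]) / 100.0
            pr *= haploid_step(path[t - 1][0], path[t][0], d)
            pr *= haploid_step(path[t - 1][1], path[t][1], d)
        for t in range(L):
            pr *= emission(int(genotypes[t]), path[t], t)
        total += pr
        for t in range(L):
            post[t, path[t][0] + path[t][1]] += pr
    return post / total


# ---------------------------------------------------------------------------
# brute-force re-implementation of the six-step AIM selection
# ---------------------------------------------------------------------------

def _freq(calls: np.ndarray, j: int) -> float:
    col = calls[:, j]
    ok = col != -1
    return col[ok].sum() / (2.0 * ok.sum())

def _r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != -1) & (y != -1)
    x, y = x[ok].astype(float), y[ok].astype(float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return (cov / (x.std() * y.std())) ** 2


def brute_force_select(parent1, parent2, criterion: str, threshold: float,
                       bin_size: int, r2_max: float,
                       maf_min: float) -> list[str]:
    """Exhaustive re-run of the published six selection steps, recomputing
    everything from scratch on every iteration (no caching, no shortcuts)."""
    snps = parent1.snps
    n = len(snps)
    p1 = np.array([_freq(parent1.calls, j) for j in range(n)])
    p2 = np.array([_freq(parent2.calls, j) for j in range(n)])
    if criterion == "delta":
        crit = np.abs(p1 - p2)
    else:
        pbar = (p1 + p2) / 2
        s2 = ((p1 - pbar) ** 2 + (p2 - pbar) ** 2) / 2
        with np.errstate(invalid="ignore", divide="ignore"):
            crit = np.where((pbar > 0) & (pbar < 1),
                            s2 / (pbar * (1 - pbar)), 0.0)

    maf1 = np.minimum(p1, 1 - p1)
    maf2 = np.minimum(p2, 1 - p2)
    keep = (maf1 >= maf_min) & (maf2 >= maf_min) & (crit >= threshold)

    bins: dict = {}
    for j in np.flatnonzero(keep):
        chrom = str(snps["chromosome"].iloc[j])
        b = (int(snps["position_bp"].iloc[j]) - 1) // bin_size
        bins.setdefault((chrom, b), []).append(j)
    for key in bins:
        bins[key].sort(key=lambda j: (-crit[j], snps["position_bp"].iloc[j]))

    while True:
        tops = {key: stack[0] for key, stack in bins.items() if stack}
        conflicts = []
        for (ka, ja), (kb, jb) in itertools.combinations(tops.items(), 2):
            if ka[0] != kb[0]:
                continue
            r2a = _r2(parent1.calls[:, ja], parent1.calls[:, jb])
            r2b = _r2(parent2.calls[:, ja], parent2.calls[:, jb])
            if max(r2a, r2b) >= r2_max:
                ids = sorted([snps["snp_id"].iloc[ja], snps["snp_id"].iloc[jb]])
                conflicts.append(((max(r2a, r2b), ids[0], ids[1]),
                                  (ka, ja), (kb, jb)))
        if not conflicts:
            break
        _, (ka, ja), (kb, jb) = max(conflicts, key=lambda c: c[0])
        ca, cb = round(crit[ja], 4), round(crit[jb], 4)
        if ca < cb:
            loser = ka
        elif cb < ca:
            loser = kb
        elif snps["position_bp"].iloc[ja] > snps["position_bp"].iloc[jb]:
            loser = ka
        else:
            loser = kb
        bins[loser].pop(0)

    chosen = [stack[0] for stack in bins.values() if stack]
    chosen.sort(key=lambda j: (int(str(snps["chromosome"].iloc[j]))
                               if str(snps["chromosome"].iloc[j]).isdigit()
                               else 99, snps["position_bp"].iloc[j]))
    return [snps["snp_id"].iloc[j] for j in chosen]


# ---------------------------------------------------------------------------
# windowed VIF pruning oracle (scikit-learn regression for R^2)
# ---------------------------------------------------------------------------

def brute_force_vif_prune(dataset, window_snps: int, slide_snps: int,
                          vif_max: float) -> list[str]:
    from sklearn.linear_model import LinearRegression

    snps = dataset.snps
    calls = dataset.calls.astype(float)
    calls[calls == -1] = np.nan
    means = np.nanmean(calls, axis=0)
    X_full = np.where(np.isnan(calls), means, calls)
    removed: set[int] = set()

    def vif_of(idx: list[int], pos: int) -> float:
        y = X_full[:, idx[pos]]
        if np.var(y) == 0:
            return 1.0
        others = [i for k, i in enumerate(idx) if k != pos]
        X = X_full[:, others]
        r2 = LinearRegression().fit(X, y).score(X, y)
        r2 = min(max(r2, 0.0), 1.0)
        return math.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)

    for chrom, grp in snps.groupby("chromosome", sort=False):
        idx_all = grp.index.to_list()
        start = 0
        while start < len(idx_all):
            window = [i for i in idx_all[start:start + window_snps]
                      if i not in removed]
            while len(window) >= 2:
                vifs = [vif_of(window, k) for k in range(len(window))]
                worst = max(vifs)
                if worst <= vif_max:
                    break
                drop = max(k for k, v in enumerate(vifs) if v == worst)
                removed.add(window[drop])
                window.pop(drop)
            start += slide_snps
    return [s for i, s in enumerate(snps["snp_id"]) if i not in removed]
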