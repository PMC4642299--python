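"""Genotype-based IBD estimation and pedigree verification.

Pairwise kinship from the pedigree lives on :class:`famseq.pedigree.Pedigree`;
this module estimates realized sharing from common autosomal markers with the
classic method-of-moments IBD-state estimator (observed IBS-state counts
against allele-frequency expectations, solved for Z0/Z1/Z2, clipped and
renormalized) and compares pi_hat = Z1/2 + Z2 with the pedigree expectation
2*phi.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .pedigree import Pedigree

__all__ = [
    "IBDResult", "select_ibd_markers", "ibd_moments", "verify_pedigree",
    "gene_drop_kinship",
]

_X_CHROMS = {"X", "chrX", "23"}


@dataclass
class IBDResult:
    pair: tuple[str, str]
    z0: float
    z1: float
    z2: float

    @property
    def pi_hat(self) -> float:
        return self.z1 / 2.0 + self.z2


def select_ibd_markers(genotypes: np.ndarray, maf_min: float = 0.01,
                       r2_max: float = 0.2, window: int = 10,
                       min_markers: int = 200,
                       chroms: np.ndarray | None = None,
                       ld_cols: np.ndarray | None = None) -> np.ndarray:
    """Greedy sliding-window LD pruning of a (markers x samples) dosage matrix.

    Retains markers with sample MAF > ``maf_min`` whose squared genotype
    correlation with every previously retained marker in the trailing window
    is <= ``r2_max``.  X-chromosome markers are excluded (autosomal estimator
    only).  Returns retained marker indices.

    ``ld_cols`` restricts the correlation computation to a subset of sample
    columns — pass the unrelated founders: r2 computed over related samples
    reflects family sharing, and pruning on it selectively discards markers
    that are informative about that sharing.
    """
    g = np.asarray(genotypes, dtype=float)
    miss = g < 0
    g = np.where(miss, np.nan, g)
    if ld_cols is not None:
        g_ld = g[:, np.asarray(ld_cols)]
    else:
        g_ld = g
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(g, axis=1) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    candidates = maf > maf_min
    if chroms is not None:
        candidates &= ~np.isin(chroms, list(_X_CHROMS))

    kept: list[int] = []
    centered = g_ld - np.nanmean(g_ld, axis=1, keepdims=True)
    centered = np.where(np.isnan(centered), 0.0, centered)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    for i in np.flatnonzero(candidates):
        ok = True
        for j in kept[-window:]:
            denom = norms[i] * norms[j]
            if denom == 0:
                continue
            r = float(centered[i] @ centered[j]) / denom
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(i)
    if len(kept) < min_markers:
        warnings.warn(f"only {len(kept)} IBD markers retained "
                      f"(< {min_markers})", stacklevel=2)
    return np.asarray(kept, dtype=int)


def _ibs_expectations(p: np.ndarray, n_chroms: int | None = None
                      ) -> tuple[np.ndarray, ...]:
    """Per-marker P(IBS state | IBD state) for allele frequency p.

    When ``n_chroms`` (the number of chromosomes the frequencies were
    estimated from) is given, the frequency powers are replaced by their
    unbiased falling-factorial estimates — the small-sample correction used
    by standard GWAS toolkits, without which estimates from a handful of
    founders are visibly biased.
    """
    q = 1.0 - p
    if n_chroms is None or n_chroms < 4:
        p2q2 = p ** 2 * q ** 2
        p3q_pq3 = p ** 3 * q + p * q ** 3
        p4_q4 = p ** 4 + q ** 4
        pq = p * q
        p2_q2 = p ** 2 + q ** 2
    else:
        n = float(n_chroms)
        x, y = p * n, q * n

        def ff(v, k):          # falling factorial v(v-1)...(v-k+1)
            out = np.ones_like(v)
            for i in range(k):
                out = out * np.maximum(v - i, 0.0)
            return out

        d4 = n * (n - 1) * (n - 2) * (n - 3)
        d2 = n * (n - 1)
        p2q2 = ff(x, 2) * ff(y, 2) / d4
        p3q_pq3 = (ff(x, 3) * y + x * ff(y, 3)) / d4
        p4_q4 = (ff(x, 4) + ff(y, 4)) / d4
        pq = x * y / d2
        p2_q2 = (ff(x, 2) + ff(y, 2)) / d2
    e00 = 2.0 * p2q2                                 # IBS0 | Z0
    e10 = 4.0 * p3q_pq3                              # IBS1 | Z0
    e20 = p4_q4 + 4.0 * p2q2                         # IBS2 | Z0
    e11 = 2.0 * pq                                   # IBS1 | Z1
    e21 = p2_q2                                      # IBS2 | Z1
    return e00, e10, e20, e11, e21


def ibd_moments(genotypes: np.ndarray, pair: tuple[int, int],
                allele_freqs: np.ndarray, min_markers: int = 200,
                n_freq_chroms: int | None = None) -> IBDResult:
    """Method-of-moments Z0/Z1/Z2 for one sample pair.

    ``genotypes`` is (markers x samples) alt-dosage (-1 missing);
    ``allele_freqs`` the per-marker alt frequency, ideally estimated from
    cohort founders to avoid relatedness bias.
    """
    i, j = pair
    gi = np.asarray(genotypes[:, i], dtype=float)
    gj = np.asarray(genotypes[:, j], dtype=float)
    ok = (gi >= 0) & (gj >= 0)
    p = np.asarray(allele_freqs, dtype=float)
    ok &= (p > 0) & (p < 1)
    if int(ok.sum()) < min_markers:
        raise ValueError(f"only {int(ok.sum())} usable markers "
                         f"(minimum {min_markers})")
    gi, gj, p = gi[ok], gj[ok], p[ok]

    diff = np.abs(gi - gj)
    n_ibs0 = float((diff == 2).sum())
    n_ibs1 = float((diff == 1).sum())
    n_ibs2 = float((diff == 0).sum())

    e00, e10, e20, e11, e21 = _ibs_expectations(p, n_freq_chroms)
    E00, E10, E20 = e00.sum(), e10.sum(), e20.sum()
    E11, E21 = e11.sum(), e21.sum()
    n = float(len(p))

    z0 = n_ibs0 / E00 if E00 > 0 else 0.0
    z1 = (n_ibs1 - z0 * E10) / E11 if E11 > 0 else 0.0
    z2 = (n_ibs2 - z0 * E20 - z1 * E21) / n

    z = np.clip(np.array([z0, z1, z2]), 0.0, 1.0)
    total = z.sum()
    z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
    return IBDResult(pair=(str(i), str(j)), z0=float(z[0]), z1=float(z[1]),
                     z2=float(z[2]))


@dataclass
class PedigreeCheck:
    pair: tuple[str, str]
    family_id: str
    expected: float         # 2 * phi from the pedigree
    observed: float         # pi_hat
    flagged: bool


def verify_pedigree(genotypes: np.ndarray, samples: list[str], ped: Pedigree,
                    allele_freqs: np.ndarray, tolerance: float = 0.15,
                    min_markers: int = 200,
                    n_freq_chroms: int | None = None) -> list[PedigreeCheck]:
    """Compare observed pi_hat with pedigree expectation for within-family pairs.

    Flags pairs with |pi_hat - 2*phi| > tolerance.  Families with fewer than
    two genotyped members yield an empty report.
    """
    col = {s: k for k, s in enumerate(samples)}
    out: list[PedigreeCheck] = []
    for fam, members in ped.families.items():
        present = [m for m in members if m in col]
        for a_i in range(len(present)):
            for b_i in range(a_i + 1, len(present)):
                a, b = present[a_i], present[b_i]
                exp = 2.0 * ped.kinship(a, b)
                res = ibd_moments(genotypes, (col[a], col[b]), allele_freqs,
                                  min_markers=min_markers,
                                  n_freq_chroms=n_freq_chroms)
                obs = res.pi_hat
                out.append(PedigreeCheck(
                    pair=(a, b), family_id=fam, expected=exp, observed=obs,
                    flagged=abs(obs - exp) > tolerance))
    return out


def gene_drop_kinship(ped: Pedigree, a: str, b: str, n_drops: int = 100_000,
                      seed: int = 0) -> float:
    """Monte-Carlo kinship: P(random allele of a IBD random allele of b).

    Founder alleles get unique labels and are dropped through the pedigree;
    the estimate is the fraction of drops in which one random allele from
    each individual carries the same founder label.  Independent oracle for
    the recursive phi.
    """
    fam = ped.family_of(a)
    if ped.family_of(b) != fam:
        return 0.0
    rng = np.random.default_rng(seed)
    order = ped.topological(fam)
    haps: dict[str, np.ndarray] = {}
    label = 0
    for iid in order:
        f, m = ped.parents(iid)
        h = np.empty((n_drops, 2), dtype=np.int32)
        for slot, parent in enumerate((f, m)):
            if parent is None:
                h[:, slot] = label
                label += 1
            else:
                choice = rng.integers(0, 2, size=n_drops)
                h[:, slot] = haps[parent][np.arange(n_drops), choice]
        haps[iid] = h
    pick_a = haps[a][np.arange(n_drops), rng.integers(0, 2, size=n_drops)]
    pick_b = haps[b][np.arange(n_drops), rng.integers(0, 2, size=n_drops)]
    return float((pick_a == pick_b).mean())
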