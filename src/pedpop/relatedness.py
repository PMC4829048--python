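"""Pairwise Lynch-Ritland relatedness on biallelic SNP genotypes.

For a reference individual x = (a, b) and proband y = (c, d) at one locus
with allele frequencies p_a, p_b, the locus estimate is

    num = p_a (S_bc + S_bd) + p_b (S_ac + S_ad) - 4 p_a p_b
    den = (1 + S_ab)(p_a + p_b) - 4 p_a p_b

with S the allele-identity indicator.  The multilocus estimate is the
weighted (ratio-of-sums) form, sum(num)/sum(den) across loci, and the final
r is the arithmetic mean of the x->y and y->x directions.  The ratio-of-sums
form is essential for SNPs: a heterozygous reference at p = 0.5 has a zero
denominator, so per-locus averaging would divide by zero.

Expectation is 0.5 for parent-offspring and full siblings, 0.25 for half
siblings, 0 for unrelated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING

_DEN_TOL = 1e-12


def allele_frequencies(genotypes: np.ndarray, clip: float = 1e-6) -> np.ndarray:
    """Plug-in reference-allele frequencies from consensus genotypes.

    Computed from identified individuals (not raw samples) so repeatedly
    sampled animals are not over-weighted.  Frequencies are clipped away
    from 0/1; loci monomorphic in the data then carry ~zero weight in the
    estimator rather than producing NaNs.
    """
    G = np.asarray(genotypes, dtype=float)
    mask = G >= 0
    with np.errstate(invalid="ignore"):
        p = np.where(
            mask.sum(axis=0) > 0,
            np.nansum(np.where(mask, G, np.nan), axis=0) / (2.0 * mask.sum(axis=0)),
            0.5,
        )
    return np.clip(p, clip, 1.0 - clip)


def _tables(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus numerator table NUM[l, gx, gy] and denominator DEN[l, gx].

    Genotypes indexed by dosage of allele A (0 = BB, 1 = AB, 2 = AA).
    """
    p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    L = p.size
    den = np.empty((L, 3))
    den[:, 0] = 4 * p * q
    den[:, 1] = 1 - 4 * p * q
    den[:, 2] = 4 * p * q
    num = np.empty((L, 3, 3))
    # reference BB
    num[:, 0, 0] = 4 * p * q
    num[:, 0, 1] = 2 * q * (p - q)
    num[:, 0, 2] = -4 * q * q
    # reference AB
    num[:, 1, 0] = 2 * p * (p - q)
    num[:, 1, 1] = 1 - 4 * p * q
    num[:, 1, 2] = 2 * q * (q - p)
    # reference AA
    num[:, 2, 0] = -4 * p * p
    num[:, 2, 1] = 2 * p * (q - p)
    num[:, 2, 2] = 4 * p * q
    return num, den


def lr_pair(gx, gy, freqs) -> float:
    """Reciprocally averaged multilocus Lynch-Ritland r for one pair.

    Returns NaN when every co-called locus is uninformative (zero total
    denominator in both directions).
    """
    gx = np.asarray(gx, dtype=int)
    gy = np.asarray(gy, dtype=int)
    p = np.asarray(freqs, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("allele frequencies must be strictly inside (0, 1)")
    mask = (gx != MISSING) & (gy != MISSING)
    if not mask.any():
        raise ValueError("pair shares no co-called locus")
    num, den = _tables(p)
    idx = np.nonzero(mask)[0]
    num_xy = num[idx, gx[idx], gy[idx]].sum()
    den_xy = den[idx, gx[idx]].sum()
    num_yx = num[idx, gy[idx], gx[idx]].sum()
    den_yx = den[idx, gy[idx]].sum()
    vals = []
    if den_xy > _DEN_TOL:
        vals.append(num_xy / den_xy)
    if den_yx > _DEN_TOL:
        vals.append(num_yx / den_yx)
    if not vals:
        return float("nan")
    return float(np.mean(vals))


@dataclass
class RelatednessMatrix:
    """Symmetric pairwise r with per-pair informative-locus counts."""

    ids: list[str]
    r: np.ndarray  # (n, n), NaN on the diagonal
    n_informative: np.ndarray  # (n, n) int
    low_confidence_min_loci: int = 20

    def __post_init__(self) -> None:
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def pair(self, id1: str, id2: str) -> float:
        return float(self.r[self._index[id1], self._index[id2]])

    def informative(self, id1: str, id2: str) -> int:
        return int(self.n_informative[self._index[id1], self._index[id2]])

    def low_confidence(self, id1: str, id2: str) -> bool:
        return self.informative(id1, id2) < self.low_confidence_min_loci

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "id1": self.ids[i],
                        "id2": self.ids[j],
                        "r": self.r[i, j],
                        "n_informative_loci": int(self.n_informative[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def lr_matrix(individuals_or_genotypes, freqs=None, ids=None) -> RelatednessMatrix:
    """All-pairs Lynch-Ritland r, vectorized over the genotype matrix.

    Accepts an :class:`~pedpop.genotyping.IndividualTable` (frequencies are
    then estimated plug-in from its consensus genotypes unless given) or a
    raw (n, L) dosage matrix plus explicit frequencies and ids.
    """
    if hasattr(individuals_or_genotypes, "genotypes"):
        table = individuals_or_genotypes
        G = table.genotypes
        ids = list(table.ids)
        if freqs is None:
            freqs = allele_frequencies(G)
    else:
        G = np.asarray(individuals_or_genotypes, dtype=np.int8)
        if freqs is None:
            freqs = allele_frequencies(G)
        if ids is None:
            ids = [f"G{k+1:04d}" for k in range(G.shape[0])]
    n, L = G.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    p = np.asarray(freqs, dtype=float)
    num_t, den_t = _tables(p)

    onehot = np.zeros((n, L, 3), dtype=float)
    called = G != MISSING
    rows, cols = np.nonzero(called)
    onehot[rows, cols, G[rows, cols]] = 1.0

    num_dir = np.zeros((n, n))
    for g in range(3):
        for h in range(3):
            num_dir += (onehot[:, :, g] * num_t[:, g, h]) @ onehot[:, :, h].T
    # directional denominator: sum of DEN over loci called in the reference
    # and co-called in the proband
    dref = np.where(called, den_t[np.arange(L)[None, :], np.clip(G, 0, 2)], 0.0)
    den_dir = dref @ called.T.astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        r_xy = np.where(den_dir > _DEN_TOL, num_dir / den_dir, np.nan)
    r_yx = r_xy.T
    both = ~np.isnan(r_xy) & ~np.isnan(r_yx)
    r = np.where(both, 0.5 * (r_xy + r_yx), np.where(np.isnan(r_xy), r_yx, r_xy))
    np.fill_diagonal(r, np.nan)

    informative_ref = called & (den_t[np.arange(L)[None, :], np.clip(G, 0, 2)] > _DEN_TOL)
    co_called = called.astype(np.int32) @ called.T.astype(np.int32)
    dead = called & ~informative_ref
    both_dead = dead.astype(np.int32) @ dead.T.astype(np.int32)
    n_informative = co_called - both_dead
    np.fill_diagonal(n_informative, 0)

    return RelatednessMatrix(ids=ids, r=r, n_informative=n_informative)
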