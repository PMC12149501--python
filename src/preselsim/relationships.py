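"""Pedigree and genomic relationship structures for single-step GBLUP.

Provides inbreeding coefficients (Meuwissen & Luo algorithm), the sparse
inverse of the numerator relationship matrix A via Henderson's rules with
inbreeding, dense pedigree submatrices (tabular method), the VanRaden
method-1 genomic relationship matrix G centered on base-population allele
frequencies, the blended G* = w G + (1-w) A22, and the single-step
H-inverse, which differs from A-inverse only on the genotyped block:

    H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1]

An incremental tabular-A accumulator is included for simulation loops where
the pedigree grows by whole cohorts whose parents already exist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


def _validate_pedigree(sire: np.ndarray, dam: np.ndarray) -> None:
    n = sire.size
    for name, par in (("sire", sire), ("dam", dam)):
        bad = (par >= np.arange(n)) & (par >= 0)
        if np.any(bad):
            raise ValueError(f"pedigree not topologically ordered: {name} of "
                             f"animal {np.flatnonzero(bad)[0]} does not precede it")
        if np.any(par < -1):
            raise ValueError(f"invalid {name} id")


def inbreeding_coefficients(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo algorithm.

    ``sire``/``dam`` are 0-based positional indices into the (topologically
    ordered) pedigree, -1 for unknown.  F_i = a(sire_i, dam_i) / 2; animals
    with any unknown parent get F = 0.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _validate_pedigree(sire, dam)
    n = sire.size
    f = np.zeros(n)
    # d_i = within-family (Mendelian sampling) variance given parental inbreeding
    d = np.empty(n)
    point = np.zeros(n, dtype=np.int64)
    for i in range(n):
        s, dd = sire[i], dam[i]
        d[i] = 0.5 - 0.25 * ((f[s] if s >= 0 else -1.0) + (f[dd] if dd >= 0 else -1.0))
        if s < 0 or dd < 0:
            f[i] = 0.0
            continue
        # trace ancestor list of i, accumulating L coefficients
        fi = -1.0
        lcoef = np.zeros(i + 1)
        ancestors = np.zeros(i + 1, dtype=bool)
        lcoef[i] = 1.0
        stack = [i]
        ancestors[i] = True
        order = []
        while stack:
            j = stack.pop()
            order.append(j)
            for p in (sire[j], dam[j]):
                if p >= 0 and not ancestors[p]:
                    ancestors[p] = True
                    stack.append(p)
        for j in sorted(order, reverse=True):
            lj = lcoef[j]
            if lj == 0.0:
                continue
            for p in (sire[j], dam[j]):
                if p >= 0:
                    lcoef[p] += 0.5 * lj
            fi += lj * lj * d[j]
        f[i] = fi
    return f


def a_inverse(sire: np.ndarray, dam: np.ndarray,
              f: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules accounting for inbreeding.

    Each animal contributes 1/d_i to the (i,i) cell, -1/(2 d_i) to
    parent-offspring cells and 1/(4 d_i) among known parents, with
    d_i = 0.5 - 0.25 (F_s + F_d) (a missing parent contributes F = -1,
    i.e. d grows by 0.25).
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _validate_pedigree(sire, dam)
    if f is None:
        f = inbreeding_coefficients(sire, dam)
    n = sire.size
    fs = np.where(sire >= 0, f[np.maximum(sire, 0)], -1.0)
    fd = np.where(dam >= 0, f[np.maximum(dam, 0)], -1.0)
    d = 0.5 - 0.25 * (fs + fd)
    alpha = 1.0 / d
    rows, cols, vals = [], [], []
    idx = np.arange(n)
    rows.append(idx); cols.append(idx); vals.append(alpha)
    for par in (sire, dam):
        known = par >= 0
        rows.append(idx[known]); cols.append(par[known])
        vals.append(-0.5 * alpha[known])
        rows.append(par[known]); cols.append(idx[known])
        vals.append(-0.5 * alpha[known])
        rows.append(par[known]); cols.append(par[known])
        vals.append(0.25 * alpha[known])
    both = (sire >= 0) & (dam >= 0)
    rows.append(sire[both]); cols.append(dam[both]); vals.append(0.25 * alpha[both])
    rows.append(dam[both]); cols.append(sire[both]); vals.append(0.25 * alpha[both])
    m = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))
    return m.tocsr()


def tabular_a(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method (small pedigrees)."""
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _validate_pedigree(sire, dam)
    n = sire.size
    a = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * a[s, :i]
        if d >= 0:
            row += 0.5 * a[d, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[s, d] if (s >= 0 and d >= 0) else 0.0)
    return a


def _prune_to_ancestors(sire, dam, ids):
    keep = np.zeros(sire.size, dtype=bool)
    stack = list(ids)
    while stack:
        i = stack.pop()
        if keep[i]:
            continue
        keep[i] = True
        for p in (sire[i], dam[i]):
            if p >= 0 and not keep[p]:
                stack.append(p)
    return np.flatnonzero(keep)


def a_submatrix(sire: np.ndarray, dam: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Dense A22: pedigree relationships among ``ids`` (tabular method on the pruned pedigree)."""
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    ids = np.asarray(ids, dtype=np.int64)
    if ids.size and (ids.min() < 0 or ids.max() >= sire.size):
        raise ValueError("unknown id in genotyped list")
    keep = _prune_to_ancestors(sire, dam, ids)
    remap = -np.ones(sire.size, dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    ps = np.where(sire[keep] >= 0, remap[np.maximum(sire[keep], 0)], -1)
    pd = np.where(dam[keep] >= 0, remap[np.maximum(dam[keep], 0)], -1)
    a = tabular_a(ps, pd)
    sub = remap[ids]
    return a[np.ix_(sub, sub)]


def g_matrix(genotypes: np.ndarray, base_freq: np.ndarray) -> np.ndarray:
    """VanRaden method-1 genomic relationships, centered on base-population frequencies.

    G = Z Z' / (2 sum_m p_m (1 - p_m)) with Z = counts - 2p, restricted to
    markers segregating in the base (0 < p < 1); frequencies are the ones
    frozen at base-population construction, which makes G compatible with A22.
    """
    counts = np.asarray(genotypes, dtype=float)
    p = np.asarray(base_freq, dtype=float)
    seg = (p > 0.0) & (p < 1.0)
    if not np.any(seg):
        raise ValueError("all markers are monomorphic in the base population")
    z = counts[:, seg] - 2.0 * p[seg]
    denom = 2.0 * np.sum(p[seg] * (1.0 - p[seg]))
    return (z @ z.T) / denom


def _checked_inverse(m: np.ndarray, name: str, tol: float = 1e-6,
                     cond_max: float = 1e12) -> np.ndarray:
    try:
        inv = np.linalg.inv(m)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"{name} is singular") from err
    # cheap 1-norm condition estimate; a full SVD would dominate at scale
    cond = np.linalg.norm(m, 1) * np.linalg.norm(inv, 1)
    if not np.isfinite(cond) or cond > cond_max:
        raise np.linalg.LinAlgError(
            f"{name} numerically singular (condition estimate {cond:.3e})")
    # probe-vector residual check: ||M M^-1 v - v||_inf on random unit vectors
    # (a full M @ M^-1 product would cost another O(n^3))
    probe_rng = np.random.default_rng(0)
    v = probe_rng.standard_normal((m.shape[0], 4))
    v /= np.abs(v).max(axis=0)
    resid = np.abs(m @ (inv @ v) - v).max()
    if resid > tol:
        raise np.linalg.LinAlgError(
            f"inversion of {name} inaccurate (probe residual {resid:.3e}, "
            f"condition estimate {cond:.3e})")
    return inv


def blend_and_invert(g: np.ndarray, a22: np.ndarray, w: float = 0.95
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """G* = w G + (1-w) A22; returns (G*, G*^-1, A22^-1) with verified inversions."""
    if g.shape != a22.shape:
        raise ValueError("G and A22 not conformable")
    g_star = w * g + (1.0 - w) * a22
    g_star_inv = _checked_inverse(g_star, "G*")
    a22_inv = _checked_inverse(a22, "A22")
    return g_star, g_star_inv, a22_inv


def h_inverse(a_inv: sp.spmatrix, a22_inv: np.ndarray, g_star_inv: np.ndarray,
              genotyped: np.ndarray) -> sp.csr_matrix:
    """H^-1 = A^-1 + correction on the genotyped block (G*^-1 - A22^-1)."""
    genotyped = np.asarray(genotyped, dtype=np.int64)
    n = a_inv.shape[0]
    if genotyped.size == 0:
        return sp.csr_matrix(a_inv)
    if g_star_inv.shape[0] != genotyped.size or a22_inv.shape[0] != genotyped.size:
        raise ValueError("genotyped index set does not match dense inverse dimensions")
    corr = g_star_inv - a22_inv
    rows = np.repeat(genotyped, genotyped.size)
    cols = np.tile(genotyped, genotyped.size)
    block = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=(n, n))
    return (sp.csr_matrix(a_inv) + block.tocsr()).tocsr()


@dataclass
class HInvOperator:
    """Matrix-free H^-1 (or plain A^-1): y = A^-1 x + correction on genotyped rows.

    Avoids materializing the dense genotyped block inside the sparse matrix,
    which matters when most of the population is genotyped.
    """

    a_inv: sp.csr_matrix
    genotyped: np.ndarray | None = None       # positional indices
    correction: np.ndarray | None = None      # G*^-1 - A22^-1

    @property
    def n(self) -> int:
        return self.a_inv.shape[0]

    def matmat(self, x: np.ndarray) -> np.ndarray:
        y = self.a_inv @ x
        if self.genotyped is not None and self.genotyped.size:
            y[self.genotyped] += self.correction @ x[self.genotyped]
        return y

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.a_inv.diagonal()).copy()
        if self.genotyped is not None and self.genotyped.size:
            d[self.genotyped] += np.diag(self.correction)
        return d


class PedigreeAccumulator:
    """Incrementally grown dense tabular A for a pedigree extended cohort-by-cohort.

    Parents of every appended cohort must already be present.  Exposes exact
    inbreeding (diag - 1) and dense submatrices without re-running the
    tabular method from scratch each round.
    """

    def __init__(self, n_founders: int, capacity: int):
        self._a = np.zeros((capacity, capacity))
        idx = np.arange(n_founders)
        self._a[idx, idx] = 1.0
        self.n = n_founders
        self.sire = np.full(capacity, -1, dtype=np.int64)
        self.dam = np.full(capacity, -1, dtype=np.int64)

    def _grow(self, need: int) -> None:
        cap = self._a.shape[0]
        if need <= cap:
            return
        new_cap = max(need, int(cap * 1.5) + 1)
        a = np.zeros((new_cap, new_cap))
        a[:self.n, :self.n] = self._a[:self.n, :self.n]
        self._a = a
        for name in ("sire", "dam"):
            old = getattr(self, name)
            arr = np.full(new_cap, -1, dtype=np.int64)
            arr[:self.n] = old[:self.n]
            setattr(self, name, arr)

    def append_cohort(self, sires: np.ndarray, dams: np.ndarray) -> np.ndarray:
        """Add a cohort with parents among existing animals; returns new positional ids."""
        sires = np.asarray(sires, dtype=np.int64)
        dams = np.asarray(dams, dtype=np.int64)
        k = sires.size
        n = self.n
        if k and (sires.max() >= n or dams.max() >= n):
            raise ValueError("cohort parents must already be in the pedigree")
        self._grow(n + k)
        a = self._a
        old = 0.5 * (a[sires, :n] + a[dams, :n])        # (k, n)
        a[n:n + k, :n] = old
        a[:n, n:n + k] = old.T
        cross = 0.5 * (old[:, sires] + old[:, dams])    # among-new (parents are old)
        a[n:n + k, n:n + k] = cross
        new_idx = np.arange(n, n + k)
        a[new_idx, new_idx] = 1.0 + 0.5 * a[sires, dams]
        self.sire[n:n + k] = sires
        self.dam[n:n + k] = dams
        self.n = n + k
        return new_idx

    @property
    def a(self) -> np.ndarray:
        return self._a[:self.n, :self.n]

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.a) - 1.0

    def submatrix(self, ids: np.ndarray) -> np.ndarray:
        ids = np.asarray(ids, dtype=np.int64)
        return self.a[np.ix_(ids, ids)]

    def a_inv(self) -> sp.csr_matrix:
        return a_inverse(self.sire[:self.n], self.dam[:self.n], f=self.inbreeding())
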