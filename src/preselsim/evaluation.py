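"""Multivariate mixed-model equations for BLUP and single-step GBLUP.

Model per record (animal i in hatch level h with dam d):

    y_i = b_h + u_i + c_d * e_BW + e_i

with b the fixed hatch-by-trait effects, u the three-trait breeding values
(prior N(0, K ox V_g) with K = A or H), c the maternal permanent-environment
effect (BW only, prior N(0, I c2)) and e ~ MVN(0, R) per animal.  Records
may miss traits (RFI/Gain exist only for preselected animals); a missing
pattern is handled exactly by weighting each record with the inverse of the
observed sub-block of R, zero-padded to 3x3.

True (simulated) variance components are used; nothing is estimated.  The
normal equations are solved matrix-free by preconditioned conjugate
gradients.  The default preconditioner is an exact sparse factorization of
the system without the dense genomic correction (a direct solve for pure
BLUP); a block-Jacobi (3x3 per level) fallback is kept as an independent
path.  Solutions are returned for every pedigree animal, records or not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .relationships import HInvOperator
from .traits import TraitParams, build_covariance_matrices, selection_index_from_ebv


@dataclass
class ModelSpec:
    """Variance structure of the three-trait evaluation model."""

    v_g: np.ndarray
    r: np.ndarray
    c2: float = 0.04

    @classmethod
    def from_params(cls, params: TraitParams) -> "ModelSpec":
        v_g, r = build_covariance_matrices(params)
        return cls(v_g=v_g, r=r, c2=params.c2)


@dataclass
class RecordSet:
    """Phenotype records: one row per animal with at least one observed trait.

    ``y`` is (m, 3) with NaN for unobserved traits; ``animal`` and ``dam``
    are positional pedigree indices, ``hatch`` indexes fixed-effect levels
    (one level per round x hatch).  ``dam`` may be -1 where no maternal PE
    equation applies (then the PE column is skipped for that record).
    """

    animal: np.ndarray
    hatch: np.ndarray
    dam: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.hatch = np.asarray(self.hatch, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.animal.size, 3):
            raise ValueError("y must be (n_records, 3)")

    @property
    def m(self) -> int:
        return self.animal.size


@dataclass
class EvaluationResult:
    """Solutions of one evaluation: breeding values plus solver diagnostics."""

    ebv: np.ndarray                 # (n_animals, 3)
    fixed: np.ndarray               # (n_hatch_levels, 3)
    pe: np.ndarray                  # (n_dam_levels,) maternal PE (BW)
    iterations: int
    residual_norm: float

    def index(self, params: TraitParams) -> np.ndarray:
        return selection_index_from_ebv(self.ebv, params)


def _pattern_weights(y: np.ndarray, r: np.ndarray):
    """Group records by observed-trait pattern; return per-record padded R-inverse blocks."""
    obs = ~np.isnan(y)
    if np.any(~obs.any(axis=1)):
        raise ValueError("record with no observed trait")
    codes = obs @ np.array([1, 2, 4])
    w = np.zeros((y.shape[0], 3, 3))
    for code in np.unique(codes):
        mask = codes == code
        pat = np.array([code & 1, code & 2, code & 4], dtype=bool)
        sub = np.linalg.inv(r[np.ix_(pat, pat)])
        block = np.zeros((3, 3))
        block[np.ix_(pat, pat)] = sub
        w[mask] = block
    return w


class _MMEOperator:
    """Matrix-free normal-equations operator and block-Jacobi preconditioner."""

    def __init__(self, records: RecordSet, kinv: HInvOperator, spec: ModelSpec,
                 n_hatch: int):
        self.rec = records
        self.kinv = kinv
        self.n_anim = kinv.n
        self.n_hatch = n_hatch
        self.vg_inv = np.linalg.inv(spec.v_g)
        self.c2 = spec.c2
        m = records.m
        self.w = _pattern_weights(records.y, spec.r)            # (m,3,3)
        self.y0 = np.nan_to_num(records.y, nan=0.0)
        # maternal-PE levels = distinct dams among records
        dams = records.dam
        self.pe_levels = np.unique(dams[dams >= 0])
        self.n_pe = self.pe_levels.size
        pe_map = {d: k for k, d in enumerate(self.pe_levels)}
        self.rec_pe = np.array([pe_map.get(d, -1) for d in dams], dtype=np.int64)
        one = np.ones(m)
        idx = np.arange(m)
        self.X_h = sp.csr_matrix((one, (idx, records.hatch)), shape=(m, n_hatch))
        self.X_a = sp.csr_matrix((one, (idx, records.animal)), shape=(m, self.n_anim))
        has_pe = self.rec_pe >= 0
        self.X_p = sp.csr_matrix((one[has_pe], (idx[has_pe], self.rec_pe[has_pe])),
                                 shape=(m, max(self.n_pe, 1)))
        self.n_unknowns = 3 * (n_hatch + self.n_anim) + self.n_pe
        self._splu = None
        self._build_preconditioner()

    # -- vector packing ----------------------------------------------------
    def split(self, v: np.ndarray):
        nh, na, npe = self.n_hatch, self.n_anim, self.n_pe
        b = v[:3 * nh].reshape(nh, 3)
        u = v[3 * nh:3 * (nh + na)].reshape(na, 3)
        c = v[3 * (nh + na):]
        return b, u, c

    def join(self, b, u, c) -> np.ndarray:
        return np.concatenate([b.ravel(), u.ravel(), c])

    # -- operator ----------------------------------------------------------
    def _data_terms(self, eta: np.ndarray):
        """Given per-record linear predictors, return weighted gradients per effect."""
        wet = np.einsum("mij,mj->mi", self.w, eta)
        gb = self.X_h.T @ wet
        gu = self.X_a.T @ wet
        gc = self.X_p.T @ wet[:, 0] if self.n_pe else np.zeros(0)
        return gb, gu, gc

    def matvec(self, v: np.ndarray) -> np.ndarray:
        b, u, c = self.split(v)
        eta = b[self.rec.hatch] + u[self.rec.animal]
        if self.n_pe:
            pe_contrib = np.where(self.rec_pe >= 0, c[np.maximum(self.rec_pe, 0)], 0.0)
            eta = eta.copy()
            eta[:, 0] += pe_contrib
        gb, gu, gc = self._data_terms(eta)
        gu = gu + self.kinv.matmat(u) @ self.vg_inv
        if self.n_pe:
            gc = gc + c / self.c2
        # pin non-estimable fixed cells (no records for that hatch x trait)
        gb[self.fixed_mask] = b[self.fixed_mask]
        return self.join(gb, gu, gc[:self.n_pe] if self.n_pe else np.zeros(0))

    def rhs(self) -> np.ndarray:
        gb, gu, gc = self._data_terms(self.y0)
        gb[self.fixed_mask] = 0.0
        return self.join(gb, gu, gc[:self.n_pe] if self.n_pe else np.zeros(0))

    # -- preconditioner ----------------------------------------------------
    def _build_preconditioner(self):
        m = self.rec.m
        # per-hatch and per-animal 3x3 blocks from the data part
        hb = np.zeros((self.n_hatch, 3, 3))
        np.add.at(hb, self.rec.hatch, self.w)
        self.fixed_mask = np.abs(np.einsum("hii->hi", hb)) < 1e-14
        hb_d = np.einsum("hii->hi", hb)
        hb = hb.copy()
        d_idx = np.arange(3)
        hb[:, d_idx, d_idx] = np.where(self.fixed_mask, 1.0, hb_d)
        ab = np.zeros((self.n_anim, 3, 3))
        np.add.at(ab, self.rec.animal, self.w)
        ab += np.einsum("n,ij->nij", self.kinv.diagonal(), self.vg_inv)
        self.prec_h = np.linalg.inv(hb)
        self.prec_a = np.linalg.inv(ab)
        if self.n_pe:
            cdiag = np.zeros(self.n_pe)
            has = self.rec_pe >= 0
            np.add.at(cdiag, self.rec_pe[has], self.w[has, 0, 0])
            self.prec_c = 1.0 / (cdiag + 1.0 / self.c2)
        else:
            self.prec_c = np.zeros(0)

    def precond(self, v: np.ndarray) -> np.ndarray:
        if self._splu is not None:
            return self._splu.solve(v)
        b, u, c = self.split(v)
        pb = np.einsum("hij,hj->hi", self.prec_h, b)
        pu = np.einsum("nij,nj->ni", self.prec_a, u)
        pc = self.prec_c * c if self.n_pe else c
        return self.join(pb, pu, pc)

    # -- explicit sparse system (pedigree part only) -----------------------
    def build_sparse(self) -> sp.csc_matrix:
        """Explicit MME coefficient matrix, omitting the dense genomic correction.

        Used as a direct solver for A-based evaluations and as a strong
        preconditioner for H-based ones (the genotyped-block correction is
        the only part left to the Krylov iteration).
        """
        m = self.rec.m
        eye3 = sp.identity(3, format="csr")
        blocks = [sp.kron(self.X_h, eye3), sp.kron(self.X_a, eye3)]
        if self.n_pe:
            has = self.rec_pe >= 0
            rows = 3 * np.flatnonzero(has)          # BW row of each record
            cols = self.rec_pe[has]
            xp = sp.csr_matrix((np.ones(rows.size), (rows, cols)),
                               shape=(3 * m, self.n_pe))
            blocks.append(xp)
        s = sp.hstack(blocks, format="csr")
        w_blk = sp.bsr_matrix((self.w, np.arange(m), np.arange(m + 1)),
                              shape=(3 * m, 3 * m))
        mme = (s.T @ (w_blk @ s)).tocsr()
        nh = self.n_hatch
        prior_u = sp.kron(self.kinv.a_inv, self.vg_inv, format="csr")
        prior_blocks = [sp.csr_matrix((3 * nh, 3 * nh)), prior_u]
        if self.n_pe:
            prior_blocks.append(sp.identity(self.n_pe, format="csr") / self.c2)
        prior = sp.block_diag(prior_blocks, format="csr")
        diag = np.zeros(self.n_unknowns)
        diag[np.flatnonzero(self.fixed_mask.ravel())] = 1.0
        return (mme + prior + sp.diags(diag)).tocsc()

    def factorize(self) -> None:
        from scipy.sparse.linalg import splu
        self._splu = splu(self.build_sparse(),
                          permc_spec="MMD_AT_PLUS_A",
                          options={"SymmetricMode": True})


def _pcg(op: _MMEOperator, tol: float, maxiter: int,
         x0: np.ndarray | None = None):
    b = op.rhs()
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return np.zeros_like(b), 0, 0.0
    if x0 is None:
        x = np.zeros_like(b)
        r = b.copy()
    else:
        x = x0.copy()
        r = b - op.matvec(x)
    z = op.precond(r)
    p = z.copy()
    rz = r @ z
    for it in range(1, maxiter + 1):
        ap = op.matvec(p)
        alpha = rz / (p @ ap)
        x += alpha * p
        r -= alpha * ap
        rnorm = np.linalg.norm(r)
        if rnorm <= tol * bnorm:
            return x, it, rnorm / bnorm
        z = op.precond(r)
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise RuntimeError(f"conjugate gradient did not converge in {maxiter} "
                       f"iterations (relative residual {rnorm / bnorm:.3e})")


def solve_mme(records: RecordSet, kinv: HInvOperator, spec: ModelSpec,
              n_hatch_levels: int, tol: float = 1e-8,
              maxiter: int = 20000,
              warm_start: "EvaluationResult | None" = None,
              precond: str = "splu") -> EvaluationResult:
    """Solve the three-trait mixed-model equations.

    ``kinv`` carries A^-1 (BLUP) or the single-step H^-1 (ssGBLUP) as a
    matrix-free operator over all pedigree animals; solutions are returned
    for every animal, including those without records (e.g. the current,
    not-yet-genotyped cohort at preselection, whose GEBVs flow through
    pedigree links).  ``warm_start`` seeds the conjugate gradient with the
    solutions of an earlier (smaller) evaluation; the convergence criterion
    is unchanged.
    """
    if records.m and (records.animal.max() >= kinv.n):
        raise ValueError("record references an animal outside the pedigree")
    if records.m and (records.hatch.max() >= n_hatch_levels):
        raise ValueError("unknown fixed-effect (hatch) level")
    op = _MMEOperator(records, kinv, spec, n_hatch_levels)
    if precond == "splu":
        op.factorize()
    elif precond != "jacobi":
        raise ValueError("precond must be 'splu' or 'jacobi'")
    x0 = None
    if warm_start is not None:
        b0 = np.zeros((n_hatch_levels, 3))
        b0[:warm_start.fixed.shape[0]] = warm_start.fixed
        u0 = np.zeros((kinv.n, 3))
        u0[:warm_start.ebv.shape[0]] = warm_start.ebv
        c0 = np.zeros(op.n_pe)
        if op.n_pe:
            known = op.pe_levels < warm_start.pe.size
            c0[known] = warm_start.pe[op.pe_levels[known]]
        x0 = op.join(b0, u0, c0)
    x, it, resid = _pcg(op, tol, maxiter, x0)
    b, u, c = op.split(x)
    pe_full = np.zeros(kinv.n)
    if op.n_pe:
        pe_full[op.pe_levels] = c
    return EvaluationResult(ebv=u, fixed=b, pe=pe_full, iterations=it,
                            residual_norm=resid)
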