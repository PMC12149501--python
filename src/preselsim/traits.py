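"""Trait architecture: QTL-effect calibration and multivariate phenotype simulation.

Three traits — body weight (BW), residual feed intake (RFI) and body-weight
gain (Gain) — with phenotypic variance fixed at 1, so the genetic variance
of each trait equals its heritability.  Genetic covariances are
r_g * sqrt(h2_i * h2_j); residual covariances are
r_e * sqrt((1 - h2_i - c2*[i=BW]) * (1 - h2_j - c2*[j=BW])), with c2 the
maternal permanent-environment fraction (BW only).  QTL effects are drawn
iid N(0,1) per trait and linearly recalibrated so that the empirical
covariance of base-population true breeding values equals V_g exactly;
they are then frozen for the whole breeding scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRAITS = ("bw", "rfi", "gain")
BW, RFI, GAIN = 0, 1, 2


@dataclass
class TraitParams:
    """Heritabilities, correlations and index weights of the three-trait breeding goal."""

    h2: np.ndarray = field(default_factory=lambda: np.array([0.18, 0.19, 0.17]))
    rg: np.ndarray = field(default_factory=lambda: np.array(
        [[1.00, 0.11, 0.15],
         [0.11, 1.00, 0.14],
         [0.15, 0.14, 1.00]]))
    re: np.ndarray = field(default_factory=lambda: np.array(
        [[1.00, -0.08, 0.07],
         [-0.08, 1.00, -0.04],
         [0.07, -0.04, 1.00]]))
    c2: float = 0.04                       # maternal PE fraction, BW only
    hatch_var_frac: np.ndarray = field(default_factory=lambda: np.full(3, 0.02))
    index_weights: np.ndarray = field(default_factory=lambda: np.array([1.0, -0.82, 0.50]))

    def __post_init__(self):
        self.h2 = np.asarray(self.h2, dtype=float)
        self.rg = np.asarray(self.rg, dtype=float)
        self.re = np.asarray(self.re, dtype=float)
        self.hatch_var_frac = np.asarray(self.hatch_var_frac, dtype=float)
        self.index_weights = np.asarray(self.index_weights, dtype=float)
        for name, m in (("rg", self.rg), ("re", self.re)):
            if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 1.0):
                raise ValueError(f"{name} must be symmetric with unit diagonal")
        if self.c2 < 0 or self.h2[BW] + self.c2 >= 1.0 or np.any(self.h2 >= 1.0) \
                or np.any(self.h2 <= 0.0):
            raise ValueError("need 0 < h2 < 1 and h2_BW + c2 < 1")

    @property
    def genetic_sd(self) -> np.ndarray:
        return np.sqrt(self.h2)

    @property
    def residual_var(self) -> np.ndarray:
        ev = 1.0 - self.h2.copy()
        ev = ev.copy()
        ev[BW] -= self.c2
        return ev


def build_covariance_matrices(params: TraitParams) -> tuple[np.ndarray, np.ndarray]:
    """Genetic (V_g) and residual (R) 3x3 covariance matrices from correlations.

    V_g has h2 on the diagonal; R has 1 - h2 (- c2 for BW).  Raises if
    either matrix is not positive definite.
    """
    sg = np.sqrt(params.h2)
    v_g = params.rg * np.outer(sg, sg)
    se = np.sqrt(params.residual_var)
    r = params.re * np.outer(se, se)
    for name, m in (("V_g", v_g), ("R", r)):
        w = np.linalg.eigvalsh(m)
        if w[0] <= 0:
            raise ValueError(f"{name} not positive definite (min eigenvalue {w[0]:.3e})")
    return v_g, r


@dataclass
class QTLEffects:
    """Calibrated allele-substitution effects and the genotype centering they assume."""

    effects: np.ndarray      # (n_qtl, 3)
    centering: np.ndarray    # (n_qtl,) mean base allele count per QTL

    @property
    def n_qtl(self) -> int:
        return self.effects.shape[0]


def _sym_sqrt(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def calibrate_qtl_effects(base_qtl_genotypes: np.ndarray, v_g: np.ndarray,
                          seed) -> QTLEffects:
    """Draw N(0,1) effects and recolor them so base TBVs have mean 0 and covariance V_g.

    The empirical (population, ddof=0) covariance of base TBVs equals V_g to
    numerical precision by construction; effects are frozen afterwards.
    """
    counts = np.asarray(base_qtl_genotypes, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a (n_individuals, n_qtl>=2) genotype matrix")
    rng = np.random.default_rng(seed)
    n_qtl = counts.shape[1]
    raw = rng.standard_normal((n_qtl, 3))
    centering = counts.mean(axis=0)
    z = counts - centering
    if np.allclose(v_g, 0.0):
        return QTLEffects(np.zeros((n_qtl, 3)), centering)
    tbv_raw = z @ raw
    s = np.cov(tbv_raw, rowvar=False, ddof=0)
    w = np.linalg.eigvalsh(s)
    if w[0] <= 1e-12 * max(w[-1], 1.0):
        raise ValueError("empirical TBV covariance is singular; "
                         "QTL set carries too little variation")
    s_inv_half = np.linalg.inv(_sym_sqrt(s))
    transform = s_inv_half @ _sym_sqrt(v_g)
    return QTLEffects(raw @ transform, centering)


def compute_tbv(qtl_genotypes: np.ndarray, effects: QTLEffects) -> np.ndarray:
    """TBV_t = sum_q (count_q - centering_q) * effect_{q,t}; accepts one animal or a matrix."""
    counts = np.asarray(qtl_genotypes, dtype=float)
    single = counts.ndim == 1
    if single:
        counts = counts[None, :]
    if counts.shape[1] != effects.n_qtl:
        raise ValueError(f"genotypes have {counts.shape[1]} QTL, "
                         f"effects have {effects.n_qtl}")
    tbv = (counts - effects.centering) @ effects.effects
    return tbv[0] if single else tbv


def draw_hatch_effects(n_hatches: int, params: TraitParams,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-hatch, per-trait fixed effects ~ N(0, hatch_var_frac) (on top of unit variance)."""
    return rng.standard_normal((n_hatches, 3)) * np.sqrt(params.hatch_var_frac)


def draw_maternal_pe(n_dams: int, params: TraitParams,
                     rng: np.random.Generator) -> np.ndarray:
    """One permanent-environment value per dam ~ N(0, c2), applied to all her chicks' BW."""
    return rng.standard_normal(n_dams) * np.sqrt(params.c2)


def simulate_phenotypes(tbv: np.ndarray, hatch_of: np.ndarray,
                        hatch_effects: np.ndarray, dam_pe: np.ndarray,
                        params: TraitParams, rng: np.random.Generator,
                        r_matrix: np.ndarray | None = None,
                        group_effect: np.ndarray | None = None) -> np.ndarray:
    """Phenotypes y = x + b_hatch + g + c_dam (BW only) + e, e ~ MVN(0, R) per animal.

    ``dam_pe`` is the per-animal maternal PE contribution (already looked up
    per dam).  ``group_effect`` is the optional contemporary-group shift x
    (default 0).  Returns an (n, 3) array; the caller decides which entries
    become records.
    """
    tbv = np.asarray(tbv, dtype=float)
    n = tbv.shape[0]
    if r_matrix is None:
        _, r_matrix = build_covariance_matrices(params)
    root = _sym_sqrt(r_matrix)          # PSD square root; allows degenerate R
    e = rng.standard_normal((n, 3)) @ root.T
    y = tbv + hatch_effects[hatch_of] + e
    y[:, BW] += np.asarray(dam_pe, dtype=float)
    if group_effect is not None:
        y += group_effect
    return y


def selection_index_from_ebv(ebv: np.ndarray, params: TraitParams) -> np.ndarray:
    """Standardized index: w . (EBV_t / sigma_g,t) with weights (+1, -0.82, +0.50)."""
    ebv = np.asarray(ebv, dtype=float)
    return (ebv / params.genetic_sd) @ params.index_weights
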