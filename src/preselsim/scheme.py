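"""The eight-stage broiler selection round and its 40-round orchestration.

Each selection round: 9000 chicks hatch in 7 hatches with an exact 50:50
sex ratio (stage 0); body weight is recorded for all and a fraction of each
sex is preselected on phenotype (P), a BLUP index (B) or an ssGBLUP index
(G) (stage 1); the preselected are phenotyped for RFI/Gain and genotyped
(stage 2); after rearing (stage 3), 10 males and 150 females are selected
on the final ssGBLUP index (stage 4); each sire is mated to 15 dams and the
cohort reproduces over the next four rounds (stages 5-8, with declining
litter sizes 16, 16, 15, 13 chicks per dam), after which it retires.  A
round's 9000 chicks therefore come from four overlapping parent cohorts.

Early rounds are bootstrapped by a single randomly chosen base parent set
(10 males, 150 females) standing in for all four cohorts until the first
selected cohorts have matured through their reproductive stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import traits as tr
from .evaluation import EvaluationResult, ModelSpec, RecordSet, solve_mme
from .genome import GenomeMap, Population, _gamete
from .relationships import HInvOperator, PedigreeAccumulator, blend_and_invert

CRITERIA = ("P", "B", "G")


@dataclass
class SchemeConfig:
    """Counts and intensities of one breeding scheme."""

    chicks_per_round: int = 9000
    hatches_per_round: int = 7
    presel_male_frac: float = 0.10
    presel_female_frac: float = 0.30
    criterion: str = "G"
    n_sires: int = 10
    n_dams: int = 150
    mates_per_sire: int = 15
    chicks_per_dam_by_stage: tuple = (16, 16, 15, 13)
    n_rounds: int = 40
    g_blend_weight: float = 0.95
    g_maf_min: float = 0.05
    solver_tol: float = 1e-8

    def __post_init__(self):
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if self.n_sires * self.mates_per_sire != self.n_dams:
            raise ValueError("n_sires * mates_per_sire must equal n_dams")
        if self.n_dams * sum(self.chicks_per_dam_by_stage) != self.chicks_per_round:
            raise ValueError("n_dams * sum(stage litter sizes) must equal chicks_per_round")
        if self.chicks_per_round % 2:
            raise ValueError("chicks_per_round must be even (50:50 sex ratio)")
        for frac in (self.presel_male_frac, self.presel_female_frac):
            if not (0.0 < frac <= 1.0):
                raise ValueError("preselection fractions must be in (0, 1]")

    @property
    def n_reproductive_stages(self) -> int:
        return len(self.chicks_per_dam_by_stage)


@dataclass
class Cohort:
    """A selected breeder cohort: its dams and each dam's fixed sire."""

    dams: np.ndarray            # positional ids, length n_dams
    sire_of_dam: np.ndarray     # positional ids, aligned with dams


@dataclass
class SimulationLog:
    """Per-round candidate tables plus pedigree; the substrate for all metrics."""

    config: SchemeConfig
    rounds: list = field(default_factory=list)        # one DataFrame per round
    sire: np.ndarray | None = None
    dam: np.ndarray | None = None
    sex: np.ndarray | None = None
    n_markers_used: int = 0
    diagnostics: list = field(default_factory=list)

    def round_frame(self, round_no: int) -> pd.DataFrame:
        return self.rounds[round_no - 1]

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


# ---------------------------------------------------------------------------
# stage operations

def preselect(ids: np.ndarray, sex: np.ndarray, scores: np.ndarray,
              male_frac: float, female_frac: float) -> np.ndarray:
    """Within-sex truncation: top ceil(frac * n) by score, ties broken by ascending id."""
    ids = np.asarray(ids)
    scores = np.asarray(scores, dtype=float)
    if np.any(np.isnan(scores)):
        raise ValueError("missing preselection scores")
    out = []
    for is_male, frac in ((True, male_frac), (False, female_frac)):
        mask = sex == is_male
        sub_ids, sub_sc = ids[mask], scores[mask]
        k = int(np.ceil(frac * sub_ids.size))
        order = np.lexsort((sub_ids, -sub_sc))
        out.append(sub_ids[order[:k]])
    return np.concatenate(out)


def final_select(ids: np.ndarray, sex: np.ndarray, index: np.ndarray,
                 n_sires: int, n_dams: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncation on the final index within sex; returns (sires, dams)."""
    ids = np.asarray(ids)
    index = np.asarray(index, dtype=float)
    if np.any(np.isnan(index)):
        raise ValueError("missing final-selection index")
    picks = []
    for is_male, quota in ((True, n_sires), (False, n_dams)):
        mask = sex == is_male
        sub_ids, sub_ix = ids[mask], index[mask]
        if sub_ids.size < quota:
            raise ValueError(f"quota infeasible: need {quota} "
                             f"{'males' if is_male else 'females'}, have {sub_ids.size}")
        order = np.lexsort((sub_ids, -sub_ix))
        picks.append(sub_ids[order[:quota]])
    return picks[0], picks[1]


def plan_matings(cohorts: list[Cohort], config: SchemeConfig
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-chick (sire, dam, hatch) for one round from the four active cohorts.

    Stage litter sizes follow cohort age (youngest cohort first in the
    list).  Hatches are filled round-robin across a dam-major interleaving,
    so hatch sizes differ by at most one and full-sib families are spread
    over hatches.
    """
    if len(cohorts) != config.n_reproductive_stages:
        raise ValueError(f"need {config.n_reproductive_stages} active cohorts, "
                         f"got {len(cohorts)}")
    sires, dams = [], []
    # interleave: one chick per dam per sweep, cycling dams across all cohorts
    per_dam = []
    for stage, cohort in enumerate(cohorts):
        if cohort.dams.size != config.n_dams:
            raise ValueError("cohort size does not match n_dams")
        k = config.chicks_per_dam_by_stage[stage]
        per_dam.append((cohort, k))
    max_k = max(k for _, k in per_dam)
    for sweep in range(max_k):
        for cohort, k in per_dam:
            if sweep < k:
                dams.append(cohort.dams)
                sires.append(cohort.sire_of_dam)
    dam_arr = np.concatenate(dams)
    sire_arr = np.concatenate(sires)
    if dam_arr.size != config.chicks_per_round:
        raise ValueError("cohort litter sizes do not add up to chicks_per_round")
    hatch = np.arange(dam_arr.size) % config.hatches_per_round
    return sire_arr, dam_arr, hatch


@dataclass
class ChickCohort:
    """One round's hatched chicks before any selection."""

    sire: np.ndarray
    dam: np.ndarray
    hatch: np.ndarray
    sex: np.ndarray                      # True = male, exact 50:50
    haplotypes: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.sire.size


def mate_and_hatch(cohorts: list[Cohort], config: SchemeConfig,
                   rng: np.random.Generator, haplotypes: np.ndarray | None = None,
                   gmap: GenomeMap | None = None,
                   mutation_rate: float = 0.0) -> ChickCohort:
    """Produce one round of chicks from the four active cohorts via meiosis.

    ``haplotypes`` is the population haplotype store indexed by the cohort
    ids; when omitted only the pedigree/hatch/sex bookkeeping is produced.
    """
    sire_arr, dam_arr, hatch = plan_matings(cohorts, config)
    n = sire_arr.size
    chick_haps = None
    if haplotypes is not None:
        slices = gmap.chrom_slices()
        chick_haps = np.empty((n, 2, gmap.n_loci), dtype=np.uint8)
        for i, (s, d) in enumerate(zip(sire_arr, dam_arr)):
            chick_haps[i, 0] = _gamete(haplotypes[s], gmap, rng, mutation_rate, slices)
            chick_haps[i, 1] = _gamete(haplotypes[d], gmap, rng, mutation_rate, slices)
    sex = np.zeros(n, dtype=bool)
    sex[rng.permutation(n)[:n // 2]] = True
    return ChickCohort(sire_arr, dam_arr, hatch, sex, chick_haps)


def assign_mates(sires: np.ndarray, dams: np.ndarray, config: SchemeConfig,
                 rng: np.random.Generator) -> Cohort:
    """Random permutation of the dams into n_sires groups of mates_per_sire, fixed for life."""
    dams = np.asarray(dams)
    perm = rng.permutation(dams)
    sire_of_dam = np.repeat(np.asarray(sires), config.mates_per_sire)
    return Cohort(dams=perm, sire_of_dam=sire_of_dam)


# ---------------------------------------------------------------------------
# the full scheme

class _State:
    """Growing population state across rounds."""

    def __init__(self, base: Population, gmap: GenomeMap, params: tr.TraitParams,
                 effects, capacity: int):
        n0 = base.n
        self.gmap = gmap
        self.params = params
        self.effects = effects
        self.haps = np.empty((capacity, 2, gmap.n_loci), dtype=np.uint8)
        self.haps[:n0] = base.haplotypes
        self.sex = np.zeros(capacity, dtype=bool)
        self.sex[:n0] = base.sex
        self.birth_round = np.zeros(capacity, dtype=np.int64)
        self.hatch_level = np.full(capacity, -1, dtype=np.int64)
        self.genotyped = np.zeros(capacity, dtype=bool)
        self.tbv = np.zeros((capacity, 3))
        self.y = np.full((capacity, 3), np.nan)          # recorded phenotypes
        self.dam_pe = np.zeros(capacity)                 # maternal PE, drawn lazily
        self.pe_drawn = np.zeros(capacity, dtype=bool)
        self.ped = PedigreeAccumulator(n0, capacity)
        self.n = n0
        qtl = gmap.qtl_idx
        self.tbv[:n0] = tr.compute_tbv(base.allele_counts(qtl), effects)

    def ensure_pe(self, dams: np.ndarray, rng: np.random.Generator) -> None:
        dams = np.unique(dams)
        new = dams[~self.pe_drawn[dams]]
        if new.size:
            self.dam_pe[new] = tr.draw_maternal_pe(new.size, self.params, rng)
            self.pe_drawn[new] = True


def _border_inverse(minv: np.ndarray, b: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Inverse of [[M, b], [b', d]] from M^-1 via the Schur complement (SPD)."""
    mb = minv @ b
    s = d - b.T @ mb
    s = 0.5 * (s + s.T)
    s_inv = np.linalg.inv(s)
    s_inv = 0.5 * (s_inv + s_inv.T)
    n, k = mb.shape
    out = np.empty((n + k, n + k))
    cross = mb @ s_inv
    out[:n, :n] = minv + cross @ mb.T
    out[:n, n:] = -cross
    out[n:, :n] = -cross.T
    out[n:, n:] = s_inv
    return out


class _GCache:
    """Incrementally grown single-step genotyped block.

    Keeps the centered marker matrix Z, and the inverses of A22 and of the
    blended G* = w G + (1-w) A22 over the genotyped animals.  Pedigree
    relationships and genomic relationships among already-genotyped animals
    never change as the population grows, so both inverses are extended by
    a bordered (Schur-complement) update per cohort instead of a full
    re-inversion; the H^-1 correction G*^-1 - A22^-1 is refreshed after
    each extension.
    """

    def __init__(self, base_freq: np.ndarray, marker_idx: np.ndarray,
                 blend_weight: float = 0.95):
        p = base_freq[marker_idx]
        seg = (p > 0.0) & (p < 1.0)
        self.markers = marker_idx[seg]
        self.p = p[seg]
        if self.markers.size == 0:
            raise ValueError("all markers are monomorphic in the base population")
        self.denom = 2.0 * np.sum(self.p * (1.0 - self.p))
        self.w = blend_weight
        self.ids = np.zeros(0, dtype=np.int64)
        self.z = np.zeros((0, self.markers.size))
        self.a22_inv = np.zeros((0, 0))
        self.g_star_inv = np.zeros((0, 0))
        self.correction = np.zeros((0, 0))

    @property
    def n_markers(self) -> int:
        return self.markers.size

    def add(self, ids: np.ndarray, counts: np.ndarray,
            ped: PedigreeAccumulator) -> None:
        z_new = counts.astype(float) - 2.0 * self.p
        w = self.w
        a = ped.a
        a22_diag = a[np.ix_(ids, ids)]
        g_diag = z_new @ z_new.T / self.denom
        if self.ids.size == 0:
            _, self.g_star_inv, self.a22_inv = blend_and_invert(
                g_diag, a22_diag, w)
        else:
            a22_cross = a[np.ix_(self.ids, ids)]
            g_cross = self.z @ z_new.T / self.denom
            self.a22_inv = _border_inverse(self.a22_inv, a22_cross, a22_diag)
            self.g_star_inv = _border_inverse(
                self.g_star_inv,
                w * g_cross + (1 - w) * a22_cross,
                w * g_diag + (1 - w) * a22_diag)
        self.z = np.vstack([self.z, z_new])
        self.ids = np.concatenate([self.ids, ids])
        self.correction = self.g_star_inv - self.a22_inv


def _evaluate(state: _State, spec: ModelSpec, config: SchemeConfig,
              n_hatch_levels: int, gcache: _GCache | None,
              a_inv=None, warm_start=None) -> EvaluationResult:
    """One (ss)GBLUP/BLUP evaluation over all animals and records to date."""
    rec_mask = ~np.isnan(state.y[:state.n]).all(axis=1)
    rec_idx = np.flatnonzero(rec_mask)
    records = RecordSet(animal=rec_idx,
                        hatch=state.hatch_level[rec_idx],
                        dam=state.ped.dam[rec_idx],
                        y=state.y[rec_idx])
    if a_inv is None:
        a_inv = state.ped.a_inv()
    if gcache is None or gcache.ids.size == 0:
        kinv = HInvOperator(a_inv)
    else:
        kinv = HInvOperator(a_inv, genotyped=gcache.ids,
                            correction=gcache.correction)
    return solve_mme(records, kinv, spec, n_hatch_levels,
                     tol=config.solver_tol, warm_start=warm_start)


def run_scheme(base: Population, gmap: GenomeMap, params: tr.TraitParams,
               effects, config: SchemeConfig, seed,
               mutation_rate: float = 0.0) -> SimulationLog:
    """Run the configured number of selection rounds; returns the full log."""
    rng = np.random.default_rng(seed)
    spec = ModelSpec.from_params(params)
    n_males_base = int(base.sex.sum())
    n_females_base = int((~base.sex).sum())
    if n_males_base < config.n_sires or n_females_base < config.n_dams:
        raise ValueError("base population too small for the bootstrap parent set")

    capacity = base.n + config.chicks_per_round * config.n_rounds
    state = _State(base, gmap, params, effects, capacity)
    gcache = _GCache(gmap.base_allele_freq, gmap.marker_idx,
                     config.g_blend_weight)
    log = SimulationLog(config=config, n_markers_used=gcache.n_markers)

    # bootstrap: one random base parent set stands in for all four cohorts
    males = np.flatnonzero(base.sex)
    females = np.flatnonzero(~base.sex)
    boot_sires = rng.choice(males, size=config.n_sires, replace=False)
    boot_dams = rng.choice(females, size=config.n_dams, replace=False)
    boot = assign_mates(boot_sires, boot_dams, config, rng)
    cohorts: list[Cohort] = [boot] * config.n_reproductive_stages

    qtl = gmap.qtl_idx
    prev_final = None      # warm starts across rounds (initial guesses only;
    prev_presel = None     # the convergence tolerance is unchanged)

    for round_no in range(1, config.n_rounds + 1):
        # stage 0: mate and hatch
        chicks = mate_and_hatch(cohorts, config, rng, haplotypes=state.haps,
                                gmap=gmap, mutation_rate=mutation_rate)
        sire_arr, dam_arr, hatch, sex = chicks.sire, chicks.dam, chicks.hatch, chicks.sex
        state.ensure_pe(dam_arr, rng)
        idx = state.ped.append_cohort(sire_arr, dam_arr)
        state.haps[idx] = chicks.haplotypes
        state.n = state.ped.n
        state.sex[idx] = sex
        state.birth_round[idx] = round_no
        level0 = (round_no - 1) * config.hatches_per_round
        state.hatch_level[idx] = level0 + hatch
        counts = state.haps[idx][:, :, qtl].sum(axis=1, dtype=np.int64)
        state.tbv[idx] = tr.compute_tbv(counts, effects)

        # stage 1: body-weight recording
        hatch_eff = tr.draw_hatch_effects(config.hatches_per_round, params, rng)
        pheno = tr.simulate_phenotypes(state.tbv[idx], hatch, hatch_eff,
                                       state.dam_pe[dam_arr], params, rng,
                                       r_matrix=spec.r)
        state.y[idx, tr.BW] = pheno[:, tr.BW]
        n_hatch_levels = round_no * config.hatches_per_round

        # preselection scores
        a_inv = state.ped.a_inv()
        presel_result = None
        if config.criterion == "P":
            scores = pheno[:, tr.BW]
        else:
            presel_result = _evaluate(state, spec, config, n_hatch_levels,
                                      gcache if config.criterion == "G" else None,
                                      a_inv=a_inv,
                                      warm_start=prev_final
                                      if config.criterion == "G" else prev_presel)
            scores = presel_result.index(params)[idx]
            prev_presel = presel_result
        preselected = preselect(idx, sex, scores, config.presel_male_frac,
                                config.presel_female_frac)

        # stage 2: phenotype RFI/Gain and genotype the preselected
        local = np.searchsorted(idx, preselected)       # idx is contiguous ascending
        state.y[preselected, tr.RFI] = pheno[local, tr.RFI]
        state.y[preselected, tr.GAIN] = pheno[local, tr.GAIN]
        state.genotyped[preselected] = True
        gcache.add(preselected,
                   state.haps[preselected][:, :, gcache.markers].sum(axis=1,
                                                                    dtype=np.int64),
                   state.ped)

        # stage 4: final selection on the ssGBLUP index
        final_result = _evaluate(state, spec, config, n_hatch_levels, gcache,
                                 a_inv=a_inv,
                                 warm_start=presel_result
                                 if config.criterion == "G" else prev_final)
        prev_final = final_result
        final_index = final_result.index(params)
        sel_sires, sel_dams = final_select(preselected, state.sex[preselected],
                                           final_index[preselected],
                                           config.n_sires, config.n_dams)
        selected = np.concatenate([sel_sires, sel_dams])

        # log the round
        frame = pd.DataFrame({
            "id": idx, "sex": np.where(sex, "M", "F"),
            "sire": sire_arr, "dam": dam_arr, "hatch": hatch,
            "tbv_bw": state.tbv[idx, 0], "tbv_rfi": state.tbv[idx, 1],
            "tbv_gain": state.tbv[idx, 2],
            "bw_phenotype": pheno[:, tr.BW],
            "preselected": np.isin(idx, preselected),
            "selected": np.isin(idx, selected),
        })
        if presel_result is not None:
            pre_ebv = presel_result.ebv[idx]
            frame["presel_ebv_bw"] = pre_ebv[:, 0]
            frame["presel_ebv_rfi"] = pre_ebv[:, 1]
            frame["presel_ebv_gain"] = pre_ebv[:, 2]
            frame["presel_index"] = presel_result.index(params)[idx]
        fin = final_result.ebv[idx]
        frame["final_gebv_bw"] = fin[:, 0]
        frame["final_gebv_rfi"] = fin[:, 1]
        frame["final_gebv_gain"] = fin[:, 2]
        frame["final_index"] = final_index[idx]
        log.rounds.append(frame)
        log.diagnostics.append({
            "round": round_no,
            "n_genotyped": int(gcache.ids.size),
            "presel_iterations": presel_result.iterations if presel_result else 0,
            "final_iterations": final_result.iterations,
        })

        # stages 5-8 bookkeeping: new cohort in, oldest out
        cohorts = [assign_mates(sel_sires, sel_dams, config, rng)] + cohorts[:-1]

    log.sire = state.ped.sire[:state.n].copy()
    log.dam = state.ped.dam[:state.n].copy()
    log.sex = state.sex[:state.n].copy()
    return log
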