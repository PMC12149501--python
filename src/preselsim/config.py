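"""Experiment configuration, profiles, orchestration and persistence.

A profile bundles the genome/founder parameters with the breeding-scheme
counts.  The ``full`` profile encodes the full-scale program (28-chromosome
2930 cM genome, 1000-generation history of 1000 birds, 52k markers + 3k
QTL, 9000 chicks per round over 40 rounds); the ``desk`` profile is a
self-consistent scale-down used for testing and desk-top experiments.
Strategies are named criterion + male-percentage: P10/B10/G10 (10% males,
30% females), P15/B15/G15 (15:45%), P20/B20/G20 (20:60%).

Replicates of one experiment share the expensive mutation-drift historical
pool and draw independent founder expansions, locus panels, base
populations, QTL effects and scheme randomness from per-replicate seed
streams; a fixed master seed makes every output bit-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import genome as gn
from . import traits as tr
from .scheme import SchemeConfig, SimulationLog, run_scheme

STRATEGIES = ("P10", "B10", "G10", "P15", "B15", "G15", "P20", "B20", "G20")
_INTENSITY = {"10": (0.10, 0.30), "15": (0.15, 0.45), "20": (0.20, 0.60)}

# 28 chromosome lengths (cM), 45-484 cM, total 2930 cM
FULL_SCALE_CHROM_LENGTHS = (484, 330, 250, 210, 175, 150, 130, 112, 98, 86,
                            76, 68, 61, 56, 52, 49, 47, 46, 45, 45, 45, 45,
                            45, 45, 45, 45, 45, 45)


def decode_strategy(strategy: str) -> tuple[str, float, float]:
    """'G10' -> ('G', 0.10, 0.30); raises on anything not in the strategy grid."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    crit, pct = strategy[0], strategy[1:]
    male, female = _INTENSITY[pct]
    return crit, male, female


@dataclass
class GenomeProfile:
    """Genome and founder-population parameters of one profile."""

    chrom_lengths: tuple
    n_loci: int
    hist_n: int
    hist_generations: int
    mutation_rate: float
    expansion_males: int
    expansion_females: int
    expansion_generations: int
    offspring_per_mating: int
    n_markers: int
    n_qtl: int
    maf_min: float
    base_males: int
    base_females: int


@dataclass
class Profile:
    name: str
    genome: GenomeProfile
    scheme: SchemeConfig
    n_replicates: int


def full_profile(criterion: str = "G", male_frac: float = 0.10,
                 female_frac: float = 0.30) -> Profile:
    """The full-scale breeding-program configuration."""
    return Profile(
        name="full",
        genome=GenomeProfile(
            chrom_lengths=FULL_SCALE_CHROM_LENGTHS, n_loci=66000,
            hist_n=1000, hist_generations=1000, mutation_rate=2.5e-8,
            expansion_males=50, expansion_females=50,
            expansion_generations=7, offspring_per_mating=10,
            n_markers=52000, n_qtl=3000, maf_min=0.05,
            base_males=320, base_females=4800),
        scheme=SchemeConfig(
            chicks_per_round=9000, hatches_per_round=7,
            presel_male_frac=male_frac, presel_female_frac=female_frac,
            criterion=criterion, n_sires=10, n_dams=150, mates_per_sire=15,
            chicks_per_dam_by_stage=(16, 16, 15, 13), n_rounds=40),
        n_replicates=15)


def desk_profile(criterion: str = "G", male_frac: float = 0.10,
                 female_frac: float = 0.30, n_rounds: int = 10) -> Profile:
    """Scaled-down configuration preserving the scheme's structure."""
    return Profile(
        name="desk",
        genome=GenomeProfile(
            chrom_lengths=(120, 100, 80), n_loci=3200,
            hist_n=200, hist_generations=200, mutation_rate=2.5e-8,
            expansion_males=25, expansion_females=25,
            expansion_generations=7, offspring_per_mating=10,
            n_markers=2000, n_qtl=200, maf_min=0.05,
            base_males=40, base_females=240),
        scheme=SchemeConfig(
            chicks_per_round=600, hatches_per_round=7,
            presel_male_frac=male_frac, presel_female_frac=female_frac,
            criterion=criterion, n_sires=4, n_dams=40, mates_per_sire=10,
            chicks_per_dam_by_stage=(4, 4, 4, 3), n_rounds=n_rounds),
        n_replicates=10)


_PROFILES = {"full": full_profile, "desk": desk_profile}


def get_profile(name: str, strategy: str = "G10", n_rounds: int | None = None
                ) -> Profile:
    if name not in _PROFILES:
        raise ValueError(f"unknown profile {name!r}")
    crit, male, female = decode_strategy(strategy)
    kwargs = {"criterion": crit, "male_frac": male, "female_frac": female}
    if name == "desk" and n_rounds is not None:
        kwargs["n_rounds"] = n_rounds
    return _PROFILES[name](**kwargs)


# ---------------------------------------------------------------------------
# pipeline stages

def build_historical_pool(gp: GenomeProfile, seed) -> gn.HaplotypePool:
    """Neutral mutation-drift pool shared by all replicates of an experiment."""
    rng = np.random.default_rng(seed)
    gmap = gn.random_genome_map(gp.chrom_lengths, gp.n_loci, rng)
    return gn.simulate_founder_pool(gmap, gp.hist_n, gp.hist_generations,
                                    gp.mutation_rate, rng)


@dataclass
class ReplicateSetup:
    """Founders, panels, base population and QTL effects of one replicate."""

    base: gn.Population
    gmap: gn.GenomeMap
    params: tr.TraitParams
    effects: tr.QTLEffects


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def setup_replicate(pool: gn.HaplotypePool, gp: GenomeProfile,
                    params: tr.TraitParams, seed) -> ReplicateSetup:
    ss = _as_seedseq(seed)
    s_exp, s_panel, s_base, s_qtl = ss.spawn(4)
    founders = gn.expand_founders(pool, gp.expansion_males, gp.expansion_females,
                                  gp.expansion_generations,
                                  gp.offspring_per_mating, s_exp)
    panel_map = gn.select_locus_panels(founders, gp.maf_min, gp.n_markers,
                                       gp.n_qtl, s_panel)
    base, gmap = gn.make_base_population(founders, panel_map, gp.base_males,
                                         gp.base_females, s_base)
    v_g, _ = tr.build_covariance_matrices(params)
    effects = tr.calibrate_qtl_effects(base.allele_counts(gmap.qtl_idx), v_g, s_qtl)
    return ReplicateSetup(base=base, gmap=gmap, params=params, effects=effects)


def run_replicate(pool: gn.HaplotypePool, profile: Profile,
                  params: tr.TraitParams, seed) -> SimulationLog:
    ss = _as_seedseq(seed)
    s_setup, s_scheme = ss.spawn(2)
    setup = setup_replicate(pool, profile.genome, params, s_setup)
    return run_scheme(setup.base, setup.gmap, params, setup.effects,
                      profile.scheme, s_scheme,
                      mutation_rate=profile.genome.mutation_rate)


def replicate_seed(master_seed: int, replicate: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master_seed),
                                  spawn_key=(int(replicate),))


def run_experiment(profile_name: str, strategy: str, n_replicates: int,
                   master_seed: int, out_dir: str | Path | None = None,
                   n_rounds: int | None = None,
                   pool: gn.HaplotypePool | None = None,
                   params: tr.TraitParams | None = None,
                   profile: "Profile | None" = None) -> list[SimulationLog]:
    """Run n_replicates independent replicates of one strategy; optionally persist.

    A pre-built historical ``pool`` may be passed so several strategies can
    share it (common random numbers across strategies come from passing the
    same master seed); a fully-built ``profile`` (e.g. from a config file)
    bypasses the named-profile lookup.
    """
    if profile is None:
        profile = get_profile(profile_name, strategy, n_rounds)
    params = params or tr.TraitParams()
    if pool is None:
        pool = build_historical_pool(profile.genome,
                                     np.random.SeedSequence(entropy=int(master_seed),
                                                            spawn_key=(999999,)))
    logs = []
    for rep in range(n_replicates):
        logs.append(run_replicate(pool, profile, params,
                                  replicate_seed(master_seed, rep)))
    if out_dir is not None:
        persist_logs(logs, Path(out_dir), profile, strategy, master_seed)
    return logs


# ---------------------------------------------------------------------------
# persistence

def persist_logs(logs: list[SimulationLog], out_dir: Path, profile: Profile,
                 strategy: str, master_seed: int) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"profile": profile.name, "strategy": strategy,
                "master_seed": int(master_seed),
                "n_replicates": len(logs),
                "scheme": dataclasses.asdict(profile.scheme),
                "replicates": []}
    for rep, log in enumerate(logs):
        rep_dir = out_dir / f"replicate_{rep:02d}"
        rep_dir.mkdir(exist_ok=True)
        hasher = hashlib.sha256()
        for rnd, frame in enumerate(log.rounds, start=1):
            path = rep_dir / f"round_{rnd:03d}.tsv"
            frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
            hasher.update(path.read_bytes())
        ped = rep_dir / "pedigree.tsv"
        with ped.open("w") as fh:
            fh.write("id\tsire\tdam\tsex\n")
            for i in range(log.sire.size):
                fh.write(f"{i}\t{log.sire[i]}\t{log.dam[i]}\t"
                         f"{'M' if log.sex[i] else 'F'}\n")
        hasher.update(ped.read_bytes())
        manifest["replicates"].append({"dir": rep_dir.name,
                                       "n_rounds": log.n_rounds,
                                       "n_markers_used": log.n_markers_used,
                                       "sha256": hasher.hexdigest()})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_config(path: str | Path) -> dict:
    """Plain-text (YAML) experiment configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def profile_from_config(cfg: dict) -> Profile:
    """Build a Profile from a config dict: a named profile plus field overrides.

    Recognized keys: ``profile`` (full/desk), ``strategy``, ``n_rounds``,
    ``n_replicates``, and nested ``genome`` / ``scheme`` mappings whose
    entries override individual profile fields; unknown field names raise.
    """
    prof = get_profile(cfg.get("profile", "desk"), cfg.get("strategy", "G10"),
                       cfg.get("n_rounds"))
    if "n_replicates" in cfg:
        prof.n_replicates = int(cfg["n_replicates"])
    for section, target in (("genome", prof.genome), ("scheme", prof.scheme)):
        for key, val in (cfg.get(section) or {}).items():
            if not hasattr(target, key):
                raise ValueError(f"unknown {section} field {key!r}")
            if isinstance(val, list):
                val = tuple(val)
            setattr(target, key, val)
    if cfg.get("scheme"):
        prof.scheme.__post_init__()       # re-validate after overrides
    return prof


# ---------------------------------------------------------------------------
# deterministic toy fixtures (the small oracle instances used in tests/docs)

def make_fixtures(kind: str, seed: int = 0) -> dict:
    """Small deterministic instances: 'toy_pedigree', 'toy_genome' or 'toy_log'."""
    if kind == "toy_pedigree":
        # founders 0,1; full sibs 2,3; their offspring 4 (F = 0.25)
        return {"id": [0, 1, 2, 3, 4],
                "sire": [-1, -1, 0, 0, 2],
                "dam": [-1, -1, 1, 1, 3]}
    if kind == "toy_genome":
        rng = np.random.default_rng(seed)
        gmap = gn.random_genome_map([100.0], 20, rng)
        pool = gn.simulate_founder_pool(gmap, 6, 5, 0.0, rng)
        return {"map": gmap, "pool": pool}
    if kind == "toy_log":
        # two replicates x two rounds of plain numbers for aggregation oracles
        rng = np.random.default_rng(seed)
        return {"replicates": [rng.standard_normal((2, 4)).round(3)
                               for _ in range(2)]}
    raise ValueError(f"unknown fixture kind {kind!r}")
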