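"""Evaluation layer: accuracy, dispersion bias, family representation, genetic progress.

All statistics operate on :class:`~preselsim.scheme.SimulationLog` round
tables.  Accuracy is the Pearson correlation of TBV with (G)EBV over the
breeder candidates available at a stage (full cohort at preselection, the
preselected at final selection); dispersion bias is the ordinary
least-squares slope of TBV on GEBV (RC < 1 means inflated predictions);
family representation counts distinct dams among the candidates chosen,
per sex; genetic progress is the change in mean (standardized) TBV or GEBV
of the final-selection candidates between two rounds.  Per-round values are
averaged within replicate over a window of late rounds, then over
replicates, with SE = sd/sqrt(n_replicates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scheme import SimulationLog
from .traits import TRAITS, TraitParams

_TBV_COLS = ["tbv_bw", "tbv_rfi", "tbv_gain"]
_GEBV_COLS = ["final_gebv_bw", "final_gebv_rfi", "final_gebv_gain"]
_PEBV_COLS = ["presel_ebv_bw", "presel_ebv_rfi", "presel_ebv_gain"]


def accuracy(tbv, ebv) -> float:
    """Pearson correlation between true and estimated breeding values.

    Returns NaN (reported as missing, never 0) when fewer than 3 pairs or
    either side is degenerate.
    """
    tbv = np.asarray(tbv, dtype=float)
    ebv = np.asarray(ebv, dtype=float)
    if tbv.size < 3 or np.std(tbv) == 0.0 or np.std(ebv) == 0.0:
        return float("nan")
    return float(np.corrcoef(tbv, ebv)[0, 1])


def dispersion_rc(tbv, gebv) -> float:
    """OLS slope of TBV on GEBV; RC < 1 flags over-dispersed (inflated) GEBVs."""
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if tbv.size < 3:
        return float("nan")
    var = np.var(gebv)
    if var == 0.0:
        raise ValueError("zero GEBV variance")
    return float(np.cov(tbv, gebv, ddof=0)[0, 1] / var)


def family_representation(selected_ids, dam_of, sex_of) -> dict:
    """Distinct dam families among selected candidates, per candidate sex."""
    selected_ids = np.asarray(selected_ids)
    dams = dam_of[selected_ids]
    if np.any(dams < 0):
        raise ValueError("selected candidate with unknown dam")
    males = sex_of[selected_ids]
    return {"male": int(np.unique(dams[males]).size),
            "female": int(np.unique(dams[~males]).size)}


def standardized_progress(log: SimulationLog, params: TraitParams,
                          source: str = "TBV", round_a: int = 30,
                          round_b: int = 40) -> dict:
    """Progress per trait (in genetic SD) and for the index, final candidates of two rounds.

    Delta_t = (mean_t(round_b) - mean_t(round_a)) / sigma_g,t; index progress
    is computed from the standardized trait means with the index weights.
    """
    if round_a > log.n_rounds or round_b > log.n_rounds:
        raise ValueError("requested rounds not present in the log")
    cols = _TBV_COLS if source.upper() == "TBV" else _GEBV_COLS
    means = {}
    for rnd in (round_a, round_b):
        frame = log.round_frame(rnd)
        cand = frame[frame["preselected"]]
        means[rnd] = cand[cols].mean().to_numpy() / params.genetic_sd
    delta = means[round_b] - means[round_a]
    out = {t: float(delta[i]) for i, t in enumerate(TRAITS)}
    out["index"] = float(delta @ params.index_weights)
    out["level_a"] = means[round_a] @ params.index_weights
    out["level_b"] = means[round_b] @ params.index_weights
    return out


def progress_overestimation(delta_gebv: float, delta_tbv: float) -> float:
    """Percent by which GEBV-based progress overstates TBV-based progress."""
    if delta_tbv == 0.0:
        raise ValueError("zero TBV progress")
    return 100.0 * (delta_gebv - delta_tbv) / delta_tbv


def replicate_se(values) -> float:
    """Standard error over replicates: sd (n-1 denominator) / sqrt(n); NaN if n < 2."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def compare_strategies(values_a, values_b) -> float:
    """Two-sided Welch t-test p-value on replicate-level progress values."""
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    if values_a.size < 2 or values_b.size < 2:
        raise ValueError("need at least 2 replicates per strategy")
    if np.var(values_a) == 0.0 and np.var(values_b) == 0.0:
        if np.mean(values_a) == np.mean(values_b):
            return 1.0
        raise ValueError("degenerate variance in both groups")
    return float(stats.ttest_ind(values_a, values_b, equal_var=False).pvalue)


# ---------------------------------------------------------------------------
# per-round and per-replicate aggregation

def round_statistics(log: SimulationLog, round_no: int) -> dict:
    """Accuracy/RC/family statistics of one round of one replicate."""
    frame = log.round_frame(round_no)
    presel = frame[frame["preselected"]]
    sel = frame[frame["selected"]]
    out = {"round": round_no}
    has_pre = "presel_index" in frame.columns
    for i, t in enumerate(TRAITS):
        if has_pre:
            out[f"presel_accuracy_{t}"] = accuracy(frame[_TBV_COLS[i]],
                                                   frame[_PEBV_COLS[i]])
        out[f"final_accuracy_{t}"] = accuracy(presel[_TBV_COLS[i]],
                                              presel[_GEBV_COLS[i]])
        out[f"rc_{t}"] = dispersion_rc(presel[_TBV_COLS[i]],
                                       presel[_GEBV_COLS[i]])
    for stage, sub in (("presel", presel), ("final", sel)):
        for sex_label, is_male in (("male", "M"), ("female", "F")):
            grp = sub[sub["sex"] == is_male]
            out[f"families_{stage}_{sex_label}"] = int(grp["dam"].nunique())
    return out


def replicate_summary(log: SimulationLog, params: TraitParams,
                      window: tuple[int, int], progress_rounds: tuple[int, int]
                      ) -> dict:
    """Window-averaged statistics plus progress for one replicate log."""
    lo, hi = window
    rows = [round_statistics(log, r) for r in range(lo, hi + 1)]
    frame = pd.DataFrame(rows).drop(columns="round")
    out = frame.mean().to_dict()
    a, b = progress_rounds
    tbv = standardized_progress(log, params, "TBV", a, b)
    gebv = standardized_progress(log, params, "GEBV", a, b)
    for t in list(TRAITS) + ["index"]:
        out[f"progress_tbv_{t}"] = tbv[t]
        out[f"progress_gebv_{t}"] = gebv[t]
        out[f"overestimation_{t}"] = progress_overestimation(gebv[t], tbv[t])
    return out


@dataclass
class StrategySummary:
    """Replicate-averaged statistics of one preselection strategy."""

    mean: pd.Series
    se: pd.Series
    replicates: pd.DataFrame

    def __getitem__(self, key: str) -> float:
        return float(self.mean[key])


def summarize_strategy(logs: list[SimulationLog], params: TraitParams,
                       window: tuple[int, int] | None = None,
                       progress_rounds: tuple[int, int] | None = None
                       ) -> StrategySummary:
    """Average replicate summaries; SEs are over replicate-level means.

    Defaults follow the full-scale program design: the window is the last 11 rounds and
    progress uses rounds (n-10, n); both scale down with shorter logs.
    """
    n_rounds = {log.n_rounds for log in logs}
    crits = {log.config.criterion for log in logs}
    if len(n_rounds) != 1 or len(crits) != 1:
        raise ValueError("replicate logs must share the same configuration")
    n = n_rounds.pop()
    if progress_rounds is None:
        progress_rounds = (max(1, n - 10), n)
    if window is None:
        window = (max(1, n - 10), n)
    rows = [replicate_summary(log, params, window, progress_rounds) for log in logs]
    frame = pd.DataFrame(rows)
    se = frame.apply(lambda col: replicate_se(col.to_numpy()))
    return StrategySummary(mean=frame.mean(), se=se, replicates=frame)
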