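"""Welch volcano statistics and the marker-selection funnel.

Per ion, a two-sided Welch unequal-variance t-test compares plant against
control soil intensities (imputed, median-normalized, untransformed — fold
changes are intensity ratios). Enriched ions must pass P < 0.01 and a
greater-than-twofold change, both strict. Within each volcano plot
(solution x mode) the qualifying ions are ranked and the top k pooled
across plots (k = 20 for the three-solution design giving 120 candidates
per direction; k = 50 for the single-solution design giving 100). The
pooled candidates are then refined by a one-way ANOVA across all
soil x solution groups with a Benjamini-Hochberg FDR cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import FeatureTable
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class SelectionParams:
    p_thresh: float = 0.01
    fc_thresh: float = 2.0
    top_k: int = 20  # 50 for the maize-style single-solution workflow
    anova_alpha: float = 0.01
    rank_by: str = "p"  # "p" (p first, |log2fc| tie-break) or "fc" (the reverse)

    def __post_init__(self) -> None:
        if not 0.0 < self.p_thresh < 1.0:
            raise ValidationError("p_thresh must be in (0, 1)")
        if self.fc_thresh <= 1.0:
            raise ValidationError("fc_thresh must exceed 1")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        if self.rank_by not in ("p", "fc"):
            raise ValidationError("rank_by must be 'p' or 'fc'")


def welch_volcano(table: FeatureTable) -> pd.DataFrame:
    """Per-ion Welch t-test and log2 fold change (plant vs control).

    Returns a DataFrame indexed by feature_id with columns log2fc, t, df, p,
    direction. Ions with zero variance in both groups and equal means get
    t = 0, p = 1.
    """
    plant = table.intensities[:, table.soil_mask("plant")]
    control = table.intensities[:, table.soil_mask("control")]
    if plant.shape[1] < 2 or control.shape[1] < 2:
        raise ValidationError(
            f"both soil types need >= 2 replicates "
            f"(plant {plant.shape[1]}, control {control.shape[1]})"
        )
    if np.isnan(plant).any() or np.isnan(control).any():
        raise ValidationError("welch_volcano requires imputed intensities (no missing)")

    mean_p = plant.mean(axis=1)
    mean_c = control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_p / mean_c)

    res = stats.ttest_ind(plant, control, axis=1, equal_var=False)
    t, p, df = np.asarray(res.statistic), np.asarray(res.pvalue), np.asarray(res.df)

    degenerate = (plant.std(axis=1) == 0) & (control.std(axis=1) == 0) & (mean_p == mean_c)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    direction = np.where(log2fc > 0, "plant", np.where(log2fc < 0, "control", "none"))
    direction = np.where(np.isnan(log2fc), "none", direction)
    return pd.DataFrame(
        {"log2fc": log2fc, "t": t, "df": df, "p": p, "direction": direction},
        index=table.feature_ids,
    )


def select_enriched(results: pd.DataFrame, params: SelectionParams) -> tuple[set, set]:
    """(plant-enriched, control-enriched) ion id sets; strict thresholds."""
    if results.empty:
        raise ValidationError("no volcano results to select from")
    log2_cut = np.log2(params.fc_thresh)
    sig = results["p"] < params.p_thresh
    plant = set(results.index[sig & (results["log2fc"] > log2_cut)])
    control = set(results.index[sig & (results["log2fc"] < -log2_cut)])
    return plant, control


def presence_overlap(table: FeatureTable) -> dict:
    """Presence/absence partition of detected ions on raw intensities.

    An ion is present in a soil type when its intensity is positive
    (non-missing) in at least one sample of that type. Returns counts and
    percentages over detected ions.
    """
    with np.errstate(invalid="ignore"):
        detected = np.nan_to_num(table.intensities, nan=0.0) > 0
    in_plant = detected[:, table.soil_mask("plant")].any(axis=1)
    in_control = detected[:, table.soil_mask("control")].any(axis=1)
    plant_only = int((in_plant & ~in_control).sum())
    control_only = int((in_control & ~in_plant).sum())
    shared = int((in_plant & in_control).sum())
    total = plant_only + control_only + shared
    pct = (lambda c: 100.0 * c / total if total else 0.0)
    return {
        "plant_only": plant_only,
        "control_only": control_only,
        "shared": shared,
        "total_detected": total,
        "pct_plant_only": pct(plant_only),
        "pct_control_only": pct(control_only),
        "pct_shared": pct(shared),
    }


def _rank_qualifying(results: pd.DataFrame, params: SelectionParams, direction: str
                     ) -> pd.DataFrame:
    log2_cut = np.log2(params.fc_thresh)
    if direction == "plant":
        mask = (results["p"] < params.p_thresh) & (results["log2fc"] > log2_cut)
    elif direction == "control":
        mask = (results["p"] < params.p_thresh) & (results["log2fc"] < -log2_cut)
    else:
        raise ValidationError("direction must be 'plant' or 'control'")
    qual = results.loc[mask].copy()
    qual["abs_log2fc"] = qual["log2fc"].abs()
    qual = qual.reset_index().rename(columns={qual.index.name or "index": "feature_id"})
    if params.rank_by == "p":
        keys, ascending = ["p", "abs_log2fc", "feature_id"], [True, False, True]
    else:
        keys, ascending = ["abs_log2fc", "p", "feature_id"], [False, True, True]
    qual = qual.sort_values(keys, ascending=ascending, kind="mergesort")
    qual["rank"] = np.arange(1, len(qual) + 1)
    return qual


def pool_top_k(
    volcanoes: Sequence[tuple[str, pd.DataFrame]],
    params: SelectionParams,
    direction: str,
) -> pd.DataFrame:
    """Pool the top-k qualifying ions of each volcano plot into a MarkerSet.

    Each plot contributes at most ``params.top_k`` entries (all qualifying
    ions, with a logged warning, when fewer qualify). Entries from different
    plots stay distinct even when feature ids coincide. Columns: plot_id,
    feature_id, rank, log2fc, p, and placeholders anova_p, bh_q, kept.
    """
    if not volcanoes:
        raise ValidationError("empty volcano plot list")
    parts = []
    for plot_id, results in volcanoes:
        qual = _rank_qualifying(results, params, direction)
        if len(qual) < params.top_k:
            log.warning(
                "plot %s: only %d of top_k=%d ions qualify in direction %s",
                plot_id, len(qual), params.top_k, direction,
            )
        top = qual.head(params.top_k).copy()
        top.insert(0, "plot_id", plot_id)
        parts.append(top[["plot_id", "feature_id", "rank", "log2fc", "p"]])
    pooled = pd.concat(parts, ignore_index=True)
    pooled["anova_p"] = np.nan
    pooled["bh_q"] = np.nan
    pooled["kept"] = False
    return pooled


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for a p-value pool."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def anova_bh_filter(
    candidates: pd.DataFrame,
    tables: Mapping[str, FeatureTable],
    alpha: float = 0.01,
    use_welch: bool = False,
) -> pd.DataFrame:
    """One-way ANOVA across all soil x solution groups + BH FDR refinement.

    ``tables`` maps a dataset key to the FeatureTable holding every
    soil/solution group of that candidate's namespace; a candidate's dataset
    key is the part of its plot_id before ':' (plot ids are
    "<dataset>:<solution>"). BH q-values are computed over the given pool
    (one direction); kept <=> q < alpha. ``use_welch`` switches to Welch's
    heteroscedastic one-way ANOVA.
    """
    out = candidates.copy()
    pvals = np.empty(len(out))
    for row_i, row in enumerate(out.itertuples(index=False)):
        dataset = str(row.plot_id).split(":")[0]
        if dataset not in tables:
            raise ValidationError(f"no table for dataset {dataset!r}")
        table = tables[dataset]
        values = table.intensities[table.features.index.get_loc(row.feature_id)]
        keys = list(zip(table.samples["soil_type"], table.samples["solution"]))
        groups = [values[[k == key for k in keys]] for key in sorted(set(keys))]
        if any(len(g) < 2 for g in groups):
            raise ValidationError("every soil x solution group needs >= 2 replicates")
        if use_welch:
            from .damage import _welch_anova_raw

            _, _, _, p = _welch_anova_raw(groups)
        else:
            if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
                p = 1.0
            else:
                p = stats.f_oneway(*groups).pvalue
        pvals[row_i] = p
    out["anova_p"] = pvals
    if len(out):
        out["bh_q"] = bh_qvalues(pvals)
        out["kept"] = out["bh_q"] < alpha
    return out
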