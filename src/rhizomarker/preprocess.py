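"""Normalization / transformation / scaling chain for the feature tables.

Fixed stage order: impute -> median-normalize -> cube-root -> Pareto-scale.
The univariate (volcano) branch stops after median normalization so fold
changes stay on the intensity scale; the multivariate branch consumes the
fully processed matrix. Each stage may run at most once per table (guarded
by the table's ``stages_applied`` record) because the chain is not
idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import FeatureTable
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    impute: str = "half_min"  # half_min | none
    normalize: str = "median"  # median | none
    transform: str = "cube_root"  # cube_root | none
    scale: str = "pareto"  # pareto | none


def impute_missing(table: FeatureTable) -> FeatureTable:
    """Replace each missing cell by half that feature's minimum positive value.

    Features with no observed positive value anywhere are dropped (logged).
    """
    x = table.intensities.copy()
    with np.errstate(invalid="ignore"):
        positive = np.where(x > 0, x, np.nan)
    min_pos = np.nanmin(
        np.where(np.isnan(positive), np.inf, positive), axis=1
    )
    all_missing = ~np.isfinite(min_pos)
    if all_missing.any():
        log.warning(
            "dropping %d feature(s) with no observed positive intensity",
            int(all_missing.sum()),
        )
    fill = np.where(np.isfinite(min_pos), min_pos / 2.0, 0.0)
    missing = np.isnan(x)
    x[missing] = np.broadcast_to(fill[:, None], x.shape)[missing]
    keep = ~all_missing
    out = table.with_stage("impute", x)
    if all_missing.any():
        out = FeatureTable(
            out.features.loc[keep].copy(), out.samples.copy(),
            out.intensities[keep], out.stages_applied,
        )
    return out


def median_normalize(table: FeatureTable) -> FeatureTable:
    """Scale each sample so all sample medians equal the median of medians."""
    x = table.intensities
    if np.isnan(x).any():
        raise ValidationError("median_normalize requires a table without missing values")
    medians = np.median(x, axis=0)
    zero = medians == 0
    if zero.any():
        bad = list(table.sample_ids[zero])
        raise ValidationError(f"sample(s) with zero median intensity: {bad}")
    reference = np.median(medians)
    return table.with_stage("normalize", x * (reference / medians)[None, :])


def cube_root_transform(table: FeatureTable) -> FeatureTable:
    x = table.intensities
    with np.errstate(invalid="ignore"):
        if np.any(x < 0):
            raise ValidationError("cube_root_transform requires non-negative intensities")
    return table.with_stage("transform", np.cbrt(x))


def pareto_scale(table: FeatureTable) -> pd.DataFrame:
    """Per feature: (x - mean) / sqrt(sd), sd with n-1 denominator.

    Returns a features x samples DataFrame. Constant features become all-zero
    rows (logged) rather than NaN.
    """
    x = table.intensities
    if table.n_samples < 2:
        raise ValidationError("pareto_scale needs at least 2 samples")
    if np.isnan(x).any():
        raise ValidationError("pareto_scale requires a table without missing values")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        log.warning("%d constant feature(s) map to zero rows", int(constant.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (x - mean) / np.sqrt(sd)
    scaled[constant] = 0.0
    return pd.DataFrame(scaled, index=table.feature_ids, columns=table.sample_ids)


def preprocess(table: FeatureTable, params: PreprocessParams | None = None):
    """Run the configured chain; returns (normalized_table, scaled_matrix).

    ``normalized_table`` is the imputed + median-normalized FeatureTable for
    the univariate branch; ``scaled_matrix`` (features x samples DataFrame,
    or None when scaling is off) feeds the multivariate branch.
    """
    params = params or PreprocessParams()
    t = table
    if params.impute == "half_min":
        t = impute_missing(t)
    if params.normalize == "median":
        t = median_normalize(t)
    normalized = t
    if params.transform == "cube_root":
        t = cube_root_transform(t)
    scaled = pareto_scale(t) if params.scale == "pareto" else None
    return normalized, scaled
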