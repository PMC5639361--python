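"""Seeded generators with known ground truth for every downstream stage.

The feature-table generator emulates the study design: aligned LC-MS ion
tables per extraction solution (0/50/95% MeOH) and ionization mode, with
5 plant vs 3 control replicates, log-normal baseline intensities, a
configurable fraction of condition-enriched ions with known log2 fold
changes, extra replicate variance for the 95% MeOH solution, and MCAR
missing values. Feature identity (m/z, RT) is seeded per (seed, mode) only,
so the solutions of one mode share an aligned feature namespace; per-ion
intensities are seeded per (seed, mode, solution).

Companion generators produce OTU count tables with group effects and
conductivity/CFU replicate data for the damage-control statistics. All
generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import MODES, SOLUTIONS, CompoundRecord, FeatureTable
from .deconv import DEFAULT_RULES, AdductRule, rules_by_label
from .errors import ConfigError
from .masses import C13_C12_DELTA

_MODE_CODE = {"positive": 1, "negative": 2}
_SOLUTION_CODE = {0: 10, 50: 11, 95: 12}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic experiment.

    Defaults follow the published design: 5 plant vs 3 control replicates,
    spiked log2 fold changes in [1.5, 4] (so every enriched ion exceeds the
    2-fold selection cut), and doubled replicate variance for the 95% MeOH
    solution, which showed higher variation than the others.
    """

    n_features_per_mode: int = 2000
    n_plant: int = 5
    n_control: int = 3
    solutions: tuple[int, ...] = (0, 50, 95)
    frac_enriched_plant: float = 0.05
    frac_enriched_control: float = 0.05
    log2fc_range: tuple[float, float] = (1.5, 4.0)
    replicate_cv: float = 0.2
    missing_rate: float = 0.02
    extra_variance_95: float = 2.0
    n_spiked_compounds: int = 0
    log10_mean: float = 4.0
    log10_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_enriched_plant", "frac_enriched_control", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_enriched_plant + self.frac_enriched_control > 1.0:
            raise ConfigError("enriched fractions must not exceed 1 in total")
        lo, hi = self.log2fc_range
        if not (lo > 1.0 and hi >= lo):
            raise ConfigError("log2fc_range lower bound must exceed 1 (the 2-fold cut)")
        if self.extra_variance_95 < 1.0:
            raise ConfigError("extra_variance_95 must be >= 1")
        unknown = set(self.solutions) - set(SOLUTIONS)
        if unknown:
            raise ConfigError(f"unknown solution(s) {sorted(unknown)}")
        if self.n_plant < 1 or self.n_control < 1 or self.n_features_per_mode < 1:
            raise ConfigError("sample and feature counts must be positive")


@dataclass
class GroundTruth:
    enriched_plant_ids: set[str] = field(default_factory=set)
    enriched_control_ids: set[str] = field(default_factory=set)
    true_log2fc: dict[str, float] = field(default_factory=dict)
    # (compound name, member feature ids, adduct labels, neutral mass)
    spiked_groups: list[tuple[str, list[str], list[str], float]] = field(default_factory=list)
    adduct_collision_count: int = 0

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            self.enriched_plant_ids | other.enriched_plant_ids,
            self.enriched_control_ids | other.enriched_control_ids,
            {**self.true_log2fc, **other.true_log2fc},
            self.spiked_groups + other.spiked_groups,
            self.adduct_collision_count + other.adduct_collision_count,
        )


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _count_adduct_collisions(mz: np.ndarray, rt: np.ndarray, mode: str,
                             mz_tol: float = 0.1, rt_tol: float = 10.0) -> int:
    """Ion pairs that would look like adduct siblings by chance."""
    shifts = np.array([r.mass_shift for r in DEFAULT_RULES[mode]])
    deltas = np.abs(shifts[:, None] - shifts[None, :])
    deltas = np.unique(deltas[deltas > 0])
    order = np.argsort(rt, kind="mergesort")
    rt_s, mz_s = rt[order], mz[order]
    count = 0
    hi = 0
    for i in range(len(rt_s)):
        while hi < len(rt_s) and rt_s[hi] <= rt_s[i] + rt_tol:
            hi += 1
        if hi - i <= 1:
            continue
        dm = np.abs(mz_s[i + 1:hi] - mz_s[i])
        count += int(np.any(np.abs(dm[:, None] - deltas[None, :]) <= mz_tol, axis=1).sum())
    return count


def generate_feature_table(
    config: SyntheticConfig, solution: int, mode: str
) -> tuple[FeatureTable, GroundTruth]:
    """One aligned feature table for a (solution, mode) dataset.

    Deterministic in (config, solution, mode): feature m/z and RT are drawn
    from (seed, mode), intensities from (seed, mode, solution), so repeated
    calls with the same arguments are bit-identical and different solutions
    of one mode share their feature namespace.
    """
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}")
    if solution not in config.solutions:
        raise ConfigError(f"solution {solution} not in configured set {config.solutions}")
    n = config.n_features_per_mode
    feat_rng = np.random.default_rng([config.seed, _MODE_CODE[mode], 101])
    rng = np.random.default_rng(
        [config.seed, _MODE_CODE[mode], _SOLUTION_CODE[solution], 202]
    )

    prefix = "P" if mode == "positive" else "N"
    ids = np.array([f"{prefix}{i:06d}" for i in range(n)])
    mz = feat_rng.uniform(80.0, 1200.0, n)
    rt = feat_rng.uniform(30.0, 900.0, n)
    features = pd.DataFrame(
        {"mz": mz, "rt": rt, "mode": mode}, index=pd.Index(ids, name="feature_id")
    )

    base = 10.0 ** rng.normal(config.log10_mean, config.log10_sd, n)
    n_up = int(round(config.frac_enriched_plant * n))
    n_dn = int(round(config.frac_enriched_control * n))
    order = rng.permutation(n)
    up_idx, dn_idx = order[:n_up], order[n_up:n_up + n_dn]
    log2fc = np.zeros(n)
    log2fc[up_idx] = rng.uniform(*config.log2fc_range, n_up)
    log2fc[dn_idx] = -rng.uniform(*config.log2fc_range, n_dn)

    control_mean = base
    plant_mean = base * 2.0**log2fc

    cv = config.replicate_cv * (np.sqrt(config.extra_variance_95) if solution == 95 else 1.0)
    plant = plant_mean[:, None] * _lognormal_noise(rng, cv, (n, config.n_plant))
    control = control_mean[:, None] * _lognormal_noise(rng, cv, (n, config.n_control))
    matrix = np.concatenate([plant, control], axis=1)
    if config.missing_rate > 0:
        matrix[rng.random(matrix.shape) < config.missing_rate] = np.nan

    sample_ids = [f"plant_{solution}_{r + 1}" for r in range(config.n_plant)] + [
        f"control_{solution}_{r + 1}" for r in range(config.n_control)
    ]
    samples = pd.DataFrame(
        {
            "soil_type": ["plant"] * config.n_plant + ["control"] * config.n_control,
            "solution": solution,
            "replicate": list(range(1, config.n_plant + 1))
            + list(range(1, config.n_control + 1)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = FeatureTable(features, samples, matrix)
    truth = GroundTruth(
        enriched_plant_ids=set(ids[up_idx]),
        enriched_control_ids=set(ids[dn_idx]),
        true_log2fc={ids[i]: float(log2fc[i]) for i in np.r_[up_idx, dn_idx]},
        adduct_collision_count=_count_adduct_collisions(mz, rt, mode),
    )
    return table, truth


def spike_compound_ions(
    table: FeatureTable,
    compound: CompoundRecord,
    adducts: list[str],
    rt: float,
    direction: str,
    seed: int = 0,
    log2fc: float = 3.0,
    base_intensity: float = 2e5,
    isotope_fraction: float = 0.10,
    replicate_cv: float = 0.2,
) -> tuple[FeatureTable, GroundTruth]:
    """Append a known compound's adduct/isotope sibling ions to a table.

    One ion per adduct label plus one 13C isotopologue per adduct
    (+1.00336 Da, ``isotope_fraction`` of the parent intensity). Siblings
    share RT within +-2 s and have correlated intensities through a common
    per-sample factor; all are enriched in ``direction`` with the given
    |log2 fold change|.
    """
    if direction not in ("plant", "control"):
        raise ConfigError("direction must be 'plant' or 'control'")
    if not adducts:
        return table.copy(), GroundTruth()
    mode = table.features["mode"].iloc[0] if len(table.features) else "positive"
    known = rules_by_label(mode)
    unknown = [a for a in adducts if a not in known]
    if unknown:
        raise ConfigError(
            f"unknown adduct label(s) {unknown}; supported for {mode}: {sorted(known)}"
        )
    rng = np.random.default_rng([abs(seed), 303, len(table.features)])

    m = compound.monoisotopic_mass
    plant_mask = table.soil_mask("plant")
    n_samples = table.n_samples
    sample_factor = _lognormal_noise(rng, replicate_cv, n_samples)
    fc = 2.0**log2fc
    soil_factor = np.where(plant_mask, fc, 1.0) if direction == "plant" else np.where(
        plant_mask, 1.0, fc
    )
    signed_fc = log2fc if direction == "plant" else -log2fc

    rows, ids, labels = [], [], []
    feat_rows = []
    safe = compound.name.replace(" ", "_")
    for label in adducts:
        rule = known[label]
        ion_mz = m + rule.mass_shift
        for tag, mz_i, level in (
            ("", ion_mz, base_intensity),
            ("_13C", ion_mz + C13_C12_DELTA, base_intensity * isotope_fraction),
        ):
            fid = f"SPK_{safe}_{label}{tag}"
            ids.append(fid)
            labels.append(label if not tag else f"{label} +1x13C")
            feat_rows.append((fid, mz_i, rt + rng.uniform(-1.0, 1.0), mode))
            rows.append(
                level * soil_factor * sample_factor
                * _lognormal_noise(rng, 0.05, n_samples)
            )

    features = pd.concat(
        [
            table.features,
            pd.DataFrame(
                [(mz_i, rt_i, md) for _, mz_i, rt_i, md in feat_rows],
                index=pd.Index([f for f, *_ in feat_rows], name="feature_id"),
                columns=["mz", "rt", "mode"],
            ),
        ]
    )
    intensities = np.vstack([table.intensities, np.array(rows)])
    spiked = FeatureTable(features, table.samples.copy(), intensities, table.stages_applied)
    truth = GroundTruth(
        enriched_plant_ids=set(ids) if direction == "plant" else set(),
        enriched_control_ids=set(ids) if direction == "control" else set(),
        true_log2fc={fid: signed_fc for fid in ids},
        spiked_groups=[(compound.name, ids, labels, m)],
    )
    return spiked, truth


@dataclass
class OtuTable:
    """OTU x sample count matrix with a two-level sample grouping."""

    counts: pd.DataFrame  # OTUs x samples, integer
    groups: pd.Series  # sample -> "root_rhizosphere" | "control_soil"
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if not (self.counts.to_numpy() >= 0).all():
            raise ConfigError("OTU counts must be non-negative")
        if set(self.counts.columns) != set(self.groups.index):
            raise ConfigError("groups must cover exactly the sample columns")


def generate_otu_table(
    n_otus: int,
    n_per_group: int,
    depth: int,
    n_effect_otus: int,
    effect_fold: float,
    seed: int = 0,
    concentration: float = 200.0,
) -> tuple[OtuTable, set[str]]:
    """Seeded OTU count table with a known rhizosphere effect.

    Per sample, counts are multinomial over Dirichlet-perturbed base
    proportions; the effect OTUs' proportions are multiplied by
    ``effect_fold`` in the root group before renormalization. Returns the
    table and the set of effect OTU ids. ``effect_fold = 1`` gives an
    exchangeable null.
    """
    if depth <= 0:
        raise ConfigError("sequencing depth must be > 0")
    if n_effect_otus > n_otus:
        raise ConfigError("n_effect_otus must not exceed n_otus")
    rng = np.random.default_rng([abs(seed), 404])
    base = rng.lognormal(0.0, 1.0, n_otus)
    base /= base.sum()
    effect_idx = rng.choice(n_otus, n_effect_otus, replace=False)

    otu_ids = [f"OTU{i:05d}" for i in range(n_otus)]
    sample_ids, group_labels, cols = [], [], []
    for group, label in (("root_rhizosphere", "root"), ("control_soil", "soil")):
        p_group = base.copy()
        if group == "root_rhizosphere" and effect_fold != 1.0:
            p_group[effect_idx] *= effect_fold
            p_group /= p_group.sum()
        for r in range(n_per_group):
            p_sample = rng.dirichlet(p_group * concentration)
            cols.append(rng.multinomial(depth, p_sample))
            sample_ids.append(f"{label}_{r + 1}")
            group_labels.append(group)
    counts = pd.DataFrame(
        np.array(cols).T, index=pd.Index(otu_ids, name="otu_id"), columns=sample_ids
    )
    groups = pd.Series(group_labels, index=sample_ids, name="group")
    return OtuTable(counts, groups), {otu_ids[i] for i in effect_idx}


@dataclass
class LeakageExperiment:
    """Replicate conductivity values per treatment plus the lysis maximum."""

    groups: dict[str, np.ndarray]  # treatment -> conductivities (uS/cm)
    lysis_max: float  # conductivity of fully lysed tissue (uS/cm)


def generate_leakage_data(
    group_means: dict[str, float],
    cv: float,
    n: int,
    seed: int = 0,
    lysis_max: float = 1000.0,
) -> LeakageExperiment:
    """Electrolyte-leakage replicates, gamma-distributed around each mean.

    ``group_means`` are relative conductivities in percent of the lysis
    maximum; generated values are absolute conductivities so that
    ``relative_conductivity`` recovers the intended percentages on average.
    """
    if n < 2:
        raise ConfigError("need n >= 2 replicates for any test")
    if any(not 0.0 <= m <= 100.0 for m in group_means.values()):
        raise ConfigError("group means are percentages and must lie in [0, 100]")
    rng = np.random.default_rng([abs(seed), 505])
    groups: dict[str, np.ndarray] = {}
    for label, pct in group_means.items():
        mean = pct / 100.0 * lysis_max
        if cv == 0 or mean == 0:
            groups[label] = np.full(n, mean)
        else:
            shape = 1.0 / cv**2
            groups[label] = rng.gamma(shape, mean / shape, n)
    return LeakageExperiment(groups=groups, lysis_max=lysis_max)
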