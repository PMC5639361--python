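"""End-to-end orchestration of the two differential workflows.

``arabidopsis`` mode runs the three-solution design (0/50/95% MeOH x two
ionization modes = 6 volcano plots, top-20 pooling -> 120 candidates per
direction); ``maize`` mode runs the single-solution design (50% MeOH x two
modes = 2 plots, top-50 pooling -> 100 candidates). Both funnel pooled
candidates through the soil x solution ANOVA with Benjamini-Hochberg FDR,
then adduct/isotope deconvolution, library annotation and class
composition. A companion diversity workflow chains OTU filtering, alpha
diversity, rarefaction, Bray-Curtis and PERMANOVA.

A single top-level seed fans out to per-stage seeds through
``numpy.random.SeedSequence`` spawning, so each stage is reproducible in
isolation and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import deconv, diversity, enrichment, multivariate, preprocess
from .dataio import FeatureTable, read_compound_library, write_report
from .deconv import DeconvParams
from .enrichment import SelectionParams
from .errors import ConfigError
from .preprocess import PreprocessParams
from .synthetic import SyntheticConfig, generate_feature_table, generate_otu_table

log = logging.getLogger(__name__)

WORKFLOW_DESIGNS = {
    "arabidopsis": {"solutions": (0, 50, 95), "top_k": 20},
    "maize": {"solutions": (50,), "top_k": 50},
}


@dataclass
class PipelineConfig:
    mode: str = "arabidopsis"  # arabidopsis | maize | custom
    synthetic: SyntheticConfig | None = None
    tables: dict[str, FeatureTable] | None = None  # dataset key ("positive"/"negative")
    selection: SelectionParams | None = None
    preprocessing: PreprocessParams = field(default_factory=PreprocessParams)
    deconv_params: DeconvParams = field(default_factory=DeconvParams)
    library_path: str | None = None  # None -> bundled library
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("arabidopsis", "maize", "custom"):
            raise ConfigError(f"unknown pipeline mode {self.mode!r}")
        if self.mode in WORKFLOW_DESIGNS:
            design = WORKFLOW_DESIGNS[self.mode]
            if self.selection is None:
                self.selection = SelectionParams(top_k=design["top_k"])
            if self.synthetic is not None:
                if tuple(self.synthetic.solutions) != design["solutions"]:
                    raise ConfigError(
                        f"{self.mode} mode expects solutions {design['solutions']}, "
                        f"got {tuple(self.synthetic.solutions)}"
                    )
        elif self.selection is None:
            self.selection = SelectionParams()
        if self.synthetic is None and self.tables is None:
            raise ConfigError("either synthetic config or input tables required")


@dataclass
class MarkerReport:
    volcanoes: dict[str, pd.DataFrame]  # plot_id -> per-ion volcano table
    enriched_counts: dict[str, dict[str, int]]
    multivariate_summary: dict[str, dict]
    markers: dict[str, pd.DataFrame]  # direction -> refined MarkerSet
    groups: dict[str, list[deconv.AdductGroup]]
    annotations: dict[str, list[deconv.Annotation]]
    composition: dict[str, dict[str, float]]
    config_echo: dict


def _resolve_tables(config: PipelineConfig) -> dict[str, FeatureTable]:
    """One table per ionization mode, samples spanning all solutions."""
    if config.tables is not None:
        return config.tables
    syn = dataclasses.replace(config.synthetic, seed=config.seed) \
        if config.synthetic.seed != config.seed else config.synthetic
    tables: dict[str, FeatureTable] = {}
    for mode in ("positive", "negative"):
        per_solution = [
            generate_feature_table(syn, solution, mode)[0] for solution in syn.solutions
        ]
        features = per_solution[0].features
        samples = pd.concat([t.samples for t in per_solution])
        samples.index = [
            f"{sid}" for t in per_solution for sid in t.sample_ids
        ]
        samples.index.name = "sample_id"
        matrix = np.concatenate([t.intensities for t in per_solution], axis=1)
        tables[mode] = FeatureTable(features.copy(), samples, matrix)
    return tables


def run_differential_workflow(config: PipelineConfig) -> MarkerReport:
    """Full marker pipeline: preprocess -> volcano/multivariate -> pool ->
    ANOVA+BH -> deconvolve -> annotate -> class composition."""
    sel = config.selection
    tables = _resolve_tables(config)
    library = read_compound_library(config.library_path)

    volcanoes: dict[str, pd.DataFrame] = {}
    plot_list: list[tuple[str, pd.DataFrame]] = []
    enriched_counts: dict[str, dict[str, int]] = {}
    multivariate_summary: dict[str, dict] = {}
    normalized_by_mode: dict[str, FeatureTable] = {}

    for mode, table in tables.items():
        solutions = sorted(table.samples["solution"].unique())
        normalized_parts = []
        for solution in solutions:
            subset = table.subset_samples(table.samples["solution"] == solution)
            normalized, scaled = preprocess.preprocess(subset, config.preprocessing)
            normalized_parts.append(normalized)
            plot_id = f"{mode}:{solution}"
            res = enrichment.welch_volcano(normalized)
            volcanoes[plot_id] = res
            plot_list.append((plot_id, res))
            plant, control = enrichment.select_enriched(res, sel)
            enriched_counts[plot_id] = {"plant": len(plant), "control": len(control)}
            if scaled is not None:
                x = scaled.to_numpy().T  # samples x features
                labels = normalized.samples["soil_type"].to_numpy()
                pca_model = multivariate.pca(x, n_components=min(3, x.shape[0] - 1))
                pls = multivariate.plsda(x, labels, n_components=2)
                multivariate_summary[plot_id] = {
                    "pca_explained_pct": pca_model.explained_pct.tolist(),
                    "r2": pls.r2,
                    "q2": pls.q2,
                }
        # re-assemble the mode-wide normalized table for the 6-group ANOVA
        features = normalized_parts[0].features
        common = features.index
        for part in normalized_parts[1:]:
            common = common.intersection(part.features.index)
        samples = pd.concat([p.samples for p in normalized_parts])
        matrix = np.concatenate(
            [p.subset_features(common).intensities for p in normalized_parts], axis=1
        )
        normalized_by_mode[mode] = FeatureTable(
            features.loc[common].copy(), samples, matrix
        )

    markers: dict[str, pd.DataFrame] = {}
    groups: dict[str, list[deconv.AdductGroup]] = {}
    annotations: dict[str, list[deconv.Annotation]] = {}
    composition: dict[str, dict[str, float]] = {}
    for direction in ("plant", "control"):
        pooled = enrichment.pool_top_k(plot_list, sel, direction)
        refined = enrichment.anova_bh_filter(
            pooled, normalized_by_mode, alpha=sel.anova_alpha
        )
        markers[direction] = refined
        kept = refined.loc[refined["kept"]]
        dir_groups: list[deconv.AdductGroup] = []
        for mode, table in tables.items():
            ids = kept.loc[
                kept["plot_id"].str.startswith(f"{mode}:"), "feature_id"
            ].unique()
            if len(ids) == 0:
                continue
            ions = tables[mode].features.loc[list(ids)]
            dir_groups.extend(
                deconv.group_adducts_isotopes(ions, config.deconv_params)
            )
        groups[direction] = dir_groups
        annotations[direction] = (
            deconv.annotate_groups(dir_groups, library, config.deconv_params.mz_tol)
            if dir_groups else []
        )
        composition[direction] = (
            deconv.class_composition(annotations[direction])
            if any(not a.excluded for a in annotations[direction]) else {}
        )

    report = MarkerReport(
        volcanoes=volcanoes,
        enriched_counts=enriched_counts,
        multivariate_summary=multivariate_summary,
        markers=markers,
        groups=groups,
        annotations=annotations,
        composition=composition,
        config_echo=_echo_config(config),
    )
    if config.output_dir:
        _write_marker_report(report, Path(config.output_dir))
    return report


def _echo_config(config: PipelineConfig) -> dict:
    echo = {
        "mode": config.mode,
        "seed": config.seed,
        "selection": dataclasses.asdict(config.selection),
        "preprocessing": dataclasses.asdict(config.preprocessing),
        "deconv": dataclasses.asdict(config.deconv_params),
    }
    if config.synthetic is not None:
        echo["synthetic"] = dataclasses.asdict(config.synthetic)
    return echo


def _write_marker_report(report: MarkerReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for plot_id, res in report.volcanoes.items():
        df = res.copy()
        df["neg_log10_p"] = -np.log10(df["p"].clip(lower=np.finfo(float).tiny))
        df.to_csv(outdir / f"volcano_{plot_id.replace(':', '_')}.tsv", sep="\t")
    for direction, df in report.markers.items():
        df.to_csv(outdir / f"markers_{direction}.tsv", sep="\t", index=False)
    summary = {
        "enriched_counts": report.enriched_counts,
        "multivariate": report.multivariate_summary,
        "composition": report.composition,
        "config": report.config_echo,
        "n_candidates": {d: len(m) for d, m in report.markers.items()},
        "n_kept": {d: int(m["kept"].sum()) for d, m in report.markers.items()},
    }
    write_report(summary, outdir / "summary.json", "json")


@dataclass
class DiversityReport:
    n_otus_before: int
    n_otus_after: int
    shannon: dict[str, float]
    richness: dict[str, int]
    rarefaction: dict[str, pd.DataFrame]
    permanova: diversity.PermanovaResult
    group_means: dict[str, dict[str, float]]


def run_diversity_workflow(
    table=None,
    seed: int = 0,
    filter_params: diversity.OtuFilterParams | None = None,
    n_perm: int = 999,
    rarefaction_depths: list[int] | None = None,
    output_dir: str | None = None,
    synthetic_kwargs: dict | None = None,
) -> DiversityReport:
    """OTU filter -> alpha diversity -> rarefaction -> Bray-Curtis -> PERMANOVA."""
    ss = np.random.SeedSequence(abs(seed))
    child = ss.spawn(2)
    if table is None:
        kwargs = dict(
            n_otus=500, n_per_group=4, depth=20000, n_effect_otus=30,
            effect_fold=4.0, seed=int(child[0].generate_state(1)[0] % 2**31),
        )
        kwargs.update(synthetic_kwargs or {})
        table, _ = generate_otu_table(**kwargs)
    counts = table.groups.value_counts()
    if (counts < 2).any():
        raise ConfigError("each group needs at least 2 samples")

    filtered = diversity.prevalence_filter(table, filter_params)
    shannon = {s: diversity.shannon(filtered.counts[s]) for s in filtered.counts}
    richness = {s: diversity.richness(filtered.counts[s]) for s in filtered.counts}
    depths = rarefaction_depths
    rarefaction: dict[str, pd.DataFrame] = {}
    rare_seed = int(child[1].generate_state(1)[0] % 2**31)
    for s in filtered.counts:
        total = int(filtered.counts[s].sum())
        sample_depths = depths or [max(1, total // 10), total // 2, total]
        rarefaction[s] = diversity.rarefaction_curve(
            filtered.counts[s], [d for d in sample_depths if d <= total],
            reps=50, seed=rare_seed,
        )
    dist = diversity.bray_curtis(filtered)
    perm = diversity.permanova(
        dist, filtered.groups.loc[dist.index], n_perm=n_perm,
        seed=int(ss.generate_state(1)[0] % 2**31),
    )
    groups = filtered.groups
    group_means = {
        "shannon": {g: float(np.mean([shannon[s] for s in groups.index[groups == g]]))
                    for g in groups.unique()},
        "richness": {g: float(np.mean([richness[s] for s in groups.index[groups == g]]))
                     for g in groups.unique()},
    }
    report = DiversityReport(
        n_otus_before=len(table.counts),
        n_otus_after=len(filtered.counts),
        shannon=shannon,
        richness=richness,
        rarefaction=rarefaction,
        permanova=perm,
        group_means=group_means,
    )
    if output_dir:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(
            {
                "n_otus_before": report.n_otus_before,
                "n_otus_after": report.n_otus_after,
                "shannon": report.shannon,
                "richness": report.richness,
                "group_means": report.group_means,
                "permanova": dataclasses.asdict(report.permanova),
            },
            out / "diversity.json",
            "json",
        )
    return report
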