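#!/usr/bin/env python
"""Microbial side analysis: OTU prevalence/abundance filtering, Shannon and
richness per sample, rarefaction, Bray-Curtis distances and PERMANOVA on a
synthetic root-vs-control-soil OTU table with a known rhizosphere effect.

Writes results/diversity/diversity.json.
"""

from pathlib import Path

from rhizomarker.pipeline import run_diversity_workflow

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    report = run_diversity_workflow(
        seed=SEED,
        n_perm=999,
        synthetic_kwargs={"n_otus": 500, "n_per_group": 4, "depth": 20_000,
                          "n_effect_otus": 30, "effect_fold": 8.0},
        output_dir=str(ROOT / "results" / "diversity"),
    )
    print(f"prevalence/abundance filter: {report.n_otus_before} -> "
          f"{report.n_otus_after} OTUs")
    for stat, means in report.group_means.items():
        pretty = {g: round(v, 2) for g, v in means.items()}
        print(f"mean {stat} per group: {pretty}")
    p = report.permanova
    print(f"PERMANOVA (Bray-Curtis): F({p.df_between},{p.df_within}) = "
          f"{p.pseudo_f:.2f}, P = {p.p:.3f} ({p.n_perm} permutations)")
    if p.p <= 0.05:
        print("\nCommunity composition differs between root-associated and "
              "control soil: the simulated rhizosphere effect is detected.")
    else:
        print("\nPERMANOVA did not reach 0.05 at this seed; note that with "
              "4 + 4 samples the permutation p-value is bounded near 0.03 "
              "by the 35 distinct label splits.")


if __name__ == "__main__":
    main()
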