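"""Microbial-diversity side analysis supporting the rhizosphere effect.

OTU prevalence/abundance filtering, alpha diversity (Shannon, richness),
rarefaction without replacement, Bray-Curtis distances and a one-way
PERMANOVA (Anderson's distance-based pseudo-F with seeded label
permutations). Shannon uses natural log by default; the filter thresholds
follow the published rule: keep an OTU when its count exceeds 5 in at least
30% of samples AND its total count exceeds 20 (strict inequalities).

The published ordination used weighted UniFrac, which needs a phylogeny;
here Bray-Curtis is the provided distance, and ``permanova`` accepts any
externally computed distance matrix so tree-based distances can be plugged
in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .synthetic import OtuTable  # noqa: F401  (re-export: container lives with its generator)


@dataclass
class OtuFilterParams:
    min_count: int = 5
    min_prevalence: float = 0.30
    min_total: int = 20
    strict: bool = True  # "> min_count"; False switches to ">="


@dataclass
class PermanovaResult:
    pseudo_f: float
    df_between: int
    df_within: int
    p: float
    n_perm: int
    seed: int | None


def prevalence_filter(table: OtuTable, params: OtuFilterParams | None = None) -> OtuTable:
    """Keep OTUs passing both the prevalence and the total-count rule."""
    params = params or OtuFilterParams()
    counts = table.counts.to_numpy()
    n_samples = counts.shape[1]
    above = counts > params.min_count if params.strict else counts >= params.min_count
    prevalent = above.sum(axis=1) >= params.min_prevalence * n_samples
    totals = counts.sum(axis=1)
    abundant = totals > params.min_total if params.strict else totals >= params.min_total
    keep = prevalent & abundant
    taxonomy = table.taxonomy[keep] if table.taxonomy is not None else None
    return OtuTable(table.counts.loc[keep], table.groups.copy(), taxonomy)


def shannon(counts, base: str = "e") -> float:
    """Shannon index of one sample's OTU counts (nats; base='2' for bits)."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValidationError("Shannon index undefined for an all-zero sample")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    return h / np.log(2) if base == "2" else h


def richness(counts) -> int:
    return int((np.asarray(counts) > 0).sum())


def rarefaction_curve(
    counts, depths, reps: int = 100, seed: int | None = None
) -> pd.DataFrame:
    """Mean and sd of richness at each subsampling depth (without replacement).

    Draws are multivariate hypergeometric, the standard ecological
    rarefaction model. Returns a DataFrame (depth, mean_richness, sd_richness).
    """
    c = np.asarray(counts, dtype=int)
    total = int(c.sum())
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > total:
            raise ValidationError(f"depth {depth} exceeds sample total {total}")
        if depth == total:
            rows.append((depth, float(richness(c)), 0.0))
            continue
        rich = np.empty(reps)
        for r in range(reps):
            sub = rng.multivariate_hypergeometric(c, depth)
            rich[r] = richness(sub)
        rows.append((depth, float(rich.mean()), float(rich.std(ddof=1))))
    return pd.DataFrame(rows, columns=["depth", "mean_richness", "sd_richness"])


def bray_curtis(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities between sample columns."""
    counts = table.counts if isinstance(table, OtuTable) else table
    x = counts.to_numpy(dtype=float)
    totals = x.sum(axis=0)
    if (totals == 0).any():
        bad = list(counts.columns[totals == 0])
        raise ValidationError(f"empty sample(s): {bad}")
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(x[:, i][:, None], x[:, i + 1:])
        d[i, i + 1:] = 1.0 - 2.0 * mins.sum(axis=0) / (totals[i] + totals[i + 1:])
    d = d + d.T
    return pd.DataFrame(d, index=counts.columns, columns=counts.columns)


def _permanova_f(d2: np.ndarray, codes: np.ndarray, group_sizes: np.ndarray) -> float:
    n = len(codes)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g, size in enumerate(group_sizes):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(size, 1)].sum() / size
    k = len(group_sizes)
    ss_among = ss_total - ss_within
    return (ss_among / (k - 1)) / (ss_within / (n - k))


def permanova(
    dist, groups, n_perm: int = 999, seed: int | None = None
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``dist`` is a square symmetric matrix (DataFrame or array) and
    ``groups`` a factor over its samples. P is the permutation tail
    probability (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(
        dist, dtype=float
    )
    groups = np.asarray(groups)
    n = len(groups)
    if d.shape != (n, n):
        raise ValidationError("distance matrix shape does not match group labels")
    levels, codes = np.unique(groups, return_inverse=True)
    if len(levels) < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        bad = [str(levels[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValidationError(f"singleton group(s): {bad}")
    d2 = d**2
    f_obs = _permanova_f(d2, codes, sizes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_f(d2, perm, sizes) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        df_between=len(levels) - 1,
        df_within=n - len(levels),
        p=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def summary_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics; (t, df, two-sided p).

    ``variant``: "pooled" (classical Student) or "welch". Two degenerate
    equal-mean, zero-sd groups give t = 0, p = 1 rather than an error.
    """
    if sd1 < 0 or sd2 < 0 or n1 < 2 or n2 < 2:
        raise ValidationError("need sds >= 0 and n >= 2 in both groups")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            df = n1 + n2 - 2 if variant == "pooled" else float("nan")
            return 0.0, float(df), 1.0
        raise ValidationError("zero variance with unequal means: t undefined")
    if variant == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    elif variant == "welch":
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValidationError("variant must be 'pooled' or 'welch'")
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
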