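"""Statistics for the extraction-damage control assays.

Electrolyte leakage is expressed relative to the conductivity of fully
lysed tissue (100%). Treatment effects are tested with Welch's
heteroscedastic one-way ANOVA on jointly rank-transformed data (robust to
both non-normality and unequal variances at n = 4), followed by
Games-Howell pairwise post-hoc tests summarized as a compact letter
display. Microbial viability (CFU/g) is compared with a pooled-variance
Student t-test, optionally on log10 counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .synthetic import LeakageExperiment  # noqa: F401  (re-export)

log = logging.getLogger(__name__)

RANK_VARIANCE_FLOOR = 1e-12


@dataclass
class RwcMeasurement:
    """Soil relative-water-content weighing: fresh (W), dry (DW), saturated (SW)."""

    W: float
    DW: float
    SW: float

    def __post_init__(self) -> None:
        if not (self.SW >= self.W >= self.DW):
            raise ValidationError("require SW >= W >= DW")
        if self.SW <= self.DW:
            raise ValidationError("SW must exceed DW")


@dataclass
class PosthocResult:
    # (label_i, label_j, mean difference, q, df, p) per pair
    pairs: list[tuple[str, str, float, float, float, float]]
    letters: dict[str, str]
    alpha: float


def relative_conductivity(value: float, lysis_max: float) -> float:
    """Conductivity as a percentage of the full-lysis maximum."""
    if lysis_max <= 0:
        raise ValidationError("lysis_max must be > 0")
    if value < 0:
        raise ValidationError("conductivity cannot be negative")
    return 100.0 * value / lysis_max


def compute_rwc(m: RwcMeasurement) -> float:
    """Relative water content (W - DW) / (SW - DW), a fraction in [0, 1]."""
    return (m.W - m.DW) / (m.SW - m.DW)


def _check_groups(groups: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    small = [k for k, v in out.items() if len(v) < 2]
    if small:
        raise ValidationError(f"group(s) with fewer than 2 replicates: {small}")
    return out


def _welch_anova_raw(values: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA; returns (F, df1, df2, p)."""
    k = len(values)
    n = np.array([len(v) for v in values], dtype=float)
    m = np.array([v.mean() for v in values])
    s2 = np.array([max(v.var(ddof=1), RANK_VARIANCE_FLOOR) for v in values])
    w = n / s2
    w_sum = w.sum()
    grand = (w * m).sum() / w_sum
    a = (w * (m - grand) ** 2).sum() / (k - 1)
    lam = ((1 - w / w_sum) ** 2 / (n - 1)).sum() * 3.0 / (k**2 - 1)
    f = a / (1 + 2 * (k - 2) / 3 * lam)
    df1 = float(k - 1)
    df2 = 1.0 / lam if lam > 0 else np.inf
    p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else float("nan")
    if f == 0:
        p = 1.0
    return float(f), df1, float(df2), p


def welch_anova_ranked(groups: dict[str, np.ndarray]) -> tuple[float, float, float, float]:
    """Welch's F-test on jointly rank-transformed data; (F, df1, df2, p).

    Mid-ranks are used for ties; zero-variance rank groups get a tiny
    variance floor (with a warning) to keep the Welch weights finite. The
    result is invariant under any strictly monotone transform of the data.
    """
    groups = _check_groups(groups)
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    ranks = stats.rankdata(pooled)
    split = np.cumsum([len(groups[k]) for k in labels])[:-1]
    ranked = list(np.split(ranks, split))
    if any(v.var(ddof=1) == 0 for v in ranked) and len({float(v.mean()) for v in ranked}) > 1:
        log.warning("zero rank variance in a group; applying variance floor")
    return _welch_anova_raw(ranked)


def _compact_letter_display(
    labels: list[str], significant: set[frozenset], alpha: float
) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Each letter marks a set of groups with no significant pairwise
    difference inside it; groups sharing no letter differ at ``alpha``.
    Letters are assigned alphabetically in group-input order.
    """
    letter_sets: list[set[str]] = [set(labels)]
    for pair in significant:
        a, b = tuple(pair)
        for s in [s for s in letter_sets if a in s and b in s]:
            letter_sets.remove(s)
            s_a, s_b = s - {a}, s - {b}
            for cand in (s_a, s_b):
                if not any(cand <= other for other in letter_sets):
                    letter_sets.append(cand)
    # absorb: drop duplicates and sets contained in another
    unique = []
    for s in letter_sets:
        if s and s not in unique:
            unique.append(s)
    letter_sets = [s for s in unique if not any(s < other for other in unique)]
    # deterministic order: by first member's input position
    pos = {lab: i for i, lab in enumerate(labels)}
    letter_sets.sort(key=lambda s: sorted(pos[x] for x in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lab: "" for lab in labels}
    for i, s in enumerate(letter_sets):
        for lab in labels:
            if lab in s:
                letters[lab] += alphabet[i]
    return letters


def games_howell(groups: dict[str, np.ndarray], alpha: float = 0.05) -> PosthocResult:
    """Games-Howell pairwise comparisons with a compact letter display.

    Per pair: q = |mean_i - mean_j| / sqrt((s_i^2/n_i + s_j^2/n_j) / 2),
    Welch-Satterthwaite df, and p from the studentized-range distribution
    with k = number of groups. Two zero-variance groups with equal means get
    p = 1.
    """
    groups = _check_groups(groups)
    labels = list(groups)
    k = len(labels)
    pairs = []
    significant: set[frozenset] = set()
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[labels[i]], groups[labels[j]]
            va, vb = a.var(ddof=1), b.var(ddof=1)
            na, nb = len(a), len(b)
            diff = a.mean() - b.mean()
            if va == 0 and vb == 0:
                if diff == 0:
                    pairs.append((labels[i], labels[j], 0.0, 0.0, float("nan"), 1.0))
                    continue
                va = vb = RANK_VARIANCE_FLOOR
            se2 = va / na + vb / nb
            q = abs(diff) / np.sqrt(se2 / 2.0)
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
            p = float(stats.studentized_range.sf(q, k, df))
            pairs.append((labels[i], labels[j], float(diff), float(q), float(df), p))
            if p < alpha:
                significant.add(frozenset((labels[i], labels[j])))
    letters = _compact_letter_display(labels, significant, alpha)
    return PosthocResult(pairs=pairs, letters=letters, alpha=alpha)


def cfu_ttest(
    treated, control, log_transform: bool = False
) -> tuple[float, float, float]:
    """Pooled-variance Student t-test on CFU/g counts; (t, df, two-sided p)."""
    a = np.asarray(treated, dtype=float)
    b = np.asarray(control, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs at least 2 replicates")
    if log_transform:
        if (a <= 0).any() or (b <= 0).any():
            raise ValidationError(
                "zero CFU with log_transform; add a pseudo-count before testing"
            )
        a, b = np.log10(a), np.log10(b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, float(len(a) + len(b) - 2), 1.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(len(a) + len(b) - 2), float(res.pvalue)
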