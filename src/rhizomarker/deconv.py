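"""Adduct/isotope deconvolution and putative annotation of marker ions.

After marker selection, several ions typically stem from one neutral
compound: salt adducts ([M+Na]+, [M+HCOO]- ...) and 13C isotopologues share
the compound's retention time. Grouping works per RT bin: for every ion pair
and every ordered pair of distinct adduct rules, the two implied neutral
masses are compared; agreements within the m/z tolerance become edges, and
connected components become compound groups. Isotope edges connect ions one
or two 13C mass shifts apart. Ungrouped ions stay singletons interpreted via
the mode's default rule ([M+H]+ / [M-H]-).

Default tolerances are m/z 0.1 Da and RT 10 s; only singly charged ions are
considered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CompoundRecord
from .errors import ValidationError
from .masses import C13_C12_DELTA, ELECTRON_MASS, MONOISOTOPIC, PROTON_MASS
from .masses import formula_to_monoisotopic_mass  # noqa: F401  (module surface)


@dataclass(frozen=True)
class AdductRule:
    label: str
    mode: str  # "positive" | "negative"
    mass_shift: float  # Da, neutral M -> observed m/z (z = 1)
    charge: int  # +1 | -1

    def __post_init__(self) -> None:
        if self.charge not in (1, -1):
            raise ValidationError(f"{self.label}: only singly charged adducts supported")
        expected = "positive" if self.charge == 1 else "negative"
        if self.mode != expected:
            raise ValidationError(f"{self.label}: mode {self.mode} inconsistent with charge")


_NA, _K, _CL = MONOISOTOPIC["Na"], MONOISOTOPIC["K"], MONOISOTOPIC["Cl"]
_NH4 = MONOISOTOPIC["N"] + 4 * MONOISOTOPIC["H"]
_HCOO = MONOISOTOPIC["C"] + MONOISOTOPIC["H"] + 2 * MONOISOTOPIC["O"]

#: Rule sets for formic-acid-acidified electrospray.
POSITIVE_RULES = (
    AdductRule("[M+H]+", "positive", PROTON_MASS, 1),
    AdductRule("[M+Na]+", "positive", _NA - ELECTRON_MASS, 1),
    AdductRule("[M+K]+", "positive", _K - ELECTRON_MASS, 1),
    AdductRule("[M+NH4]+", "positive", _NH4 - ELECTRON_MASS, 1),
)
NEGATIVE_RULES = (
    AdductRule("[M-H]-", "negative", -PROTON_MASS, -1),
    AdductRule("[M+HCOO]-", "negative", _HCOO + ELECTRON_MASS, -1),
    AdductRule("[M+Cl]-", "negative", _CL + ELECTRON_MASS, -1),
)
DEFAULT_RULES = {"positive": POSITIVE_RULES, "negative": NEGATIVE_RULES}
DEFAULT_RULE = {"positive": POSITIVE_RULES[0], "negative": NEGATIVE_RULES[0]}


def rules_by_label(mode: str) -> dict[str, AdductRule]:
    return {r.label: r for r in DEFAULT_RULES[mode]}


@dataclass
class DeconvParams:
    mz_tol: float = 0.1  # Da
    rt_tol: float = 10.0  # seconds
    isotope_delta: float = C13_C12_DELTA
    max_isotopes: int = 2

    def __post_init__(self) -> None:
        if self.mz_tol <= 0 or self.rt_tol <= 0:
            raise ValidationError("tolerances must be > 0")


@dataclass
class AdductGroup:
    member_ids: list[str]
    labels: dict[str, str]  # feature_id -> adduct/isotope label
    neutral_mass: float
    rt_centroid: float
    support: int  # number of independent adduct assignments


@dataclass
class Annotation:
    group: AdductGroup
    matches: list[tuple[CompoundRecord, float]]  # (record, mass error Da), by |error|
    met_class: str
    excluded: bool
    reason: str = ""


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _as_ion_frame(ions) -> pd.DataFrame:
    if isinstance(ions, pd.DataFrame):
        df = ions.copy()
        if "feature_id" in df.columns:
            df = df.set_index("feature_id")
        return df[["mz", "rt", "mode"]]
    rows = {i.feature_id: (i.mz, i.rt, i.mode) for i in ions}
    return pd.DataFrame.from_dict(rows, orient="index", columns=["mz", "rt", "mode"])


def group_adducts_isotopes(
    ions,
    params: DeconvParams | None = None,
    rules: tuple[AdductRule, ...] | None = None,
) -> list[AdductGroup]:
    """Group co-eluting marker ions into compound groups with neutral masses.

    ``ions``: DataFrame (feature_id index or column; mz, rt, mode columns) or
    a sequence of :class:`~rhizomarker.dataio.IonFeature`. All ions must share
    one ionization mode.
    """
    params = params or DeconvParams()
    df = _as_ion_frame(ions)
    if df.empty:
        return []
    modes = df["mode"].unique()
    if len(modes) > 1:
        raise ValidationError(f"mixed ionization modes {sorted(modes)}: deconvolve per mode")
    mode = modes[0]
    if rules is None:
        rules = DEFAULT_RULES[mode]
    if not rules:
        raise ValidationError("empty adduct rule set")

    # deterministic processing order, independent of input order
    df = df.sort_values(["rt", "mz"], kind="mergesort")
    df = df[~df.index.duplicated(keep="first")]
    ids = df.index.to_numpy()
    mz = df["mz"].to_numpy()
    rt = df["rt"].to_numpy()
    n = len(df)

    # RT single-linkage bins: split where consecutive gap exceeds rt_tol
    bin_breaks = np.flatnonzero(np.diff(rt) > params.rt_tol) + 1
    shifts = np.array([r.mass_shift for r in rules])

    uf = _UnionFind(n)
    # edge evidence: (i, rule_index, implied neutral mass)
    evidence: dict[int, list[tuple[int, int, float]]] = {}
    iso_links: list[tuple[int, int, int]] = []  # (parent idx, iso idx, n 13C)

    is_isotope = np.zeros(n, dtype=bool)
    for lo, hi in zip(np.r_[0, bin_breaks], np.r_[bin_breaks, n]):
        idx = np.arange(lo, hi)
        if len(idx) < 2:
            continue
        order = idx[np.argsort(mz[idx], kind="mergesort")]
        # pass 1: isotopologue detection, light to heavy; an isotope attaches
        # to the nearest lighter non-isotope ion at k x the 13C shift
        for bi, j in enumerate(order):
            for i in order[:bi][::-1]:
                if is_isotope[i]:
                    continue
                dmz = mz[j] - mz[i]
                if dmz - params.max_isotopes * params.isotope_delta > params.mz_tol:
                    break
                for k in range(1, params.max_isotopes + 1):
                    if abs(dmz - k * params.isotope_delta) <= params.mz_tol:
                        uf.union(i, j)
                        iso_links.append((i, j, k))
                        is_isotope[j] = True
                        break
                if is_isotope[j]:
                    break
        # pass 2: adduct-pair hypotheses among the remaining parent ions
        parents = [i for i in order if not is_isotope[i]]
        neutral = {i: mz[i] - shifts for i in parents}
        for a_i, i in enumerate(parents):
            for j in parents[a_i + 1:]:
                diff = np.abs(neutral[i][:, None] - neutral[j][None, :])
                np.fill_diagonal(diff, np.inf)  # same rule twice is not adduct evidence
                hits = np.argwhere(diff <= params.mz_tol)
                for r, s in hits:
                    uf.union(i, j)
                    ev = evidence.setdefault(uf.find(i), [])
                    ev.append((i, int(r), neutral[i][r]))
                    ev.append((j, int(s), neutral[j][s]))

    # components -> groups
    comp: dict[int, list[int]] = {}
    for i in range(n):
        comp.setdefault(uf.find(i), []).append(i)
    # merge evidence keyed by stale roots
    merged_evidence: dict[int, list[tuple[int, int, float]]] = {}
    for root, ev in evidence.items():
        merged_evidence.setdefault(uf.find(root), []).extend(ev)

    groups: list[AdductGroup] = []
    default_rule = DEFAULT_RULE[mode]
    for root in sorted(comp):
        members = comp[root]
        iso_here = {b: (a, k) for a, b, k in iso_links if uf.find(a) == root}
        parents = [i for i in members if i not in iso_here]
        ev = merged_evidence.get(root, [])
        labels: dict[str, str] = {}
        if ev:
            # per-parent adduct assignment by majority vote over edge evidence,
            # ties by smaller |implied - consensus|
            assign: dict[int, tuple[int, float]] = {}
            consensus = float(np.mean([m for _, _, m in ev]))
            for i in parents:
                votes: dict[int, list[float]] = {}
                for j, r, m in ev:
                    if j == i:
                        votes.setdefault(r, []).append(m)
                if votes:
                    r_best = min(
                        votes,
                        key=lambda r: (-len(votes[r]), abs(np.mean(votes[r]) - consensus)),
                    )
                    assign[i] = (r_best, float(np.mean(votes[r_best])))
            implied = [m for _, m in assign.values()]
            neutral_mass = float(np.mean(implied))
            support = len(assign)
            for i in parents:
                if i in assign:
                    labels[ids[i]] = rules[assign[i][0]].label
                else:
                    labels[ids[i]] = "?"
        else:
            # singleton (or isotope-only pair): default-rule interpretation
            neutral_mass = float(mz[parents[0]] - default_rule.mass_shift)
            support = 1
            labels[ids[parents[0]]] = default_rule.label
            for i in parents[1:]:
                labels[ids[i]] = default_rule.label
        for b, (a, k) in iso_here.items():
            parent_label = labels.get(ids[a], default_rule.label)
            labels[ids[b]] = f"{parent_label} +{k}x13C"
        groups.append(
            AdductGroup(
                member_ids=[ids[i] for i in members],
                labels=labels,
                neutral_mass=neutral_mass,
                rt_centroid=float(np.mean(rt[members])),
                support=support,
            )
        )
    return groups


def annotate_groups(
    groups: list[AdductGroup],
    library: list[CompoundRecord],
    match_tol: float = 0.1,
) -> list[Annotation]:
    """Match group neutral masses against the compound library.

    Every record within ``match_tol`` Da is a putative match (sorted by
    absolute mass error). Implausible matches (synthetic drugs, mammalian
    hormones) stay listed but are flagged; an annotation whose matches are
    all implausible is excluded from composition profiles. No match at all
    means class "unknown".
    """
    if not library:
        raise ValidationError("empty compound library")
    annotations = []
    for g in groups:
        matches = sorted(
            ((rec, g.neutral_mass - rec.monoisotopic_mass) for rec in library
             if abs(g.neutral_mass - rec.monoisotopic_mass) <= match_tol),
            key=lambda pair: abs(pair[1]),
        )
        plausible = [(rec, err) for rec, err in matches if rec.plausible_in_soil]
        if not matches:
            annotations.append(Annotation(g, [], "unknown", False))
        elif plausible:
            annotations.append(Annotation(g, matches, plausible[0][0].met_class, False))
        else:
            annotations.append(
                Annotation(g, matches, matches[0][0].met_class, True,
                           reason="only implausible matches (e.g. synthetic drug or "
                                  "mammalian hormone)")
            )
    return annotations


def class_composition(annotations: list[Annotation]) -> dict[str, float]:
    """Percentage of (non-excluded) marker groups per metabolite class.

    Each annotation counts once; several groups resolving to the same library
    compound each count (additive counting). Raises when every annotation is
    excluded.
    """
    if not annotations:
        raise ValidationError("no annotations given")
    kept = [a for a in annotations if not a.excluded]
    if not kept:
        raise ValidationError("empty composition: all annotations excluded")
    counts: dict[str, int] = {}
    for a in kept:
        counts[a.met_class] = counts.get(a.met_class, 0) + 1
    total = sum(counts.values())
    return {cls: 100.0 * c / total for cls, c in sorted(counts.items())}
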