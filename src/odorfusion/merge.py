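"""Pairwise merging of response datasets into a consensus profile.

The algorithm: (1) every dataset is rescaled to [0, 1]; (2) two datasets
with at least ``overlap_min`` (default 5) common odorants are merged by
fitting the ten candidate monotone models on the common odorants, choosing
the fit with the lowest mean orthogonal distance (MD), projecting common
odorants onto the nearest curve point and unique odorants directly onto the
curve, and taking the arc-length coordinate of each projection as the
merged value, rescaled to [0, 1]; (3) repeat until one profile remains.

Because the result depends on the merge order, the order is chosen either
by scoring every permutation (the fold result is compared against every
input dataset and the permutation with the lowest average MD wins) or, when
the permutation count is infeasible, greedily by always merging the
currently best-fitting pair.  Datasets that never reach the overlap
minimum, or whose best fit exceeds the MD cap (default 0.1*sqrt(2), i.e.
10% of the response-space diagonal), are excluded and logged, never fatal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import (
    FAMILY_ORDER,
    FittedCurve,
    compute_md,
    fit_family,
    project_onto_curve,
)
from .datasets import SCALE_GLOBAL, SCALE_UNIT, ResponseMatrix, StudyDataset, rescale_unit_interval
from .identifiers import SFR_KEY

DEFAULT_MD_CAP = 0.1 * math.sqrt(2.0)

EXCL_TOO_FEW = "too-few-overlap"
EXCL_MD_CAP = "md-above-cap"


@dataclass
class MergeConfig:
    overlap_min: int = 5
    md_cap: float = DEFAULT_MD_CAP
    strategy: str = "auto"  # auto | exhaustive | greedy
    permutation_cap: int = 10_000
    allow_flat: bool = False

    @classmethod
    def from_file(cls, path) -> "MergeConfig":
        """Read a key=value config file ('#' starts a comment)."""
        kwargs: dict = {}
        casts = {
            "overlap_min": int,
            "md_cap": float,
            "permutation_cap": int,
            "strategy": str,
            "allow_flat": lambda v: v.lower() in ("1", "true", "yes"),
        }
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                if key not in casts:
                    raise KeyError(f"unknown merge config key: {key}")
                kwargs[key] = casts[key](value.strip())
        return cls(**kwargs)


class MergeExclusion(Exception):
    """A pair cannot be merged; carries the exclusion reason."""

    def __init__(self, reason: str, detail: str = ""):
        super().__init__(f"{reason}: {detail}" if detail else reason)
        self.reason = reason


class InsufficientOverlapError(ValueError):
    pass


class NoValidModelError(RuntimeError):
    pass


@dataclass
class ModelFit:
    """One candidate monotone fit between two datasets."""

    family: str
    orientation: str  # forward: y = f(x); inverse: x = f(y)
    params: np.ndarray
    curve: FittedCurve
    md: float
    n_common: int

    @property
    def overlap_range(self) -> tuple[float, float]:
        return self.curve.overlap_range

    @property
    def label(self) -> str:
        return self.family + ("" if self.orientation == "forward" else "-inverse")


@dataclass
class MergeStep:
    left: str
    right: str
    chosen: ModelFit
    merged_id: str


@dataclass
class ConsensusProfile:
    unit_id: str
    values: pd.Series  # odorant -> [0, 1]
    included_studies: list[str]
    excluded_studies: list[tuple[str, str]]  # (study, reason)
    merge_log: list[MergeStep]
    strategy: str
    fit_log: list[str] = field(default_factory=list)


def _family_rank(fit: ModelFit) -> tuple:
    return (
        fit.md,
        FAMILY_ORDER.index(fit.family),
        0 if fit.orientation == "forward" else 1,
    )


def fit_candidate_models(x, y, fit_log: list[str] | None = None) -> list[ModelFit]:
    """Fit all ten candidate models (5 families x forward/inverse).

    Non-convergent or non-monotone fits are dropped with a logged reason.
    The survivors are sorted by MD (ties: fixed family order, forward
    before inverse).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise InsufficientOverlapError(
            f"insufficient overlap: {x.size} common odorants"
        )
    fits: list[ModelFit] = []
    for family in FAMILY_ORDER:
        for orientation in ("forward", "inverse"):
            u, v = (x, y) if orientation == "forward" else (y, x)
            params = fit_family(family, u, v)
            label = family + ("" if orientation == "forward" else "-inverse")
            if params is None:
                if fit_log is not None:
                    fit_log.append(f"{label}\tdropped\tno convergent start")
                continue
            curve = FittedCurve(
                family=family,
                params=params,
                orientation=orientation,
                t_range=(float(np.min(u)), float(np.max(u))),
            )
            if not curve.is_monotone():
                if fit_log is not None:
                    fit_log.append(f"{label}\tdropped\tnon-monotone on overlap")
                continue
            md = compute_md(curve, x, y)
            fits.append(
                ModelFit(
                    family=family,
                    orientation=orientation,
                    params=params,
                    curve=curve,
                    md=md,
                    n_common=int(x.size),
                )
            )
            if fit_log is not None:
                fit_log.append(f"{label}\tfit\tMD={md:.6g}")
    if not fits:
        raise NoValidModelError("no valid model: all candidate fits failed")
    fits.sort(key=_family_rank)
    return fits


def best_fit_md(a: pd.Series, b: pd.Series, config: MergeConfig) -> ModelFit:
    """Best candidate fit between two unit-scaled profiles (no cap applied)."""
    common = a.dropna().index.intersection(b.dropna().index)
    if len(common) < config.overlap_min:
        raise MergeExclusion(EXCL_TOO_FEW, f"{len(common)} common odorants")
    fits = fit_candidate_models(a[common].to_numpy(), b[common].to_numpy())
    return fits[0]


def merge_pair(
    a: pd.Series,
    b: pd.Series,
    config: MergeConfig | None = None,
    fit_log: list[str] | None = None,
) -> tuple[pd.Series, ModelFit]:
    """Merge two unit-scaled profiles into one [0, 1] profile.

    Raises :class:`MergeExclusion` when the pair has too few common
    odorants or the best MD exceeds the cap.
    """
    config = config or MergeConfig()
    a = a.astype(float)
    b = b.astype(float)
    common = a.dropna().index.intersection(b.dropna().index)
    if len(common) < config.overlap_min:
        raise MergeExclusion(EXCL_TOO_FEW, f"{len(common)} common odorants")
    fits = fit_candidate_models(
        a[common].to_numpy(), b[common].to_numpy(), fit_log=fit_log
    )
    best = fits[0]
    if best.md > config.md_cap:
        raise MergeExclusion(
            EXCL_MD_CAP, f"best MD {best.md:.6g} > cap {config.md_cap:.6g}"
        )
    curve = best.curve
    merged: dict[str, float] = {}
    a_idx = set(a.dropna().index)
    b_idx = set(b.dropna().index)
    for odorant in sorted(a_idx | b_idx):
        xv = float(a[odorant]) if odorant in a_idx else None
        yv = float(b[odorant]) if odorant in b_idx else None
        _, s = project_onto_curve((xv, yv), curve)
        merged[odorant] = s
    series = pd.Series(merged).sort_index()
    series = rescale_unit_interval(series, allow_flat=config.allow_flat)
    return series, best


def _fold_merge(
    profiles: dict[str, pd.Series],
    order: tuple[str, ...],
    config: MergeConfig,
    log: list[MergeStep] | None = None,
    fit_log: list[str] | None = None,
    excluded: list[tuple[str, str]] | None = None,
) -> pd.Series:
    """Merge profiles left to right along ``order``.

    A step that signals exclusion drops the right operand (recorded in
    ``excluded``) and continues.
    """
    acc = profiles[order[0]].astype(float)
    acc_id = order[0]
    for step, right in enumerate(order[1:], start=1):
        try:
            merged, fit = merge_pair(acc, profiles[right], config, fit_log=fit_log)
        except MergeExclusion as exc:
            if excluded is not None:
                excluded.append((right, exc.reason))
            continue
        merged_id = f"({acc_id}+{right})"
        if log is not None:
            log.append(MergeStep(left=acc_id, right=right, chosen=fit, merged_id=merged_id))
        acc, acc_id = merged, merged_id
    return acc


def _avg_md_against_inputs(
    merged: pd.Series, profiles: dict[str, pd.Series], config: MergeConfig
) -> float:
    """Average best-fit MD of the merged profile against every input."""
    mds = []
    for sid in sorted(profiles):
        try:
            mds.append(best_fit_md(merged, profiles[sid], config).md)
        except (MergeExclusion, NoValidModelError):
            mds.append(np.inf)
    return float(np.mean(mds))


@dataclass
class MergePlan:
    """Either a left-to-right fold order (exhaustive/trivial) or explicit
    pair steps (greedy, where merges need not form a single fold chain)."""

    order: tuple[str, ...]
    strategy: str
    score: float | None = None  # exhaustive: winning average MD
    steps: list[tuple[str, str]] = field(default_factory=list)  # greedy pairs
    leftovers: list[str] = field(default_factory=list)  # greedy: never merged


def select_merge_order(
    profiles: dict[str, pd.Series],
    config: MergeConfig | None = None,
) -> MergePlan:
    """Choose the merge order.

    exhaustive -- fold-merge every permutation, score each result by its
    average MD against every single input dataset, keep the minimum (ties:
    lexicographically first permutation).  greedy -- repeatedly merge the
    pair with the lowest MD.  auto -- exhaustive iff the permutation count
    does not exceed ``permutation_cap``.
    """
    config = config or MergeConfig()
    ids = sorted(profiles)
    if len(ids) < 2:
        return MergePlan(order=tuple(ids), strategy="trivial")
    strategy = config.strategy
    if strategy == "auto":
        strategy = (
            "exhaustive"
            if math.factorial(len(ids)) <= config.permutation_cap
            else "greedy"
        )
    if strategy == "exhaustive":
        best_perm, best_score = None, np.inf
        for perm in itertools.permutations(ids):
            merged = _fold_merge(profiles, perm, config)
            score = _avg_md_against_inputs(merged, profiles, config)
            if score < best_score - 1e-15:
                best_perm, best_score = perm, score
        return MergePlan(order=best_perm, strategy="exhaustive", score=best_score)
    if strategy != "greedy":
        raise ValueError(f"unknown strategy: {config.strategy}")
    pool = {sid: profiles[sid].astype(float) for sid in ids}
    steps: list[tuple[str, str]] = []
    while len(pool) > 1:
        best_key, best_md = None, np.inf
        for left, right in itertools.combinations(sorted(pool), 2):
            try:
                md = best_fit_md(pool[left], pool[right], config).md
            except (MergeExclusion, NoValidModelError):
                continue
            if md <= config.md_cap and md < best_md - 1e-15:
                best_key, best_md = (left, right), md
        if best_key is None:
            break
        left, right = best_key
        merged, _ = merge_pair(pool[left], pool[right], config)
        steps.append((left, right))
        new_id = f"({left}+{right})"
        del pool[left], pool[right]
        pool[new_id] = merged
    leftovers = sorted(sid for sid in pool if sid in ids)
    return MergePlan(order=tuple(ids), strategy="greedy", steps=steps, leftovers=leftovers)


def _largest_component(
    profiles: dict[str, pd.Series], overlap_min: int
) -> tuple[set[str], list[tuple[str, str]]]:
    """Connected component (>= overlap_min shared odorants) to merge.

    Components are ranked by total odorant coverage (ties: containing the
    lexicographically smallest id); everything else is excluded as
    too-few-overlap.
    """
    ids = sorted(profiles)
    adj = {i: set() for i in ids}
    for a, b in itertools.combinations(ids, 2):
        n = len(
            profiles[a].dropna().index.intersection(profiles[b].dropna().index)
        )
        if n >= overlap_min:
            adj[a].add(b)
            adj[b].add(a)
    seen: set[str] = set()
    components: list[set[str]] = []
    for i in ids:
        if i in seen:
            continue
        comp, stack = set(), [i]
        while stack:
            j = stack.pop()
            if j in comp:
                continue
            comp.add(j)
            stack.extend(adj[j] - comp)
        seen |= comp
        components.append(comp)
    def coverage(comp: set[str]) -> int:
        odorants = set()
        for sid in comp:
            odorants |= set(profiles[sid].dropna().index)
        return len(odorants)

    components.sort(key=lambda c: (-coverage(c), min(c)))
    keep = components[0]
    excluded = [(sid, EXCL_TOO_FEW) for sid in ids if sid not in keep]
    return keep, excluded


def merge_unit(
    datasets: list[StudyDataset],
    config: MergeConfig | None = None,
    unit_id: str | None = None,
) -> ConsensusProfile:
    """Merge all of one responding unit's datasets into a consensus profile."""
    config = config or MergeConfig()
    if not datasets:
        raise ValueError("no datasets given")
    unit_id = unit_id or datasets[0].unit_id
    profiles = {
        ds.study_id: ds.scaled(allow_flat=config.allow_flat) for ds in datasets
    }
    keep, excluded = _largest_component(profiles, config.overlap_min)
    if len(datasets) == 1:
        keep = set(profiles)
        excluded = []
    pool = {sid: profiles[sid] for sid in keep}
    merge_log: list[MergeStep] = []
    fit_log: list[str] = []
    if len(pool) == 1:
        (only_id, only) = next(iter(pool.items()))
        values = rescale_unit_interval(only, allow_flat=config.allow_flat)
        return ConsensusProfile(
            unit_id=unit_id,
            values=values.sort_index(),
            included_studies=[only_id],
            excluded_studies=sorted(excluded),
            merge_log=[],
            strategy="trivial",
            fit_log=fit_log,
        )
    plan = select_merge_order(pool, config)
    step_excluded: list[tuple[str, str]] = []
    if plan.strategy == "greedy":
        working = dict(pool)
        for left, right in plan.steps:
            merged, fit = merge_pair(working[left], working[right], config, fit_log=fit_log)
            merged_id = f"({left}+{right})"
            merge_log.append(
                MergeStep(left=left, right=right, chosen=fit, merged_id=merged_id)
            )
            del working[left], working[right]
            working[merged_id] = merged
        step_excluded = [(sid, EXCL_MD_CAP) for sid in plan.leftovers]
        if plan.steps:
            final_id = max(working, key=len)
            merged = working[final_id]
        else:
            # nothing mergeable: keep the profile covering the most odorants
            best = max(
                sorted(working), key=lambda sid: working[sid].dropna().size
            )
            merged = working[best]
            step_excluded = [
                (sid, EXCL_MD_CAP) for sid in plan.leftovers if sid != best
            ]
    else:
        merged = _fold_merge(
            pool, plan.order, config, log=merge_log, fit_log=fit_log, excluded=step_excluded
        )
    excluded = sorted(excluded + step_excluded)
    included = [sid for sid in sorted(keep) if sid not in {e[0] for e in excluded}]
    if not included:
        raise ValueError(
            "zero includable datasets: "
            + "; ".join(f"{sid} ({reason})" for sid, reason in excluded)
        )
    values = rescale_unit_interval(merged, allow_flat=config.allow_flat)
    return ConsensusProfile(
        unit_id=unit_id,
        values=values.sort_index(),
        included_studies=included,
        excluded_studies=excluded,
        merge_log=merge_log,
        strategy=plan.strategy,
        fit_log=fit_log,
    )


def write_merge_log(profile: ConsensusProfile, path) -> None:
    """Tab-separated merge log: candidate fits and chosen merge steps."""
    with open(path, "w") as fh:
        for line in profile.fit_log:
            fh.write(f"candidate\t{line}\n")
        for i, step in enumerate(profile.merge_log, start=1):
            params = ",".join(f"{p:.6g}" for p in step.chosen.params)
            fh.write(
                f"step{i}\t{step.left}\t{step.right}\t{step.chosen.label}\t"
                f"{params}\t{step.chosen.md:.6g}\tmerged\n"
            )
        for sid, reason in profile.excluded_studies:
            fh.write(f"excluded\t{sid}\t\t\t\t\t{reason}\n")


def global_normalize(
    consensus: dict[str, pd.Series],
    studies: list[StudyDataset],
) -> ResponseMatrix:
    """Rescale the units' response ranges relative to each other.

    Studies that recorded more than one responding unit carry the relative
    scale information: each such study is scaled to [0, 1] jointly across
    all its units, and a unit's factor is the largest scaled response it
    reaches in any of those studies.  Factors are normalized so the largest
    is 1; units absent from every multi-unit study keep factor 1 and are
    flagged.  The matrix maximum after normalization is 1.
    """
    by_study: dict[str, list[StudyDataset]] = {}
    for ds in studies:
        by_study.setdefault(ds.study_id, []).append(ds)
    factors: dict[str, float] = {}
    for sid, group in sorted(by_study.items()):
        units = {ds.unit_id for ds in group}
        if len(units) < 2:
            continue
        pooled = np.concatenate([ds.responses.to_numpy(dtype=float) for ds in group])
        lo, hi = float(np.min(pooled)), float(np.max(pooled))
        if hi == lo:
            continue
        for ds in group:
            m = (float(ds.responses.max()) - lo) / (hi - lo)
            factors[ds.unit_id] = max(factors.get(ds.unit_id, 0.0), m)
    flags: dict[str, str] = {}
    if factors:
        top = max(factors.values())
        if top > 0:
            factors = {u: f / top for u, f in factors.items()}
    df = pd.DataFrame(consensus)
    for unit in df.columns:
        if unit in factors:
            df[unit] = df[unit] * factors[unit]
        else:
            flags[unit] = "no-multi-unit-study"
    return ResponseMatrix(
        values=df,
        scale_state=SCALE_GLOBAL if factors else SCALE_UNIT,
        normalization_flags=flags,
    )
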