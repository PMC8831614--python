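"""Comparative statistics and the discovery filter cascade.

Mirrors the classic comparative-metabolomics funnel: remove features that
are not clearly more abundant in biological samples than in blanks, compute
group-wise fold changes and significance (Welch t-test per group vs control,
one-way ANOVA across groups, unadjusted by default), then cull by fold
change, p-value, intensity percentile, presence and RT window. Missing
intensities count as zero in group means, matching a fill-then-compare
workflow.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .features import FeatureTable

__all__ = [
    "FilterSpec",
    "blank_subtract",
    "group_statistics",
    "top_intensity_filter",
    "apply_filters",
    "bh_adjust",
]


def _group_matrix(table: FeatureTable, group: str) -> np.ndarray:
    cols = table.group_samples(group)
    return table.df[cols].fillna(0.0).to_numpy(dtype=float)


def blank_subtract(
    table: FeatureTable,
    sample_groups: Sequence[str],
    blank_group: str,
    min_fold: float = 10.0,
) -> FeatureTable:
    """Remove features not at least ``min_fold`` more abundant in biological
    samples than in blanks.

    A feature is kept iff mean(sample groups) >= min_fold * mean(blanks);
    features absent from blanks (blank mean 0) are always kept when they
    carry any sample signal.
    """
    for g in list(sample_groups) + [blank_group]:
        table.group_samples(g)  # raises on unknown labels
    sample_cols = [s for g in sample_groups for s in table.group_samples(g)]
    sample_mean = table.df[sample_cols].fillna(0.0).mean(axis=1)
    blank_mean = table.df[table.group_samples(blank_group)].fillna(0.0).mean(axis=1)
    keep = (sample_mean >= min_fold * blank_mean) & (sample_mean > 0)
    keep |= (blank_mean == 0) & (sample_mean > 0)
    out = table.with_df(table.df.loc[keep].copy())
    out.log(
        "blank_subtract",
        {"sample_groups": list(sample_groups), "blank_group": blank_group, "min_fold": min_fold},
        n_removed=int((~keep).sum()),
        n_kept=int(keep.sum()),
    )
    return out


def group_statistics(
    table: FeatureTable,
    control: str,
    groups: Optional[Sequence[str]] = None,
) -> FeatureTable:
    """Per-feature group means, fold changes vs control, Welch t-tests and
    one-way ANOVA.

    Adds columns ``mean_<g>`` for every group, and ``fold_<g>``, ``t_<g>``,
    ``p_<g>`` for every non-control group (Welch unequal-variance two-sided
    t-test, unadjusted), plus ``anova_F`` / ``anova_p`` when more than one
    comparison group exists. Fold change is mean(group) / max(mean(control),
    eps) with eps = 1e-3 x the smallest positive intensity in the table, so
    features absent from the control survive fold filters.
    """
    if groups is None:
        groups = table.group_labels()
    if control not in groups:
        raise KeyError(f"control group {control!r} not among {list(groups)}")
    df = table.df.copy()
    mats = {g: _group_matrix(table, g) for g in groups}
    for g in groups:
        df[f"mean_{g}"] = mats[g].mean(axis=1)

    pos = df[table.samples].to_numpy(dtype=float)
    pos = pos[np.isfinite(pos) & (pos > 0)]
    eps = (pos.min() * 1e-3) if pos.size else 1e-12
    ctrl = mats[control]
    ctrl_mean = np.maximum(ctrl.mean(axis=1), eps)

    for g in groups:
        if g == control:
            continue
        df[f"fold_{g}"] = mats[g].mean(axis=1) / ctrl_mean
        if mats[g].shape[1] < 2 or ctrl.shape[1] < 2:
            _warnings.warn(
                f"group {g!r} or control has < 2 samples; t-test columns set to NaN"
            )
            df[f"t_{g}"] = np.nan
            df[f"p_{g}"] = np.nan
            continue
        t, p = stats.ttest_ind(mats[g], ctrl, axis=1, equal_var=False)
        # identical groups give 0/0 -> NaN; by convention no evidence => p=1
        t = np.where(np.isnan(t), 0.0, t)
        p = np.where(np.isnan(p), 1.0, p)
        df[f"t_{g}"], df[f"p_{g}"] = t, p

    if len(groups) >= 2 and all(mats[g].shape[1] >= 2 for g in groups):
        F, p = stats.f_oneway(*[mats[g] for g in groups], axis=1)
        df["anova_F"] = np.where(np.isnan(F), 0.0, F)
        df["anova_p"] = np.where(np.isnan(p), 1.0, p)

    out = table.with_df(df)
    out.log("group_statistics", {"control": control, "groups": list(groups)})
    return out


def top_intensity_filter(table: FeatureTable, fraction: float) -> FeatureTable:
    """Keep the top ``ceil(fraction * N)`` features by overall mean
    intensity (ties broken by feature id)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(table.df)
    if n == 0:
        raise ValueError("cannot rank an empty table")
    k = math.ceil(fraction * n)
    mean = table.df[table.samples].fillna(0.0).mean(axis=1)
    order = sorted(table.df.index, key=lambda i: (-mean[i], str(i)))
    keep = set(order[:k])
    out = table.with_df(table.df.loc[[i for i in table.df.index if i in keep]].copy())
    out.log("top_intensity_filter", {"fraction": fraction}, n_kept=k, n_removed=n - k)
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (opt-in; the default cascade is
    unadjusted)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass
class FilterSpec:
    """Ordered predicate set for the discovery cascade.

    All predicates are optional and applied in declared order:
    ``min_fold`` on ``fold_<fold_group>``, ``max_p`` on ``p_<fold_group>``,
    ``top_fraction`` by overall mean intensity, ``min_mean_intensity``,
    ``present_in`` (group, minimum number of detected samples), and
    ``rt_range`` in seconds.
    """

    fold_group: Optional[str] = None
    min_fold: Optional[float] = None
    max_p: Optional[float] = None
    top_fraction: Optional[float] = None
    min_mean_intensity: Optional[float] = None
    present_in: Optional[Tuple[str, int]] = None
    rt_range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.top_fraction is not None and not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        for name in ("min_fold", "max_p", "min_mean_intensity"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "FilterSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("present_in"):
            raw["present_in"] = tuple(raw["present_in"])
        if raw.get("rt_range"):
            raw["rt_range"] = tuple(raw["rt_range"])
        return cls(**raw)


def apply_filters(
    table: FeatureTable,
    spec: FilterSpec,
    control: Optional[str] = None,
) -> FeatureTable:
    """Apply a :class:`FilterSpec` cascade; survivor counts per predicate go
    to provenance.

    Statistics columns referenced by the spec are computed on demand when a
    ``control`` group is given; a missing column without a way to compute it
    raises KeyError.
    """
    out = table
    needs_stats = spec.fold_group is not None and (
        spec.min_fold is not None or spec.max_p is not None
    )
    if needs_stats and f"fold_{spec.fold_group}" not in out.df.columns:
        if control is None:
            raise KeyError(
                f"column fold_{spec.fold_group} missing and no control group given"
            )
        out = group_statistics(out, control)
    # predicates are a conjunction evaluated against the *input* table: the
    # intensity percentile refers to all detected features, not to whatever
    # earlier predicates left over
    base = out.df
    keep = pd.Series(True, index=base.index)
    counts: List[Tuple[str, int]] = []

    def cut(mask: pd.Series, label: str) -> None:
        nonlocal keep
        keep &= mask
        counts.append((label, int(keep.sum())))

    if spec.min_fold is not None:
        col = f"fold_{spec.fold_group}"
        if col not in base.columns:
            raise KeyError(f"missing column {col}")
        cut(base[col] >= spec.min_fold, f"fold>={spec.min_fold}")
    if spec.max_p is not None:
        col = f"p_{spec.fold_group}"
        if col not in base.columns:
            raise KeyError(f"missing column {col}")
        cut(base[col] < spec.max_p, f"p<{spec.max_p}")
    if spec.top_fraction is not None and len(base):
        k = math.ceil(spec.top_fraction * len(base))
        mean = base[out.samples].fillna(0.0).mean(axis=1)
        order = sorted(base.index, key=lambda i: (-mean[i], str(i)))
        top = pd.Series(base.index.isin(order[:k]), index=base.index)
        cut(top, f"top {spec.top_fraction:.4g}")
    if spec.min_mean_intensity is not None:
        mean = base[out.samples].fillna(0.0).mean(axis=1)
        cut(mean >= spec.min_mean_intensity, f"mean>={spec.min_mean_intensity}")
    if spec.present_in is not None:
        g, k = spec.present_in
        cols = out.group_samples(g)
        cut(base[cols].notna().sum(axis=1) >= k, f"present in >= {k} of {g}")
    if spec.rt_range is not None:
        lo, hi = spec.rt_range
        cut((base["rt"] >= lo) & (base["rt"] <= hi), f"rt in [{lo},{hi}]")

    out = out.with_df(base.loc[keep].copy())
    out.log("apply_filters", asdict(spec), survivors=counts, n_kept=len(out.df))
    return out
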