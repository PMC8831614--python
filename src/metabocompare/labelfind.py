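"""Stable-isotope label finding.

In a tracer experiment (e.g. 13C6-leucine feeding), a metabolite that
incorporates n labeled atoms appears as a feature pair: the unlabeled
(light) species, present with and without tracer, and a heavy partner
shifted by n x the isotope mass difference (1.0033548 Da per 13C), eluting
at the same retention time and abundant only in tracer-fed samples. The
finder scans a feature table for such pairs; shifted-EIC overlays support
visual validation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import C13_DELTA, MassTolerance
from .features import FeatureTable
from .rawdata import EICTrace, RawRun, extract_eic

__all__ = ["LabelParams", "find_label_pairs", "mass_shift_eics"]

PAIR_COLUMNS = [
    "light_id", "heavy_id", "n", "light_mz", "heavy_mz", "light_rt", "heavy_rt",
    "observed_delta", "delta_ppm_error", "enrichment_fold",
]


@dataclass
class LabelParams:
    """Label-finder settings.

    ``isotope_delta`` is the per-label mass shift (default 13C/12C);
    ``n_range`` the inclusive label-count window (5-6 for a 13C6-leucine
    experiment whose BCFA products keep five carbons); enrichment demands
    the heavy partner be ``min_enrichment_fold`` more abundant with the
    tracer than without.
    """

    isotope_delta: float = C13_DELTA
    n_range: Tuple[int, int] = (1, 20)
    rt_tol: float = 5.0
    mz_tol: MassTolerance = MassTolerance(5.0, "ppm")
    min_enrichment_fold: float = 5.0
    min_heavy_intensity: float = 0.0
    charge: int = 1

    def __post_init__(self) -> None:
        if self.n_range[0] < 1 or self.n_range[1] < self.n_range[0]:
            raise ValueError("n_range must satisfy 1 <= n_min <= n_max")
        if self.rt_tol <= 0:
            raise ValueError("rt_tol must be positive")


def find_label_pairs(
    table: FeatureTable,
    unlabeled_group: str,
    labeled_group: str,
    params: Optional[LabelParams] = None,
) -> pd.DataFrame:
    """Find light/heavy feature pairs consistent with isotope labeling.

    For every feature (as the light partner) and every n in ``n_range``, a
    heavy candidate must sit at light m/z + n*delta/|charge| within the m/z
    tolerance, co-elute within ``rt_tol``, and be at least
    ``min_enrichment_fold`` more abundant (group mean) in the labeled than
    in the unlabeled samples (an absent unlabeled signal counts as maximal
    enrichment). One light feature may pair at several n; all are reported.
    """
    if params is None:
        params = LabelParams()
    unlab = table.group_samples(unlabeled_group)
    lab = table.group_samples(labeled_group)
    df = table.df
    mz = df["mz"].to_numpy(dtype=float)
    rt = df["rt"].to_numpy(dtype=float)
    ids = df.index.to_numpy()
    unlab_mean = df[unlab].fillna(0.0).mean(axis=1).to_numpy()
    lab_mean = df[lab].fillna(0.0).mean(axis=1).to_numpy()

    order = np.argsort(mz, kind="stable")
    mz_s, rt_s, ids_s = mz[order], rt[order], ids[order]
    unlab_s, lab_s = unlab_mean[order], lab_mean[order]

    per_label = params.isotope_delta / abs(params.charge)
    rows: List[dict] = []
    for i in range(mz_s.size):
        if unlab_s[i] <= 0:  # light partner must exist without the tracer
            continue
        for n in range(params.n_range[0], params.n_range[1] + 1):
            target = mz_s[i] + n * per_label
            half = params.mz_tol.window(target)
            lo = np.searchsorted(mz_s, target - half, side="left")
            hi = np.searchsorted(mz_s, target + half, side="right")
            for j in range(lo, hi):
                if j == i or abs(rt_s[j] - rt_s[i]) > params.rt_tol:
                    continue
                if lab_s[j] < params.min_heavy_intensity or lab_s[j] <= 0:
                    continue
                if unlab_s[j] > 0 and lab_s[j] / unlab_s[j] < params.min_enrichment_fold:
                    continue
                enrich = lab_s[j] / unlab_s[j] if unlab_s[j] > 0 else np.inf
                delta = mz_s[j] - mz_s[i]
                rows.append(
                    {
                        "light_id": ids_s[i],
                        "heavy_id": ids_s[j],
                        "n": n,
                        "light_mz": mz_s[i],
                        "heavy_mz": mz_s[j],
                        "light_rt": rt_s[i],
                        "heavy_rt": rt_s[j],
                        "observed_delta": delta,
                        "delta_ppm_error": 1e6 * (delta - n * per_label) / target,
                        "enrichment_fold": enrich,
                    }
                )
    out = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    out = out.sort_values(["light_id", "n", "heavy_id"], kind="stable").reset_index(drop=True)
    table.log(
        "find_label_pairs",
        {
            "unlabeled_group": unlabeled_group,
            "labeled_group": labeled_group,
            "isotope_delta": params.isotope_delta,
            "n_range": list(params.n_range),
            "rt_tol": params.rt_tol,
            "min_enrichment_fold": params.min_enrichment_fold,
        },
        n_pairs=len(out),
    )
    return out


def mass_shift_eics(
    run: RawRun,
    mz: float,
    n_list: Sequence[int],
    params: Optional[LabelParams] = None,
    rt_range: Optional[Tuple[float, float]] = None,
) -> Dict[int, EICTrace]:
    """EIC overlays for isotope-shift validation: the base trace (key 0) and
    one trace per requested label count at m/z + n*delta, all on the same
    RT axis."""
    if params is None:
        params = LabelParams()
    per_label = params.isotope_delta / abs(params.charge)
    out: Dict[int, EICTrace] = {
        0: extract_eic(run, mz, params.mz_tol, rt_range=rt_range)
    }
    for n in n_list:
        if n == 0:
            continue
        out[int(n)] = extract_eic(run, mz + n * per_label, params.mz_tol, rt_range=rt_range)
    return out
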