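"""Cross-sample feature grouping and the FeatureTable analysis hub.

A *feature* is an ion species seen across samples, defined by a consensus
m/z and retention time with one intensity per sample. Per-sample peak lists
are grouped into features by m/z binning plus kernel-density clustering of
retention times (the XCMS ``group.density`` approach: Gaussian kernel with
bandwidth ``bw``, clusters cut at density minima). The resulting
:class:`FeatureTable` carries all downstream annotation columns (statistics,
quality scores, MS2 links, pattern hits) and an append-only provenance log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .chem import C13_DELTA, CH2_DELTA, MassTolerance
from .rawdata import EICTrace, RawRun, extract_eic, integrate_eic

__all__ = [
    "FeatureTable",
    "GroupingParams",
    "FillParams",
    "group_features",
    "fill_missing",
    "peak_quality",
    "annotate_mass_relations",
    "normalize_to_reference",
    "BUILTIN_DELTAS",
]

#: Built-in mass relations: 13C isotope spacing and methylene homologs.
BUILTIN_DELTAS: Tuple[Tuple[str, float], ...] = (
    ("13C", C13_DELTA),
    ("CH2", CH2_DELTA),
)


@dataclass
class GroupingParams:
    """Feature-grouping settings (defaults: 0.002 mzwid, 2 s bw,
    0.2 minfrac, 500 max, 1 minsamp)."""

    mzwid: float = 0.002
    bw: float = 2.0
    minfrac: float = 0.2
    max_features: int = 500
    minsamp: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.minfrac <= 1):
            raise ValueError("minfrac must be in [0, 1]")
        if self.mzwid <= 0 or self.bw <= 0:
            raise ValueError("mzwid and bw must be positive")


@dataclass
class FillParams:
    """Peak-filling settings (defaults: 3 ppm_m, 3 s rtw, use feature RT
    range, report max intensity rather than area)."""

    ppm_m: float = 3.0
    rtw: float = 3.0
    use_rt_range: bool = True
    area_mode: bool = False

    def __post_init__(self) -> None:
        if self.ppm_m <= 0 or self.rtw <= 0:
            raise ValueError("fill tolerances must be positive")


@dataclass
class FeatureTable:
    """Features (rows) x metadata + per-sample intensities (columns).

    ``df`` holds columns ``mz, mzmin, mzmax, rt, rtmin, rtmax`` plus one
    intensity column per sample (NaN = not detected / not filled) and any
    annotation columns. ``groups`` maps sample id to group label.
    ``provenance`` records every applied operation with its parameters.
    """

    df: pd.DataFrame
    samples: List[str]
    groups: Dict[str, str]
    provenance: List[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [s for s in self.samples if s not in self.df.columns]
        if missing:
            raise ValueError(f"intensity columns missing for samples: {missing}")

    # -- helpers ------------------------------------------------------
    def intensities(self, fill_value: float = np.nan) -> pd.DataFrame:
        out = self.df[self.samples]
        return out if math.isnan(fill_value) else out.fillna(fill_value)

    def group_samples(self, group: str) -> List[str]:
        out = [s for s in self.samples if self.groups[s] == group]
        if not out:
            raise KeyError(f"no samples in group {group!r}")
        return out

    def group_labels(self) -> List[str]:
        seen: List[str] = []
        for s in self.samples:
            if self.groups[s] not in seen:
                seen.append(self.groups[s])
        return seen

    def log(self, stage: str, params: Optional[Mapping] = None, **counts) -> None:
        self.provenance.append({"stage": stage, "params": dict(params or {}), **counts})

    def with_df(self, df: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(df, list(self.samples), dict(self.groups), list(self.provenance))

    def __len__(self) -> int:
        return len(self.df)

    # -- I/O ----------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="feature_id")

    @classmethod
    def from_csv(cls, path, groups: Mapping[str, str]) -> "FeatureTable":
        df = pd.read_csv(path, index_col="feature_id")
        samples = [s for s in groups if s in df.columns]
        if not samples:
            raise ValueError("no sample columns from the group map found in the CSV")
        return cls(df, samples, dict(groups))

    def to_metaboanalyst_csv(self, path) -> None:
        """Samples x features matrix with a group row, as MetaboAnalyst's
        one-factor CSV layout expects."""
        names = [f"{m:.4f}@{r:.1f}" for m, r in zip(self.df["mz"], self.df["rt"])]
        mat = self.df[self.samples].T.fillna(0.0)
        mat.columns = names
        mat.insert(0, "Label", [self.groups[s] for s in self.samples])
        mat.to_csv(path, index_label="Sample")


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def _rt_clusters(rts: np.ndarray, bw: float) -> np.ndarray:
    """Cluster retention times by cutting a Gaussian kernel density estimate
    (bandwidth ``bw``) at its local minima. Returns integer labels."""
    if rts.size == 1:
        return np.zeros(1, dtype=int)
    lo, hi = rts.min() - 3 * bw, rts.max() + 3 * bw
    grid = np.linspace(lo, hi, max(64, int((hi - lo) / (bw / 4)) + 1))
    dens = np.exp(-((grid[:, None] - rts[None, :]) ** 2) / (2 * bw * bw)).sum(axis=1)
    interior = np.arange(1, grid.size - 1)
    is_min = (dens[interior] <= dens[interior - 1]) & (dens[interior] < dens[interior + 1])
    cuts = grid[interior[is_min & (dens[interior] < dens.max() * 0.999)]]
    return np.searchsorted(cuts, rts).astype(int)


def group_features(
    peaks_by_sample: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    params: Optional[GroupingParams] = None,
    value: str = "maxo",
) -> FeatureTable:
    """Group per-sample peak lists into a cross-sample FeatureTable.

    Peaks are binned by m/z (sorted gap-clustering at ``mzwid``), RT
    clusters are cut at kernel-density minima with bandwidth ``bw``, and a
    cluster becomes a feature when it holds peaks from at least ``minfrac``
    of the samples of some group and at least ``minsamp`` samples. When one
    sample contributes several peaks to a cluster, the most intense is kept.
    """
    if params is None:
        params = GroupingParams()
    samples = list(peaks_by_sample)
    group_sizes: Dict[str, int] = {}
    for s in samples:
        g = groups[s]
        group_sizes[g] = group_sizes.get(g, 0) + 1

    frames = []
    for s, df in peaks_by_sample.items():
        if len(df):
            sub = df[["mz", "mzmin", "mzmax", "rt", "rtmin", "rtmax", value]].copy()
            sub["sample"] = s
            frames.append(sub)
    if not frames:
        return FeatureTable(
            pd.DataFrame(columns=["mz", "mzmin", "mzmax", "rt", "rtmin", "rtmax", *samples]),
            samples,
            dict(groups),
        )
    allp = pd.concat(frames, ignore_index=True).sort_values("mz", kind="stable")
    mz = allp["mz"].to_numpy()
    bin_id = np.concatenate([[0], np.cumsum(np.diff(mz) > params.mzwid)])
    allp = allp.assign(_bin=bin_id)

    rows = []
    for _, binp in allp.groupby("_bin", sort=True):
        labels = _rt_clusters(binp["rt"].to_numpy(), params.bw)
        for lab in np.unique(labels):
            cl = binp.iloc[labels == lab]
            contributing = cl["sample"].unique()
            per_group = {}
            for s in contributing:
                g = groups[s]
                per_group[g] = per_group.get(g, 0) + 1
            frac_ok = any(
                cnt / group_sizes[g] >= params.minfrac for g, cnt in per_group.items()
            )
            if not frac_ok or len(contributing) < params.minsamp:
                continue
            best = cl.sort_values(value, ascending=False).drop_duplicates("sample")
            row = {
                "mz": float(cl["mz"].median()),
                "mzmin": float(cl["mzmin"].min()),
                "mzmax": float(cl["mzmax"].max()),
                "rt": float(cl["rt"].median()),
                "rtmin": float(cl["rtmin"].min()),
                "rtmax": float(cl["rtmax"].max()),
            }
            for s in samples:
                row[s] = np.nan
            for _, p in best.iterrows():
                row[p["sample"]] = float(p[value])
            rows.append(row)

    df = pd.DataFrame(rows, columns=["mz", "mzmin", "mzmax", "rt", "rtmin", "rtmax", *samples])
    df = df.sort_values(["mz", "rt"], kind="stable").reset_index(drop=True)
    table = FeatureTable(df, samples, dict(groups))
    table.log("group_features", asdict(params), n_features=len(df))
    return table


# ---------------------------------------------------------------------------
# Filling, quality, relations, normalization
# ---------------------------------------------------------------------------

def fill_missing(
    table: FeatureTable,
    runs: Mapping[str, RawRun],
    params: Optional[FillParams] = None,
) -> FeatureTable:
    """Replace missing per-sample intensities by direct EIC integration at
    the feature's m/z over its RT range widened by ``rtw``.

    Detected intensities are never altered; filled cells (including zero
    fills) are flagged in the ``filled_samples`` annotation column, so
    applying the operation twice is a no-op.
    """
    if params is None:
        params = FillParams()
    missing_runs = [s for s in table.samples if s not in runs]
    if missing_runs:
        raise KeyError(f"no raw run provided for samples: {missing_runs}")
    df = table.df.copy()
    if "filled_samples" not in df.columns:
        df["filled_samples"] = ""
    tol = MassTolerance(params.ppm_m, "ppm")
    n_filled = 0
    for idx, row in df.iterrows():
        flagged = []
        for s in table.samples:
            if not pd.isna(row[s]):
                continue
            if params.use_rt_range:
                window = (row["rtmin"] - params.rtw, row["rtmax"] + params.rtw)
            else:
                window = (row["rt"] - params.rtw, row["rt"] + params.rtw)
            trace = extract_eic(runs[s], row["mz"], tol, rt_range=window)
            area, maxo = integrate_eic(trace)
            df.at[idx, s] = area if params.area_mode else maxo
            flagged.append(s)
            n_filled += 1
        if flagged:
            prev = df.at[idx, "filled_samples"]
            joined = ";".join(flagged)
            df.at[idx, "filled_samples"] = f"{prev};{joined}" if prev else joined
    out = table.with_df(df)
    out.log("fill_missing", asdict(params), n_filled=n_filled)
    return out


def _gaussian_fit_score(rt: np.ndarray, inten: np.ndarray) -> float:
    """Pearson correlation between an EIC window and its best-fit
    apex-anchored Gaussian, clipped to [0, 1]."""
    if rt.size < 4 or inten.max() <= 0:
        return 0.0
    apex = int(np.argmax(inten))
    t0, a0 = rt[apex], float(inten[apex])
    span = max(rt[-1] - rt[0], 1e-6)
    # a peak narrower than the scan spacing is unphysical; bounding sigma
    # below keeps single noise spikes from fitting perfectly
    sigma_min = max(float(np.median(np.diff(rt))), span / 50)

    def model(t, a, sigma):
        return a * np.exp(-((t - t0) ** 2) / (2 * sigma**2))

    try:
        popt, _ = optimize.curve_fit(
            model,
            rt,
            inten,
            p0=(a0, max(span / 4, sigma_min)),
            bounds=((0, sigma_min), (np.inf, span * 2)),
            maxfev=200,
        )
    except Exception:
        return 0.0
    fitted = model(rt, *popt)
    if np.std(fitted) == 0 or np.std(inten) == 0:
        return 0.0
    r = float(np.corrcoef(inten, fitted)[0, 1])
    return min(max(r, 0.0), 1.0)


def peak_quality(
    table: FeatureTable,
    runs: Mapping[str, RawRun],
    tol: MassTolerance = MassTolerance(5.0, "ppm"),
    pad: float = 2.0,
) -> FeatureTable:
    """Score every feature by how well its EICs fit an idealized (Gaussian)
    chromatographic peak shape.

    Per sample with detected signal the score is the Pearson correlation of
    the EIC over the feature's RT window against a least-squares Gaussian
    anchored at the apex, clipped to [0, 1]; the feature score (column
    ``quality``) is the mean over scored samples. Windows with fewer than 4
    points score 0.
    """
    df = table.df.copy()
    scores = np.zeros(len(df))
    for i, (idx, row) in enumerate(df.iterrows()):
        per_sample = []
        for s in table.samples:
            v = row[s]
            if pd.isna(v) or v <= 0:
                continue
            trace = extract_eic(
                runs[s], row["mz"], tol, rt_range=(row["rtmin"] - pad, row["rtmax"] + pad)
            )
            per_sample.append(_gaussian_fit_score(trace.rt, trace.intensity))
        scores[i] = float(np.mean(per_sample)) if per_sample else 0.0
    df["quality"] = scores
    out = table.with_df(df)
    out.log("peak_quality", {"tol_ppm": tol.value, "pad": pad})
    return out


def annotate_mass_relations(
    table: FeatureTable,
    deltas: Sequence[Tuple[str, float]] = BUILTIN_DELTAS,
    rt_tol: float = 3.0,
    mz_tol: MassTolerance = MassTolerance(0.002, "da"),
) -> Tuple[FeatureTable, pd.DataFrame]:
    """Annotate co-eluting feature pairs whose m/z difference matches a named
    delta (built-ins: 13C isotope spacing 1.00336 and methylene 14.01565).

    Returns the annotated table (``relations`` column, entries
    ``name:partner_feature_id``) and an edge DataFrame
    (low_id, high_id, name, delta, observed_delta, rt_diff).
    """
    if not deltas:
        raise ValueError("at least one mass delta is required")
    df = table.df
    mz = df["mz"].to_numpy()
    rt = df["rt"].to_numpy()
    ids = df.index.to_numpy()
    order = np.argsort(mz, kind="stable")
    mz_s, rt_s, ids_s = mz[order], rt[order], ids[order]
    edges = []
    rel: Dict[object, List[str]] = {i: [] for i in ids}
    for name, delta in deltas:
        half = mz_tol.window(float(np.median(mz)) + delta if mz.size else delta)
        target = mz_s + delta
        lo = np.searchsorted(mz_s, target - half, side="left")
        hi = np.searchsorted(mz_s, target + half, side="right")
        for i in range(mz_s.size):
            for j in range(lo[i], hi[i]):
                if j == i or abs(rt_s[j] - rt_s[i]) > rt_tol:
                    continue
                edges.append(
                    {
                        "low_id": ids_s[i],
                        "high_id": ids_s[j],
                        "name": name,
                        "delta": delta,
                        "observed_delta": mz_s[j] - mz_s[i],
                        "rt_diff": rt_s[j] - rt_s[i],
                    }
                )
                rel[ids_s[i]].append(f"{name}:+{ids_s[j]}")
                rel[ids_s[j]].append(f"{name}:-{ids_s[i]}")
    out_df = table.df.copy()
    out_df["relations"] = [";".join(rel[i]) for i in out_df.index]
    out = table.with_df(out_df)
    out.log(
        "annotate_mass_relations",
        {"deltas": list(deltas), "rt_tol": rt_tol, "mz_tol": (mz_tol.value, mz_tol.unit)},
        n_edges=len(edges),
    )
    return out, pd.DataFrame(
        edges, columns=["low_id", "high_id", "name", "delta", "observed_delta", "rt_diff"]
    )


def normalize_to_reference(table: FeatureTable, reference: object) -> FeatureTable:
    """Divide every sample's intensities by that sample's intensity of a
    reference feature (e.g. an internal-standard metabolite), making the
    reference row all ones.

    Raises
    ------
    ValueError
        Naming the offending samples when the reference is missing or zero
        anywhere.
    """
    if reference not in table.df.index:
        raise KeyError(f"reference feature {reference!r} not in table")
    ref = table.df.loc[reference, table.samples].astype(float)
    bad = [s for s in table.samples if pd.isna(ref[s]) or ref[s] == 0]
    if bad:
        raise ValueError(f"reference feature has zero/missing intensity in samples: {bad}")
    df = table.df.copy()
    df[table.samples] = df[table.samples].to_numpy(dtype=float) / ref.to_numpy(dtype=float)
    out = table.with_df(df)
    out.log("normalize_to_reference", {"reference": reference})
    return out
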