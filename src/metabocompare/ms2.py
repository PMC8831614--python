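"""MS/MS handling: scan-to-feature matching, spectral merging, cosine
similarity, molecular networks, fragmentation-pattern search.

The cosine here follows the feature-based molecular networking convention:
peaks of two averaged spectra are pair-matched within a fragment tolerance
(greedily, by descending intensity product, each peak used once; optionally
also at an offset equal to the precursor mass difference — the "modified"
cosine), and the score is the dot product of matched relative intensities
normalized by the norms over *all* peaks, so unshared intensity is
penalized. Raw relative intensities are used by default; square-root
weighting is available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import networkx as nx
import pandas as pd
import yaml

from .chem import MassTolerance, ppm_error
from .features import FeatureTable
from .rawdata import RawRun, Spectrum

__all__ = [
    "MergedSpectrum",
    "FragmentationPattern",
    "NetworkParams",
    "SpectralNetwork",
    "match_scans_to_features",
    "merge_spectra",
    "cosine_score",
    "build_network",
    "simplify_network",
    "find_patterns",
    "shared_fragments",
    "write_mgf",
    "read_mgf",
]


@dataclass
class MergedSpectrum:
    """MS2 consensus spectrum of one feature: peaks averaged over all
    contributing scans, normalized so the strongest peak is 1."""

    feature_id: object
    mz: np.ndarray
    intensity: np.ndarray
    counts: np.ndarray
    precursor_mz: Optional[float] = None
    n_scans: int = 1

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz, self.intensity, self.counts = (
                self.mz[order],
                self.intensity[order],
                self.counts[order],
            )
        peak = self.intensity.max() if self.intensity.size else 0.0
        if peak > 0:
            self.intensity = self.intensity / peak

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass
class NetworkParams:
    """Molecular networking knobs (GNPS-conventional defaults: 0.002 Da
    fragment tolerance, cosine >= 0.7, >= 6 matched peaks, <= 10 edges per
    node, <= 100 nodes per cluster)."""

    fragment_tol: float = 0.002
    cosine_threshold: float = 0.7
    min_matched_peaks: int = 6
    max_edges_per_node: int = 10
    max_cluster_size: int = 100
    modified_cosine: bool = False
    sqrt_intensity: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.cosine_threshold <= 1):
            raise ValueError("cosine threshold must be in [0, 1]")
        if self.max_edges_per_node < 1:
            raise ValueError("max edges per node must be >= 1")


@dataclass
class FragmentationPattern:
    """A named fragmentation fingerprint: required fragment m/z values and/or
    neutral losses (each with a tolerance in Da). A spectrum is a hit when at
    least ``min_matches`` elements are found (default: all), counting only
    peaks above ``min_rel_intensity``."""

    name: str
    fragments: Sequence[Tuple[float, float]] = ()  # (m/z, tol Da)
    losses: Sequence[Tuple[float, float]] = ()  # (Da vs precursor, tol Da)
    min_matches: Optional[int] = None
    min_rel_intensity: float = 0.01

    def __post_init__(self) -> None:
        if not self.fragments and not self.losses:
            raise ValueError("a pattern needs at least one fragment or neutral loss")
        for _, tol in list(self.fragments) + list(self.losses):
            if tol <= 0:
                raise ValueError("pattern tolerances must be positive")

    @property
    def n_elements(self) -> int:
        return len(self.fragments) + len(self.losses)

    @classmethod
    def from_yaml(cls, path) -> "List[FragmentationPattern]":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or []
        out = []
        for entry in raw:
            out.append(
                cls(
                    name=entry["name"],
                    fragments=[tuple(x) for x in entry.get("fragments", [])],
                    losses=[tuple(x) for x in entry.get("losses", [])],
                    min_matches=entry.get("min_matches"),
                    min_rel_intensity=entry.get("min_rel_intensity", 0.01),
                )
            )
        return out


# ---------------------------------------------------------------------------
# Scan matching and merging
# ---------------------------------------------------------------------------

def match_scans_to_features(
    table: FeatureTable,
    runs: Mapping[str, RawRun],
    mz_tol: MassTolerance = MassTolerance(5.0, "ppm"),
    rt_pad: float = 5.0,
) -> Dict[object, List[Spectrum]]:
    """Assign MS2 scans to features by precursor m/z (ppm) and RT window
    (feature rtmin-pad .. rtmax+pad). A scan matching several features goes
    to the one with the closest m/z. Returns feature_id -> scans and writes
    an ``ms2_scans`` count column on the table in place."""
    df = table.df
    fmz = df["mz"].to_numpy()
    order = np.argsort(fmz, kind="stable")
    fmz_s = fmz[order]
    ids_s = df.index.to_numpy()[order]
    rtmin_s = df["rtmin"].to_numpy()[order] - rt_pad
    rtmax_s = df["rtmax"].to_numpy()[order] + rt_pad

    assigned: Dict[object, List[Spectrum]] = {i: [] for i in df.index}
    for run in runs.values():
        for scan in run.ms2:
            p = scan.precursor_mz
            half = mz_tol.window(p)
            lo = np.searchsorted(fmz_s, p - half, side="left")
            hi = np.searchsorted(fmz_s, p + half, side="right")
            best = None
            best_d = math.inf
            for j in range(lo, hi):
                if rtmin_s[j] <= scan.rt <= rtmax_s[j]:
                    d = abs(fmz_s[j] - p)
                    if d < best_d:
                        best, best_d = ids_s[j], d
            if best is not None:
                assigned[best].append(scan)
    table.df["ms2_scans"] = [len(assigned[i]) for i in table.df.index]
    table.log("match_scans_to_features", {"mz_tol_ppm": mz_tol.value, "rt_pad": rt_pad},
              n_matched_features=int(sum(1 for v in assigned.values() if v)))
    return assigned


def merge_spectra(
    scans: Sequence[Spectrum], tol: float = 0.002, feature_id: object = None
) -> MergedSpectrum:
    """Average MS2 scans of one feature into a consensus spectrum.

    Peaks across scans are clustered by single-linkage in ascending m/z
    (gap > ``tol`` starts a new cluster); the merged m/z is the
    intensity-weighted mean and the merged intensity the mean of per-scan
    relative intensities (a scan without the peak contributes 0), then
    renormalized to max 1.
    """
    if not scans:
        raise ValueError("cannot merge an empty scan list")
    all_mz: List[np.ndarray] = []
    all_rel: List[np.ndarray] = []
    all_scan: List[np.ndarray] = []
    for k, s in enumerate(scans):
        top = s.intensity.max() if s.intensity.size else 0.0
        rel = s.intensity / top if top > 0 else s.intensity
        all_mz.append(s.mz)
        all_rel.append(rel)
        all_scan.append(np.full(s.mz.size, k))
    mz = np.concatenate(all_mz)
    rel = np.concatenate(all_rel)
    scan_of = np.concatenate(all_scan)
    order = np.argsort(mz, kind="stable")
    mz, rel, scan_of = mz[order], rel[order], scan_of[order]
    if mz.size == 0:
        return MergedSpectrum(feature_id, mz, rel, np.zeros(0, dtype=int),
                              scans[0].precursor_mz, len(scans))
    cluster = np.concatenate([[0], np.cumsum(np.diff(mz) > tol)])
    n_cl = int(cluster[-1]) + 1
    out_mz = np.zeros(n_cl)
    out_int = np.zeros(n_cl)
    out_cnt = np.zeros(n_cl, dtype=int)
    for c in range(n_cl):
        sel = cluster == c
        w = rel[sel]
        out_mz[c] = float(np.average(mz[sel], weights=w)) if w.sum() > 0 else float(mz[sel].mean())
        out_int[c] = w.sum() / len(scans)  # absent scans contribute zero
        out_cnt[c] = int(np.unique(scan_of[sel]).size)
    precs = [s.precursor_mz for s in scans if s.precursor_mz]
    return MergedSpectrum(
        feature_id, out_mz, out_int, out_cnt,
        float(np.mean(precs)) if precs else None, len(scans),
    )


# ---------------------------------------------------------------------------
# Cosine similarity and networks
# ---------------------------------------------------------------------------

def _weights(spec: MergedSpectrum, params: NetworkParams) -> np.ndarray:
    return np.sqrt(spec.intensity) if params.sqrt_intensity else spec.intensity


def cosine_score(
    a: MergedSpectrum, b: MergedSpectrum, params: Optional[NetworkParams] = None
) -> Tuple[float, int]:
    """Greedy-matched cosine similarity between two consensus spectra.

    Returns (cosine in [0, 1], number of matched peak pairs). Symmetric,
    scale-invariant, and 1.0 for a spectrum against itself.
    """
    if params is None:
        params = NetworkParams()
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    wa, wb = _weights(a, params), _weights(b, params)
    tol = params.fragment_tol
    offsets = [0.0]
    if params.modified_cosine and a.precursor_mz and b.precursor_mz:
        offsets.append(a.precursor_mz - b.precursor_mz)

    cand: List[Tuple[float, int, int]] = []
    for off in offsets:
        # peak i of a matches peak j of b when |mz_a - mz_b - off| <= tol
        lo = np.searchsorted(b.mz, a.mz - off - tol, side="left")
        hi = np.searchsorted(b.mz, a.mz - off + tol, side="right")
        for i in range(len(a)):
            for j in range(lo[i], hi[i]):
                cand.append((float(wa[i] * wb[j]), i, j))
    if not cand:
        return 0.0, 0
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: Set[int] = set()
    used_b: Set[int] = set()
    dot = 0.0
    matched = 0
    for prod, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        dot += prod
        matched += 1
    denom = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    return (dot / denom if denom > 0 else 0.0), matched


@dataclass
class SpectralNetwork:
    """Molecular network: nodes are features with merged MS2 spectra, edges
    carry cosine similarity and matched-peak counts; ``clusters`` labels
    connected components."""

    graph: nx.Graph

    @property
    def clusters(self) -> Dict[object, int]:
        return {
            n: k for k, comp in enumerate(sorted(nx.connected_components(self.graph), key=sorted))
            for n in comp
        }

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, **d} for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "cosine", "n_matched"])

    def node_frame(self) -> pd.DataFrame:
        rows = [{"node": n, **d} for n, d in self.graph.nodes(data=True)]
        return pd.DataFrame(rows)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_network(
    spectra: Mapping[object, MergedSpectrum],
    params: Optional[NetworkParams] = None,
    node_attrs: Optional[pd.DataFrame] = None,
) -> SpectralNetwork:
    """All-pairs cosine network over merged spectra.

    An edge survives when cosine >= threshold and matched peaks >=
    ``min_matched_peaks``. ``node_attrs`` rows (indexed by feature id) are
    copied onto nodes for export/display.
    """
    if params is None:
        params = NetworkParams()
    g = nx.Graph()
    ids = list(spectra)
    for fid in ids:
        attrs = {}
        if node_attrs is not None and fid in node_attrs.index:
            attrs = {
                k: v for k, v in node_attrs.loc[fid].items() if not isinstance(v, (list, dict))
            }
        g.add_node(fid, **attrs)
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            cos, n = cosine_score(spectra[ids[x]], spectra[ids[y]], params)
            if cos >= params.cosine_threshold and n >= params.min_matched_peaks:
                g.add_edge(ids[x], ids[y], cosine=float(cos), n_matched=int(n))
    return SpectralNetwork(g)


def simplify_network(
    net: SpectralNetwork, params: Optional[NetworkParams] = None
) -> SpectralNetwork:
    """Prune a network to display size: keep an edge only when it ranks in
    the top-K by cosine for *both* endpoints, then break oversized connected
    components by removing their weakest edges. Deterministic (ties broken
    by node id); idempotent."""
    if params is None:
        params = NetworkParams()
    g = net.graph.copy()
    K = params.max_edges_per_node

    def rank(node) -> List[Tuple]:
        return sorted(
            g.edges(node, data=True),
            key=lambda e: (-e[2]["cosine"], str(sorted((e[0], e[1])))),
        )

    keep: Set[Tuple] = set()
    for node in g.nodes:
        for u, v, _ in rank(node)[:K]:
            keep.add(tuple(sorted((u, v), key=str)))
    mutual = [
        (u, v)
        for u, v in g.edges
        if tuple(sorted((u, v), key=str)) in keep
        and all(
            tuple(sorted((u, v), key=str))
            in {tuple(sorted((a, b), key=str)) for a, b, _ in rank(end)[:K]}
            for end in (u, v)
        )
    ]
    pruned = nx.Graph()
    pruned.add_nodes_from(g.nodes(data=True))
    for u, v in mutual:
        pruned.add_edge(u, v, **g.edges[u, v])

    cap = params.max_cluster_size
    while True:
        oversized = [c for c in nx.connected_components(pruned) if len(c) > cap]
        if not oversized:
            break
        comp = oversized[0]
        worst = min(
            (e for e in pruned.edges(comp, data=True)),
            key=lambda e: (e[2]["cosine"], str(sorted((e[0], e[1])))),
        )
        pruned.remove_edge(worst[0], worst[1])
    return SpectralNetwork(pruned)


# ---------------------------------------------------------------------------
# Pattern search and spectrum comparison
# ---------------------------------------------------------------------------

def find_patterns(
    spectra: Mapping[object, MergedSpectrum],
    pattern: FragmentationPattern,
    table: Optional[FeatureTable] = None,
) -> pd.DataFrame:
    """Search merged spectra for a fragmentation pattern.

    Returns a DataFrame indexed by feature id with columns ``hit`` (bool),
    ``n_matched`` and ``detail`` (which elements matched where). When a
    ``table`` is given, a ``pattern_<name>`` boolean column is written onto
    it in place. Neutral-loss elements require a precursor m/z.
    """
    need = pattern.min_matches or pattern.n_elements
    rows = []
    for fid, spec in spectra.items():
        mask = spec.intensity >= pattern.min_rel_intensity
        mz = spec.mz[mask]
        matched = 0
        detail: List[str] = []
        for target, tol in pattern.fragments:
            j = np.searchsorted(mz, target)
            ok = False
            for jj in (j - 1, j):
                if 0 <= jj < mz.size and abs(mz[jj] - target) <= tol:
                    ok = True
                    detail.append(f"frag {target:.4f}@{mz[jj]:.4f}")
                    break
            matched += ok
        for loss, tol in pattern.losses:
            if spec.precursor_mz is None:
                raise ValueError(
                    f"pattern {pattern.name!r} has neutral losses but spectrum "
                    f"{fid!r} lacks a precursor m/z"
                )
            target = spec.precursor_mz - loss
            j = np.searchsorted(mz, target)
            ok = False
            for jj in (j - 1, j):
                if 0 <= jj < mz.size and abs(mz[jj] - target) <= tol:
                    ok = True
                    detail.append(f"loss {loss:.4f}@{mz[jj]:.4f}")
                    break
            matched += ok
        rows.append(
            {"feature_id": fid, "hit": matched >= need, "n_matched": matched,
             "detail": ";".join(detail)}
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    if table is not None:
        col = f"pattern_{pattern.name}"
        table.df[col] = out["hit"].reindex(table.df.index).fillna(False).astype(bool)
        table.log("find_patterns", {"pattern": pattern.name}, n_hits=int(out["hit"].sum()))
    return out


def shared_fragments(
    spectra: Sequence[MergedSpectrum], tol: float = 0.002
) -> pd.DataFrame:
    """Group fragments across >= 2 spectra and label which spectra contain
    each group ('conserved' = present in all) — the side-by-side spectrum
    comparison used to spot shared substructures."""
    if len(spectra) < 2:
        raise ValueError("need at least two spectra to compare")
    mz = np.concatenate([s.mz for s in spectra])
    who = np.concatenate([np.full(len(s), k) for k, s in enumerate(spectra)])
    order = np.argsort(mz, kind="stable")
    mz, who = mz[order], who[order]
    if mz.size == 0:
        return pd.DataFrame(columns=["mz", "members", "conserved"])
    cluster = np.concatenate([[0], np.cumsum(np.diff(mz) > tol)])
    rows = []
    for c in range(int(cluster[-1]) + 1):
        sel = cluster == c
        members = sorted(set(who[sel].tolist()))
        rows.append(
            {
                "mz": float(mz[sel].mean()),
                "members": members,
                "conserved": len(members) == len(spectra),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MGF import/export
# ---------------------------------------------------------------------------

def write_mgf(spectra: Mapping[object, MergedSpectrum], path) -> None:
    """Write merged spectra as an MGF file (one BEGIN IONS block each)."""
    with open(path, "w") as fh:
        for fid, s in spectra.items():
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={fid}\n")
            if s.precursor_mz:
                fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{m:.6f} {i:.6f}\n")
            fh.write("END IONS\n")


def read_mgf(path) -> Dict[str, MergedSpectrum]:
    """Read an MGF file written by :func:`write_mgf`."""
    from pyteomics import mgf as _mgf

    out: Dict[str, MergedSpectrum] = {}
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            title = entry["params"].get("title", f"spec{len(out)}")
            pep = entry["params"].get("pepmass")
            prec = float(pep[0]) if pep else None
            mzs = np.asarray(entry["m/z array"], dtype=float)
            out[title] = MergedSpectrum(
                title, mzs, np.asarray(entry["intensity array"], dtype=float),
                np.ones(mzs.size, dtype=int), prec,
            )
    return out
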