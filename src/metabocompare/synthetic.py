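"""Deterministic synthetic LC-MS/MS data with planted ground truth.

Emulates a multi-group comparative experiment — wildtype vs mutant plus
extraction blanks, and a 13C-labeling design — at the raw-scan level:
Gaussian chromatographic profiles on a fixed scan grid, lognormal
between-replicate intensity noise, uniform low-level noise centroids,
sub-ppm m/z jitter, and data-dependent MS2 scans near each compound apex
carrying planted fragment spectra. The same seed always produces identical
output, and every planted property (expected feature m/z/RT, group means,
differential set, pattern hits, labeled pairs) is returned as a
:class:`GroundTruth` registry so downstream stages can be verified exactly.

What this emulates and what it does not: peaks are pure Gaussians on a
noiseless baseline grid (real peaks tail and drift), isotope envelopes and
adducts are not simulated, and MS2 is one clean scan per compound apex
rather than a full top-N duty cycle.
"""

from __future__ import annotations

import base64
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .chem import C13_DELTA, ion_mz
from .features import FeatureTable
from .rawdata import RawRun, Spectrum

__all__ = [
    "SimCompound",
    "SimSpec",
    "GroundTruth",
    "generate_dataset",
    "write_mzml",
    "comparative_benchmark",
    "pattern_benchmark",
    "label_benchmark_table",
    "null_table",
    "GLEA_FRAGMENT_MZ",
    "FORMIC_ACID_LOSS",
]

#: Diagnostic hexosyl-glycerophosphate headgroup fragment ([M-H]- of C9H19O11P).
GLEA_FRAGMENT_MZ = round(ion_mz("C9H19O11P", "[M-H]-"), 4)

#: Neutral loss of formic acid (monoisotopic CH2O2), Da.
FORMIC_ACID_LOSS = 46.0055


@dataclass
class SimCompound:
    """One planted ion species: observed m/z, RT apex, Gaussian width, and a
    mean apex intensity per sample group (groups omitted = absent)."""

    cid: str
    mz: float
    rt: float
    heights: Dict[str, float]
    sigma: float = 3.0
    cv: float = 0.2
    ms2: Optional[List[Tuple[float, float]]] = None  # (fragment m/z, relative intensity)
    tags: Tuple[str, ...] = ()


@dataclass
class SimSpec:
    """Full description of a simulated experiment; ``seed`` fixes all
    randomness."""

    seed: int
    groups: Dict[str, int]  # group -> replicate count
    compounds: List[SimCompound]
    rt_range: Tuple[float, float] = (0.0, 1500.0)
    scan_interval: float = 1.0
    noise_per_scan: int = 20
    noise_mz_range: Tuple[float, float] = (150.0, 800.0)
    noise_mean_intensity: float = 30.0
    mz_jitter_ppm: float = 0.5
    ms2_rt_offset: float = 0.4
    min_resolvable_mz: float = 0.01
    min_resolvable_rt: float = 10.0


@dataclass
class GroundTruth:
    """Registry of everything planted, for exact downstream verification."""

    registry: pd.DataFrame  # cid, mz, rt, sigma + mean_<group> columns
    differential_ids: Set[str] = field(default_factory=set)
    blank_only_ids: Set[str] = field(default_factory=set)
    pattern_hits: Dict[str, Set[str]] = field(default_factory=dict)
    label_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    warnings: List[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        import json

        payload = {
            "registry": self.registry.to_dict(orient="records"),
            "differential_ids": sorted(self.differential_ids),
            "blank_only_ids": sorted(self.blank_only_ids),
            "pattern_hits": {k: sorted(v) for k, v in self.pattern_hits.items()},
            "label_pairs": self.label_pairs.to_dict(orient="records"),
            "warnings": self.warnings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with the requested CV."""
    if cv <= 0:
        return np.ones(n)
    s = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=n)


def generate_dataset(spec: SimSpec) -> Tuple[List[RawRun], GroundTruth]:
    """Simulate all runs of a :class:`SimSpec`.

    Returns the runs (sample ids ``<group>_<i>``) and the ground-truth
    registry. Compounds closer than the resolvable spacing in both m/z and
    RT are noted in ``GroundTruth.warnings`` rather than raising.
    """
    rng = np.random.default_rng(spec.seed)
    t0, t1 = spec.rt_range
    scan_times = np.arange(t0, t1 + 1e-9, spec.scan_interval)
    n_scans = scan_times.size

    comps = spec.compounds
    cmz = np.array([c.mz for c in comps])
    crt = np.array([c.rt for c in comps])
    csig = np.array([c.sigma for c in comps])

    truth_warnings: List[str] = []
    order = np.argsort(cmz, kind="stable")
    for a, b in zip(order[:-1], order[1:]):
        if abs(cmz[b] - cmz[a]) < spec.min_resolvable_mz and abs(crt[b] - crt[a]) < spec.min_resolvable_rt:
            truth_warnings.append(
                f"compounds {comps[a].cid} and {comps[b].cid} may be unresolvable"
            )

    runs: List[RawRun] = []
    for group, n_rep in spec.groups.items():
        heights_mean = np.array([c.heights.get(group, 0.0) for c in comps])
        for rep in range(1, n_rep + 1):
            sample_id = f"{group}_{rep}"
            factors = _lognormal_factors(rng, comps[0].cv if comps else 0.2, len(comps))
            apex = heights_mean * factors
            jitter = rng.uniform(-1.0, 1.0, len(comps)) * spec.mz_jitter_ppm * 1e-6
            mz_obs = cmz * (1.0 + jitter)

            active = np.nonzero(apex > 0)[0]
            i0 = np.clip(np.ceil((crt[active] - 4 * csig[active] - t0) / spec.scan_interval), 0, n_scans - 1).astype(int)
            i1 = np.clip(np.floor((crt[active] + 4 * csig[active] - t0) / spec.scan_interval), 0, n_scans - 1).astype(int)
            counts = i1 - i0 + 1
            total = int(counts.sum())
            comp_rep = np.repeat(np.arange(active.size), counts)
            starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
            scan_idx = np.arange(total) - np.repeat(starts, counts) + np.repeat(i0, counts)
            t = t0 + scan_idx * spec.scan_interval
            k = active[comp_rep]
            inten = apex[k] * np.exp(-((t - crt[k]) ** 2) / (2 * csig[k] ** 2))
            keep = inten >= 1.0
            sig_scan, sig_mz, sig_int = scan_idx[keep], mz_obs[k][keep], inten[keep]

            n_noise = n_scans * spec.noise_per_scan
            noise_scan = np.repeat(np.arange(n_scans), spec.noise_per_scan)
            noise_mz = rng.uniform(*spec.noise_mz_range, n_noise)
            noise_int = rng.exponential(spec.noise_mean_intensity, n_noise)

            all_scan = np.concatenate([sig_scan, noise_scan])
            all_mz = np.concatenate([sig_mz, noise_mz])
            all_int = np.concatenate([sig_int, noise_int])
            order2 = np.lexsort((all_mz, all_scan))
            all_scan, all_mz, all_int = all_scan[order2], all_mz[order2], all_int[order2]
            per_scan = np.bincount(all_scan, minlength=n_scans)
            offs = np.concatenate([[0], np.cumsum(per_scan)])

            spectra = [
                Spectrum(
                    rt=float(scan_times[i]),
                    ms_level=1,
                    mz=all_mz[offs[i] : offs[i + 1]],
                    intensity=all_int[offs[i] : offs[i + 1]],
                )
                for i in range(n_scans)
            ]
            for ci in active:
                c = comps[ci]
                if not c.ms2:
                    continue
                frag_mz = np.array([f[0] for f in c.ms2])
                frag_int = np.array([f[1] for f in c.ms2]) * apex[ci] * 0.1
                fj = rng.uniform(-1.0, 1.0, frag_mz.size) * 1e-6  # <= 1 ppm jitter
                spectra.append(
                    Spectrum(
                        rt=float(crt[ci] + spec.ms2_rt_offset),
                        ms_level=2,
                        mz=frag_mz * (1 + fj),
                        intensity=frag_int,
                        precursor_mz=float(mz_obs[ci]),
                        precursor_intensity=float(apex[ci]),
                        isolation_window=1.0,
                    )
                )
            runs.append(RawRun(sample_id=sample_id, group=group, spectra=spectra))

    rows = []
    for c in comps:
        row = {"cid": c.cid, "mz": c.mz, "rt": c.rt, "sigma": c.sigma}
        for g in spec.groups:
            row[f"mean_{g}"] = c.heights.get(g, 0.0)
        rows.append(row)
    registry = pd.DataFrame(rows)

    truth = GroundTruth(registry=registry, warnings=truth_warnings)
    truth.differential_ids = {c.cid for c in comps if "differential" in c.tags}
    truth.blank_only_ids = {c.cid for c in comps if "blank_only" in c.tags}
    for c in comps:
        for tag in c.tags:
            if tag.startswith("pattern:"):
                truth.pattern_hits.setdefault(tag.split(":", 1)[1], set()).add(c.cid)
    return runs, truth


# ---------------------------------------------------------------------------
# mzML output
# ---------------------------------------------------------------------------

def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


_MZ_ARRAY_CV = (
    '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
    '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
)


def _binary_array(data: np.ndarray, kind_cv: str) -> str:
    b = _b64(data)
    return (
        f'<binaryDataArray encodedLength="{len(b)}">{_MZ_ARRAY_CV}{kind_cv}'
        f"<binary>{b}</binary></binaryDataArray>"
    )


def _spectrum_xml(i: int, s: Spectrum) -> str:
    parts = [
        f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{s.mz.size}">',
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>',
        '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>',
        '<scanList count="1">'
        '<cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>'
        "<scan>"
        f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.rt:.10f}" '
        'unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>'
        "</scan></scanList>",
    ]
    if s.ms_level >= 2:
        half = (s.isolation_window or 1.0) / 2.0
        pint = s.precursor_intensity or 0.0
        parts.append(
            '<precursorList count="1"><precursor><isolationWindow>'
            f'<cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{s.precursor_mz:.10f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f'<cvParam cvRef="MS" accession="MS:1000828" name="isolation window lower offset" value="{half:.3f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f'<cvParam cvRef="MS" accession="MS:1000829" name="isolation window upper offset" value="{half:.3f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            "</isolationWindow>"
            '<selectedIonList count="1"><selectedIon>'
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz:.10f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f'<cvParam cvRef="MS" accession="MS:1000042" name="peak intensity" value="{pint:.3f}" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
            "</selectedIon></selectedIonList>"
            '<activation><cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation" value=""/></activation>'
            "</precursor></precursorList>"
        )
    parts.append('<binaryDataArrayList count="2">')
    parts.append(
        _binary_array(
            s.mz,
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>',
        )
    )
    parts.append(
        _binary_array(
            s.intensity,
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>',
        )
    )
    parts.append("</binaryDataArrayList></spectrum>")
    return "".join(parts)


def write_mzml(runs: Sequence[RawRun], out_dir: "str | Path") -> List[Path]:
    """Write each run as a centroided mzML file (``<sample_id>.mzML``),
    64-bit float arrays, uncompressed; round-trips through
    :func:`metabocompare.rawdata.read_run`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: List[Path] = []
    for run in runs:
        body = "".join(_spectrum_xml(i, s) for i, s in enumerate(run.spectra))
        doc = (
            '<?xml version="1.0" encoding="utf-8"?>'
            '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
            '<cvList count="2">'
            '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
            '<cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
            "</cvList>"
            "<fileDescription><fileContent>"
            '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
            "</fileContent></fileDescription>"
            '<softwareList count="1"><software id="metabocompare" version="0.1.0"/></softwareList>'
            '<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1"/></instrumentConfigurationList>'
            '<dataProcessingList count="1"><dataProcessing id="DP1"><processingMethod order="0" softwareRef="metabocompare"/></dataProcessing></dataProcessingList>'
            f'<run id="{run.sample_id}" defaultInstrumentConfigurationRef="IC1">'
            f'<spectrumList count="{len(run.spectra)}" defaultDataProcessingRef="DP1">'
            f"{body}"
            "</spectrumList></run></mzML>"
        )
        path = out_dir / f"{run.sample_id}.mzML"
        path.write_text(doc)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Benchmark builders (the bundled study conditions)
# ---------------------------------------------------------------------------

def _mz_grid(rng: np.random.Generator, n: int, lo: float, hi: float, jitter: float) -> np.ndarray:
    """n well-separated m/z positions: a uniform grid, jittered and
    shuffled, so no two compounds collide within grouping tolerances."""
    grid = np.linspace(lo, hi, n)
    grid = grid + rng.uniform(-jitter, jitter, n)
    rng.shuffle(grid)
    return grid


def comparative_benchmark(
    seed: int,
    n_features: int = 4000,
    n_differential: int = 50,
    n_blank_only: int = 100,
    n_per_group: int = 3,
    n_blanks: int = 2,
    fold: float = 20.0,
    cv: float = 0.2,
    base_height: float = 1e5,
    diff_control_height: float = 1e6,
    noise_per_scan: int = 20,
) -> SimSpec:
    """The bundled comparative study: wildtype vs mutant (3 + 3) plus blanks.

    ``n_features`` sample-derived compounds (absent from blanks), of which
    ``n_differential`` are strongly mutant-enriched (planted fold = 20, i.e.
    comfortably past a 10-fold filter) and intense enough to sit in the top
    intensity percentile; the rest have equal lognormal-distributed means in
    both biological groups. ``n_blank_only`` background compounds appear
    only in blanks.
    """
    rng = np.random.default_rng(seed)
    total = n_features + n_blank_only
    mzs = _mz_grid(rng, total, 150.0, 800.0, 0.03)
    rts = rng.uniform(100.0, 1400.0, total)
    null_heights = base_height * rng.lognormal(0.0, 1.0, n_features)
    diff_idx = set(rng.choice(n_features, size=n_differential, replace=False).tolist())

    compounds: List[SimCompound] = []
    for i in range(n_features):
        if i in diff_idx:
            heights = {"wt": diff_control_height, "mut": fold * diff_control_height}
            tags: Tuple[str, ...] = ("differential",)
        else:
            heights = {"wt": float(null_heights[i]), "mut": float(null_heights[i])}
            tags = ()
        compounds.append(
            SimCompound(
                cid=f"c{i:05d}", mz=float(mzs[i]), rt=float(rts[i]), heights=heights,
                cv=cv, tags=tags,
            )
        )
    for j in range(n_blank_only):
        i = n_features + j
        compounds.append(
            SimCompound(
                cid=f"b{j:04d}", mz=float(mzs[i]), rt=float(rts[i]),
                heights={"blank": 5e5}, cv=cv, tags=("blank_only",),
            )
        )
    return SimSpec(
        seed=seed,
        groups={"wt": n_per_group, "mut": n_per_group, "blank": n_blanks},
        compounds=compounds,
        noise_per_scan=noise_per_scan,
    )


def pattern_benchmark(
    seed: int,
    n_glea: int = 10,
    n_loss: int = 8,
    n_plain: int = 12,
) -> SimSpec:
    """Two-replicate single-group dataset whose MS2 spectra carry planted
    fragmentation patterns: the hexosyl-glycerophosphate diagnostic ion
    (m/z 333.0592), a formic-acid neutral loss (46.0055 Da), or neither."""
    rng = np.random.default_rng(seed)
    total = n_glea + n_loss + n_plain
    mzs = _mz_grid(rng, total, 380.0, 700.0, 0.05)
    rts = rng.uniform(60.0, 480.0, total)

    def random_fragments(precursor: float, avoid: Sequence[float], k: int) -> List[Tuple[float, float]]:
        out: List[Tuple[float, float]] = []
        while len(out) < k:
            f = float(rng.uniform(80.0, precursor - 60.0))
            if all(abs(f - a) > 0.05 for a in avoid) and all(abs(f - o[0]) > 0.05 for o in out):
                out.append((f, float(rng.uniform(0.1, 0.9))))
        return out

    compounds: List[SimCompound] = []
    for i in range(total):
        prec, rt = float(mzs[i]), float(rts[i])
        loss_frag = prec - FORMIC_ACID_LOSS
        avoid = [GLEA_FRAGMENT_MZ, loss_frag]
        if i < n_glea:
            frags = [(GLEA_FRAGMENT_MZ, 1.0)] + random_fragments(prec, avoid, 2)
            tags: Tuple[str, ...] = ("pattern:glea",)
        elif i < n_glea + n_loss:
            frags = [(loss_frag, 0.8)] + random_fragments(prec, avoid, 2)
            tags = ("pattern:formic_loss",)
        else:
            frags = random_fragments(prec, avoid, 3)
            tags = ()
        compounds.append(
            SimCompound(
                cid=f"p{i:03d}", mz=prec, rt=rt, heights={"wt": 1e6}, cv=0.1,
                ms2=sorted(frags), tags=tags,
            )
        )
    return SimSpec(
        seed=seed,
        groups={"wt": 2},
        compounds=compounds,
        rt_range=(0.0, 540.0),
        noise_per_scan=10,
    )


def _feature_frame(
    mz: np.ndarray, rt: np.ndarray, values: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    df = pd.DataFrame({"mz": mz, "rt": rt})
    df["mzmin"] = df["mz"] - 0.001
    df["mzmax"] = df["mz"] + 0.001
    df["rtmin"] = df["rt"] - 5.0
    df["rtmax"] = df["rt"] + 5.0
    for col, v in values.items():
        df[col] = v
    return df[["mz", "mzmin", "mzmax", "rt", "rtmin", "rtmax", *values]]


def label_benchmark_table(
    seed: int,
    n_pairs: int = 20,
    n_decoys: int = 200,
    n_labels: int = 5,
    n_per_group: int = 3,
    cv: float = 0.15,
) -> Tuple[FeatureTable, pd.DataFrame]:
    """A feature table emulating a 13C tracer experiment: ``n_pairs``
    light/heavy feature pairs (heavy = light + n_labels x 1.0033548 Da,
    co-eluting, abundant only in the labeled group) among ``n_decoys``
    unlabeled features present equally in both groups.

    Returns the table and the planted-pair frame (light_id, heavy_id, n).
    """
    rng = np.random.default_rng(seed)
    n_light = n_pairs + n_decoys
    light_mz = _mz_grid(rng, n_light, 150.0, 700.0, 0.05)
    rts = rng.uniform(60.0, 900.0, n_light)
    heavy_mz = light_mz[:n_pairs] + n_labels * C13_DELTA

    mz = np.concatenate([light_mz, heavy_mz])
    rt = np.concatenate([rts, rts[:n_pairs]])
    samples = [f"unlabeled_{i+1}" for i in range(n_per_group)] + [
        f"labeled_{i+1}" for i in range(n_per_group)
    ]
    groups = {s: s.rsplit("_", 1)[0] for s in samples}
    n_feat = mz.size
    values: Dict[str, np.ndarray] = {}
    base = 1e6 * rng.lognormal(0.0, 0.5, n_light)
    for s in samples:
        v = np.empty(n_feat)
        v[:n_light] = base * _lognormal_factors(rng, cv, n_light)
        if groups[s] == "labeled":
            v[n_light:] = 0.5 * base[:n_pairs] * _lognormal_factors(rng, cv, n_pairs)
        else:
            v[n_light:] = 0.0  # heavy isotopologues absent without the tracer
        values[s] = v
    df = _feature_frame(mz, rt, values)
    df.index = [f"L{i:04d}" for i in range(n_light)] + [f"H{i:04d}" for i in range(n_pairs)]
    table = FeatureTable(df, samples, groups)
    pairs = pd.DataFrame(
        {
            "light_id": [f"L{i:04d}" for i in range(n_pairs)],
            "heavy_id": [f"H{i:04d}" for i in range(n_pairs)],
            "n": n_labels,
        }
    )
    return table, pairs


def null_table(
    seed: int,
    n_features: int = 2000,
    n_per_group: int = 3,
    cv: float = 0.2,
    groups: Tuple[str, str] = ("wt", "mut"),
) -> FeatureTable:
    """A feature table with no group effect: every feature has the same mean
    in both groups with lognormal replicate noise. Used to check that the
    t-test's false-positive rate sits near its nominal level."""
    rng = np.random.default_rng(seed)
    mz = _mz_grid(rng, n_features, 150.0, 800.0, 0.03)
    rt = rng.uniform(60.0, 1400.0, n_features)
    base = 1e5 * rng.lognormal(0.0, 1.0, n_features)
    samples = [f"{g}_{i+1}" for g in groups for i in range(n_per_group)]
    gmap = {s: s.rsplit("_", 1)[0] for s in samples}
    values = {s: base * _lognormal_factors(rng, cv, n_features) for s in samples}
    df = _feature_frame(mz, rt, values)
    df.index = [f"n{i:05d}" for i in range(n_features)]
    return FeatureTable(df, samples, gmap)
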