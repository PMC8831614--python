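"""Raw LC-MS scan data: mzML reading, EIC extraction, and peak detection.

The detector is a simplified centWave-style algorithm: regions of interest
(ROIs) are consecutive centroids within a ppm window, a prefilter demands a
minimum run of scans above an intensity floor, apexes are located on the
per-ROI intensity trace and peak boundaries found by descending from the
apex; a signal-to-noise estimate against flanking signal and a retention
time width window gate the final peak list. Parameter names and defaults
mirror the XCMS centWave interface (ppm, peakwidth, snthresh, prefilter,
noise, mzdiff, mzCenterFun) so settings translate directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import MassTolerance

__all__ = [
    "Spectrum",
    "RawRun",
    "EICTrace",
    "DetectionParams",
    "RawDataError",
    "read_run",
    "extract_eic",
    "integrate_eic",
    "detect_peaks",
    "PEAK_COLUMNS",
]

#: XCMS-style column names of a per-sample peak table.
PEAK_COLUMNS = ["mz", "mzmin", "mzmax", "rt", "rtmin", "rtmax", "area", "maxo", "sn"]


class RawDataError(ValueError):
    """Raised for malformed raw data files or inconsistent scan content."""


@dataclass
class Spectrum:
    """One centroided scan: retention time (s), MS level, and paired
    m/z / intensity arrays. MS2 scans carry precursor metadata."""

    rt: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    precursor_intensity: Optional[float] = None
    isolation_window: Optional[float] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise RawDataError("m/z and intensity arrays differ in length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            # merge exactly-equal centroids so m/z stays strictly increasing
            if np.any(np.diff(self.mz) <= 0):
                uniq, inv = np.unique(self.mz, return_inverse=True)
                summed = np.zeros(uniq.size)
                np.add.at(summed, inv, self.intensity)
                self.mz, self.intensity = uniq, summed
        if np.any(self.intensity < 0):
            raise RawDataError("negative intensities")
        if self.ms_level >= 2 and (self.precursor_mz is None or self.precursor_mz <= 0):
            raise RawDataError("MS2 spectrum requires a positive precursor m/z")


@dataclass
class RawRun:
    """All scans of one sample, ordered by retention time."""

    sample_id: str
    group: str
    spectra: List[Spectrum]

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.spectra = sorted(self.spectra, key=lambda s: s.rt)
        if not any(s.ms_level == 1 for s in self.spectra):
            raise RawDataError(f"run {self.sample_id!r} contains no MS1 spectra")

    @property
    def ms1(self) -> List[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    @property
    def ms2(self) -> List[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


@dataclass
class EICTrace:
    """Extracted ion chromatogram: summed intensity per MS1 scan within a
    narrow m/z window."""

    target_mz: float
    tol: MassTolerance
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rt": self.rt, "intensity": self.intensity})


@dataclass
class DetectionParams:
    """centWave-style detection settings (defaults: 4 ppm, 3-20 s peakwidth,
    S/N >= 3, prefilter 3 scans >= 100)."""

    ppm: float = 4.0
    peakwidth: Tuple[float, float] = (3.0, 20.0)
    snthresh: float = 3.0
    prefilter: Tuple[int, float] = (3, 100.0)
    noise: float = 0.0
    mzdiff: float = -0.005
    mz_center: str = "wMean"
    max_peaks_per_roi: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.peakwidth
        if not (0 < lo <= hi):
            raise ValueError("peakwidth must satisfy 0 < min <= max")
        if self.prefilter[0] < 1:
            raise ValueError("prefilter scan count must be >= 1")


# ---------------------------------------------------------------------------
# mzML input
# ---------------------------------------------------------------------------

def _decode_binary(el, n_expected: int) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    import base64 as _base64
    import zlib as _zlib

    accessions = {c.get("accession") for c in el if c.tag.endswith("cvParam")}
    binary = None
    for c in el:
        if c.tag.endswith("binary"):
            binary = c.text or ""
    raw = _base64.b64decode(binary or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = _zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    arr = np.frombuffer(raw, dtype=dtype).astype(float)
    if n_expected and arr.size != n_expected:
        raise RawDataError(
            f"binary array length {arr.size} != defaultArrayLength {n_expected}"
        )
    return arr


def read_run(path: "str | Path", sample_id: Optional[str] = None, group: str = "") -> RawRun:
    """Read a centroided mzML file into a :class:`RawRun`.

    A self-contained mzML parser (namespace-agnostic, base64 float arrays
    with optional zlib compression). Scan times are normalized to seconds;
    MS2 precursor m/z, intensity and isolation window width are preserved.
    Profile-mode spectra raise :class:`RawDataError` advising centroiding.
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    def cv(el) -> Dict[str, Tuple[str, str]]:
        """accession -> (value, unit accession) over immediate cvParams."""
        return {
            c.get("accession"): (c.get("value", ""), c.get("unitAccession", ""))
            for c in el
            if c.tag.endswith("cvParam")
        }

    def find(el, name: str):
        return [c for c in el.iter() if c.tag.endswith(name)]

    spectra: List[Spectrum] = []
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise RawDataError(f"malformed mzML in {path}: {exc}") from exc
    for spec_el in find(tree.getroot(), "spectrum"):
        params = cv(spec_el)
        if "MS:1000128" in params:
            raise RawDataError(
                f"{path} contains profile-mode spectra; centroid the data first"
            )
        level = int(params.get("MS:1000511", ("1", ""))[0])
        rt_s = 0.0
        for scan_el in find(spec_el, "scan"):
            sp = cv(scan_el)
            if "MS:1000016" in sp:
                val, unit = sp["MS:1000016"]
                rt_s = float(val) * (60.0 if unit == "UO:0000031" else 1.0)
                break
        prec_mz = prec_int = iso = None
        if level >= 2:
            for sel_el in find(spec_el, "selectedIon"):
                sp = cv(sel_el)
                if "MS:1000744" in sp:
                    prec_mz = float(sp["MS:1000744"][0])
                if "MS:1000042" in sp:
                    prec_int = float(sp["MS:1000042"][0])
                break
            for iso_el in find(spec_el, "isolationWindow"):
                sp = cv(iso_el)
                lo = float(sp.get("MS:1000828", ("0.5", ""))[0])
                hi = float(sp.get("MS:1000829", ("0.5", ""))[0])
                iso = lo + hi
                break
        n = int(spec_el.get("defaultArrayLength", "0"))
        mz_arr = np.zeros(0)
        int_arr = np.zeros(0)
        for arr_el in find(spec_el, "binaryDataArray"):
            ap = cv(arr_el)
            if "MS:1000514" in ap:
                mz_arr = _decode_binary(arr_el, n)
            elif "MS:1000515" in ap:
                int_arr = _decode_binary(arr_el, n)
        spectra.append(
            Spectrum(
                rt=rt_s,
                ms_level=level,
                mz=mz_arr,
                intensity=int_arr,
                precursor_mz=prec_mz,
                precursor_intensity=prec_int,
                isolation_window=iso,
            )
        )
    if not spectra:
        raise RawDataError(f"{path} contains no spectra")
    return RawRun(sample_id=sample_id or path.stem, group=group, spectra=spectra)


# ---------------------------------------------------------------------------
# EIC extraction / integration
# ---------------------------------------------------------------------------

def extract_eic(
    run: RawRun,
    mz: float,
    tol: "MassTolerance | float" = MassTolerance(5.0, "ppm"),
    rt_range: Optional[Tuple[float, float]] = None,
) -> EICTrace:
    """Extract an ion chromatogram: per MS1 scan, the summed intensity of
    centroids within ``tol`` of ``mz`` (zero when none)."""
    if not isinstance(tol, MassTolerance):
        tol = MassTolerance(float(tol), "ppm")
    half = tol.window(mz)
    lo, hi = mz - half, mz + half
    rts: List[float] = []
    ints: List[float] = []
    for spec in run.ms1:
        if rt_range is not None and not (rt_range[0] <= spec.rt <= rt_range[1]):
            continue
        a = np.searchsorted(spec.mz, lo, side="left")
        b = np.searchsorted(spec.mz, hi, side="right")
        rts.append(spec.rt)
        ints.append(float(spec.intensity[a:b].sum()) if b > a else 0.0)
    return EICTrace(target_mz=mz, tol=tol, rt=np.array(rts), intensity=np.array(ints))


def integrate_eic(
    trace: EICTrace, rt_window: Optional[Tuple[float, float]] = None
) -> Tuple[float, float]:
    """Trapezoidal area and maximum intensity of a trace over an RT window.

    A disjoint window or an empty trace yields ``(0.0, 0.0)``; a
    single-scan window has zero area by the trapezoid convention but
    reports that scan's intensity as the maximum.
    """
    if trace.rt.size == 0:
        return 0.0, 0.0
    if rt_window is None:
        mask = np.ones(trace.rt.size, dtype=bool)
    else:
        mask = (trace.rt >= rt_window[0]) & (trace.rt <= rt_window[1])
    if not mask.any():
        return 0.0, 0.0
    rt = trace.rt[mask]
    inten = trace.intensity[mask]
    area = float(np.trapezoid(inten, rt)) if rt.size > 1 else 0.0
    return area, float(inten.max())


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def _longest_run(mask: np.ndarray) -> int:
    """Length of the longest run of True values."""
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def _descend(trace: np.ndarray, apex: int, floor: float) -> Tuple[int, int]:
    """Walk outward from the apex until intensity drops below ``floor`` or a
    local minimum is passed; returns inclusive scan-index boundaries."""
    lo = apex
    while lo > 0:
        if trace[lo - 1] < floor:
            break
        if trace[lo - 1] > trace[lo]:  # rising again: stop at the minimum
            break
        lo -= 1
    hi = apex
    n = trace.size
    while hi < n - 1:
        if trace[hi + 1] < floor:
            break
        if trace[hi + 1] > trace[hi]:
            break
        hi += 1
    return lo, hi


def detect_peaks(run: RawRun, params: Optional[DetectionParams] = None) -> pd.DataFrame:
    """Detect chromatographic peaks in one run.

    Returns a DataFrame with XCMS-style columns
    ``mz, mzmin, mzmax, rt, rtmin, rtmax, area, maxo, sn`` (one row per
    peak, empty when nothing qualifies). Reported m/z is the
    intensity-weighted mean of contributing centroids.
    """
    if params is None:
        params = DetectionParams()
    ms1 = run.ms1
    if not ms1:
        raise RawDataError("no MS1 spectra")
    scan_rts = np.array([s.rt for s in ms1])
    n_scans = len(ms1)

    # flatten all centroids above the noise floor
    sizes = [s.mz.size for s in ms1]
    total = int(sum(sizes))
    if total == 0:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    cmz = np.empty(total)
    cint = np.empty(total)
    cscan = np.empty(total, dtype=np.int64)
    pos = 0
    for i, s in enumerate(ms1):
        k = s.mz.size
        cmz[pos : pos + k] = s.mz
        cint[pos : pos + k] = s.intensity
        cscan[pos : pos + k] = i
        pos += k
    if params.noise > 0:
        keep = cint >= params.noise
        cmz, cint, cscan = cmz[keep], cint[keep], cscan[keep]
    if cmz.size == 0:
        return pd.DataFrame(columns=PEAK_COLUMNS)

    order = np.argsort(cmz, kind="stable")
    cmz, cint, cscan = cmz[order], cint[order], cscan[order]

    # ROIs: break the sorted m/z sequence where the gap exceeds the ppm window
    gaps = np.diff(cmz) > (cmz[:-1] * params.ppm * 1e-6)
    roi_starts = np.concatenate([[0], np.nonzero(gaps)[0] + 1])
    roi_ends = np.concatenate([roi_starts[1:], [cmz.size]])

    k_pre, int_pre = params.prefilter
    min_w, max_w = params.peakwidth
    rows: List[Tuple[float, ...]] = []

    for a, b in zip(roi_starts, roi_ends):
        npts = b - a
        if npts < k_pre:
            continue
        roi_scan = cscan[a:b]
        roi_int = cint[a:b]
        roi_mz = cmz[a:b]
        s0, s1 = int(roi_scan.min()), int(roi_scan.max())
        if s1 - s0 + 1 < k_pre:
            continue
        # per-scan trace over the ROI span
        trace = np.zeros(s1 - s0 + 1)
        np.add.at(trace, roi_scan - s0, roi_int)
        if int_pre > 0 and _longest_run(trace >= int_pre) < k_pre:
            continue

        # flanking-signal baseline over the whole ROI trace
        work = trace.copy()
        for _ in range(params.max_peaks_per_roi):
            apex = int(np.argmax(work))
            apex_int = work[apex]
            if apex_int <= 0 or (int_pre > 0 and apex_int < int_pre):
                break
            lo, hi = _descend(work, apex, 0.005 * apex_int)
            width = scan_rts[s0 + hi] - scan_rts[s0 + lo]
            flank = np.concatenate([work[:lo], work[hi + 1 :]])
            baseline = float(np.median(flank)) if flank.size else 0.0
            noise_sd = float(np.std(flank)) if flank.size else 0.0
            sn = (apex_int - baseline) / max(noise_sd, 1.0)
            ok_width = min_w <= width <= max_w
            ok_run = int_pre <= 0 or _longest_run(work[lo : hi + 1] >= int_pre) >= k_pre
            if ok_width and ok_run and sn >= params.snthresh and hi - lo + 1 >= 3:
                seg = work[lo : hi + 1]
                seg_rt = scan_rts[s0 + lo : s0 + hi + 1]
                area = float(np.trapezoid(seg, seg_rt))
                member = (roi_scan >= s0 + lo) & (roi_scan <= s0 + hi)
                w = roi_int[member]
                m = roi_mz[member]
                if params.mz_center == "wMean" and w.sum() > 0:
                    mz_c = float(np.average(m, weights=w))
                else:
                    mz_c = float(np.mean(m))
                rows.append(
                    (
                        mz_c,
                        float(m.min()),
                        float(m.max()),
                        float(scan_rts[s0 + apex]),
                        float(scan_rts[s0 + lo]),
                        float(scan_rts[s0 + hi]),
                        area,
                        float(apex_int),
                        float(sn),
                    )
                )
            # carve out the peak plus its monotone tails so residual flanks
            # are not re-detected as spurious peaks; descent stops at local
            # minima, so a neighboring isomer's rise is preserved
            elo, ehi = lo, hi
            while elo > 0 and 0 < work[elo - 1] <= work[elo]:
                elo -= 1
            while ehi < work.size - 1 and 0 < work[ehi + 1] <= work[ehi]:
                ehi += 1
            work[elo : ehi + 1] = 0.0
            if not work.any():
                break

    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return df.sort_values(["mz", "rt"], kind="stable").reset_index(drop=True)
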