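"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metabocompare.features import FeatureTable
from metabocompare.rawdata import RawRun, Spectrum

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def gaussian_run(
    compounds: Sequence[Tuple[float, float, float, float]],
    rt_range: Tuple[float, float] = (0.0, 600.0),
    interval: float = 1.0,
    sample_id: str = "s1",
    group: str = "g",
    noise_rng: Optional[np.random.Generator] = None,
    noise_per_scan: int = 0,
    noise_mz_range: Tuple[float, float] = (100.0, 900.0),
    noise_scale: float = 30.0,
    min_intensity: float = 0.0,
) -> RawRun:
    """Build an MS1-only run with exact Gaussian profiles; ``compounds`` are
    (mz, rt_apex, sigma, apex_height) tuples."""
    times = np.arange(rt_range[0], rt_range[1] + 1e-9, interval)
    spectra = []
    for t in times:
        mzs: List[float] = []
        ints: List[float] = []
        for mz, rt, sigma, h in compounds:
            v = h * np.exp(-((t - rt) ** 2) / (2 * sigma**2))
            if v > min_intensity:
                mzs.append(mz)
                ints.append(v)
        if noise_rng is not None and noise_per_scan:
            mzs.extend(noise_rng.uniform(*noise_mz_range, noise_per_scan))
            ints.extend(noise_rng.exponential(noise_scale, noise_per_scan))
        spectra.append(Spectrum(rt=float(t), ms_level=1, mz=np.array(mzs), intensity=np.array(ints)))
    return RawRun(sample_id=sample_id, group=group, spectra=spectra)


def make_table(
    values: Dict[str, Sequence[float]],
    groups: Dict[str, str],
    mz: Optional[Sequence[float]] = None,
    rt: Optional[Sequence[float]] = None,
    index: Optional[Sequence] = None,
) -> FeatureTable:
    """Build a FeatureTable directly from per-sample intensity vectors."""
    samples = list(values)
    n = len(next(iter(values.values())))
    mz = np.asarray(mz if mz is not None else 200.0 + np.arange(n) * 1.0, dtype=float)
    rt = np.asarray(rt if rt is not None else 100.0 + np.arange(n) * 10.0, dtype=float)
    df = pd.DataFrame(
        {
            "mz": mz,
            "mzmin": mz - 0.001,
            "mzmax": mz + 0.001,
            "rt": rt,
            "rtmin": rt - 5.0,
            "rtmax": rt + 5.0,
            **{s: np.asarray(v, dtype=float) for s, v in values.items()},
        }
    )
    if index is not None:
        df.index = list(index)
    return FeatureTable(df, samples, dict(groups))


@pytest.fixture
def simple_table() -> FeatureTable:
    """3 vs 3 table with one strongly differential feature (row 0), one null
    (row 1) and one blank-dominated feature (row 2)."""
    return make_table(
        {
            "wt_1": [1000.0, 500.0, 100.0],
            "wt_2": [1200.0, 520.0, 110.0],
            "wt_3": [1100.0, 480.0, 90.0],
            "mut_1": [20000.0, 510.0, 100.0],
            "mut_2": [22000.0, 505.0, 105.0],
            "mut_3": [21000.0, 495.0, 95.0],
            "blank_1": [0.0, 10.0, 300.0],
            "blank_2": [0.0, 12.0, 320.0],
        },
        {
            "wt_1": "wt", "wt_2": "wt", "wt_3": "wt",
            "mut_1": "mut", "mut_2": "mut", "mut_3": "mut",
            "blank_1": "blank", "blank_2": "blank",
        },
    )
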