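"""Shared containers and constants for breathogram data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MZ_MIN = 35
MZ_MAX = 350
N_MZ = MZ_MAX - MZ_MIN + 1

CLASSES = ("healthy", "transient_wheeze", "asthma")

RT_WINDOW = (1.3, 23.0)


@dataclass
class Chromatogram:
    """One breathogram: a TIC trace with per-scan stick mass spectra.

    ``rt`` is a strictly increasing uniform grid in minutes; ``spectra`` has
    one row per scan over integer m/z 35-350.  The scan-count lockstep
    between TIC and spectra is an invariant every preprocessing operation
    preserves.
    """

    rt: np.ndarray
    tic: np.ndarray
    spectra: np.ndarray
    sample_id: str
    mz: np.ndarray = field(default_factory=lambda: np.arange(MZ_MIN, MZ_MAX + 1))

    def __post_init__(self) -> None:
        if not (len(self.rt) == len(self.tic) == self.spectra.shape[0]):
            raise ValueError("rt, tic and spectra must have one entry per scan")

    @property
    def grid_step(self) -> float:
        return float(self.rt[1] - self.rt[0])


@dataclass
class Peak:
    """A detected TIC peak with integration bounds and consensus spectrum."""

    apex_rt: float
    area: float
    start_rt: float
    end_rt: float
    spectrum: np.ndarray


@dataclass
class PeakList:
    """All peaks of one sample, ordered by apex retention time."""

    sample_id: str
    peaks: list[Peak]

    def __len__(self) -> int:
        return len(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "apex_rt": [p.apex_rt for p in self.peaks],
                "start_rt": [p.start_rt for p in self.peaks],
                "end_rt": [p.end_rt for p in self.peaks],
                "area": [p.area for p in self.peaks],
            }
        )
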