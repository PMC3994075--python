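"""Shared fixtures: small synthetic libraries, cohorts and peak lists."""

import numpy as np
import pandas as pd
import pytest

from breathomics import synthetic
from breathomics.core import N_MZ, Peak, PeakList


@pytest.fixture(scope="session")
def small_library():
    return synthetic.generate_compound_library(40, seed=11)


@pytest.fixture(scope="session")
def null_cohort():
    """Two wheeze classes, no planted effects: labels carry no signal."""
    lib = synthetic.generate_compound_library(60, seed=5)
    design = synthetic.CohortDesign(
        n_subjects_per_class=(1, 18, 18),
        samples_per_subject=(3, 5),
        n_compounds=60,
        effect_table={},
        seed=5,
    )
    meta, truth = synthetic.generate_cohort(design, lib)
    return meta, truth


def ideal_peaklists(
    library,
    abundances: pd.DataFrame,
    rt_shift_sd: float = 0.0,
    seed: int = 0,
) -> list[PeakList]:
    """Noise-free peak lists straight from the library (no rendering).

    Each present compound becomes one peak with the library spectrum and the
    true abundance as area; apex times optionally jitter by a small shift.
    """
    rng = np.random.default_rng(seed)
    out = []
    for sid in abundances.index:
        peaks = []
        a = abundances.loc[sid]
        for j, cid in enumerate(abundances.columns):
            if a.iloc[j] == 0:
                continue
            rt = library.true_rt[j] + (
                rng.normal(0, rt_shift_sd) if rt_shift_sd else 0.0
            )
            peaks.append(
                Peak(
                    apex_rt=float(rt),
                    area=float(a.iloc[j]),
                    start_rt=float(rt - 0.1),
                    end_rt=float(rt + 0.1),
                    spectrum=library.spectra[j].copy(),
                )
            )
        out.append(PeakList(sample_id=str(sid), peaks=peaks))
    return out


@pytest.fixture(scope="session")
def gaussian_chromatogram():
    """A clean multi-peak chromatogram on a fine grid, with analytic areas."""
    rt = np.arange(0.0, 25.0 + 1e-9, 0.02)
    apexes = [5.0, 10.0, 15.0, 20.0]
    areas = [2.0, 1.0, 3.0, 1.5]
    sigma = 0.06
    tic = np.zeros_like(rt)
    for mu, a in zip(apexes, areas):
        tic += a * np.exp(-0.5 * ((rt - mu) / sigma) ** 2) / (
            sigma * np.sqrt(2 * np.pi)
        )
    spectra = np.tile(tic[:, None], (1, N_MZ)) / N_MZ
    from breathomics.core import Chromatogram

    chrom = Chromatogram(rt=rt, tic=tic, spectra=spectra, sample_id="toy")
    return chrom, apexes, areas, sigma
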