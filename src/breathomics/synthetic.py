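"""Synthetic breath-cohort generator.

Emulates a longitudinal preschool-wheeze breathomics study: three clinical
classes (healthy, transient wheeze, asthma), repeated breath samples per
child, and raw GC-MS breathograms rendered from a shared library of volatile
organic compounds (VOCs).  Every generated object carries its ground truth,
so the preprocessing, feature-building and classification stages can be
scored against known answers.

The abundance model is log-normal with three variance layers:

    log a[s, c] = log(base_c) + log(effect[class(s), c])
                  + u[subject(s), c] + e[s, c]

where ``u ~ N(0, subject_sd^2)`` is a per-subject random intercept shared by
all of a child's samples and ``e ~ N(0, sample_sd^2)`` is per-sample noise.
Class effects are multiplicative on abundance (additive on the log scale), so
a planted discriminatory compound has a signed direction: up- or
down-regulated in asthma relative to transient wheeze.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .core import CLASSES, MZ_MAX, MZ_MIN, N_MZ, RT_WINDOW, Chromatogram


class InvalidDesignError(ValueError):
    """Raised when a cohort design or library request is inconsistent."""


@dataclass
class CompoundLibrary:
    """A shared pool of compounds that breath samples draw from.

    Each compound has a true retention time inside the retained window, a
    stick mass spectrum over integer m/z 35-350 normalized to unit maximum,
    a relative base abundance and a chromatographic peak width (minutes).
    """

    compound_ids: list[str]
    true_rt: np.ndarray          # minutes, strictly inside (1.3, 23)
    spectra: np.ndarray          # (n_compounds, N_MZ), unit max per row
    base_abundance: np.ndarray   # positive relative scale
    peak_sigma: np.ndarray       # Gaussian sd of the eluting peak, minutes

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def mz(self) -> np.ndarray:
        return np.arange(MZ_MIN, MZ_MAX + 1)


@dataclass
class CohortDesign:
    """Parameters of a synthetic cohort.

    ``n_subjects_per_class`` follows the class order (healthy,
    transient_wheeze, asthma).  ``effect_table`` maps compound id to a
    per-class multiplicative abundance shift; compounds listed there are the
    planted discriminatory VOCs.  Standard deviations act on log-abundance.
    """

    n_subjects_per_class: tuple[int, int, int] = (49, 121, 76)
    samples_per_subject: tuple[int, int] = (3, 7)
    n_compounds: int = 400
    effect_table: dict[str, dict[str, float]] = field(default_factory=dict)
    subject_sd: float = 0.4
    sample_sd: float = 0.3
    noise_sd: float = 0.01
    baseline_amplitude: float = 1.0
    max_rt_shift: float = 0.15
    zero_inflation: float = 0.3
    seed: int = 0

    @property
    def n_discriminatory(self) -> int:
        return len(self.effect_table)

    def validate(self) -> None:
        if len(self.n_subjects_per_class) != 3 or any(
            n < 1 for n in self.n_subjects_per_class
        ):
            raise InvalidDesignError(
                "three-class output requires at least one subject per class"
            )
        lo, hi = self.samples_per_subject
        if not (1 <= lo <= hi):
            raise InvalidDesignError("samples_per_subject range invalid")
        if self.n_discriminatory > self.n_compounds:
            raise InvalidDesignError("more discriminatory compounds than compounds")
        if not (0.0 <= self.zero_inflation < 1.0):
            raise InvalidDesignError("zero_inflation must be in [0, 1)")
        for sd in (self.subject_sd, self.sample_sd):
            if sd < 0:
                raise InvalidDesignError("variance components must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    abundances: pd.DataFrame            # samples x compounds, true scale
    discriminatory: list[str]
    signs: dict[str, int]               # asthma-vs-transient direction, +1/-1/0
    effect_table: dict[str, dict[str, float]]
    rt_shift: dict[str, np.ndarray] = field(default_factory=dict)
    baseline: dict[str, np.ndarray] = field(default_factory=dict)


def generate_compound_library(
    n_compounds: int,
    seed: int,
    rt_window: tuple[float, float] = RT_WINDOW,
    sigma_range: tuple[float, float] = (0.03, 0.08),
) -> CompoundLibrary:
    """Draw a random compound library.

    Retention times are uniform strictly inside the retained window (with a
    3-sigma margin so rendered peaks stay inside it), spectra are sparse
    random sticks (8-25 lines) with unit maximum, and base abundances are
    log-normal so a few compounds dominate the total ion current, as in
    real breath.  Deterministic for a fixed seed.
    """
    if n_compounds < 2:
        raise InvalidDesignError("a library needs at least 2 compounds")
    rng = np.random.default_rng(seed)
    lo, hi = rt_window
    sigma = rng.uniform(*sigma_range, size=n_compounds)
    margin = 3.0 * sigma_range[1]
    rt = rng.uniform(lo + margin, hi - margin, size=n_compounds)
    rt.sort()
    spectra = np.zeros((n_compounds, N_MZ))
    for i in range(n_compounds):
        n_lines = int(rng.integers(8, 26))
        pos = rng.choice(N_MZ, size=n_lines, replace=False)
        spectra[i, pos] = rng.exponential(1.0, size=n_lines)
        spectra[i] /= spectra[i].max()
    base = rng.lognormal(mean=1.0, sigma=1.0, size=n_compounds)
    ids = [f"C{i:04d}" for i in range(n_compounds)]
    return CompoundLibrary(ids, rt, spectra, base, sigma)


def make_effect_table(
    library: CompoundLibrary,
    n_shared: int = 7,
    n_healthy_model: int = 5,
    n_wheeze_model: int = 5,
    effect: float = 0.8,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Build a signed effect table with the two-model structure of the study.

    Three groups of planted VOCs:

    * ``n_shared`` asthma-specific compounds: shifted in asthma only, hence
      visible to both binary models (healthy-vs-asthma and
      transient-vs-asthma).
    * ``n_healthy_model`` inflammation compounds: shifted equally in both
      wheeze classes, visible only to the healthy-vs-asthma model.
    * ``n_wheeze_model`` progression compounds: shifted in transient wheeze
      only, visible only to the transient-vs-asthma model.

    ``effect`` is the absolute log-scale shift; each compound's direction is
    drawn at random so up- and down-regulated VOCs both occur.
    """
    n_total = n_shared + n_healthy_model + n_wheeze_model
    if n_total > library.n_compounds:
        raise InvalidDesignError("effect table larger than library")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(library.n_compounds, size=n_total, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_total)
    table: dict[str, dict[str, float]] = {}
    for k, (idx, s) in enumerate(zip(chosen, signs)):
        cid = library.compound_ids[int(idx)]
        m = float(np.exp(s * effect))
        if k < n_shared:
            table[cid] = {"healthy": 1.0, "transient_wheeze": 1.0, "asthma": m}
        elif k < n_shared + n_healthy_model:
            table[cid] = {"healthy": 1.0, "transient_wheeze": m, "asthma": m}
        else:
            table[cid] = {"healthy": 1.0, "transient_wheeze": m, "asthma": 1.0}
    return table


def _effect_signs(effect_table: dict[str, dict[str, float]]) -> dict[str, int]:
    """Asthma-vs-transient direction of each planted compound."""
    signs = {}
    for cid, eff in effect_table.items():
        d = np.log(eff.get("asthma", 1.0)) - np.log(eff.get("transient_wheeze", 1.0))
        signs[cid] = int(np.sign(d))
    return signs


def generate_cohort(
    design: CohortDesign, library: CompoundLibrary
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate sample metadata and true abundances for a cohort.

    Returns a metadata frame (sample_id, subject_id, class, visit) and a
    :class:`GroundTruth` whose ``abundances`` are the noiseless-chromatogram
    peak areas each breathogram will integrate to.  Zeros mark compounds
    genuinely absent from a sample (only non-discriminatory compounds are
    zero-inflated, with probability ``design.zero_inflation``).
    """
    design.validate()
    if library.n_compounds < design.n_compounds:
        raise InvalidDesignError("library smaller than design.n_compounds")
    for cid in design.effect_table:
        if cid not in library.compound_ids:
            raise InvalidDesignError(f"effect table references unknown compound {cid}")
    rng = np.random.default_rng(design.seed)
    ids = library.compound_ids[: design.n_compounds]
    base_log = np.log(library.base_abundance[: design.n_compounds])
    disc = [cid for cid in design.effect_table if cid in ids]
    disc_mask = np.isin(ids, disc)

    # per-class log effect matrix (3, n_compounds)
    class_shift = np.zeros((3, design.n_compounds))
    col = {cid: j for j, cid in enumerate(ids)}
    for cid, eff in design.effect_table.items():
        if cid in col:
            for ci, cls in enumerate(CLASSES):
                class_shift[ci, col[cid]] = np.log(eff.get(cls, 1.0))

    rows, meta_rows = [], []
    lo, hi = design.samples_per_subject
    subj_counter = 0
    for ci, (cls, n_subj) in enumerate(zip(CLASSES, design.n_subjects_per_class)):
        for _ in range(n_subj):
            subj_id = f"S{subj_counter:04d}"
            subj_counter += 1
            u = rng.normal(0.0, design.subject_sd, size=design.n_compounds)
            n_samples = int(rng.integers(lo, hi + 1))
            for visit in range(1, n_samples + 1):
                e = rng.normal(0.0, design.sample_sd, size=design.n_compounds)
                log_a = base_log + class_shift[ci] + u + e
                a = np.exp(log_a)
                if design.zero_inflation > 0:
                    drop = rng.random(design.n_compounds) < design.zero_inflation
                    a[drop & ~disc_mask] = 0.0
                sample_id = f"{subj_id}_v{visit}"
                rows.append(a)
                meta_rows.append((sample_id, subj_id, cls, visit))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "subject_id", "class", "visit"]
    )
    abundances = pd.DataFrame(
        np.asarray(rows), index=meta["sample_id"], columns=ids
    )
    truth = GroundTruth(
        abundances=abundances,
        discriminatory=disc,
        signs=_effect_signs(design.effect_table),
        effect_table=design.effect_table,
    )
    return meta, truth


def _smooth_shift(rt: np.ndarray, max_shift: float, rng: np.random.Generator,
                  n_knots: int = 4) -> np.ndarray:
    """A smooth bounded retention-time shift profile over the grid."""
    if max_shift == 0:
        return np.zeros_like(rt)
    knots_x = np.linspace(rt[0], rt[-1], n_knots)
    knots_y = rng.uniform(-max_shift, max_shift, size=n_knots)
    shift = CubicSpline(knots_x, knots_y)(rt)
    return np.clip(shift, -max_shift, max_shift)


def _smooth_baseline(rt: np.ndarray, amplitude: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Non-negative low-frequency chromatographic background."""
    if amplitude == 0:
        return np.zeros_like(rt)
    span = rt[-1] - rt[0]
    b = np.zeros_like(rt)
    for _ in range(3):
        period = rng.uniform(0.5, 1.5) * span
        phase = rng.uniform(0, 2 * np.pi)
        b += rng.uniform(0.2, 1.0) * np.cos(2 * np.pi * rt / period + phase)
    b += rng.uniform(0.5, 1.5) * np.exp(-rt / (0.3 * span))  # injection tail
    b -= b.min()
    if b.max() > 0:
        b *= amplitude / b.max()
    return b


def render_breathogram(
    abundances: np.ndarray | pd.Series,
    library: CompoundLibrary,
    design: CohortDesign,
    sample_id: str = "sample",
    rt_range: tuple[float, float] = (0.0, 25.0),
    grid_step: float = 0.02,
    rng: np.random.Generator | None = None,
) -> tuple[Chromatogram, np.ndarray, np.ndarray]:
    """Render one raw breathogram from true abundances.

    The TIC is a sum of unit-area Gaussian peaks (apex at the shifted true
    retention time, scaled by abundance), plus a smooth baseline and
    heteroscedastic Gaussian noise whose sd grows with the signal.  Per-scan
    stick spectra are the abundance-weighted mixture of the contributing
    compounds' spectra (baseline and noise live on the TIC only).

    Returns ``(chromatogram, shift_profile, baseline_curve)`` so the caller
    can record them in the ground truth.
    """
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    if rng is None:
        rng = np.random.default_rng(design.seed)
    a = np.asarray(abundances, dtype=float)
    n_c = len(a)
    rt = np.arange(rt_range[0], rt_range[1] + grid_step / 2, grid_step)
    n = len(rt)
    shift = _smooth_shift(rt, design.max_rt_shift, rng)
    tic = np.zeros(n)
    spectra = np.zeros((n, N_MZ))
    for c in range(n_c):
        if a[c] == 0:
            continue
        mu = library.true_rt[c]
        mu_shifted = mu + np.interp(mu, rt, shift)
        sig = library.peak_sigma[c]
        i0 = max(0, int(np.floor((mu_shifted - 5 * sig - rt[0]) / grid_step)))
        i1 = min(n, int(np.ceil((mu_shifted + 5 * sig - rt[0]) / grid_step)) + 1)
        window = rt[i0:i1]
        peak = a[c] * np.exp(-0.5 * ((window - mu_shifted) / sig) ** 2) / (
            sig * np.sqrt(2 * np.pi)
        )
        tic[i0:i1] += peak
        spectra[i0:i1] += np.outer(peak, library.spectra[c])
    baseline = _smooth_baseline(rt, design.baseline_amplitude, rng)
    noisy = tic + baseline
    if design.noise_sd > 0:
        sd = design.noise_sd * (1.0 + 0.1 * np.sqrt(np.clip(tic, 0, None)))
        noisy = noisy + rng.normal(0.0, 1.0, size=n) * sd
    chrom = Chromatogram(rt=rt, tic=noisy, spectra=spectra, sample_id=sample_id)
    return chrom, shift, baseline


def render_cohort(
    meta: pd.DataFrame,
    truth: GroundTruth,
    library: CompoundLibrary,
    design: CohortDesign,
    grid_step: float = 0.02,
) -> list[Chromatogram]:
    """Render every sample of a cohort, recording shifts and baselines.

    A child stream is spawned per sample from the design seed, so rendering
    is reproducible and independent of rendering order.
    """
    chroms = []
    ss = np.random.SeedSequence([design.seed, 7_010_001])
    children = ss.spawn(len(meta))
    for k, sid in enumerate(meta["sample_id"]):
        rng = np.random.default_rng(children[k])
        chrom, shift, baseline = render_breathogram(
            truth.abundances.loc[sid, :].to_numpy(),
            library,
            design,
            sample_id=sid,
            grid_step=grid_step,
            rng=rng,
        )
        truth.rt_shift[sid] = shift
        truth.baseline[sid] = baseline
        chroms.append(chrom)
    return chroms
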