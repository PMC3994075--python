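"""Build, filter, normalize and transform the samples x compounds matrix.

Peaks detected in individual breathograms are merged across samples into
compounds by retention-time proximity and mass-spectral correlation; the
resulting relative-area matrix is normalized (total-area or probabilistic
quotient), filtered by the per-class presence ("20%") rule, and optionally
per-subject centered or rank-transformed for downstream modelling.

Zeros are genuine absences: a compound not detected in a sample stays 0 and
is never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import PeakList


@dataclass
class CompoundTable:
    """Samples x compounds matrix of relative peak areas with compound meta.

    ``values`` rows are samples; ``consensus_rt`` and ``consensus_spectrum``
    describe each merged compound (mean apex time, area-weighted mean
    spectrum).
    """

    values: pd.DataFrame
    consensus_rt: pd.Series
    consensus_spectra: np.ndarray  # (n_compounds, n_mz)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def merge_compounds_across_samples(
    peaklists: list[PeakList],
    rt_tolerance: float = 0.1,
    min_spectral_correlation: float = 0.9,
) -> CompoundTable:
    """Greedy agglomeration of per-sample peaks into cross-sample compounds.

    Samples are processed in ascending ``sample_id`` order and peaks in
    ascending retention time, which makes the agglomeration deterministic
    and independent of the order the lists are handed in.  A peak joins the
    existing compound with the highest spectral correlation among those
    within ``rt_tolerance`` of the compound's consensus retention time,
    provided the correlation reaches ``min_spectral_correlation``; otherwise
    it founds a new compound.  A sample contributes at most one peak per
    compound — on a clash the higher-correlation peak wins and the loser
    founds its own compound.
    """
    if not peaklists or all(len(pl) == 0 for pl in peaklists):
        raise ValueError("no peaks to merge")
    ordered = sorted(peaklists, key=lambda pl: pl.sample_id)
    sample_ids = [pl.sample_id for pl in ordered]

    # each compound: list of (sample_id, Peak, correlation-at-merge)
    compounds: list[list[tuple[str, object, float]]] = []

    def consensus(j: int) -> tuple[float, np.ndarray]:
        mem = compounds[j]
        rt = float(np.mean([p.apex_rt for _, p, _ in mem]))
        w = np.array([max(p.area, 1e-12) for _, p, _ in mem])
        spec = np.sum([wi * p.spectrum for wi, (_, p, _) in zip(w, mem)], axis=0)
        return rt, spec / w.sum()

    cons_cache: list[tuple[float, np.ndarray]] = []

    def add_compound(sid, peak, corr=1.0):
        compounds.append([(sid, peak, corr)])
        cons_cache.append((peak.apex_rt, peak.spectrum))

    for pl in ordered:
        sid = pl.sample_id
        for peak in sorted(pl.peaks, key=lambda p: p.apex_rt):
            best_j, best_corr = -1, -np.inf
            for j, (crt, cspec) in enumerate(cons_cache):
                if abs(peak.apex_rt - crt) > rt_tolerance:
                    continue
                corr = _pearson(peak.spectrum, cspec)
                if corr >= min_spectral_correlation and corr > best_corr:
                    best_j, best_corr = j, corr
            if best_j < 0:
                add_compound(sid, peak)
                continue
            j = best_j
            holder = next(
                (k for k, (s, _, _) in enumerate(compounds[j]) if s == sid), None
            )
            if holder is not None:
                _, prev_peak, prev_corr = compounds[j][holder]
                if best_corr <= prev_corr:
                    add_compound(sid, peak)
                    continue
                compounds[j].pop(holder)  # higher-correlation peak wins
                compounds[j].append((sid, peak, best_corr))
                cons_cache[j] = consensus(j)
                add_compound(sid, prev_peak, prev_corr)
                continue
            compounds[j].append((sid, peak, best_corr))
            cons_cache[j] = consensus(j)

    rts = [c[0] for c in cons_cache]
    order = np.argsort(rts, kind="stable")
    ids = [f"V{k:04d}" for k in range(len(order))]
    mat = np.zeros((len(sample_ids), len(order)))
    row = {sid: i for i, sid in enumerate(sample_ids)}
    n_mz = ordered[0].peaks[0].spectrum.shape[0] if ordered[0].peaks else next(
        pl.peaks[0].spectrum.shape[0] for pl in ordered if pl.peaks
    )
    cons_spec = np.zeros((len(order), n_mz))
    cons_rt = np.zeros(len(order))
    for k, j in enumerate(order):
        cons_rt[k], cons_spec[k] = consensus(j)
        for sid, peak, _ in compounds[j]:
            mat[row[sid], k] = peak.area
    values = pd.DataFrame(mat, index=pd.Index(sample_ids, name="sample_id"),
                          columns=ids)
    return CompoundTable(
        values=values,
        consensus_rt=pd.Series(cons_rt, index=ids, name="consensus_rt"),
        consensus_spectra=cons_spec,
    )


def normalize_total_area(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample (row) by its total peak area."""
    sums = table.sum(axis=1)
    if (sums <= 0).any():
        bad = list(table.index[sums <= 0])
        raise ValueError(f"samples with non-positive total area: {bad}")
    return table.div(sums, axis=0)


def normalize_pqn(table: pd.DataFrame, reference: str = "median") -> pd.DataFrame:
    """Probabilistic quotient normalization.

    Expects a total-area-normalized table.  The reference spectrum is the
    column-wise median over samples; each sample is divided by the median of
    its entrywise quotients to the reference, taken over the entries where
    both the sample and the reference are nonzero.
    """
    if reference != "median":
        raise ValueError("only the median reference is supported")
    ref = table.median(axis=0)
    X = table.to_numpy(dtype=float)
    r = ref.to_numpy(dtype=float)
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        support = (X[i] > 0) & (r > 0)
        if not support.any():
            raise ValueError(
                f"sample {table.index[i]} shares no support with the reference"
            )
        q = np.median(X[i, support] / r[support])
        out[i] = X[i] / q
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def apply_presence_filter(
    table: pd.DataFrame, meta: pd.DataFrame, fraction: float = 0.20
) -> pd.DataFrame:
    """The 20% rule: keep a compound only if it is present often enough.

    A column is kept iff, in at least one class, the fraction of samples
    with a nonzero value reaches ``fraction`` (inclusive comparison).
    """
    classes = meta.set_index("sample_id").loc[table.index, "class"]
    keep = np.zeros(table.shape[1], dtype=bool)
    for cls, idx in classes.groupby(classes).groups.items():
        sub = table.loc[idx]
        if len(sub) == 0:
            raise ValueError(f"class {cls} has no samples")
        frac = (sub.to_numpy() != 0).mean(axis=0)
        keep |= frac >= fraction
    return table.loc[:, keep]


def center_per_subject(table: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Remove each subject's own mean profile (per compound).

    Converts relative concentrations to fluctuations around zero per child,
    suppressing inter-individual variation.  A subject with a single sample
    becomes an all-zero row.
    """
    subjects = meta.set_index("sample_id").loc[table.index, "subject_id"]
    centered = table.copy()
    for _, idx in subjects.groupby(subjects).groups.items():
        centered.loc[idx] = table.loc[idx] - table.loc[idx].mean(axis=0)
    return centered


def rank_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise ranks across samples (smallest value gets rank 1).

    Ties receive the average of the ranks they span.
    """
    ranked = np.apply_along_axis(rankdata, 0, table.to_numpy(dtype=float))
    return pd.DataFrame(ranked, index=table.index, columns=table.columns)
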