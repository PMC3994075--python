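"""Reading and writing the package's plain-text interchange formats.

Chromatograms travel as CSV (``rt_min``, ``tic``, one column per integer
m/z bin), peak lists and tables as TSV.  An mzML reader is provided for
instrument data; all synthetic artifacts use the text formats.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import MZ_MAX, MZ_MIN, N_MZ, Chromatogram, Peak, PeakList


def write_chromatogram_csv(chrom: Chromatogram, path: str) -> None:
    cols = {"rt_min": chrom.rt, "tic": chrom.tic}
    for k, mz in enumerate(chrom.mz):
        cols[f"mz_{mz}"] = chrom.spectra[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def read_chromatogram_csv(path: str, sample_id: str | None = None) -> Chromatogram:
    df = pd.read_csv(path)
    mz_cols = [c for c in df.columns if c.startswith("mz_")]
    mz = np.array([int(c[3:]) for c in mz_cols])
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    return Chromatogram(
        rt=df["rt_min"].to_numpy(dtype=float),
        tic=df["tic"].to_numpy(dtype=float),
        spectra=df[mz_cols].to_numpy(dtype=float),
        sample_id=sample_id,
        mz=mz,
    )


def read_mzml(path: str, sample_id: str | None = None) -> Chromatogram:
    """Read an mzML file into a Chromatogram, binning m/z to integer 35-350."""
    from pyteomics import mzml as pymzml_reader

    rts, tics, spectra = [], [], []
    with pymzml_reader.MzML(path) as reader:
        for scan in reader:
            if scan.get("ms level", 1) != 1:
                continue
            rt = scan["scanList"]["scan"][0]["scan start time"]
            mz = np.asarray(scan["m/z array"], dtype=float)
            inten = np.asarray(scan["intensity array"], dtype=float)
            binned = np.zeros(N_MZ)
            idx = np.rint(mz).astype(int) - MZ_MIN
            ok = (idx >= 0) & (idx <= MZ_MAX - MZ_MIN)
            np.add.at(binned, idx[ok], inten[ok])
            rts.append(float(rt))
            tics.append(float(inten.sum()))
            spectra.append(binned)
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    return Chromatogram(
        rt=np.asarray(rts),
        tic=np.asarray(tics),
        spectra=np.asarray(spectra),
        sample_id=sample_id,
    )


def write_meta_tsv(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_meta_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _spectrum_to_text(spectrum: np.ndarray, mz: np.ndarray) -> str:
    nz = spectrum > 0
    return ";".join(f"{m}:{v:.5g}" for m, v in zip(mz[nz], spectrum[nz]))


def _spectrum_from_text(text: str, mz: np.ndarray) -> np.ndarray:
    out = np.zeros(len(mz))
    if isinstance(text, str) and text:
        base = int(mz[0])
        for pair in text.split(";"):
            m, v = pair.split(":")
            out[int(m) - base] = float(v)
    return out


def write_peaklists_tsv(peaklists: list[PeakList], path: str,
                        mz: np.ndarray | None = None) -> None:
    if mz is None:
        mz = np.arange(MZ_MIN, MZ_MAX + 1)
    rows = []
    for pl in peaklists:
        for p in pl.peaks:
            rows.append(
                {
                    "sample_id": pl.sample_id,
                    "apex_rt": p.apex_rt,
                    "start_rt": p.start_rt,
                    "end_rt": p.end_rt,
                    "area": p.area,
                    "spectrum": _spectrum_to_text(p.spectrum, mz),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_peaklists_tsv(path: str, mz: np.ndarray | None = None) -> list[PeakList]:
    if mz is None:
        mz = np.arange(MZ_MIN, MZ_MAX + 1)
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, sub in df.groupby("sample_id", sort=True):
        peaks = [
            Peak(
                apex_rt=float(r.apex_rt),
                area=float(r.area),
                start_rt=float(r.start_rt),
                end_rt=float(r.end_rt),
                spectrum=_spectrum_from_text(r.spectrum, mz),
            )
            for r in sub.itertuples()
        ]
        out.append(PeakList(sample_id=str(sid), peaks=peaks))
    return out


def write_table_tsv(table: pd.DataFrame, path: str) -> None:
    table.rename_axis("sample_id").to_csv(path, sep="\t", float_format="%.10g")


def read_table_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")
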