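"""Per-breathogram signal cleanup and cross-sample retention alignment.

The cleanup chain mirrors standard GC-MS chemometrics practice: trim the
retention window (noisy spectra at the start of a run, column bleed at the
end), wavelet denoising, asymmetric-least-squares (Whittaker / P-spline)
baseline subtraction, correlation-optimized warping (COW) against a
reference chromatogram, then peak detection and trapezoidal integration on
the cleaned TIC.  All operations keep the per-scan mass spectra in lockstep
with the TIC.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import sparse
from scipy.signal import find_peaks
from scipy.sparse.linalg import spsolve
from sklearn.decomposition import PCA

from .core import Chromatogram, Peak, PeakList


class EmptyWindowError(ValueError):
    """Trim window retains no scans."""


def trim_retention_window(
    chrom: Chromatogram, lo: float = 1.3, hi: float = 23.0
) -> Chromatogram:
    """Keep only scans with ``lo <= rt <= hi`` (both boundaries inclusive)."""
    if lo >= hi:
        raise ValueError("lo must be below hi")
    eps = 1e-9  # tolerate float accumulation on the rt grid
    keep = (chrom.rt >= lo - eps) & (chrom.rt <= hi + eps)
    if not keep.any():
        raise EmptyWindowError(f"no scans in window [{lo}, {hi}]")
    return Chromatogram(
        rt=chrom.rt[keep],
        tic=chrom.tic[keep],
        spectra=chrom.spectra[keep],
        sample_id=chrom.sample_id,
        mz=chrom.mz,
    )


def denoise_wavelet(
    chrom: Chromatogram,
    wavelet: str = "db4",
    level: int = 2,
    threshold_rule: str = "soft",
) -> Chromatogram:
    """Wavelet-shrinkage denoising of the TIC.

    Daubechies decomposition to ``level``; detail coefficients are soft- or
    hard-thresholded with the universal threshold sigma*sqrt(2 log n),
    sigma estimated per level from the median absolute deviation.
    ``threshold_rule="truncate"`` zeroes the detail coefficients instead
    (pure low-pass reconstruction).  Output is clipped at zero.
    """
    x = chrom.tic
    if len(x) < 2**level:
        raise ValueError("signal too short for the requested level")
    coeffs = pywt.wavedec(x, wavelet, level=level)
    out = [coeffs[0]]
    for d in coeffs[1:]:
        if threshold_rule == "truncate":
            out.append(np.zeros_like(d))
            continue
        sigma = np.median(np.abs(d)) / 0.6745
        thr = sigma * np.sqrt(2 * np.log(len(x)))
        out.append(pywt.threshold(d, thr, mode=threshold_rule))
    y = pywt.waverec(out, wavelet)[: len(x)]
    return Chromatogram(
        rt=chrom.rt,
        tic=np.clip(y, 0.0, None),
        spectra=chrom.spectra,
        sample_id=chrom.sample_id,
        mz=chrom.mz,
    )


def asls_baseline(
    y: np.ndarray,
    lam: float = 1e8,
    p: float = 0.1,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> np.ndarray:
    """Asymmetric-least-squares baseline of a 1-D signal.

    Whittaker smoother with a second-order difference penalty of weight
    ``lam`` and asymmetry ``p``: points above the current baseline get
    weight ``p``, points below get ``1 - p``, so the fit hugs the signal's
    lower envelope.  Iterates until the weights stabilize.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    n = len(y)
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    penalty = lam * (D.T @ D)
    w = np.ones(n)
    z = np.zeros(n)
    for _ in range(max_iter):
        W = sparse.diags(w, format="csc")
        z = spsolve(W + penalty, w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.abs(w_new - w).sum() / n < tol:
            w = w_new
            break
        w = w_new
    else:
        warnings.warn("baseline weights did not stabilize; returning last iterate")
    return z


def correct_baseline(
    chrom: Chromatogram,
    lam: float = 1e8,
    p: float = 0.1,
    max_iter: int = 20,
) -> tuple[Chromatogram, np.ndarray]:
    """Subtract the asymmetric-least-squares baseline from the TIC.

    Returns the corrected chromatogram (clipped at zero) and the estimated
    baseline itself.
    """
    z = asls_baseline(chrom.tic, lam=lam, p=p, max_iter=max_iter)
    corrected = Chromatogram(
        rt=chrom.rt,
        tic=np.clip(chrom.tic - z, 0.0, None),
        spectra=chrom.spectra,
        sample_id=chrom.sample_id,
        mz=chrom.mz,
    )
    return corrected, z


# ---------------------------------------------------------------------------
# Correlation optimized warping
# ---------------------------------------------------------------------------


def _nominal_boundaries(n: int, segment_len: int) -> list[int]:
    """Reference boundary grid: multiples of segment_len, last at n-1.

    The final segment absorbs the remainder (it is dropped into the
    previous one when it would hold fewer than 2 points).
    """
    nominal = [i * segment_len for i in range((n - 1) // segment_len + 1)]
    if (n - 1) - nominal[-1] < 2 and len(nominal) > 1 and nominal[-1] != n - 1:
        nominal.pop()
    if nominal[-1] != n - 1:
        nominal.append(n - 1)
    return nominal


def _segment_correlation(target_piece: np.ndarray, ref_piece: np.ndarray) -> float:
    """Pearson correlation after linearly resampling the target piece."""
    m = len(ref_piece)
    xs = np.linspace(0.0, len(target_piece) - 1.0, m)
    warped = np.interp(xs, np.arange(len(target_piece)), target_piece)
    wc = warped - warped.mean()
    rc = ref_piece - ref_piece.mean()
    nw = np.sqrt(wc @ wc)
    nr = np.sqrt(rc @ rc)
    if nw == 0 or nr == 0:
        return 1.0 if nw == nr else 0.0
    return float(wc @ rc / (nw * nr))


TIE_PENALTY = 1e-4   # per point of boundary deviation from nominal
FLAT_FRAC = 1e-3     # segment dynamic range below this fraction of the
                     # signal's range carries no alignment information


def _segment_score(
    target_piece: np.ndarray, ref_piece: np.ndarray, scale: float
) -> float:
    """Alignment score of one segment pair.

    A reference segment whose dynamic range is negligible relative to the
    whole signal carries no alignment information and scores 1.0 no matter
    the target (the boundary is then held in place by the nominal-deviation
    penalty).  Otherwise the score is the Pearson correlation of the
    linearly resampled target piece with the reference piece (0.0 when the
    target piece is flat, since correlation is undefined there).
    """
    if np.ptp(ref_piece) <= FLAT_FRAC * scale:
        return 1.0
    return _segment_correlation(target_piece, ref_piece)


def cow_path_score(
    target: np.ndarray,
    reference: np.ndarray,
    boundaries: list[int] | np.ndarray,
    segment_len: int,
    tie_penalty: float = TIE_PENALTY,
) -> float:
    """The COW objective of one boundary placement.

    Sum of segment-wise scores (:func:`_segment_score`), minus a small
    penalty per point of boundary deviation from the nominal grid.  The
    penalty regularizes uninformative segments and breaks exact ties toward
    the identity warp; correlation differences of real alignment dominate it.
    """
    nominal = _nominal_boundaries(len(reference), segment_len)
    scale = max(np.ptp(reference), np.ptp(target))
    score = 0.0
    for i in range(1, len(nominal)):
        r0, r1 = nominal[i - 1], nominal[i]
        v0, v1 = int(boundaries[i - 1]), int(boundaries[i])
        score += _segment_score(
            target[v0 : v1 + 1], reference[r0 : r1 + 1], scale
        )
        if i < len(nominal) - 1:
            score -= tie_penalty * abs(v1 - nominal[i])
    return float(score)


def cow_warp_path(
    target: np.ndarray,
    reference: np.ndarray,
    segment_len: int = 20,
    slack: int = 7,
) -> tuple[np.ndarray, float]:
    """Optimal COW boundary placement by dynamic programming.

    The reference is cut into segments of ``segment_len`` points (the last
    segment absorbs the remainder); each interior boundary of the target may
    shift by at most ``slack`` points from its nominal position, endpoints
    fixed.  Each target segment is linearly stretched or compressed onto its
    reference segment and scored by the :func:`cow_path_score` objective;
    the returned boundary vector maximizes it globally over the boundary
    grid (verifiable by exhaustive enumeration on small signals).

    Returns ``(boundaries, benefit)`` where ``boundaries[i]`` is the target
    index mapped to reference index ``nominal[i]``.
    """
    n = len(reference)
    if len(target) != n:
        raise ValueError("target and reference must be on equal-length grids")
    if not (segment_len > slack >= 1):
        raise ValueError("need segment_len > slack >= 1")
    if segment_len >= n:
        raise ValueError("segment_len must be below the signal length")
    nominal = _nominal_boundaries(n, segment_len)
    # candidate target positions per boundary
    candidates = [np.array([0])]
    for i in range(1, len(nominal) - 1):
        lo = max(1, nominal[i] - slack)
        hi = min(n - 2, nominal[i] + slack)
        candidates.append(np.arange(lo, hi + 1))
    candidates.append(np.array([n - 1]))

    NEG = -np.inf
    scale = max(np.ptp(reference), np.ptp(target))
    best = [np.full(len(c), NEG) for c in candidates]
    back = [np.zeros(len(c), dtype=int) for c in candidates]
    best[0][0] = 0.0
    for i in range(1, len(candidates)):
        r0, r1 = nominal[i - 1], nominal[i]
        m = r1 - r0 + 1
        ref_piece = reference[r0 : r1 + 1].astype(float)
        ref_flat = np.ptp(ref_piece) <= FLAT_FRAC * scale
        rc = ref_piece - ref_piece.mean()
        nr = np.sqrt(rc @ rc)
        base = np.linspace(0.0, 1.0, m)
        for j, u in enumerate(candidates[i]):
            for k, v in enumerate(candidates[i - 1]):
                if u - v < 2:  # each segment needs at least 2 points
                    continue
                if best[i - 1][k] == NEG:
                    continue
                if ref_flat:
                    corr = 1.0
                else:
                    warped = np.interp(v + base * (u - v),
                                       np.arange(v, u + 1), target[v : u + 1])
                    wc = warped - warped.mean()
                    nw = np.sqrt(wc @ wc)
                    corr = 0.0 if nw == 0 else wc @ rc / (nw * nr)
                if i < len(candidates) - 1:
                    corr -= TIE_PENALTY * abs(u - nominal[i])
                score = best[i - 1][k] + corr
                if score > best[i][j]:
                    best[i][j] = score
                    back[i][j] = k
    if best[-1][0] == NEG:
        raise ValueError("no feasible warp under the given slack")
    n_b = len(candidates)
    idx_path = np.empty(n_b, dtype=int)
    idx_path[-1] = 0
    for i in range(n_b - 1, 0, -1):
        idx_path[i - 1] = back[i][idx_path[i]]
    boundaries = np.array([int(candidates[i][idx_path[i]]) for i in range(n_b)])
    return boundaries, float(best[-1][0])


def _apply_warp(
    values: np.ndarray, boundaries: np.ndarray, nominal: np.ndarray
) -> np.ndarray:
    """Piecewise-linear resampling of ``values`` onto the reference grid."""
    n = len(values)
    out = np.empty(n, dtype=float)
    for i in range(1, len(nominal)):
        r0, r1 = nominal[i - 1], nominal[i]
        v0, v1 = boundaries[i - 1], boundaries[i]
        xs = np.linspace(v0, v1, r1 - r0 + 1)
        out[r0 : r1 + 1] = np.interp(xs, np.arange(n), values)
    return out


def align_cow(
    chrom: Chromatogram,
    reference: Chromatogram | np.ndarray,
    segment_len: int = 20,
    slack: int = 7,
) -> tuple[Chromatogram, np.ndarray]:
    """Align a chromatogram to a reference by correlation-optimized warping.

    The TIC drives the warp; the per-scan spectra are carried along the same
    piecewise-linear warp so peak spectra stay attached to their peaks.
    Returns the aligned chromatogram and the boundary path.
    """
    ref = reference.tic if isinstance(reference, Chromatogram) else np.asarray(reference)
    boundaries, _ = cow_warp_path(chrom.tic, ref, segment_len, slack)
    n = len(ref)
    nominal = np.array(_nominal_boundaries(n, segment_len))
    tic = _apply_warp(chrom.tic, boundaries, nominal)
    spectra = np.empty_like(chrom.spectra)
    for i in range(1, len(nominal)):
        r0, r1 = nominal[i - 1], nominal[i]
        v0, v1 = boundaries[i - 1], boundaries[i]
        xs = np.linspace(v0, v1, r1 - r0 + 1)
        frac = xs - np.floor(xs)
        idx = np.floor(xs).astype(int)
        idx1 = np.minimum(idx + 1, len(chrom.tic) - 1)
        spectra[r0 : r1 + 1] = (
            chrom.spectra[idx] * (1 - frac)[:, None]
            + chrom.spectra[idx1] * frac[:, None]
        )
    aligned = Chromatogram(
        rt=chrom.rt, tic=tic, spectra=spectra, sample_id=chrom.sample_id, mz=chrom.mz
    )
    return aligned, boundaries


def choose_reference(chroms: list[Chromatogram]) -> int:
    """Index of the chromatogram with maximal mean correlation to the rest."""
    tics = np.array([c.tic for c in chroms])
    corr = np.corrcoef(tics)
    return int(np.argmax(corr.mean(axis=1)))


# ---------------------------------------------------------------------------
# Peak detection and integration
# ---------------------------------------------------------------------------


def detect_and_integrate_peaks(
    chrom: Chromatogram,
    min_prominence: float | None = None,
    min_width: int = 3,
) -> PeakList:
    """Detect TIC peaks and integrate their areas.

    Local maxima with prominence at least ``min_prominence`` (default: 5x
    the median absolute deviation of the corrected TIC) and width at least
    ``min_width`` scans.  Integration bounds sit at the flanking minima,
    split at the lowest point between adjacent peaks so bounds never
    overlap; areas are trapezoidal in retention-time units.  The peak
    spectrum is the intensity-weighted mean of the apex-region scan spectra
    (scans within the bounds reaching half the apex height), which limits
    contamination from partially co-eluting neighbours.
    """
    y = chrom.tic
    if min_prominence is None:
        mad = np.median(np.abs(y - np.median(y)))
        min_prominence = 5.0 * max(mad, 1e-12)
    idx, props = find_peaks(y, prominence=min_prominence, width=min_width)
    if len(idx) == 0:
        return PeakList(sample_id=chrom.sample_id, peaks=[])
    bases_l = props["left_bases"]
    bases_r = props["right_bases"]
    starts, ends = [], []
    for k, i in enumerate(idx):
        lo = bases_l[k]
        hi = bases_r[k]
        if k > 0:  # split at the minimum between neighbouring apices
            between = np.argmin(y[idx[k - 1] : i + 1]) + idx[k - 1]
            lo = max(lo, between)
        if k < len(idx) - 1:
            between = np.argmin(y[i : idx[k + 1] + 1]) + i
            hi = min(hi, between)
        starts.append(lo)
        ends.append(hi)
    peaks = []
    for i, lo, hi in zip(idx, starts, ends):
        if hi - lo < 2:
            continue
        area = float(np.trapezoid(y[lo : hi + 1], chrom.rt[lo : hi + 1]))
        region = y[lo : hi + 1]
        apex_sel = region >= 0.5 * y[i]
        w = region[apex_sel]
        total = w.sum()
        spectrum = (
            (w[:, None] * chrom.spectra[lo : hi + 1][apex_sel]).sum(axis=0) / total
            if total > 0
            else chrom.spectra[i].copy()
        )
        peaks.append(
            Peak(
                apex_rt=float(chrom.rt[i]),
                area=area,
                start_rt=float(chrom.rt[lo]),
                end_rt=float(chrom.rt[hi]),
                spectrum=spectrum,
            )
        )
    return PeakList(sample_id=chrom.sample_id, peaks=peaks)


def screen_outliers(
    tic_matrix: np.ndarray, threshold_sd: float = 5.0, n_components: int = 2
) -> np.ndarray:
    """Flag atypical samples by PCA score and residual distances.

    PCA on the row-centered TIC matrix; a sample is flagged when its score
    distance or its orthogonal residual exceeds ``threshold_sd`` robust
    standard deviations (MAD-based) of the cohort.  Flags only — nothing is
    removed automatically.
    """
    X = np.asarray(tic_matrix, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to screen for outliers")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    recon = pca.inverse_transform(scores)
    sd_score = np.sqrt((scores**2).sum(axis=1))
    sd_resid = np.sqrt(((X - recon) ** 2).sum(axis=1))
    flags = np.zeros(X.shape[0], dtype=bool)
    for d in (sd_score, sd_resid):
        med = np.median(d)
        mad = np.median(np.abs(d - med)) / 0.6745
        if mad == 0:
            continue
        flags |= (d - med) / mad > threshold_sd
    return flags


def preprocess_chromatogram(
    chrom: Chromatogram,
    reference: Chromatogram | np.ndarray | None = None,
    trim_lo: float = 1.3,
    trim_hi: float = 23.0,
    wavelet: str = "db4",
    level: int = 2,
    lam: float = 1e8,
    p: float = 0.1,
    segment_len: int = 20,
    slack: int = 7,
) -> Chromatogram:
    """Full cleanup chain: trim, denoise, baseline-correct, then align."""
    c = trim_retention_window(chrom, trim_lo, trim_hi)
    c = denoise_wavelet(c, wavelet=wavelet, level=level)
    c, _ = correct_baseline(c, lam=lam, p=p)
    if reference is not None:
        c, _ = align_cow(c, reference, segment_len=segment_len, slack=slack)
    return c
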