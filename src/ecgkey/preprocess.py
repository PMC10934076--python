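"""Denoising, fiducial delineation, beat normalization and ensembling.

The chain mirrors the standard single-lead pipeline for fiducial-feature
biometrics:

1. ``denoise``  — 60 Hz IIR notch + third-order 0.5 Hz Butterworth high-pass,
   both applied forward-backward (zero phase, no fiducial shift).
2. ``delineate`` — dyadic quadratic-spline wavelet decomposition (the à-trous
   algorithm, scales 2^1..2^4). QRS complexes appear as opposite-sign modulus
   maxima pairs at scale 2^2 with the R peak at the zero crossing between
   them; P and T waves are located the same way at scale 2^4 inside
   physiological search windows; onsets/offsets sit where the modulus falls
   below a fraction of the peak modulus.
3. ``normalize_beat`` — non-linear (per-section) time normalization of the
   PR interval, QRS complex, ST interval and TP tail to fixed standard
   durations representing a 70 bpm beat.
4. ``remove_outliers`` — beats whose correlation with the mean-beat template
   falls below mean(rho) - 0.5*std(rho) are dropped.
5. ``ensemble`` — pointwise mean of the three most template-like beats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import (
    DegenerateSectionError,
    InsufficientBeatsError,
    ParameterError,
)
from .types import LANDMARKS, BeatSet, ECGRecord, EnsembleBeat, FiducialMap


# --------------------------------------------------------------------------
# configuration defaults (every threshold the delineator uses is exposed)
# --------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    notch_freq: float = 60.0
    notch_q: float = 30.0
    highpass_cutoff: float = 0.5
    highpass_order: int = 3
    # beat window around the R peak, pre-normalization
    window_pre_ms: float = 250.0
    window_post_ms: float = 450.0
    # QRS detection
    qrs_threshold: float = 0.25      # fraction of the 99th percentile modulus
    refractory_ms: float = 250.0
    gamma_on: float = 0.05           # QRS onset modulus fraction
    gamma_off: float = 0.09          # QRS offset modulus fraction
    # P/T search windows relative to R (ms) and boundary modulus fraction
    p_search_ms: tuple[float, float] = (-280.0, -80.0)
    t_search_ms: tuple[float, float] = (80.0, 450.0)
    wave_boundary_frac: float = 0.25
    # 70 bpm standard section durations (ms)
    standard_pr_ms: float = 160.0
    standard_qrs_ms: float = 95.0
    standard_st_ms: float = 310.0
    standard_beat_ms: float = 600.0
    # outlier rule multiplier (mean(rho) - outlier_k * std(rho))
    outlier_k: float = 0.5
    # ensemble fiducials: "median" (per-landmark median of sources) or
    # "redelineate" (landmarks re-located on the averaged waveform)
    ensemble_fiducials: str = "median"


# --------------------------------------------------------------------------
# denoising
# --------------------------------------------------------------------------

def denoise(record: ECGRecord, config: PreprocessConfig | None = None) -> ECGRecord:
    """Zero-phase 60 Hz notch + 0.5 Hz high-pass."""
    cfg = config or PreprocessConfig()
    if record.fs < 2 * cfg.notch_freq:
        raise ParameterError(
            f"fs={record.fs} too low to notch {cfg.notch_freq} Hz")
    b, a = sps.iirnotch(cfg.notch_freq, cfg.notch_q, fs=record.fs)
    sos = sps.butter(cfg.highpass_order, cfg.highpass_cutoff,
                     btype="highpass", fs=record.fs, output="sos")
    min_len = 3 * (max(len(b), len(a)) + 6)
    if record.samples.size <= min_len:
        raise ParameterError("record shorter than filter warm-up")
    x = sps.filtfilt(b, a, record.samples)
    x = sps.sosfiltfilt(sos, x)
    return ECGRecord(samples=x, fs=record.fs, subject_id=record.subject_id,
                     session_index=record.session_index, truth=record.truth)


# --------------------------------------------------------------------------
# à-trous quadratic-spline wavelet transform
# --------------------------------------------------------------------------

# Smoothing/detail filter pair of the dyadic quadratic-spline wavelet used by
# the classical ECG delineator family: the detail output approximates the
# derivative of the signal smoothed at each scale.
_H = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0
_G = np.array([2.0, -2.0])


def _atrous(x: np.ndarray, n_scales: int = 4) -> list[np.ndarray]:
    """Detail coefficients w_1..w_n, aligned (filter delays compensated)."""
    details = []
    s = x
    smooth_delay = 0.0
    for j in range(1, n_scales + 1):
        up = 2 ** (j - 1)
        g = np.zeros((len(_G) - 1) * up + 1)
        g[::up] = _G
        h = np.zeros((len(_H) - 1) * up + 1)
        h[::up] = _H
        w = np.convolve(s, g, mode="full")
        delay = smooth_delay + (len(g) - 1) / 2.0
        k = int(round(delay))
        w = w[k:k + x.size] if w.size >= k + x.size else np.resize(w, x.size)
        details.append(w)
        s = np.convolve(s, h, mode="full")
        smooth_delay += (len(h) - 1) / 2.0
        s = s[:x.size + int(smooth_delay) + 1]
    return details


def _zero_crossing(w: np.ndarray, lo: int, hi: int) -> int | None:
    """Index of the (first, largest-slope) sign change of w in [lo, hi)."""
    seg = w[lo:hi]
    if seg.size < 2:
        return None
    sign = np.signbit(seg)
    flips = np.nonzero(sign[:-1] != sign[1:])[0]
    if flips.size == 0:
        return None
    slopes = np.abs(seg[flips + 1] - seg[flips])
    best = flips[int(np.argmax(slopes))]
    # sub-position: pick the side closer to zero
    pick = best if abs(seg[best]) <= abs(seg[best + 1]) else best + 1
    return lo + int(pick)


def _boundary_left(w: np.ndarray, start: int, thresh: float, limit: int) -> int:
    i = start
    while i > limit and abs(w[i]) > thresh:
        i -= 1
    return i


def _boundary_right(w: np.ndarray, start: int, thresh: float, limit: int) -> int:
    i = start
    while i < limit and abs(w[i]) > thresh:
        i += 1
    return i


def _detect_r_peaks(x: np.ndarray, w2: np.ndarray, fs: float,
                    cfg: PreprocessConfig) -> list[int]:
    """R peaks from opposite-sign modulus-maxima pairs at scale 2^2."""
    absw = np.abs(w2)
    base = np.percentile(absw, 99)
    if base <= 0:
        return []
    thresh = cfg.qrs_threshold * base
    min_dist = max(1, int(0.01 * fs))
    peaks, _ = sps.find_peaks(absw, height=thresh, distance=min_dist)
    if peaks.size == 0:
        return []

    # group modulus maxima belonging to one QRS complex, then take the
    # strongest adjacent opposite-sign pair inside each group: its zero
    # crossing is the R peak (refined as the waveform maximum nearby)
    gap = int(0.12 * fs)
    refractory = int(cfg.refractory_ms / 1000.0 * fs)
    groups: list[list[int]] = [[int(peaks[0])]]
    for p in peaks[1:]:
        if p - groups[-1][-1] <= gap:
            groups[-1].append(int(p))
        else:
            groups.append([int(p)])

    r_list: list[int] = []
    r_strength: list[float] = []
    for grp in groups:
        best, best_strength = None, 0.0
        for p, q in zip(grp[:-1], grp[1:]):
            if np.sign(w2[p]) != np.sign(w2[q]):
                strength = min(absw[p], absw[q])
                if strength > best_strength:
                    best, best_strength = (p, q), strength
        if best is None:
            continue
        zc = _zero_crossing(w2, best[0], best[1] + 1)
        if zc is None:
            continue
        lo = max(0, zc - int(0.03 * fs))
        hi = min(x.size, zc + int(0.03 * fs) + 1)
        r = lo + int(np.argmax(x[lo:hi]))
        if r_list and r - r_list[-1] < refractory:
            if best_strength > r_strength[-1]:
                r_list[-1], r_strength[-1] = r, best_strength
        else:
            r_list.append(r)
            r_strength.append(best_strength)
    return r_list


def _locate_wave(w4: np.ndarray, x: np.ndarray, lo: int, hi: int,
                 frac: float) -> tuple[int, int, int] | None:
    """(onset, peak, offset) of a P/T wave inside [lo, hi) at scale 2^4."""
    lo = max(lo, 0)
    hi = min(hi, w4.size)
    if hi - lo < 4:
        return None
    seg = np.abs(w4[lo:hi])
    m1 = lo + int(np.argmax(seg))
    # strongest opposite-sign companion
    cands = [i for i in range(lo, hi)
             if np.sign(w4[i]) == -np.sign(w4[m1]) and abs(w4[i]) > 0]
    if not cands:
        return None
    m2 = max(cands, key=lambda i: abs(w4[i]))
    a, b = min(m1, m2), max(m1, m2)
    zc = _zero_crossing(w4, a, b + 1)
    if zc is None:
        return None
    onset = _boundary_left(w4, a, frac * abs(w4[a]), lo)
    offset = _boundary_right(w4, b, frac * abs(w4[b]), hi - 1)
    # peak refinement on the waveform: largest |deviation from local baseline|
    baseline = np.median(x[lo:hi])
    p_lo, p_hi = max(onset, lo), min(offset + 1, hi)
    if p_hi - p_lo < 1:
        return None
    peak = p_lo + int(np.argmax(np.abs(x[p_lo:p_hi] - baseline)))
    return onset, peak, offset


def delineate(record: ECGRecord, config: PreprocessConfig | None = None) -> BeatSet:
    """Fiducial delineation of a denoised record into fixed beat windows."""
    cfg = config or PreprocessConfig()
    x = record.samples
    fs = record.fs
    if x.size < 2 * fs:
        raise ParameterError("delineation needs at least 2 s of signal")
    w1, w2, w3, w4 = _atrous(x, 4)

    r_peaks = _detect_r_peaks(x, w2, fs, cfg)
    pre = int(cfg.window_pre_ms / 1000.0 * fs)
    post = int(cfg.window_post_ms / 1000.0 * fs)
    win_len = pre + post

    if not r_peaks:
        return BeatSet(beats=np.empty((0, win_len)), fiducials=[], fs=fs,
                       condition="no_beats")

    beats = []
    fids: list[FiducialMap] = []
    r_abs: list[int] = []
    for r in r_peaks:
        if r - pre < 0 or r + post > x.size:
            continue
        # --- QRS support at scale 2^2 ---
        # The QRS complex produces a group of alternating-sign modulus
        # extrema; the onset/offset lie beyond the outermost significant
        # extremum of that group, where the modulus falls below gamma * peak.
        span_l = max(0, r - int(0.09 * fs))
        span_r = min(x.size - 1, r + int(0.12 * fs))
        lseg = np.abs(w2[span_l:r])
        rseg = np.abs(w2[r + 1:span_r + 1])
        if lseg.size < 3 or rseg.size < 3:
            continue
        main = max(lseg.max(), rseg.max())
        lpk, _ = sps.find_peaks(lseg, height=0.08 * main)
        rpk, _ = sps.find_peaks(rseg, height=0.08 * main)
        contig = int(0.04 * fs)
        ml = span_l + int(np.argmax(lseg))
        for p in sorted((span_l + int(i) for i in lpk), reverse=True):
            if ml - p <= contig and p < ml:
                ml = p
        mr = r + 1 + int(np.argmax(rseg))
        for p in sorted(r + 1 + int(i) for i in rpk):
            if p - mr <= contig and p > mr:
                mr = p
        qrson = _boundary_left(w2, ml, cfg.gamma_on * main, span_l)
        qrsoff = _boundary_right(w2, mr, cfg.gamma_off * main, span_r)
        if not qrson < r < qrsoff:
            continue
        # Q/S: dominant negative deflections flanking R inside the QRS support
        q = qrson + int(np.argmin(x[qrson:r])) if r > qrson + 1 else qrson
        s = (r + 1) + int(np.argmin(x[r + 1:qrsoff + 1])) if qrsoff > r + 1 else qrsoff

        # --- P and T waves at scale 2^4 ---
        p_lo = r + int(cfg.p_search_ms[0] / 1000.0 * fs)
        p_hi = min(r + int(cfg.p_search_ms[1] / 1000.0 * fs), qrson)
        p_res = _locate_wave(w4, x, p_lo, p_hi, cfg.wave_boundary_frac)
        t_lo = max(r + int(cfg.t_search_ms[0] / 1000.0 * fs), qrsoff + 1)
        t_hi = r + int(cfg.t_search_ms[1] / 1000.0 * fs)
        t_res = _locate_wave(w4, x, t_lo, t_hi, cfg.wave_boundary_frac)
        if p_res is None or t_res is None:
            continue
        pon, ppk, _ = p_res
        _, tpk, toff = t_res
        # clamp wave bounds into the beat window and against the QRS
        pon = max(pon, r - pre)
        toff = min(toff, r + post - 1)

        fid = FiducialMap(Pon=pon, Ppk=ppk, QRSon=qrson, Q=q, Rpeak=r, S=s,
                          QRSoff=qrsoff, Tpk=tpk, Toff=toff)
        if not fid.is_ordered():
            continue
        beat = x[r - pre:r + post].copy()
        fids.append(fid.shifted(-(r - pre)))
        beats.append(beat)
        r_abs.append(r)

    if not beats:
        return BeatSet(beats=np.empty((0, win_len)), fiducials=[], fs=fs,
                       condition="no_beats")
    out = BeatSet(beats=np.vstack(beats), fiducials=fids, fs=fs,
                  r_abs=np.asarray(r_abs))
    _fill_amplitudes(out)
    return out


def _fill_amplitudes(bs: BeatSet) -> None:
    for beat, fid in zip(bs.beats, bs.fiducials):
        fid.amplitudes = {k: float(beat[fid.index(k)]) for k in LANDMARKS}


def observed_heart_rate(beats: BeatSet) -> float:
    """60 / median RR of the delineated record (bpm)."""
    if beats.r_abs is None or len(beats.r_abs) < 2:
        raise InsufficientBeatsError("need >= 2 beats to estimate heart rate")
    rr = np.diff(np.asarray(beats.r_abs, dtype=float)) / beats.fs
    return 60.0 / float(np.median(rr))


# --------------------------------------------------------------------------
# non-linear normalization
# --------------------------------------------------------------------------

def _section_lengths(fs: float, cfg: PreprocessConfig) -> tuple[int, int, int, int]:
    pr = int(round(cfg.standard_pr_ms / 1000.0 * fs))
    qrs = int(round(cfg.standard_qrs_ms / 1000.0 * fs))
    st = int(round(cfg.standard_st_ms / 1000.0 * fs))
    total = int(round(cfg.standard_beat_ms / 1000.0 * fs))
    return pr, qrs, st, total


def normalize_beat(beat: np.ndarray, fiducials: FiducialMap, observed_hr: float,
                   fs: float = 500.0, config: PreprocessConfig | None = None
                   ) -> tuple[np.ndarray, FiducialMap]:
    """Time-rescale PR / QRS / ST sections to the 70 bpm standard durations.

    The warp is piecewise-linear and anchored at every landmark: each
    landmark maps to an integer target index, so landmark amplitudes are
    conserved exactly; spans between consecutive anchors are linearly
    resampled. The TP tail after Toff fills the remainder of a fixed-length
    beat window.
    """
    cfg = config or PreprocessConfig()
    if not 30 <= observed_hr <= 180:
        raise ParameterError("observed_hr must lie in [30, 180] bpm")
    beat = np.asarray(beat, dtype=float)
    f = fiducials
    pr_len, qrs_len, st_len, total = _section_lengths(fs, cfg)

    for a, b in (("Pon", "QRSon"), ("QRSon", "QRSoff"), ("QRSoff", "Toff")):
        if f.index(b) - f.index(a) <= 0:
            raise DegenerateSectionError(f"section {a}->{b} has no length")

    # target anchor positions
    t_pon = 0
    t_qrson = pr_len
    t_qrsoff = pr_len + qrs_len
    t_toff = pr_len + qrs_len + st_len
    if t_toff >= total:
        raise ParameterError("standard section durations exceed the beat window")

    def interior(src_a: int, src_b: int, tgt_a: int, tgt_b: int, src: int) -> int:
        pos = tgt_a + (src - src_a) / (src_b - src_a) * (tgt_b - tgt_a)
        return int(np.clip(round(pos), tgt_a + 1, tgt_b - 1))

    t_ppk = interior(f.Pon, f.QRSon, t_pon, t_qrson, f.Ppk) if f.Ppk > f.Pon else t_pon
    t_q = interior(f.QRSon, f.QRSoff, t_qrson, t_qrsoff, f.Q) \
        if f.Q > f.QRSon else t_qrson
    t_r = interior(f.QRSon, f.QRSoff, t_qrson, t_qrsoff, f.Rpeak)
    t_s = interior(f.QRSon, f.QRSoff, t_qrson, t_qrsoff, f.S) \
        if f.S < f.QRSoff else t_qrsoff
    t_tpk = interior(f.QRSoff, f.Toff, t_qrsoff, t_toff, f.Tpk) \
        if f.Tpk < f.Toff else t_toff
    # enforce strict interior ordering for the QRS landmarks
    if not t_qrson <= t_q < t_r < t_s <= t_qrsoff:
        t_q = max(t_qrson, min(t_r - 1, t_q))
        t_s = min(t_qrsoff, max(t_r + 1, t_s))
        if not t_qrson <= t_q < t_r < t_s <= t_qrsoff:
            raise DegenerateSectionError("QRS landmarks collapse after rescale")

    src_anchor = [f.Pon, f.Ppk, f.QRSon, f.Q, f.Rpeak, f.S, f.QRSoff, f.Tpk,
                  f.Toff, beat.size - 1]
    tgt_anchor = [t_pon, t_ppk, t_qrson, t_q, t_r, t_s, t_qrsoff, t_tpk,
                  t_toff, total - 1]

    out = np.empty(total)
    for (sa, sb), (ta, tb) in zip(zip(src_anchor[:-1], src_anchor[1:]),
                                  zip(tgt_anchor[:-1], tgt_anchor[1:])):
        if tb <= ta:
            continue
        if sb <= sa:
            raise DegenerateSectionError("source anchors out of order")
        tt = np.arange(ta, tb + 1)
        src_pos = sa + (tt - ta) / (tb - ta) * (sb - sa)
        out[ta:tb + 1] = np.interp(src_pos, np.arange(beat.size), beat)

    new_f = FiducialMap(Pon=t_pon, Ppk=t_ppk, QRSon=t_qrson, Q=t_q, Rpeak=t_r,
                        S=t_s, QRSoff=t_qrsoff, Tpk=t_tpk, Toff=t_toff)
    new_f.amplitudes = {k: float(out[new_f.index(k)]) for k in LANDMARKS}
    return out, new_f


def normalize_beats(beats: BeatSet, observed_hr: float,
                    config: PreprocessConfig | None = None) -> BeatSet:
    """Apply ``normalize_beat`` to every beat, dropping degenerate ones."""
    cfg = config or PreprocessConfig()
    out_beats, out_fids, out_r = [], [], []
    r_abs = beats.r_abs if beats.r_abs is not None else [None] * len(beats)
    for beat, fid, r in zip(beats.beats, beats.fiducials, r_abs):
        try:
            nb, nf = normalize_beat(beat, fid, observed_hr, beats.fs, cfg)
        except DegenerateSectionError:
            continue
        out_beats.append(nb)
        out_fids.append(nf)
        out_r.append(r)
    if not out_beats:
        total = _section_lengths(beats.fs, cfg)[3]
        return BeatSet(beats=np.empty((0, total)), fiducials=[], fs=beats.fs,
                       condition="no_beats")
    return BeatSet(beats=np.vstack(out_beats), fiducials=out_fids, fs=beats.fs,
                   condition=beats.condition,
                   r_abs=None if out_r[0] is None else np.asarray(out_r))


# --------------------------------------------------------------------------
# outlier removal and ensembling
# --------------------------------------------------------------------------

def _template_correlations(beats: np.ndarray) -> np.ndarray:
    """Pearson correlation of each beat against the mean-beat template."""
    template = beats.mean(axis=0)
    tc = template - template.mean()
    tn = np.sqrt(np.sum(tc ** 2))
    rhos = np.empty(beats.shape[0])
    for i, b in enumerate(beats):
        bc = b - b.mean()
        bn = np.sqrt(np.sum(bc ** 2))
        rhos[i] = np.sum(bc * tc) / (bn * tn) if bn > 0 and tn > 0 else 0.0
    return rhos


def remove_outliers(beats: BeatSet, config: PreprocessConfig | None = None
                    ) -> BeatSet:
    """Drop beats with rho < mean(rho) - 0.5*std(rho) against the template."""
    cfg = config or PreprocessConfig()
    n = len(beats)
    if n < 2:
        warnings.warn("fewer than 2 beats: outlier removal skipped",
                      stacklevel=2)
        return BeatSet(beats=beats.beats, fiducials=list(beats.fiducials),
                       fs=beats.fs, condition="too_few_for_outlier_removal")
    rhos = _template_correlations(beats.beats)
    thresh = rhos.mean() - cfg.outlier_k * rhos.std()
    keep = rhos >= thresh
    return BeatSet(beats=beats.beats[keep],
                   fiducials=[f for f, k in zip(beats.fiducials, keep) if k],
                   fs=beats.fs, condition=beats.condition,
                   r_abs=beats.r_abs[keep] if beats.r_abs is not None else None)


def ensemble(beats: BeatSet, selector_start: int = 0,
             config: PreprocessConfig | None = None) -> EnsembleBeat:
    """Mean of three beats chosen by template correlation rank.

    The selector ranks surviving beats by Pearson correlation against the
    post-removal mean template (ties broken by earlier index) and averages
    the three starting at ``selector_start`` in that ranking, so successive
    starts give independent ensembles from one record.
    """
    cfg = config or PreprocessConfig()
    n = len(beats)
    if n < 3:
        raise InsufficientBeatsError(
            f"ensemble needs >= 3 beats, got {n}")
    if selector_start < 0 or selector_start + 3 > n:
        raise ParameterError(
            f"selector_start={selector_start} leaves fewer than 3 of {n} beats")
    rhos = _template_correlations(beats.beats)
    order = np.argsort(-rhos, kind="stable")
    chosen = order[selector_start:selector_start + 3]
    avg = beats.beats[chosen].mean(axis=0)

    fids = [beats.fiducials[i] for i in chosen]
    if cfg.ensemble_fiducials == "redelineate":
        fid = _redelineate_beat(avg, fids, beats.fs, cfg)
    else:
        fid = FiducialMap(**{
            k: int(np.median([f.index(k) for f in fids])) for k in LANDMARKS})
    fid.amplitudes = {k: float(avg[fid.index(k)]) for k in LANDMARKS}
    return EnsembleBeat(samples=avg, fiducials=fid, fs=beats.fs, source_count=3)


def _redelineate_beat(avg: np.ndarray, fids: list[FiducialMap], fs: float,
                      cfg: PreprocessConfig) -> FiducialMap:
    """Re-locate landmarks on the averaged waveform.

    Boundary landmarks (Pon, QRSon, QRSoff, Toff) are aligned by the
    normalization warp, so the median is kept for them; the five wave peaks
    are re-located as signal extrema within the (median) wave bounds.
    """
    med = {k: int(np.median([f.index(k) for f in fids])) for k in LANDMARKS}
    r_lo = max(med["QRSon"], med["Rpeak"] - int(0.03 * fs))
    r_hi = min(med["QRSoff"], med["Rpeak"] + int(0.03 * fs)) + 1
    r = r_lo + int(np.argmax(avg[r_lo:r_hi]))
    q = med["QRSon"] + int(np.argmin(avg[med["QRSon"]:r])) if r > med["QRSon"] \
        else med["Q"]
    s_hi = med["QRSoff"] + 1
    s = (r + 1) + int(np.argmin(avg[r + 1:s_hi])) if s_hi > r + 1 else med["S"]
    base_p = np.median(avg[med["Pon"]:med["QRSon"]])
    ppk = med["Pon"] + int(np.argmax(np.abs(
        avg[med["Pon"]:med["QRSon"]] - base_p)))
    base_t = np.median(avg[med["QRSoff"]:med["Toff"] + 1])
    tpk = med["QRSoff"] + 1 + int(np.argmax(np.abs(
        avg[med["QRSoff"] + 1:med["Toff"] + 1] - base_t)))
    fid = FiducialMap(Pon=med["Pon"], Ppk=ppk, QRSon=med["QRSon"], Q=q,
                      Rpeak=r, S=s, QRSoff=med["QRSoff"], Tpk=tpk,
                      Toff=med["Toff"])
    if not fid.is_ordered():  # fall back to the median landmarks
        fid = FiducialMap(**med)
    return fid
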