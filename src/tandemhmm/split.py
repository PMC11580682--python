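"""Repeat splitting: locating changes of repetitive pattern inside a region.

A period-p region is scanned with two adjacent windows; each window is
summarized as a p x 4 profile (letter frequencies per profile index) and
the two profiles are compared with the symmetrized Kullback-Leibler
divergence.  Peaks above a threshold mark repeat splits; the resulting
subrepeats are named by the lexicographically least rotation of their
consensus unit, and neighboring subrepeats whose units are rotations of
each other (the signature of an undetected indel, not of a true pattern
change) are merged back together.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import ALPHABET, AMBIG_CODE
from .decode import RepeatRegion, SubRepeat

DEFAULT_THRESHOLD = 3.5
PSEUDOCOUNT = 0.01
MIN_WINDOW_LETTERS = 15
MIN_WINDOW_UNITS = 5


MAX_WINDOW_LETTERS = 150


def window_length(period: int, region_length: int | None = None) -> int:
    """Profile window size: at least 15 letters and 5 repeat units.

    Given the region length, the window additionally grows to a quarter of
    the region (capped at 150 letters): the sampling noise of the
    divergence between two windows scales like p^2 / w, so the stated
    minima alone would drown the splitting threshold in noise for mutated
    or large-period repeats.
    """
    w = max(MIN_WINDOW_LETTERS, MIN_WINDOW_UNITS * period)
    if region_length is not None:
        w = max(w, min(MAX_WINDOW_LETTERS, region_length // 4))
    return w


def canonical_pattern(unit: str) -> str:
    """Lexicographically least rotation (Booth's algorithm)."""
    if not unit:
        raise ValueError("empty repeat unit")
    s = unit + unit
    n = len(unit)
    f = [-1] * len(s)
    least = 0
    for j in range(1, len(s)):
        c = s[j]
        i = f[j - least - 1]
        while i != -1 and c != s[least + i + 1]:
            if c < s[least + i + 1]:
                least = j - i - 1
            i = f[i]
        if c != s[least + i + 1]:
            if c < s[least]:
                least = j
            f[j - least] = -1
        else:
            f[j - least] = i + 1
    return s[least:least + n]


def normalize_profile(counts: np.ndarray, pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    """Add the pseudocount to every cell, then normalize each row to sum 1."""
    m = counts + pseudocount
    return m / m.sum(axis=1, keepdims=True)


def jsd(L: np.ndarray, R: np.ndarray, pseudocount: float = PSEUDOCOUNT) -> float:
    """Profile divergence: -(1/2) sum_i sum_c [L log(R/L) + R log(L/R)].

    This is the symmetrized Kullback-Leibler divergence of the row
    distributions, summed over profile indices; nonnegative, zero iff the
    normalized profiles coincide.  Measured in bits (base-2 log), the
    conventional unit for this divergence, on which the default splitting
    threshold of 3.5 is calibrated.
    """
    if L.shape != R.shape:
        raise ValueError("profile shape mismatch")
    Ln = normalize_profile(np.asarray(L, dtype=np.float64), pseudocount)
    Rn = normalize_profile(np.asarray(R, dtype=np.float64), pseudocount)
    return float(-0.5 * np.sum(Ln * np.log2(Rn / Ln) + Rn * np.log2(Ln / Rn)))


@njit(cache=True)
def _jsd_series(rows, letters, p, w, eps):
    """Sliding two-window divergence at every interior boundary.

    rows[i]: profile index - 1 (or -1 for inserted/ambiguous letters);
    letters[i]: 0..3.  Boundary b separates [b-w, b) from [b, b+w);
    series[j] corresponds to b = w + j.
    """
    n = rows.shape[0]
    nb = n - 2 * w + 1
    series = np.empty(nb)
    cl = np.zeros((p, 4))
    cr = np.zeros((p, 4))
    for i in range(w):
        if rows[i] >= 0:
            cl[rows[i], letters[i]] += 1.0
        if rows[w + i] >= 0:
            cr[rows[w + i], letters[w + i]] += 1.0
    for j in range(nb):
        tot = 0.0
        for i in range(p):
            sl = 0.0
            sr = 0.0
            for c in range(4):
                sl += cl[i, c] + eps
                sr += cr[i, c] + eps
            for c in range(4):
                a = (cl[i, c] + eps) / sl
                b = (cr[i, c] + eps) / sr
                tot += a * np.log2(a / b) + b * np.log2(b / a)
        series[j] = 0.5 * tot
        if j + 1 < nb:
            bnd = w + j
            if rows[bnd - w] >= 0:
                cl[rows[bnd - w], letters[bnd - w]] -= 1.0
            if rows[bnd] >= 0:
                cl[rows[bnd], letters[bnd]] += 1.0
                cr[rows[bnd], letters[bnd]] -= 1.0
            if rows[bnd + w] >= 0:
                cr[rows[bnd + w], letters[bnd + w]] += 1.0
    return series


def jsd_series(region_codes: np.ndarray, track: np.ndarray, period: int,
               pseudocount: float = PSEUDOCOUNT) -> np.ndarray:
    """Divergence at every boundary with a full window on each side."""
    n = len(region_codes)
    w = window_length(period, n)
    if n < 2 * w:
        return np.empty(0)
    rows = track.astype(np.int64) - 1          # gap marker 0 -> -1
    rows[region_codes == AMBIG_CODE] = -1
    letters = np.where(region_codes == AMBIG_CODE, 0, region_codes).astype(np.int64)
    return _jsd_series(rows, letters, period, w, float(pseudocount))


def find_peaks(series: np.ndarray, threshold: float,
               min_separation: int) -> list[int]:
    """Strict local maxima above threshold, plateaus resolved leftmost,
    greedy value-ordered acceptance with a minimum separation."""
    n = len(series)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and series[j + 1] == series[i]:
            j += 1
        left_ok = i == 0 or series[i - 1] < series[i]
        right_ok = j == n - 1 or series[j + 1] < series[i]
        if left_ok and right_ok and series[i] > threshold:
            peaks.append(i)
        i = j + 1
    accepted: list[int] = []
    for idx in sorted(peaks, key=lambda x: (-series[x], x)):
        if all(abs(idx - a) >= min_separation for a in accepted):
            accepted.append(idx)
    return sorted(accepted)


def _refine_peak(region_codes: np.ndarray, track: np.ndarray, period: int,
                 b: int, w: int, pseudocount: float) -> int:
    """Re-localize a coarse peak with minimum-size windows around it.

    Large detection windows blur the peak position by up to ~w/10; the
    divergence recomputed with the minimal window inside [b - wmin, b + wmin]
    restores single-unit localization.
    """
    wmin = max(MIN_WINDOW_LETTERS, MIN_WINDOW_UNITS * period)
    if wmin >= w:
        return b
    lo = max(b - 2 * wmin, 0)
    hi = min(b + 2 * wmin, len(region_codes))
    if hi - lo < 2 * wmin:
        return b
    rows = track[lo:hi].astype(np.int64) - 1
    rows[region_codes[lo:hi] == AMBIG_CODE] = -1
    letters = np.where(region_codes[lo:hi] == AMBIG_CODE, 0,
                       region_codes[lo:hi]).astype(np.int64)
    series = _jsd_series(rows, letters, period, wmin, float(pseudocount))
    if len(series) == 0:
        return b
    return lo + wmin + int(np.argmax(series))


def scan_splits(region_codes: np.ndarray, track: np.ndarray, period: int,
                threshold: float = DEFAULT_THRESHOLD,
                pseudocount: float = PSEUDOCOUNT) -> list[tuple[int, float]]:
    """Split positions (offset within the region) with their peak values."""
    w = window_length(period, len(region_codes))
    series = jsd_series(region_codes, track, period, pseudocount)
    if len(series) == 0:
        return []
    out = []
    for i in find_peaks(series, threshold, w):
        b = _refine_peak(region_codes, track, period, w + i, w, pseudocount)
        out.append((b, float(series[i])))
    return out


def consensus_unit(segment_codes: np.ndarray, segment_track: np.ndarray,
                   period: int) -> str:
    """Majority letter at each profile index (ties to the alphabetically
    first letter), canonicalized to the least rotation."""
    counts = np.zeros((period, 4), dtype=np.int64)
    mask = (segment_track > 0) & (segment_codes != AMBIG_CODE)
    np.add.at(counts, (segment_track[mask] - 1, segment_codes[mask]), 1)
    unit = "".join(ALPHABET[c] for c in counts.argmax(axis=1))
    return canonical_pattern(unit)


def merge_rotation_equivalent(subrepeats: list[SubRepeat]) -> list[SubRepeat]:
    """Fuse neighboring subrepeats whose canonical units coincide, to a
    fixed point."""
    out = list(subrepeats)
    changed = True
    while changed:
        changed = False
        merged: list[SubRepeat] = []
        for s in out:
            if merged and canonical_pattern(merged[-1].pattern) == canonical_pattern(s.pattern):
                prev = merged[-1]
                merged[-1] = SubRepeat(prev.start, s.end, prev.pattern,
                                       max(prev.mean_jsd_at_boundary,
                                           s.mean_jsd_at_boundary))
                changed = True
            else:
                merged.append(s)
        out = merged
    return out


def split_region(region: RepeatRegion, codes: np.ndarray,
                 threshold: float = DEFAULT_THRESHOLD,
                 pseudocount: float = PSEUDOCOUNT) -> RepeatRegion:
    """Annotate a region's subrepeats and canonical pattern in place.

    ``codes`` is the full sequence the region was called on.
    """
    seg = codes[region.start:region.end]
    track = region.profile_indices
    if track is None:
        track = (np.arange(len(seg)) % region.period + 1).astype(np.int32)
        region.profile_indices = track
    splits = scan_splits(seg, track, region.period, threshold, pseudocount)
    splits = sorted({s: v for s, v in splits if 0 < s < len(seg)}.items())
    bounds = [0] + [s for s, _ in splits] + [len(seg)]
    bounds = sorted(set(bounds))
    values = {s: v for s, v in splits}
    subs = []
    for a, b in zip(bounds, bounds[1:]):
        pattern = consensus_unit(seg[a:b], track[a:b], region.period)
        subs.append(SubRepeat(region.start + a, region.start + b, pattern,
                              values.get(a, 0.0)))
    subs = merge_rotation_equivalent(subs)
    region.subrepeats = subs
    region.pattern = consensus_unit(seg, track, region.period)
    return region
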