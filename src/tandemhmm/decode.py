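"""Windowed Viterbi decoding, region extraction, scoring and merging.

The decoder fills, per window, one value track per repetitive period plus
the nonrepetitive track (emission ratios are taken relative to background,
so an all-background path scores exactly 0), with indel excursions handled
by the aggregated J-chain update in :mod:`tandemhmm._kernels`.  Repeat
regions are maximal runs of non-background states on the Viterbi path;
their reported start is shifted left by one period because a look-back
model cannot place the first p letters of a repeat on the path.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import (
    ModelParams, emission_tables, gamma_vector,
    state_count, state_id, INSERT, DELETE, OFFSET,
)

NEG_INF = float("-inf")

CELL_BUDGET = 100_000_000  # Viterbi cells per window
MIN_WINDOW = 10_000
MAX_WINDOW = 1_000_000


def _log(x: float) -> float:
    return float(np.log(x)) if x > 0 else NEG_INF


def _indel_open_split(params: ModelParams) -> tuple[float, float]:
    ni, nd = params.n_insert, params.n_delete
    open_ = params.effective_indel_open
    if ni > 0 and nd > 0:
        return open_ / 2, open_ / 2
    return (open_ if ni > 0 else 0.0), (open_ if nd > 0 else 0.0)


@dataclass(frozen=True)
class _LogConstants:
    t00: float
    tR0: float
    t0R: np.ndarray
    selfR: float
    toI1: float
    toD1: float
    iext: float
    dext: float
    inextm: float
    dnextm: float


def _log_constants(params: ModelParams) -> _LogConstants:
    k = params.max_period
    gammas = gamma_vector(params.decay, k)
    entry = params.repeat_entry
    t0R = np.array([_log(entry * float(g)) for g in gammas])
    open_i, open_d = _indel_open_split(params)
    ext = params.indel_extend
    return _LogConstants(
        t00=_log(1.0 - entry),
        tR0=_log(params.repeat_exit),
        t0R=t0R,
        selfR=_log(1.0 - params.repeat_exit - params.effective_indel_open),
        toI1=_log(open_i),
        toD1=_log(open_d),
        iext=_log(ext),
        dext=_log(ext),
        inextm=_log(1.0 - ext),
        dnextm=_log(1.0 - ext),
    )


@dataclass
class _ChainMeta:
    off: np.ndarray
    q: np.ndarray
    p: np.ndarray
    isdel: np.ndarray
    j: np.ndarray
    base: np.ndarray   # state id of the chain's first offset state
    i_id: np.ndarray   # (k, ni) insert-state ids
    d_id: np.ndarray   # (k, nd) deletion-state ids
    total_slots: int


def _chain_meta(k: int, ni: int, nd: int) -> _ChainMeta:
    n_chains = k * (ni + nd)
    off = np.zeros(n_chains, dtype=np.int64)
    q = np.zeros(n_chains, dtype=np.int64)
    per = np.zeros(n_chains, dtype=np.int64)
    isdel = np.zeros(n_chains, dtype=np.int64)
    dep = np.zeros(n_chains, dtype=np.int64)
    base = np.zeros(n_chains, dtype=np.int64)
    i_id = np.zeros((k, max(ni, 1)), dtype=np.int64)
    d_id = np.zeros((k, max(nd, 1)), dtype=np.int64)
    c = 0
    slots = 0
    for p in range(1, k + 1):
        for j in range(1, ni + 1):
            off[c] = slots
            q[c] = p + j
            per[c] = p
            isdel[c] = 0
            dep[c] = j
            base[c] = state_id(k, ni, nd, OFFSET, p, j, 1, deletion=False)
            i_id[p - 1, j - 1] = state_id(k, ni, nd, INSERT, p, j)
            slots += p + 1
            c += 1
        for j in range(1, nd + 1):
            off[c] = slots
            q[c] = p - j
            per[c] = p
            isdel[c] = 1
            dep[c] = j
            base[c] = state_id(k, ni, nd, OFFSET, p, j, 1, deletion=True)
            d_id[p - 1, j - 1] = state_id(k, ni, nd, DELETE, p, j)
            slots += p + 1
            c += 1
    return _ChainMeta(off, q, per, isdel, dep, base, i_id, d_id, slots)


@dataclass
class ViterbiMatrix:
    """Per-window decoding state: value tracks, backpointers, chain buffers."""

    params: ModelParams
    codes: np.ndarray
    v0: np.ndarray
    vR: np.ndarray
    bp0: np.ndarray
    bpR: np.ndarray
    lastI: np.ndarray
    lastD: np.ndarray
    jval: np.ndarray
    jentry: np.ndarray
    consts: _LogConstants
    chains: _ChainMeta
    full: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.codes)


def viterbi_fill(codes: np.ndarray, params: ModelParams,
                 materialize: bool = False) -> ViterbiMatrix:
    """Run the relative-emission Viterbi recurrence over one window.

    With ``materialize`` the full (n+1) x m matrix (every state, including
    every individual offset state) is reconstructed; this is only intended
    for small inputs and for cross-checking against the naive engine.
    """
    codes = np.ascontiguousarray(codes, dtype=np.int8)
    n = len(codes)
    k, ni, nd = params.max_period, params.n_insert, params.n_delete
    consts = _log_constants(params)
    chains = _chain_meta(k, ni, nd)
    ematch, emismatch = emission_tables(params)

    v0 = np.full(n + 1, NEG_INF)
    vR = np.full((k, n + 1), NEG_INF)
    bp0 = np.zeros(n + 1, dtype=np.int32)
    bpR = np.zeros((k, n + 1), dtype=np.int32)
    lastI = np.full((k, max(ni, 1)), NEG_INF)
    lastD = np.full((k, max(nd, 1)), NEG_INF)
    jval = np.full(max(chains.total_slots, 1), NEG_INF)
    jentry = np.full(max(chains.total_slots, 1), -(10 ** 9), dtype=np.int64)
    if materialize:
        m = state_count(k, ni, nd)
        full = np.full((n + 1, m), NEG_INF)
    else:
        full = np.zeros((1, 1))

    _kernels.fill_window(
        codes, k, ni, nd, ematch, emismatch,
        consts.t00, consts.tR0, consts.t0R, consts.selfR,
        consts.toI1, consts.toD1, consts.iext, consts.dext,
        consts.inextm, consts.dnextm,
        chains.off, chains.q, chains.p, chains.isdel, chains.j, chains.base,
        chains.i_id, chains.d_id,
        v0, vR, bp0, bpR, lastI, lastD, jval, jentry,
        full, materialize,
    )
    return ViterbiMatrix(params, codes, v0, vR, bp0, bpR, lastI, lastD,
                         jval, jentry, consts, chains,
                         full if materialize else None)


# final-state descriptor types (shared with the traceback kernel)
F_BG, F_R, F_I, F_J = 0, 1, 2, 3


def final_state(vm: ViterbiMatrix) -> tuple[tuple[int, int, int, int, int], float]:
    """Best final state by value, ties broken by the shared preference rule
    (lower period, non-indel before indel, lower state id)."""
    n = vm.n
    k, ni, nd = vm.params.max_period, vm.params.n_insert, vm.params.n_delete
    best = vm.v0[n]
    desc = (F_BG, 0, 0, 0, 0)
    # insert states carry period 0, so they precede every repetitive state
    for p in range(1, k + 1):
        for j in range(1, ni + 1):
            val = vm.lastI[p - 1, j - 1]
            if val > best:
                best = val
                desc = (F_I, p, j, 0, 0)
    c = 0
    for p in range(1, k + 1):
        if vm.vR[p - 1, n] > best:
            best = vm.vR[p - 1, n]
            desc = (F_R, p, 0, 0, 0)
        # offset states of period p, in state-id order (ins chains, then del)
        for local in range(ni + nd):
            cc = c + local
            off = vm.chains.off[cc]
            p_c = vm.chains.p[cc]
            for pos in range(1, p_c + 1):
                slot = (n - pos) % (p_c + 1)
                if vm.jentry[off + slot] == n - pos:
                    val = vm.jval[off + slot]
                    if val > best:
                        best = val
                        desc = (F_J, p, 0, cc, pos)
        c += ni + nd
    return desc, float(best)


@dataclass
class StatePath:
    """Viterbi path projected onto emitting positions.

    kind: 0 background, 1 repetitive, 2 insert, 3 offset; ``period`` is the
    repeat machinery's period (0 on background), ``look`` the emission
    look-back, ``translog`` the transition log-probability into each
    position (silent deletion hops folded forward).  ``del_events`` lists
    (position, depth): ``depth`` pattern letters were deleted immediately
    before ``position``.
    """

    kind: np.ndarray
    period: np.ndarray
    look: np.ndarray
    translog: np.ndarray
    del_events: list[tuple[int, int]]
    final_value: float

    @property
    def n(self) -> int:
        return len(self.kind)


def traceback(vm: ViterbiMatrix) -> StatePath:
    n = vm.n
    desc, value = final_state(vm)
    ftype, fp, fj, fchain, fs = desc
    kind = np.zeros(n, dtype=np.int8)
    per = np.zeros(n, dtype=np.int32)
    look = np.zeros(n, dtype=np.int32)
    translog = np.zeros(n)
    del_pos = np.zeros(max(n, 1), dtype=np.int64)
    del_depth = np.zeros(max(n, 1), dtype=np.int32)
    c = vm.consts
    ndel = _kernels.traceback_window(
        n, vm.params.max_period, vm.params.n_insert, vm.params.n_delete,
        vm.bp0, vm.bpR,
        c.t00, c.tR0, c.t0R, c.selfR,
        c.toI1, c.toD1, c.iext, c.dext, c.inextm, c.dnextm,
        vm.chains.q, vm.chains.p, vm.chains.isdel, vm.chains.j,
        ftype, fp, fj, fchain, fs,
        kind, per, look, translog, del_pos, del_depth,
    )
    events = [(int(del_pos[i]), int(del_depth[i])) for i in range(ndel)]
    events.sort()
    return StatePath(kind, per, look, translog, events, value)


def path_emission_ratios(path: StatePath, codes: np.ndarray,
                         params: ModelParams) -> np.ndarray:
    ematch, emismatch = emission_tables(params)
    out = np.zeros(path.n)
    _kernels.emission_ratios_for_path(
        np.ascontiguousarray(codes, dtype=np.int8),
        path.kind, path.look, ematch, emismatch, out)
    return out


@dataclass
class SubRepeat:
    start: int
    end: int
    pattern: str
    mean_jsd_at_boundary: float = 0.0


@dataclass
class RepeatRegion:
    """An annotated tandem repeat (0-based half-open coordinates)."""

    seq_id: str
    start: int
    end: int
    period: int
    score: float
    p_value: float | None = None
    pattern: str = ""
    subrepeats: list[SubRepeat] = field(default_factory=list)
    indel_events: int = 0
    # internals for splitting / diagnostics
    run_start: int = 0          # raw Viterbi run start (global coords)
    run_end: int = 0
    end_kind: int = 1           # path kind at the last run position
    profile_indices: np.ndarray | None = None  # 1..p, 0 for inserted letters

    def __len__(self) -> int:
        return self.end - self.start


def _profile_track(path: StatePath, rs: int, re_: int, start: int, p: int) -> np.ndarray:
    """Profile indices over [start, re_): cyclic 1..p, 0 on insertions,
    skipping deleted pattern positions."""
    track = np.zeros(re_ - start, dtype=np.int32)
    dels = {pos: depth for pos, depth in path.del_events if rs <= pos < re_}
    phase = 0
    for i, pos in enumerate(range(start, re_)):
        if pos >= rs:
            if pos in dels:
                phase += dels[pos]
            if path.kind[pos] == 2:  # inserted letter: gap marker
                continue
        track[i] = phase % p + 1
        phase += 1
    return track


def extract_regions(path: StatePath, codes: np.ndarray, params: ModelParams,
                    min_unit: int = 2, seq_id: str = "seq",
                    offset: int = 0) -> list[RepeatRegion]:
    """Maximal non-background runs of the path, scored per the telescoping
    sum (transition + relative-emission log terms, entry included).

    The reported start is run_start - p (clamped at the sequence origin);
    runs shorter than ``min_unit`` repeat units are discarded.
    """
    n = path.n
    if n == 0:
        return []
    nz = path.kind != 0
    if not nz.any():
        return []
    eratio = path_emission_ratios(path, codes, params)
    step = path.translog + eratio
    boundaries = np.flatnonzero(np.diff(nz.astype(np.int8)))
    starts = [0] if nz[0] else []
    starts += [int(b) + 1 for b in boundaries if not nz[b]]
    ends = [int(b) + 1 for b in boundaries if nz[b]]
    if nz[-1]:
        ends.append(n)

    regions = []
    for rs, re_ in zip(starts, ends):
        p = int(path.period[rs])
        if min_unit > 0 and (re_ - rs) < min_unit * p:
            continue
        start = max(offset + rs - p, 0)
        score = float(step[rs:re_].sum())
        n_ins_runs = int(np.sum((path.kind[rs:re_] == 2)
                                & (np.r_[0, path.kind[rs:re_ - 1]] != 2))) if re_ > rs else 0
        n_del = sum(1 for pos, _ in path.del_events if rs <= pos < re_)
        local_start = start - offset
        track = _profile_track(path, rs, re_, local_start, p)
        regions.append(RepeatRegion(
            seq_id=seq_id, start=start, end=offset + re_, period=p,
            score=score, indel_events=n_ins_runs + n_del,
            run_start=offset + rs, run_end=offset + re_,
            end_kind=int(path.kind[re_ - 1]),
            profile_indices=track,
        ))
    return regions


def score_region(region: RepeatRegion, vm: ViterbiMatrix,
                 offset: int = 0) -> float:
    """Endpoint-difference form of the region score.

    Equals the per-step sum computed by :func:`extract_regions` (the sum
    telescopes along the Viterbi path).  Requires the run to end on its
    repetitive state, which holds for every run followed by background.
    """
    rs = region.run_start - offset
    re_ = region.run_end - offset
    if region.end_kind != 1:
        raise ValueError("run ends inside an indel excursion; "
                         "endpoint-difference form needs the repetitive track")
    # positions [rs, re_) occupy matrix columns rs+1 .. re_; the background
    # predecessor of the run sits at column rs
    return float(vm.vR[region.period - 1, re_] - vm.v0[rs])


@dataclass(frozen=True)
class WindowPlan:
    window_size: int
    overlap: int

    def __post_init__(self):
        if self.overlap >= self.window_size:
            raise ValueError("overlap must be smaller than window size")
        if self.window_size < 1 or self.overlap < 0:
            raise ValueError("invalid window plan")

    def windows(self, n: int) -> list[tuple[int, int]]:
        """Half-open windows covering [0, n)."""
        if n <= self.window_size:
            return [(0, n)]
        out = []
        stride = self.window_size - self.overlap
        s = 0
        while True:
            e = min(s + self.window_size, n)
            out.append((s, e))
            if e >= n:
                return out
            s += stride


def plan_windows(n: int, params: ModelParams,
                 requested: WindowPlan | None = None) -> WindowPlan:
    """Auto-size windows from the model's state count: a fixed cell budget
    divided by the number of states, clamped to [10 kb, 1 Mb]; overlap wide
    enough for any single repeat-unit plus indel excursion context."""
    if n < 1:
        raise ValueError("empty sequence")
    if requested is not None:
        return requested
    k, ni, nd = params.max_period, params.n_insert, params.n_delete
    m = state_count(k, ni, nd)
    w = int(min(MAX_WINDOW, max(MIN_WINDOW, CELL_BUDGET // m)))
    ov = max(4 * (k + max(ni, nd)), 100)
    if ov >= w:
        ov = w // 2
    return WindowPlan(w, ov)


MERGE_GAP = 15  # max unannotated letters bridged when fusing compatible regions


def merge_windows(per_window: list[tuple[tuple[int, int], list[RepeatRegion]]]
                  ) -> list[RepeatRegion]:
    """Merge repeat annotations from overlapping windows.

    Overlapping or abutting regions of equal period are fused: span union,
    score s1 + s2 minus the overlap length times the smaller per-letter
    score density (so a repeat annotated identically in two windows keeps
    its single-window score).  Regions whose periods share a common factor
    (harmonics: the same repeat can be annotated at any multiple of its
    true period, and substitution noise makes neighboring harmonic tracks
    nearly equivalent) are fused the same way at the common period when
    they overlap or are separated by fewer than 15 letters.  Overlapping
    regions of incompatible period are kept separate: the lower-scoring
    one is truncated at the overlap midpoint, its score scaled by the
    retained fraction.
    """
    regions = [r for _, regs in per_window for r in regs]
    regions.sort(key=lambda r: (r.seq_id, r.start, r.end))
    out: list[RepeatRegion] = []
    for r in regions:
        if (not out or out[-1].seq_id != r.seq_id
                or r.start > out[-1].end + MERGE_GAP):
            out.append(r)
            continue
        o = out[-1]
        compatible = (r.period == o.period
                      or math.gcd(r.period, o.period) > 1)
        if r.start > o.end and not compatible:
            out.append(r)
            continue
        if r.end <= o.end and r.period == o.period:
            # fully contained duplicate annotation from the overlap zone
            continue
        g = r.period if r.period == o.period else math.gcd(r.period, o.period)
        if g > 1 or r.period == o.period:
            ov = max(0, o.end - r.start)
            d_o = o.score / max(len(o), 1)
            d_r = r.score / max(len(r), 1)
            o.score = o.score + r.score - ov * min(d_o, d_r)
            o.end = max(o.end, r.end)
            o.period = g
            o.run_end = max(o.run_end, r.run_end)
            o.end_kind = r.end_kind if r.run_end >= o.run_end else o.end_kind
            o.indel_events += r.indel_events
            # profile phase cannot be stitched exactly across windows:
            # rebuild as a pure cycle from the merged start
            o.profile_indices = (np.arange(len(o)) % o.period + 1).astype(np.int32)
        else:
            mid = (r.start + o.end) // 2
            if o.score >= r.score:
                keep = (r.end - mid) / max(len(r), 1)
                if r.end - mid >= 1:
                    r.score *= keep
                    trim = mid - r.start
                    r.start = mid
                    r.run_start = max(r.run_start, mid)
                    if r.profile_indices is not None:
                        r.profile_indices = r.profile_indices[trim:]
                    out.append(r)
            else:
                keep = (mid - o.start) / max(len(o), 1)
                if mid - o.start >= 1:
                    o.score *= keep
                    if o.profile_indices is not None:
                        o.profile_indices = o.profile_indices[:mid - o.start]
                    o.end = mid
                    o.run_end = min(o.run_end, mid)
                    out.append(r)
                else:
                    out[-1] = r
    return [r for r in out if len(r) >= 1]


def decode_window(codes: np.ndarray, params: ModelParams, min_unit: int = 2,
                  seq_id: str = "seq", offset: int = 0) -> list[RepeatRegion]:
    vm = viterbi_fill(codes, params)
    path = traceback(vm)
    return extract_regions(path, codes, params, min_unit=min_unit,
                           seq_id=seq_id, offset=offset)


def annotate_codes(codes: np.ndarray, params: ModelParams,
                   plan: WindowPlan | None = None, min_unit: int = 2,
                   seq_id: str = "seq", threads: int = 1) -> list[RepeatRegion]:
    """Windowed decode of a full sequence, merged across windows."""
    n = len(codes)
    if n == 0:
        return []
    plan = plan_windows(n, params, plan)
    wins = plan.windows(n)

    def work(win):
        a, b = win
        return decode_window(codes[a:b], params, min_unit=min_unit,
                             seq_id=seq_id, offset=a)

    if threads > 1 and len(wins) > 1:
        with ThreadPoolExecutor(max_workers=threads) as ex:
            results = list(ex.map(work, wins))
    else:
        results = [work(w) for w in wins]
    return merge_windows(list(zip(wins, results)))


def estimate_memory(n: int, params: ModelParams, plan: WindowPlan | None = None,
                    threads: int = 1) -> int:
    """Expected peak decoder memory in bytes: one value (8 B) plus one
    backpointer (4 B) per Viterbi cell per concurrent window, plus fixed
    overhead."""
    m = state_count(params.max_period, params.n_insert, params.n_delete)
    if m < 1:
        raise ValueError("topology has no states")
    if threads < 1:
        raise ValueError("threads must be >= 1")
    plan = plan_windows(max(n, 1), params, plan)
    w = min(plan.window_size, max(n, 1))
    fixed = 64 * 2 ** 20
    return threads * w * m * 12 + fixed
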