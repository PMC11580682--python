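"""Numba inner loops for the windowed Viterbi decoder.

The aggregated J-chain update: every I/D-state owns a chain of p offset
states that is purely deterministic (single predecessor, transition
probability 1).  Instead of storing a column value and backpointer for
every offset state, each chain keeps a circular buffer of its in-flight
excursions (one per possible entry column in the last p+1 columns).  Each
column, every in-flight excursion is advanced by adding the chain's
emission log-ratio -- the same single floating-point addition the naive
per-state dynamic program would perform, in the same order, so results are
bit-identical -- and the excursion that has completed its p offset
emissions competes for the period-p repetitive state.  No per-offset-state
transition lookups, max() scans, or backpointers are needed; traceback
through a chain is reconstructed arithmetically from the entry column.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = float("-inf")


@njit(cache=True, nogil=True)
def fill_window(codes, k, ni, nd,
                ematch, emismatch,
                t00, tR0, t0R, selfR,
                toI1, toD1, iext, dext, inextm, dnextm,
                ch_off, ch_q, ch_p, ch_isdel, ch_j, ch_base,
                i_id, d_id,
                v0, vR, bp0, bpR,
                lastI, lastD, jval, jentry,
                fullmat, materialize):
    """Fill one window; outputs are written into the preallocated arrays.

    codes: int8[n]; v0: f8[n+1]; vR: f8[k, n+1]; bp0/bpR: int32.
    bpR codes: 0 = entered from nonrepetitive, 1 = self, 2+c = exit of
    chain c.  jval/jentry hold the chain ring buffers (entry column of the
    excursion currently in each slot, -10**9 when empty).
    """
    n = codes.shape[0]
    nchains = ch_off.shape[0]
    kq = k + ni
    e = np.zeros(kq + 1)

    prevR = np.full(k + 1, NEG_INF)
    newR = np.full(k + 1, NEG_INF)
    prevI = np.full((k + 1, ni + 1), NEG_INF)
    curI = np.full((k + 1, ni + 1), NEG_INF)
    curD = np.full((k + 1, nd + 1), NEG_INF)
    prev0 = 0.0

    v0[0] = 0.0
    for p in range(1, k + 1):
        vR[p - 1, 0] = NEG_INF
    if materialize:
        fullmat[0, 0] = 0.0

    for t in range(1, n + 1):
        c = codes[t - 1]
        # emission log-ratios for every look-back used by any state
        for q in range(1, kq + 1):
            idx = t - 1 - q
            if idx < 0 or c == 4:
                e[q] = 0.0
            else:
                c0 = codes[idx]
                if c0 == 4:
                    e[q] = 0.0
                elif c0 == c:
                    e[q] = ematch[c]
                else:
                    e[q] = emismatch[c0]

        # repetitive states: enter / self / return from a completed chain
        ci = 0
        for p in range(1, k + 1):
            best = prev0 + t0R[p - 1]
            arg = 0
            cand = prevR[p] + selfR
            if cand > best:
                best = cand
                arg = 1
            for local in range(ni + nd):
                cc = ci + local
                fin = jval[ch_off[cc] + t % (p + 1)]
                if fin > best:           # J_p -> R transition has log-prob 0
                    best = fin
                    arg = 2 + cc
            newR[p] = best + e[p]
            bpR[p - 1, t] = arg
            ci += ni + nd

        # nonrepetitive state
        best0 = prev0 + t00
        arg0 = 0
        for p in range(1, k + 1):
            cand = prevR[p] + tR0
            if cand > best0:
                best0 = cand
                arg0 = p
        new0 = best0

        # insertion states (emit at background: log-ratio 0)
        for p in range(1, k + 1):
            if ni > 0:
                curI[p, 1] = prevR[p] + toI1
                for j in range(2, ni + 1):
                    curI[p, j] = prevI[p, j - 1] + iext

        # advance in-flight chain excursions (each emits this column's letter)
        for cc in range(nchains):
            p = ch_p[cc]
            q = ch_q[cc]
            eq = e[q] if q >= 1 else 0.0
            off = ch_off[cc]
            skip = t % (p + 1)
            for s in range(p + 1):
                if s != skip:
                    jval[off + s] += eq

        # silent deletion states (same column) and new chain entries
        ci = 0
        for p in range(1, k + 1):
            if nd > 0:
                curD[p, 1] = newR[p] + toD1
                for j in range(2, nd + 1):
                    curD[p, j] = curD[p, j - 1] + dext
            slot = t % (p + 1)
            for j in range(1, ni + 1):
                cc = ci + (j - 1)
                commit = inextm if j < ni else 0.0
                jval[ch_off[cc] + slot] = curI[p, j] + commit
                jentry[ch_off[cc] + slot] = t
            for j in range(1, nd + 1):
                cc = ci + ni + (j - 1)
                commit = dnextm if j < nd else 0.0
                jval[ch_off[cc] + slot] = curD[p, j] + commit
                jentry[ch_off[cc] + slot] = t
            ci += ni + nd

        # commit column
        v0[t] = new0
        bp0[t] = arg0
        for p in range(1, k + 1):
            vR[p - 1, t] = newR[p]
        if materialize:
            fullmat[t, 0] = new0
            for p in range(1, k + 1):
                fullmat[t, p] = newR[p]
                for j in range(1, ni + 1):
                    fullmat[t, i_id[p - 1, j - 1]] = curI[p, j]
                for j in range(1, nd + 1):
                    fullmat[t, d_id[p - 1, j - 1]] = curD[p, j]
            for cc in range(nchains):
                p = ch_p[cc]
                off = ch_off[cc]
                for s in range(p + 1):
                    t0 = jentry[off + s]
                    pos = t - t0
                    if 1 <= pos <= p:
                        fullmat[t, ch_base[cc] + pos - 1] = jval[off + s]

        prev0 = new0
        tmp = prevR
        prevR = newR
        newR = tmp
        tmpI = prevI
        prevI = curI
        curI = tmpI

    for p in range(1, k + 1):
        for j in range(1, ni + 1):
            lastI[p - 1, j - 1] = prevI[p, j]
        for j in range(1, nd + 1):
            lastD[p - 1, j - 1] = curD[p, j]
    return 0


# traceback modes
_BG, _R, _I, _J = 0, 1, 2, 3


@njit(cache=True, nogil=True)
def traceback_window(n, k, ni, nd,
                     bp0, bpR,
                     t00, tR0, t0R, selfR,
                     toI1, toD1, iext, dext, inextm, dnextm,
                     ch_q, ch_p, ch_isdel, ch_j,
                     ftype, fp, fj, fchain, fs,
                     kind, per, look, translog, del_pos, del_depth):
    """Walk backpointers from the final state; fill per-position arrays.

    kind: 0 background, 1 repetitive, 2 insert, 3 offset.  translog[i] is
    the transition log-probability into position i's state (silent deletion
    hops folded into the first offset position).  Returns the number of
    deletion events recorded.
    """
    col = n
    mode = ftype
    p = fp
    j = fj
    chain = fchain
    s = fs
    ndel = 0
    while col > 0:
        if mode == _BG:
            kind[col - 1] = 0
            per[col - 1] = 0
            look[col - 1] = 0
            b = bp0[col]
            if b == 0:
                translog[col - 1] = t00
                mode = _BG
            else:
                translog[col - 1] = tR0
                mode = _R
                p = b
            col -= 1
        elif mode == _R:
            kind[col - 1] = 1
            per[col - 1] = p
            look[col - 1] = p
            b = bpR[p - 1, col]
            if b == 0:
                translog[col - 1] = t0R[p - 1]
                mode = _BG
            elif b == 1:
                translog[col - 1] = selfR
            else:
                translog[col - 1] = 0.0  # J_p -> R
                chain = b - 2
                mode = _J
                s = ch_p[chain]
            col -= 1
        elif mode == _J:
            kind[col - 1] = 3
            per[col - 1] = ch_p[chain]
            look[col - 1] = ch_q[chain]
            depth = ch_j[chain]
            if s > 1:
                translog[col - 1] = 0.0
                s -= 1
            elif ch_isdel[chain] == 1:
                commit = dnextm if depth < nd else 0.0
                translog[col - 1] = toD1 + (depth - 1) * dext + commit
                del_pos[ndel] = col - 1
                del_depth[ndel] = depth
                ndel += 1
                mode = _R
                p = ch_p[chain]
            else:
                commit = inextm if depth < ni else 0.0
                translog[col - 1] = commit
                mode = _I
                p = ch_p[chain]
                j = depth
            col -= 1
        else:  # _I
            kind[col - 1] = 2
            per[col - 1] = p
            look[col - 1] = 0
            if j > 1:
                translog[col - 1] = iext
                j -= 1
            else:
                translog[col - 1] = toI1
                mode = _R
            col -= 1
    return ndel


@njit(cache=True, nogil=True)
def emission_ratios_for_path(codes, kind, look, ematch, emismatch, out):
    """Per-position emission log-ratios along a traced path."""
    n = codes.shape[0]
    for i in range(n):
        kd = kind[i]
        q = look[i]
        if (kd != 1 and kd != 3) or q < 1 or i - q < 0:
            out[i] = 0.0
            continue
        c = codes[i]
        c0 = codes[i - q]
        if c == 4 or c0 == 4:
            out[i] = 0.0
        elif c == c0:
            out[i] = ematch[c]
        else:
            out[i] = emismatch[c0]
    return 0
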