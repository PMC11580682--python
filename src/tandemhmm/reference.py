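"""Naive decoding engines used as independent cross-checks.

Two engines live here, both deliberately simple and both operating on the
explicit :class:`~tandemhmm.model.Topology`:

* :func:`viterbi_matrix` / :func:`traceback_matrix` -- a per-state dynamic
  program that stores a value and a backpointer for every state at every
  position, including every individual J (offset) state.  The production
  decoder's aggregated J-chain update must reproduce this matrix
  bit-for-bit.

* :func:`best_path_enumeration` -- exhaustive depth-first enumeration of
  all valid state paths.  Only usable for tiny sequences and tiny models;
  it is the ground truth for the Viterbi recurrence itself.

Ties are broken identically everywhere: prefer lower period, then
non-indel states, then lower state id (for paths, applied from the final
position backwards).
"""

from __future__ import annotations

import numpy as np

from .model import (
    Topology, emission_tables, emission_log_ratio,
)

NEG_INF = float("-inf")


def viterbi_matrix(codes: np.ndarray, topo: Topology) -> tuple[np.ndarray, np.ndarray]:
    """Fill the full (n+1) x m matrix of best log score-ratios.

    Row 0 is the start column (only the nonrepetitive state is live).
    Silent D-states take their value within the same column, in chain
    order.  Returns (values, backpointers); backpointer -1 marks an
    unreachable cell.
    """
    n = len(codes)
    m = topo.n_states
    states = topo.states
    logT = topo.log_transitions
    ematch, emismatch = emission_tables(topo.params)

    V = np.full((n + 1, m), NEG_INF)
    ptr = np.full((n + 1, m), -1, dtype=np.int64)
    V[0, 0] = 0.0

    emitting = [s for s in states if not s.silent]
    silent = [s for s in states if s.silent]  # id order == chain-depth order

    for t in range(1, n + 1):
        for s in emitting:
            best = NEG_INF
            arg = -1
            for u in topo.predecessors(s.id):
                val = V[t - 1, u]
                if val == NEG_INF:
                    continue
                cand = val + logT[(u, s.id)]
                if cand > best:
                    best = cand
                    arg = u
            if arg >= 0:
                V[t, s.id] = best + emission_log_ratio(
                    codes, t - 1, s.look_back, ematch, emismatch)
                ptr[t, s.id] = arg
        for s in silent:
            best = NEG_INF
            arg = -1
            for u in topo.predecessors(s.id):
                val = V[t, u]  # same column: silent states consume no letter
                if val == NEG_INF:
                    continue
                cand = val + logT[(u, s.id)]
                if cand > best:
                    best = cand
                    arg = u
            if arg >= 0:
                V[t, s.id] = best
                ptr[t, s.id] = arg
    return V, ptr


def _final_state(V: np.ndarray, topo: Topology, t: int) -> int:
    order = sorted(topo.states, key=lambda s: s.sort_key)
    best = NEG_INF
    arg = 0
    for s in order:
        if V[t, s.id] > best:
            best = V[t, s.id]
            arg = s.id
    return arg


def traceback_matrix(V: np.ndarray, ptr: np.ndarray, topo: Topology):
    """Recover the best path from a filled matrix.

    Returns ``(emitted, silent_events)``: ``emitted[i]`` is the state id
    that emitted letter i, ``silent_events`` is a list of (position, state
    id) pairs for silent states crossed immediately before the letter at
    ``position`` was emitted (position == n for trailing silent states).
    """
    n = V.shape[0] - 1
    states = topo.states
    v = _final_state(V, topo, n)
    t = n
    emitted: list[int] = []
    silent_events: list[tuple[int, int]] = []
    while t > 0 or states[v].silent:
        if states[v].silent:
            silent_events.append((t, v))
            v = int(ptr[t, v])
        else:
            emitted.append(v)
            u = int(ptr[t, v])
            t -= 1
            v = u
    emitted.reverse()
    silent_events.reverse()
    # silent event recorded at column t sits before the letter at index t
    silent_events = [(t, s) for (t, s) in silent_events]
    return emitted, silent_events


def path_score(codes: np.ndarray, topo: Topology, full_path: list[int]) -> float:
    """Score of an explicit state path (column-0 start state included)."""
    ematch, emismatch = emission_tables(topo.params)
    logT = topo.log_transitions
    states = topo.states
    score = 0.0
    t = 0
    for prev, cur in zip(full_path, full_path[1:]):
        score += logT[(prev, cur)]
        if not states[cur].silent:
            score += emission_log_ratio(codes, t, states[cur].look_back,
                                        ematch, emismatch)
            t += 1
    return score


def best_path_enumeration(codes: np.ndarray, topo: Topology,
                          tol: float = 1e-12):
    """Exhaustively enumerate all state paths; return (best_score, best_path).

    The best path is chosen among (near-)maximal-score paths by the shared
    tie rule, applied backwards from the final state.  ``best_path`` is the
    full path including silent states, starting with state 0 at column 0.
    Exponential in sequence length: tiny inputs only.
    """
    n = len(codes)
    states = topo.states
    logT = topo.log_transitions
    ematch, emismatch = emission_tables(topo.params)
    succ: dict[int, list[int]] = {s.id: [] for s in states}
    for (u, v) in topo.transitions:
        succ[u].append(v)

    best_score = NEG_INF
    best_key: tuple | None = None
    best_path: list[int] | None = None

    def revkey(path: list[int]) -> tuple:
        return tuple(states[v].sort_key for v in reversed(path))

    stack: list[tuple[int, int, float, list[int]]] = [(0, 0, 0.0, [0])]
    while stack:
        v, t, score, path = stack.pop()
        if t == n:
            if score > best_score + tol:
                best_score, best_key, best_path = score, revkey(path), list(path)
            elif score > best_score - tol:
                if score > best_score:
                    best_score = score
                key = revkey(path)
                if best_key is None or key < best_key:
                    best_key, best_path = key, list(path)
        for w in succ[v]:
            if states[w].silent:
                stack.append((w, t, score + logT[(v, w)], path + [w]))
            elif t < n:
                e = emission_log_ratio(codes, t, states[w].look_back,
                                       ematch, emismatch)
                stack.append((w, t + 1, score + logT[(v, w)] + e, path + [w]))
    assert best_path is not None
    return best_score, best_path


def emitted_states_of(full_path: list[int], topo: Topology) -> list[int]:
    """Project a full path (with silent states) onto emitting positions."""
    return [v for v in full_path[1:] if not topo.states[v].silent]
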