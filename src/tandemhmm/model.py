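"""Hidden Markov model for tandemly repetitive DNA/RNA.

The model couples one *nonrepetitive* state (background emission, blind to
context) with one *repetitive* state per period p = 1..k.  A period-p
repetitive state is context-sensitive: at position t it prefers to re-emit
the letter observed at position t-p (probability ``match_prob``), spreading
the remaining mass over the three mismatching letters in proportion to the
background composition.  Insertions and deletions are modeled explicitly:
up to ``n_insert`` consecutive I-states (emitting at background, look-back
0), up to ``n_delete`` consecutive silent D-states, and -- after every
I/D-state -- a dedicated chain of p offset (J) states whose look-back is
shifted by the indel length (p+j after j insertions, p-j after j deletions)
before control returns to the period-p repetitive state.

Entry into a period-p repeat from the nonrepetitive state is weighted by a
geometric decay over periods, gamma_p = lambda^p / sum_q lambda^q, so small
periods are a priori more common than large ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# Canonical alphabet order; fixed because profile matrices are indexed by it.
ALPHABET = ("A", "C", "G", "T")
AMBIG_CODE = 4  # any non-ACGT letter (N, IUPAC ambiguity codes, ...)

_ENCODE = np.full(256, AMBIG_CODE, dtype=np.int8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i
    _ENCODE[ord(_c.lower())] = _i
_ENCODE[ord("U")] = 3  # RNA: U behaves as T
_ENCODE[ord("u")] = 3


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode_sequence(codes: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def gamma(p: int, decay: float, k: int) -> float:
    """Prior weight of entering a period-p repeat: decay^p / sum_q decay^q."""
    if decay <= 0:
        raise ValueError("decay must be positive")
    if not 1 <= p <= k:
        raise ValueError(f"period {p} outside 1..{k}")
    return float(gamma_vector(decay, k)[p - 1])


def gamma_vector(decay: float, k: int) -> np.ndarray:
    if decay <= 0:
        raise ValueError("decay must be positive")
    if k < 1:
        raise ValueError("max period must be >= 1")
    powers = np.power(float(decay), np.arange(1, k + 1, dtype=np.float64))
    return powers / powers.sum()


def background_from_at(at_richness: float) -> np.ndarray:
    """Background composition from AT richness: P(A)=P(T)=at/2, P(C)=P(G)=(1-at)/2."""
    if not 0.0 < at_richness < 1.0:
        raise ValueError("at_richness must lie in (0, 1)")
    at = float(at_richness)
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])


@dataclass(frozen=True)
class ModelParams:
    """All user-tunable HMM parameters.

    Probabilities are linear (not log).  ``background`` must sum to 1 over
    the A, C, G, T order.
    """

    max_period: int = 100
    match_prob: float = 0.7
    decay: float = 0.85
    n_insert: int = 10
    n_delete: int = 10
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    repeat_entry: float = 0.01
    repeat_exit: float = 0.05
    indel_open: float = 0.02
    indel_extend: float = 0.2

    def __post_init__(self):
        if self.max_period < 1:
            raise ValueError("max_period must be >= 1")
        if self.n_insert < 0 or self.n_delete < 0:
            raise ValueError("indel state counts must be >= 0")
        for name in ("match_prob", "repeat_entry", "repeat_exit", "indel_extend"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0.0 <= self.indel_open < 1.0:
            raise ValueError("indel_open must lie in [0, 1)")
        bg = np.asarray(self.background, dtype=np.float64)
        if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 positive values summing to 1")
        if self.repeat_exit + self.effective_indel_open >= 1.0:
            raise ValueError("repeat_exit + indel_open must leave positive self-transition mass")

    @property
    def effective_indel_open(self) -> float:
        """Indel-opening mass actually spent (0 when no indel states exist)."""
        if self.n_insert == 0 and self.n_delete == 0:
            return 0.0
        return self.indel_open

    @property
    def background_array(self) -> np.ndarray:
        return np.asarray(self.background, dtype=np.float64)

    def with_at_richness(self, at_richness: float) -> "ModelParams":
        return replace(self, background=tuple(background_from_at(at_richness)))

    def without_indels(self) -> "ModelParams":
        return replace(self, n_insert=0, n_delete=0)


def state_count(k: int, n_insert: int, n_delete: int) -> int:
    """Closed-form model size: 1 + sum_p [1 + (i+d)(1+p)]."""
    return 1 + k + (n_insert + n_delete) * (k + k * (k + 1) // 2)


NONREP, REPETITIVE, INSERT, DELETE, OFFSET = "nonrepetitive", "repetitive", "insert", "delete", "offset"


@dataclass(frozen=True)
class State:
    id: int
    kind: str
    period: int       # 0 for nonrepetitive and insert states
    look_back: int    # 0 where no context is consulted; may be <=0 for deep deletions
    silent: bool = False
    machinery_period: int = 0   # period of the repeat machinery the state belongs to
    depth: int = 0              # indel chain depth j (I/D and their J chains)
    chain_pos: int = 0          # 1..p within a J chain

    @property
    def is_indel(self) -> bool:
        return self.kind in (INSERT, DELETE, OFFSET)

    @property
    def sort_key(self) -> tuple[int, int, int]:
        """Tie-break preference: lower period, then non-indel, then lower id."""
        return (self.period, 1 if self.is_indel else 0, self.id)


@dataclass
class Topology:
    """Explicit state set with transition probabilities (linear and log)."""

    params: ModelParams
    states: list[State]
    transitions: dict[tuple[int, int], float]
    log_transitions: dict[tuple[int, int], float]
    _preds: dict[int, list[int]] = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def predecessors(self, v: int) -> list[int]:
        """Predecessor state ids of v, sorted by tie-break preference."""
        if not self._preds:
            preds: dict[int, list[int]] = {s.id: [] for s in self.states}
            for (u, w) in self.transitions:
                preds[w].append(u)
            for w, lst in preds.items():
                lst.sort(key=lambda u: self.states[u].sort_key)
            self._preds = preds
        return self._preds[v]

    def outgoing_mass(self, u: int) -> float:
        return sum(p for (a, _), p in self.transitions.items() if a == u)


def build_topology(params: ModelParams, max_states: int = 1_000_000) -> Topology:
    """Enumerate states and transitions for the full model.

    State ids: 0 = nonrepetitive; 1..k = repetitive (period order); then per
    period p: insertion states I_1..I_i, their J chains, deletion states
    D_1..D_d, their J chains.  Every J chain has exactly p members and leads
    deterministically back to its period-p repetitive state.
    """
    k, ni, nd = params.max_period, params.n_insert, params.n_delete
    m = state_count(k, ni, nd)
    if m > max_states:
        raise ValueError(
            f"model would require {m} states (k={k}, i={ni}, d={nd}), "
            f"exceeding the cap of {max_states}"
        )

    states: list[State] = [State(0, NONREP, 0, 0)]
    for p in range(1, k + 1):
        states.append(State(p, REPETITIVE, p, p, machinery_period=p))

    trans: dict[tuple[int, int], float] = {}
    gammas = gamma_vector(params.decay, k)
    entry, exit_, open_, ext = (
        params.repeat_entry, params.repeat_exit,
        params.effective_indel_open, params.indel_extend,
    )
    # Indel-open mass split evenly between the I and D chains (all of it to
    # one side when the other has no states).
    open_i = open_ / 2 if (ni > 0 and nd > 0) else (open_ if ni > 0 else 0.0)
    open_d = open_ / 2 if (ni > 0 and nd > 0) else (open_ if nd > 0 else 0.0)

    trans[(0, 0)] = 1.0 - entry
    for p in range(1, k + 1):
        trans[(0, p)] = entry * float(gammas[p - 1])
        trans[(p, 0)] = exit_
        trans[(p, p)] = 1.0 - exit_ - open_

    def add_chain(p: int, r_id: int, kind: str, n_chain: int, open_prob: float,
                  next_id: int) -> int:
        """Append I/D states and their J chains for one period; return next id."""
        silent = kind == DELETE
        indel_ids = []
        for j in range(1, n_chain + 1):
            states.append(State(next_id, kind, 0 if kind == INSERT else p,
                                0, silent=silent, machinery_period=p, depth=j))
            indel_ids.append(next_id)
            next_id += 1
        for j, sid in enumerate(indel_ids, start=1):
            src = r_id if j == 1 else indel_ids[j - 2]
            prob = open_prob if j == 1 else ext
            trans[(src, sid)] = prob
            # continue the consecutive-indel chain or commit to the J chain
            stay = ext if j < n_chain else 0.0
            look = p + j if kind == INSERT else p - j
            first_j = next_id
            for pos in range(1, p + 1):
                states.append(State(next_id, OFFSET, p, look,
                                    machinery_period=p, depth=j, chain_pos=pos))
                if pos == 1:
                    trans[(sid, next_id)] = 1.0 - stay
                else:
                    trans[(next_id - 1, next_id)] = 1.0
                next_id += 1
            trans[(next_id - 1, r_id)] = 1.0
            del first_j
        return next_id

    next_id = k + 1
    for p in range(1, k + 1):
        if ni > 0:
            next_id = add_chain(p, p, INSERT, ni, open_i, next_id)
        if nd > 0:
            next_id = add_chain(p, p, DELETE, nd, open_d, next_id)

    assert len(states) == m, (len(states), m)
    log_trans = {uv: float(np.log(pr)) for uv, pr in trans.items()}
    return Topology(params, states, trans, log_trans)


def state_id(k: int, ni: int, nd: int, kind: str, p: int = 0,
             depth: int = 0, chain_pos: int = 0, deletion: bool = False) -> int:
    """Closed-form state id matching :func:`build_topology`'s enumeration.

    ``deletion`` selects the D-side J chain when ``kind`` is "offset".
    """
    if kind == NONREP:
        return 0
    if kind == REPETITIVE:
        return p
    base = k + 1 + (ni + nd) * ((p - 1) + (p - 1) * p // 2)
    if kind == INSERT:
        return base + (depth - 1)
    if kind == OFFSET and not deletion:
        return base + ni + (depth - 1) * p + (chain_pos - 1)
    if kind == DELETE:
        return base + ni * (1 + p) + (depth - 1)
    if kind == OFFSET and deletion:
        return base + ni * (1 + p) + nd + (depth - 1) * p + (chain_pos - 1)
    raise ValueError(f"unknown state kind {kind!r}")


def emission_probability(state: State, t: int, codes: np.ndarray,
                         params: ModelParams) -> float:
    """Probability of ``state`` emitting the letter at 0-based position t.

    Nonrepetitive and insert states emit from the background.  A state with
    look-back q emits the letter matching position t-q with probability
    ``match_prob`` and spreads the remaining mass over the other letters in
    proportion to the background.  Positions within the look-back of the
    sequence start and any comparison involving an ambiguity letter fall
    back to the background distribution.
    """
    if state.silent:
        raise ValueError("silent states do not emit")
    bg = params.background_array
    c = int(codes[t])
    if state.kind in (NONREP, INSERT) or state.look_back < 1:
        return 1.0 / len(bg) if c == AMBIG_CODE else float(bg[c])
    q = state.look_back
    if t - q < 0:
        return 1.0 / len(bg) if c == AMBIG_CODE else float(bg[c])
    c0 = int(codes[t - q])
    if c == AMBIG_CODE or c0 == AMBIG_CODE:
        return 1.0 / len(bg) if c == AMBIG_CODE else float(bg[c])
    if c == c0:
        return params.match_prob
    return (1.0 - params.match_prob) * float(bg[c]) / (1.0 - float(bg[c0]))


def emission_tables(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Log emission ratios shared by both decoding engines.

    ``ematch[c]`` = log(match_prob / bg[c]) -- letter c repeats the letter
    look-back positions earlier.  ``emismatch[c0]`` = log((1-match_prob) /
    (1-bg[c0])) -- mismatch against earlier letter c0.  Background, insert,
    ambiguity and out-of-range comparisons all contribute log-ratio 0.
    """
    bg = params.background_array
    ematch = np.log(params.match_prob / bg)
    emismatch = np.log((1.0 - params.match_prob) / (1.0 - bg))
    return ematch, emismatch


def emission_log_ratio(codes: np.ndarray, t: int, look_back: int,
                       ematch: np.ndarray, emismatch: np.ndarray) -> float:
    """log(E[t,v] / E[t,0]) for an emitting state with the given look-back."""
    if look_back < 1 or t - look_back < 0:
        return 0.0
    c = int(codes[t])
    c0 = int(codes[t - look_back])
    if c == AMBIG_CODE or c0 == AMBIG_CODE:
        return 0.0
    if c == c0:
        return float(ematch[c])
    return float(emismatch[c0])
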