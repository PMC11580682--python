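"""Synthetic tandem-repeat sequence generators and motif-counting utilities.

The two-subrepeat benchmark concatenates two perfect length-500 tandem
tracts built from repeat units of the same period that share at most 50%
positional identity under every relative rotation, then applies uniform
substitution noise; splitting accuracy is the fraction of such sequences
for which exactly one repeat split is reported within 10 nt of the true
junction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ALPHABET, ModelParams, encode_sequence, decode_sequence
from .decode import annotate_codes
from .split import split_region

DEFAULT_TRACT = 500


def rotations(unit: str) -> list[str]:
    return [unit[i:] + unit[:i] for i in range(len(unit))]


def rotational_identity(unit_a: str, unit_b: str) -> float:
    """Max over all relative rotations of the fraction of matching positions."""
    if len(unit_a) != len(unit_b):
        raise ValueError("units must have equal length")
    p = len(unit_a)
    best = 0
    for rb in rotations(unit_b):
        matches = sum(1 for x, y in zip(unit_a, rb) if x == y)
        best = max(best, matches)
    return best / p


def is_primitive(unit: str) -> bool:
    """True when no proper rotation reproduces the unit (its true period
    is its full length)."""
    return all(unit != r for r in rotations(unit)[1:])


def valid_unit_pair(unit_a: str, unit_b: str) -> bool:
    return (is_primitive(unit_a) and is_primitive(unit_b)
            and rotational_identity(unit_a, unit_b) <= 0.5)


def sample_unit_pair(period: int, seed: int = 0) -> tuple[str, str]:
    """Rejection-sample two primitive units with <= 50% rotational identity."""
    if not 1 <= period <= 10:
        raise ValueError("period must lie in 1..10")
    rng = np.random.default_rng(seed)
    if period == 1:
        a, b = rng.choice(4, size=2, replace=False)
        return ALPHABET[a], ALPHABET[b]
    while True:
        ua = "".join(ALPHABET[c] for c in rng.integers(0, 4, period))
        ub = "".join(ALPHABET[c] for c in rng.integers(0, 4, period))
        if valid_unit_pair(ua, ub):
            return ua, ub


def mutate_substitutions(codes: np.ndarray, rate: float, seed: int = 0) -> np.ndarray:
    """Substitute each position independently with probability ``rate``;
    the replacement is uniform over the three other letters."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = np.array(codes, dtype=np.int8, copy=True)
    hit = np.flatnonzero(rng.random(len(out)) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = (out[hit] + shift) % 4
    return out


@dataclass(frozen=True)
class SimSpec:
    """Two-subrepeat benchmark sequence specification."""

    period: int
    unit_a: str
    unit_b: str
    tract_length: int = DEFAULT_TRACT
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.unit_a) != self.period or len(self.unit_b) != self.period:
            raise ValueError("unit lengths must equal the period")
        if rotational_identity(self.unit_a, self.unit_b) > 0.5:
            raise ValueError("units share more than 50% rotational identity")


def build_two_subrepeat_sequence(spec: SimSpec) -> tuple[np.ndarray, int]:
    """Perfect tract of unit_a then of unit_b, then substitution noise.

    Returns (encoded sequence, junction position).
    """
    L = spec.tract_length
    reps = -(-L // spec.period) + 1
    tract_a = (spec.unit_a * reps)[:L]
    tract_b = (spec.unit_b * reps)[:L]
    codes = encode_sequence(tract_a + tract_b)
    if spec.substitution_rate > 0:
        codes = mutate_substitutions(codes, spec.substitution_rate, spec.seed)
    return codes, L


def _benchmark_params(period: int) -> ModelParams:
    return ModelParams(max_period=max(10, period), n_insert=0, n_delete=0)


def find_single_split(codes: np.ndarray, params: ModelParams,
                      threshold: float = 3.5) -> list[int]:
    """Full pipeline on one benchmark sequence; all reported split
    positions (sequence coordinates)."""
    regions = annotate_codes(codes, params)
    splits: list[int] = []
    for r in regions:
        split_region(r, codes, threshold=threshold)
        bounds = [s.start for s in r.subrepeats[1:]]
        splits.extend(bounds)
    return splits


def splitting_accuracy(trials: int, period: int, rate: float, seed: int = 0,
                       tract_length: int = DEFAULT_TRACT,
                       threshold: float = 3.5, tolerance_nt: int = 10) -> float:
    """Fraction of simulated two-subrepeat sequences for which exactly one
    split is reported within ``tolerance_nt`` of the true junction."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    params = _benchmark_params(period)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(trials):
        s1, s2 = rng.integers(0, 2 ** 31, size=2)
        ua, ub = sample_unit_pair(period, int(s1))
        spec = SimSpec(period, ua, ub, tract_length, rate, int(s2))
        codes, junction = build_two_subrepeat_sequence(spec)
        splits = find_single_split(codes, params, threshold)
        if len(splits) == 1 and abs(splits[0] - junction) <= tolerance_nt:
            hits += 1
    return hits / trials


def planted_genome(length: int, repeat_fraction: float = 0.2,
                   max_period: int = 10, seed: int = 0,
                   substitution_rate: float = 0.05, at_richness: float = 0.5,
                   mean_tract: int = 300) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Background sequence with tandem-repeat tracts planted to the target
    coverage.  Returns (sequence, truth list of (start, end, period))."""
    from .calibrate import generate_background

    rng = np.random.default_rng(seed)
    codes = generate_background(length, at_richness, int(rng.integers(2 ** 31)))
    target = int(length * repeat_fraction)
    truth = []
    planted = 0
    guard = 0
    while planted < target and guard < 10_000:
        guard += 1
        p = int(rng.integers(1, max_period + 1))
        tract = int(max(2 * p, rng.geometric(1.0 / mean_tract)))
        start = int(rng.integers(0, max(length - tract, 1)))
        if any(s < start + tract and start < e for s, e, _ in truth):
            continue
        unit = rng.integers(0, 4, p).astype(np.int8)
        reps = -(-tract // p)
        rep = np.tile(unit, reps)[:tract]
        rep = mutate_substitutions(rep, substitution_rate,
                                   int(rng.integers(2 ** 31)))
        codes[start:start + tract] = rep
        truth.append((start, start + tract, p))
        planted += tract
    truth.sort()
    return codes, truth


def count_exact_nonoverlapping(haystack: str, motif: str) -> int:
    """Greedy left-to-right nonoverlapping occurrence count (grep -o style),
    case-insensitive."""
    if not motif:
        raise ValueError("empty motif")
    hs = haystack.upper()
    mt = motif.upper()
    count = 0
    i = hs.find(mt)
    while i != -1:
        count += 1
        i = hs.find(mt, i + len(mt))
    return count


def count_fuzzy_nonoverlapping(haystack: str, motif: str, max_subs: int) -> int:
    """Greedy left-to-right nonoverlapping count allowing up to ``max_subs``
    substitutions (fixed-length windows, no indels), case-insensitive."""
    if max_subs < 0:
        raise ValueError("max_subs must be >= 0")
    if not motif:
        raise ValueError("empty motif")
    hs = encode_sequence(haystack.upper())
    mt = encode_sequence(motif.upper())
    n, w = len(hs), len(mt)
    count = 0
    i = 0
    while i + w <= n:
        if int(np.sum(hs[i:i + w] != mt)) <= max_subs:
            count += 1
            i += w
        else:
            i += 1
    return count


def write_benchmark_fasta(path: str, specs: list[SimSpec]) -> None:
    """FASTA of benchmark sequences plus a BED of true junctions."""
    bed = []
    with open(path, "w") as fh:
        for i, spec in enumerate(specs):
            codes, junction = build_two_subrepeat_sequence(spec)
            name = f"sim{i}_p{spec.period}_r{spec.substitution_rate}"
            fh.write(f">{name}\n{decode_sequence(codes)}\n")
            bed.append(f"{name}\t{junction}\t{junction + 1}\tjunction")
    with open(path + ".junctions.bed", "w") as fh:
        fh.write("\n".join(bed) + "\n")
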