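"""FDR-constrained parameter tuning against a locally shuffled null.

Shuffling letters within fixed windows preserves regional composition
(isochore-like structure) but destroys tandem repeats, so annotation
coverage of the shuffled input estimates false coverage.  For each
candidate parameter set the estimated false discovery rate is

    FDR = coverage(shuffled input) / coverage(input)

and the tuner picks the candidate with the greatest coverage among those
with FDR at or below the threshold (10% by default).  Indel states are
disabled during tuning by default (they are re-enabled for the final run),
trading a slightly optimistic FDR estimate for a large speedup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .model import ModelParams, background_from_at
from .decode import RepeatRegion, WindowPlan, annotate_codes, plan_windows


class TuningError(RuntimeError):
    def __init__(self, message: str, report: list["TuneCandidate"] | None = None):
        super().__init__(message)
        self.report = report or []


def local_shuffle(codes: np.ndarray, window: int, seed: int = 0) -> np.ndarray:
    """Independently permute each consecutive window of the sequence.

    Per-window letter multisets (hence regional composition) are preserved
    exactly.
    """
    if window < 2:
        raise ValueError("shuffle window must be >= 2")
    rng = np.random.default_rng(seed)
    out = np.array(codes, dtype=np.int8, copy=True)
    for a in range(0, len(out), window):
        b = min(a + window, len(out))
        out[a:b] = out[a:b][rng.permutation(b - a)]
    return out


def coverage(regions: list[RepeatRegion], n: int) -> float:
    """Fraction of positions covered by at least one region."""
    if n <= 0:
        raise ValueError("sequence length must be positive")
    ivs = sorted((r.start, r.end) for r in regions)
    covered = 0
    cur_s, cur_e = None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / n


def estimate_fdr(cov: float, shuf_cov: float) -> float:
    """Shuffled coverage over original coverage; NaN when undefined."""
    if cov <= 0:
        return math.nan
    return shuf_cov / cov


@dataclass
class TuneCandidate:
    params: ModelParams
    coverage: float
    shuffled_coverage: float
    fdr: float

    @property
    def passed(self) -> bool:
        return not math.isnan(self.fdr)


def builtin_grids(size: str, base: ModelParams | None = None) -> list[ModelParams]:
    """Candidate parameter grids of 18 / 40 / 252 configurations.

    Cartesian products over AT richness, match probability and period
    decay, anchored on the base parameters (max period and indel counts
    are taken from ``base``):

    * small (18): at in {0.3, 0.4, 0.5, 0.6, 0.7} x m in {0.6, 0.7, 0.9}
      at the default decay, plus decay in {0.6, 0.75, 0.95} at
      (at=0.5, m=0.7).
    * medium (40): at in {0.2..0.8} x m in {0.5, 0.6, 0.7, 0.9}, plus
      decay in {0.5, 0.7, 0.9, 0.95} x m in {0.6, 0.7, 0.9} at at=0.5.
    * large (252): at in {0.2..0.8} x m in {0.5, 0.6, 0.65, 0.7, 0.8, 0.9}
      x decay in {0.5, 0.6, 0.7, 0.8, 0.9, 0.95}.
    """
    base = base or ModelParams()
    grid: list[ModelParams] = []

    def add(at, m, decay):
        grid.append(replace(base, match_prob=m, decay=decay,
                            background=tuple(background_from_at(at))))

    if size == "small":
        for at in (0.3, 0.4, 0.5, 0.6, 0.7):
            for m in (0.6, 0.7, 0.9):
                add(at, m, 0.85)
        for decay in (0.6, 0.75, 0.95):
            add(0.5, 0.7, decay)
    elif size == "medium":
        for at in (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8):
            for m in (0.5, 0.6, 0.7, 0.9):
                add(at, m, 0.85)
        for decay in (0.5, 0.7, 0.9, 0.95):
            for m in (0.6, 0.7, 0.9):
                add(0.5, m, decay)
    elif size == "large":
        for at in (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8):
            for m in (0.5, 0.6, 0.65, 0.7, 0.8, 0.9):
                for decay in (0.5, 0.6, 0.7, 0.8, 0.9, 0.95):
                    add(at, m, decay)
    else:
        raise ValueError("grid size must be small, medium or large")
    return grid


def read_grid_file(path: str, base: ModelParams | None = None) -> list[ModelParams]:
    """User grid: whitespace-separated columns ``at match decay`` (header
    line optional)."""
    base = base or ModelParams()
    grid = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0].lower() in ("at", "at_richness"):
                continue
            at, m, decay = (float(x) for x in parts[:3])
            grid.append(replace(base, match_prob=m, decay=decay,
                                background=tuple(background_from_at(at))))
    if not grid:
        raise TuningError(f"no parameter rows found in {path}")
    return grid


def tune(codes: np.ndarray, grid: list[ModelParams],
         fdr_threshold: float = 0.10, indel_during_tuning: bool = False,
         seed: int = 0, shuffle_window: int | None = None,
         min_unit: int = 2, threads: int = 1
         ) -> tuple[ModelParams, list[TuneCandidate]]:
    """Grid search maximizing coverage subject to the FDR constraint.

    Returns the winning parameter set (with indel states restored) and the
    full per-candidate report.  Raises :class:`TuningError` (with the
    report attached) when no candidate meets the threshold.
    """
    if not grid:
        raise ValueError("empty tuning grid")
    n = len(codes)
    if shuffle_window is None:
        shuffle_window = plan_windows(n, grid[0]).window_size
    shuffled = local_shuffle(codes, shuffle_window, seed)

    report: list[TuneCandidate] = []
    for cand in grid:
        run_params = cand if indel_during_tuning else cand.without_indels()
        cov = coverage(annotate_codes(codes, run_params, min_unit=min_unit,
                                      threads=threads), n)
        shuf = coverage(annotate_codes(shuffled, run_params, min_unit=min_unit,
                                       threads=threads), n)
        report.append(TuneCandidate(cand, cov, shuf, estimate_fdr(cov, shuf)))

    passing = [c for c in report
               if c.passed and c.fdr <= fdr_threshold and c.coverage > 0]
    if not passing:
        raise TuningError(
            f"no candidate achieved FDR <= {fdr_threshold:.2f}", report)
    best = max(passing, key=lambda c: (c.coverage, c.params.match_prob,
                                       -c.params.decay))
    return best.params, report
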