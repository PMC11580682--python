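"""High-level annotation pipeline: decode, split, assign P-values."""

from __future__ import annotations

import numpy as np

from .model import ModelParams, encode_sequence
from .decode import RepeatRegion, WindowPlan, annotate_codes
from .split import DEFAULT_THRESHOLD, split_region
from .calibrate import PvalModel, p_value


def annotate_sequence(seq: "str | np.ndarray", params: ModelParams | None = None,
                      min_unit: int = 2,
                      split_threshold: float = DEFAULT_THRESHOLD,
                      pval_model: PvalModel | None = None,
                      plan: WindowPlan | None = None, seq_id: str = "seq",
                      threads: int = 1) -> list[RepeatRegion]:
    """Annotate one sequence: repeat regions with subrepeats, canonical
    pattern names and (given a calibration) P-values."""
    params = params or ModelParams()
    codes = encode_sequence(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.int8)
    regions = annotate_codes(codes, params, plan=plan, min_unit=min_unit,
                             seq_id=seq_id, threads=threads)
    for r in regions:
        split_region(r, codes, threshold=split_threshold)
        if pval_model is not None:
            r.p_value = p_value(r.score, pval_model)
    return regions


def annotate_fasta(path: str, params: ModelParams | None = None,
                   **kwargs) -> list[RepeatRegion]:
    """Annotate every record of a FASTA file (optionally gzipped)."""
    from .io import read_fasta

    out: list[RepeatRegion] = []
    for seq_id, seq in read_fasta(path):
        out.extend(annotate_sequence(seq, params, seq_id=seq_id, **kwargs))
    return out
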