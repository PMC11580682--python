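"""FASTA input, annotation output (BED6 / TSV / JSON) and flat config files."""

from __future__ import annotations

import gzip
import json
import sys
from typing import Iterator

from Bio import SeqIO

from .decode import RepeatRegion, SubRepeat


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) records in file order.

    Accepts gzip-compressed files, lowercase letters (uppercased) and RNA
    (U mapped to T).  Non-ACGT letters are preserved and treated as
    ambiguous downstream.
    """
    with _open_text(path) as fh:
        first = fh.read(1)
        if first == "":
            raise ValueError(f"{path}: empty file")
        if first != ">":
            raise ValueError(f"{path}: not FASTA (line 1 does not start with '>')")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq).upper().replace("U", "T")


TSV_COLUMNS = ("seq_id", "start", "end", "record_type", "period", "score",
               "p_value", "pattern", "indel_events", "parent")


def _tsv_rows(regions: list[RepeatRegion]):
    for i, r in enumerate(regions):
        pv = "" if r.p_value is None else f"{r.p_value:.3g}"
        # TSV uses 1-based inclusive coordinates
        yield (r.seq_id, r.start + 1, r.end, "region", r.period,
               f"{r.score:.4f}", pv, r.pattern, r.indel_events, "")
        for s in r.subrepeats:
            yield (r.seq_id, s.start + 1, s.end, "subrepeat", r.period,
                   "", "", s.pattern, "", f"region_{i}")


def write_annotations(regions: list[RepeatRegion], fmt: str, path: str,
                      ) -> None:
    """Write sorted annotations; BED6 is 0-based half-open, TSV 1-based
    inclusive, JSON nests subrepeats under their parent region."""
    regions = sorted(regions, key=lambda r: (r.seq_id, r.start, r.end))
    if fmt == "bed":
        with open(path, "w") as fh:
            for r in regions:
                score = min(1000, max(0, round(r.score)))
                fh.write(f"{r.seq_id}\t{r.start}\t{r.end}\t{r.pattern or '.'}"
                         f"\t{score}\t+\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(TSV_COLUMNS) + "\n")
            for row in _tsv_rows(regions):
                fh.write("\t".join(str(x) for x in row) + "\n")
    elif fmt == "json":
        payload = [region_to_dict(r) for r in regions]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def region_to_dict(r: RepeatRegion) -> dict:
    return {
        "seq_id": r.seq_id, "start": r.start, "end": r.end,
        "period": r.period, "score": r.score, "p_value": r.p_value,
        "pattern": r.pattern, "indel_events": r.indel_events,
        "subrepeats": [
            {"start": s.start, "end": s.end, "pattern": s.pattern,
             "mean_jsd_at_boundary": s.mean_jsd_at_boundary}
            for s in r.subrepeats
        ],
    }


def region_from_dict(d: dict) -> RepeatRegion:
    r = RepeatRegion(seq_id=d["seq_id"], start=d["start"], end=d["end"],
                     period=d["period"], score=d["score"],
                     p_value=d.get("p_value"), pattern=d.get("pattern", ""),
                     indel_events=d.get("indel_events", 0))
    r.subrepeats = [SubRepeat(s["start"], s["end"], s["pattern"],
                              s.get("mean_jsd_at_boundary", 0.0))
                    for s in d.get("subrepeats", [])]
    return r


def read_annotations_json(path: str) -> list[RepeatRegion]:
    with open(path) as fh:
        return [region_from_dict(d) for d in json.load(fh)]


def read_config(path: str) -> dict[str, str]:
    """Flat ``key = value`` configuration file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, value = (x.strip() for x in line.split("=", 1))
            out[key] = value
    return out


def log(msg: str, verbose: bool = True) -> None:
    if verbose:
        print(msg, file=sys.stderr)
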