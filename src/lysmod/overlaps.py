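"""Detect overlapping (overprinted) gene pairs and report offsets and frames.

Overlapping reading frames compress phage coding capacity; the canonical case
here is a second endolysin ORF starting ~39 nt inside the first, putting an
endopeptidase frame inside an amidase gene. Offsets are start-to-start
distances measured 5'->3' on the upstream gene's coding strand; the records
carry both spans so stop-to-start distances can be recomputed, since either
reading of "downstream of" may be wanted.
"""
from __future__ import annotations

from itertools import combinations
from typing import Iterable, Optional

import pandas as pd

from .model import GeneFeature, OverlapRecord, PhageGenome

FRAME_SENTINEL = -1  # frame offset is undefined for opposite-strand pairs


def _pair_record(genome_id: str, a: GeneFeature, b: GeneFeature) -> Optional[OverlapRecord]:
    ov = min(a.end, b.end) - max(a.start, b.start) + 1
    if ov < 1:
        return None
    same = a.strand == b.strand
    # upstream = first in transcription direction of the pair's coding strand
    if a.strand == "-" and same:
        up, down = (a, b) if a.end >= b.end else (b, a)
        offset = up.end - down.end
    else:
        up, down = (a, b) if a.start <= b.start else (b, a)
        offset = down.start - up.start
    return OverlapRecord(
        genome_id=genome_id,
        upstream_id=up.feature_id, downstream_id=down.feature_id,
        start_offset_nt=offset, overlap_len_nt=ov,
        frame_offset=offset % 3 if same else FRAME_SENTINEL,
        same_strand=same,
        upstream_span=(up.start, up.end), downstream_span=(down.start, down.end),
    )


def detect_overlaps(
    genome: PhageGenome,
    roles_filter: Optional[Iterable[str]] = ("endolysin",),
) -> list[OverlapRecord]:
    """One record per pair of features whose nucleotide spans intersect.

    ``roles_filter`` restricts to pairs where both members carry one of the
    given roles (default endolysin-endolysin, the overprinting case); pass
    ``None`` for all pairs.
    """
    feats = genome.features
    if roles_filter is not None:
        allowed = set(roles_filter)
        feats = [f for f in feats if f.role in allowed]
    records = []
    for a, b in combinations(feats, 2):
        rec = _pair_record(genome.accession, a, b)
        if rec is not None:
            records.append(rec)
    records.sort(key=lambda r: (r.upstream_span[0], r.downstream_span[0]))
    return records


def stop_to_start_nt(rec: OverlapRecord) -> int:
    """The alternative reading of "starting N nt downstream": distance from
    the upstream gene's stop to the downstream gene's start (negative inside)."""
    return rec.downstream_span[0] - rec.upstream_span[1]


def overlaps_table(records: Iterable[OverlapRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "genome_id": r.genome_id, "upstream_id": r.upstream_id,
            "downstream_id": r.downstream_id,
            "start_offset_nt": r.start_offset_nt,
            "overlap_len_nt": r.overlap_len_nt,
            "frame_offset": r.frame_offset, "same_strand": r.same_strand,
            "upstream_start": r.upstream_span[0], "upstream_end": r.upstream_span[1],
            "downstream_start": r.downstream_span[0],
            "downstream_end": r.downstream_span[1],
            "stop_to_start_nt": stop_to_start_nt(r),
        })
    return pd.DataFrame(rows, columns=[
        "genome_id", "upstream_id", "downstream_id", "start_offset_nt",
        "overlap_len_nt", "frame_offset", "same_strand", "upstream_start",
        "upstream_end", "downstream_start", "downstream_end", "stop_to_start_nt",
    ])
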