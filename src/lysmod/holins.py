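"""Holin characterization: hydropathy-based TMD calling, transporter-family
assignment from hit tables, and the tandem/family-consistency analyses.

The TMD caller is a transparent sliding-window hydropathy method
(Kyte-Doolittle scale, window 19, call threshold 1.6): maximal runs of the
smoothed profile at or above threshold become transmembrane segments after a
minimum-length filter and a merge of near-adjacent runs. Parameters are
config; externally computed TMD tables can override predictions. Family
assignment takes the best hit (lowest E-value, then highest bit score) under
the E < 0.01 cutoff and reads the family as the first three dot-fields of the
subject accession (class.subclass.family, e.g. 1.E.10).
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .model import HolinProfile

logger = logging.getLogger(__name__)

FAMILY_RE = re.compile(r"^\d+\.[A-Za-z]+\.\d+$")


@dataclass
class HydropathyParams:
    """Sliding-window TMD-calling parameters (Kyte-Doolittle defaults)."""

    scale: dict[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))
    window: int = 19
    threshold: float = 1.6
    min_tmd_len: int = 15
    min_gap: int = 5

    def __post_init__(self) -> None:
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 5")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def hydropathy_profile(
    protein: str, params: Optional[HydropathyParams] = None
) -> np.ndarray:
    """Centered moving average of per-residue hydropathy; same length as input.

    End windows are truncated; unknown residues score 0 with a warning; a
    protein shorter than the window collapses to its single global mean.
    """
    params = params or HydropathyParams()
    vals = np.empty(len(protein))
    unknown = set()
    for i, aa in enumerate(protein):
        v = params.scale.get(aa)
        if v is None:
            unknown.add(aa)
            v = 0.0
        vals[i] = v
    if unknown:
        logger.warning("unknown residue symbol(s) %s scored as 0", sorted(unknown))
    n = len(vals)
    if n == 0:
        return vals
    if n < params.window:
        return np.full(n, vals.mean())
    half = params.window // 2
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def predict_tmds(
    protein: str,
    params: Optional[HydropathyParams] = None,
    protein_id: str = "",
    genome_id: str = "",
) -> HolinProfile:
    """Call transmembrane segments from the smoothed hydropathy profile.

    Maximal runs >= threshold are candidates; runs shorter than
    ``min_tmd_len`` are discarded, then surviving runs separated by fewer than
    ``min_gap`` residues are merged. A protein with no called segment is
    flagged as a no-TMD holin candidate.
    """
    params = params or HydropathyParams()
    series = hydropathy_profile(protein, params)
    above = series >= params.threshold
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start + 1, i))  # 1-based inclusive
            start = None
    if start is not None:
        runs.append((start + 1, len(protein)))
    runs = [(a, b) for a, b in runs if b - a + 1 >= params.min_tmd_len]
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and a - merged[-1][1] - 1 < params.min_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    if not merged:
        logger.warning("%s: no-TMD holin candidate", protein_id or "<protein>")
    return HolinProfile(protein_id=protein_id, tmd_segments=merged,
                        genome_id=genome_id)


def assign_family(
    protein_id: str, tcdb_hits: pd.DataFrame, e_cutoff: float = 0.01
) -> str:
    """Transporter family of the best qualifying hit, or "unclassified".

    Expects columns qseqid, sseqid, evalue, bitscore. The family is the first
    three dot-fields of the subject accession; malformed subjects are skipped
    with a warning. Best hit = lowest E-value, ties to higher bit score, then
    lexicographically smallest subject.
    """
    if tcdb_hits is None or tcdb_hits.empty:
        return "unclassified"
    rows = tcdb_hits[(tcdb_hits["qseqid"] == protein_id)
                     & (tcdb_hits["evalue"] < e_cutoff)]
    candidates = []
    for _, row in rows.iterrows():
        fields = str(row["sseqid"]).split(".")
        family = ".".join(fields[:3])
        if not FAMILY_RE.match(family):
            logger.warning("%s: malformed subject accession %r skipped",
                           protein_id, row["sseqid"])
            continue
        candidates.append((float(row["evalue"]), -float(row["bitscore"]),
                           str(row["sseqid"]), family))
    if not candidates:
        return "unclassified"
    candidates.sort()
    return candidates[0][3]


def profile_holins(
    proteins: dict[str, tuple[str, str]],
    tcdb_hits: Optional[pd.DataFrame] = None,
    params: Optional[HydropathyParams] = None,
    tmd_overrides: Optional[pd.DataFrame] = None,
) -> list[HolinProfile]:
    """Predict TMDs and assign families for protein_id -> (genome_id, seq).

    ``tmd_overrides`` (protein_id, tmd_from, tmd_to rows) replaces the
    hydropathy prediction for the listed proteins, e.g. with externally
    computed deep-learning TMD calls.
    """
    profiles = []
    for pid in sorted(proteins):
        genome_id, seq = proteins[pid]
        if tmd_overrides is not None and pid in set(tmd_overrides["protein_id"]):
            rows = tmd_overrides[tmd_overrides["protein_id"] == pid]
            segs = sorted((int(r["tmd_from"]), int(r["tmd_to"]))
                          for _, r in rows.iterrows())
            prof = HolinProfile(protein_id=pid, tmd_segments=segs,
                                genome_id=genome_id)
        else:
            prof = predict_tmds(seq, params, protein_id=pid, genome_id=genome_id)
        prof.tcdb_family = assign_family(pid, tcdb_hits) if tcdb_hits is not None \
            else "unclassified"
        profiles.append(prof)
    return profiles


def tandem_and_consistency_report(profiles: Iterable[HolinProfile]) -> dict:
    """Two-holin family checks and per-family TMD-count conservation.

    (1) Every genome with two holins is checked for family inequality
    (pairs involving "unclassified" are indeterminate); (2) every family is
    checked for a single shared TMD count; (3) two-holin genomes where both
    holins carry a single TMD are listed. Violations are reported, never
    dropped.
    """
    profiles = list(profiles)
    by_genome: dict[str, list[HolinProfile]] = {}
    for p in profiles:
        by_genome.setdefault(p.genome_id, []).append(p)

    tandem_rows = []
    single_tmd_double = []
    for gid in sorted(by_genome):
        group = by_genome[gid]
        if len(group) != 2:
            continue
        a, b = group
        if "unclassified" in (a.tcdb_family, b.tcdb_family):
            status = "indeterminate"
        else:
            status = "pass" if a.tcdb_family != b.tcdb_family else "violation"
        tandem_rows.append({
            "genome_id": gid, "families": f"{a.tcdb_family},{b.tcdb_family}",
            "status": status,
        })
        if a.tmd_count == 1 and b.tmd_count == 1:
            single_tmd_double.append(gid)

    fam_rows = []
    by_family: dict[str, list[int]] = {}
    for p in profiles:
        if p.tcdb_family != "unclassified":
            by_family.setdefault(p.tcdb_family, []).append(p.tmd_count)
    for fam in sorted(by_family):
        counts = sorted(set(by_family[fam]))
        fam_rows.append({
            "family": fam, "tmd_counts": ",".join(map(str, counts)),
            "n_members": len(by_family[fam]),
            "status": "pass" if len(counts) == 1 else "violation",
        })

    return {
        "tandem": pd.DataFrame(tandem_rows,
                               columns=["genome_id", "families", "status"]),
        "family_consistency": pd.DataFrame(
            fam_rows, columns=["family", "tmd_counts", "n_members", "status"]),
        "single_tmd_double_holin_genomes": single_tmd_double,
    }


def holins_table(profiles: Iterable[HolinProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({
            "protein_id": p.protein_id, "genome_id": p.genome_id,
            "tmd_count": p.tmd_count,
            "tmd_segments": ";".join(f"{a}-{b}" for a, b in p.tmd_segments),
            "tcdb_family": p.tcdb_family,
        })
    return pd.DataFrame(rows, columns=["protein_id", "genome_id", "tmd_count",
                                       "tmd_segments", "tcdb_family"])
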