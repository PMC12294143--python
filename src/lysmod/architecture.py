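"""Endolysin domain-architecture typing and frequency ranking.

Domain hits (HMMER3 per-domain tables) are filtered at the standard E-value
cutoff (< 0.01), overlap-resolved, and assembled into canonical N->C
architectures. Architecture identity is the *ordered* domain-name sequence —
types are defined by EAD/CBD composition AND arrangement, so the same domain
set in a different order is a different type, and repeated domains are kept.
Labels (A1, A2, ...) are panel-relative frequency ranks; a label map can pin
them to a reference table for cross-run comparability.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SearchIO

from .config import default_domain_lexicon_dict, load_yaml
from .model import DomainHit, EndolysinArchitecture

logger = logging.getLogger(__name__)

NONE_CANONICAL = "(none)"

#: descriptive gene-length bounds (bp) for endolysins; a warning filter only
ENDOLYSIN_LEN_BOUNDS_BP = (228, 1386)


@dataclass
class DomainLexicon:
    """domain name -> (role, activity); editable config."""

    domains: dict[str, tuple[str, str]] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "DomainLexicon":
        return cls.from_dict(default_domain_lexicon_dict())

    @classmethod
    def from_yaml(cls, path=None) -> "DomainLexicon":
        return cls.from_dict(load_yaml(path, "domain_lexicon.yaml"))

    @classmethod
    def from_dict(cls, cfg: dict) -> "DomainLexicon":
        return cls(domains={
            name: (str(v["role"]), str(v.get("activity", "unknown")))
            for name, v in cfg["domains"].items()
        })

    def role(self, domain_name: str) -> str:
        return self.domains.get(domain_name, ("unknown", "unknown"))[0]

    def activity(self, domain_name: str) -> str:
        return self.domains.get(domain_name, ("unknown", "unknown"))[1]

    def annotate(self, hit: DomainHit) -> DomainHit:
        hit.role, hit.activity = self.domains.get(hit.domain_name,
                                                  ("unknown", "unknown"))
        return hit


def parse_domtblout(
    path, e_cutoff: float = 0.01, lexicon: Optional[DomainLexicon] = None
) -> list[DomainHit]:
    """Parse an HMMER3 per-domain table, keeping hits with i-Evalue < cutoff.

    Retained hits are annotated via the domain lexicon; unknown domain names
    are kept with role "unknown". Malformed rows are skipped with a counted
    warning; a file with rows but none parseable is an error.
    """
    lexicon = lexicon or DomainLexicon.default()
    hits: list[DomainHit] = []
    n_rows = 0
    n_bad = 0
    # quick pre-scan so malformed rows are counted (SearchIO aborts on them)
    with open(path) as fh:
        data_lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    good_lines = []
    for ln in data_lines:
        n_rows += 1
        parts = ln.split()
        try:
            float(parts[12])  # i-Evalue column
            int(parts[17]), int(parts[18])
            good_lines.append(ln)
        except (IndexError, ValueError):
            n_bad += 1
    if n_rows and not good_lines:
        raise ValueError(f"{path}: no parseable rows ({n_bad} malformed)")
    if n_bad:
        logger.warning("%s: skipped %d malformed row(s)", path, n_bad)

    import io

    stream = io.StringIO("".join(good_lines))
    for qres in SearchIO.parse(stream, "hmmsearch3-domtab"):
        for hit in qres:
            for hsp in hit:
                if hsp.evalue >= e_cutoff:
                    continue
                h = DomainHit(
                    protein_id=hit.id, domain_name=qres.id, source_db="hmmer",
                    ali_from=hsp.hit_start + 1, ali_to=hsp.hit_end,
                    e_value=hsp.evalue, bit_score=hsp.bitscore,
                )
                hits.append(lexicon.annotate(h))
    return hits


def hits_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    out: dict[str, list[DomainHit]] = {}
    for h in hits:
        out.setdefault(h.protein_id, []).append(h)
    return out


def resolve_overlaps(
    hits: list[DomainHit], max_overlap_frac: float = 0.5
) -> list[DomainHit]:
    """Keep one hit per protein region.

    When two hits overlap by more than ``max_overlap_frac`` of the shorter
    hit, the lower-E-value hit survives; ties break by higher bit score, then
    lexicographic domain name. All hits must be on one protein.
    """
    if len({h.protein_id for h in hits}) > 1:
        raise ValueError("resolve_overlaps expects hits on a single protein")
    ranked = sorted(hits, key=lambda h: (h.e_value, -h.bit_score, h.domain_name,
                                         h.ali_from))
    kept: list[DomainHit] = []
    for h in ranked:
        conflict = False
        for k in kept:
            ov = min(h.ali_to, k.ali_to) - max(h.ali_from, k.ali_from) + 1
            if ov <= 0:
                continue
            shorter = min(h.span_len, k.span_len)
            if ov > max_overlap_frac * shorter or (
                h.ali_from == k.ali_from and h.ali_to == k.ali_to
                and h.domain_name == k.domain_name
            ):
                conflict = True
                break
        if not conflict:
            kept.append(h)
    kept.sort(key=lambda h: (h.ali_from, h.ali_to, h.domain_name))
    return kept


def build_architecture(
    protein_id: str,
    hits: Iterable[DomainHit],
    lexicon: Optional[DomainLexicon] = None,
) -> EndolysinArchitecture:
    """Assemble the canonical N->C architecture from overlap-resolved hits.

    Domains are ordered strictly by alignment start; the canonical string
    joins domain names with " & "; an empty hit list yields "(none)" with
    both EAD/CBD flags false.
    """
    lexicon = lexicon or DomainLexicon.default()
    hits = list(hits)
    if any(h.protein_id != protein_id for h in hits):
        raise ValueError("hits from multiple proteins passed to build_architecture")
    ordered = sorted(hits, key=lambda h: (h.ali_from, h.ali_to, h.domain_name))
    doms = [(h.domain_name, lexicon.role(h.domain_name)) for h in ordered]
    return EndolysinArchitecture(
        protein_id=protein_id,
        ordered_domains=doms,
        canonical=" & ".join(d for d, _ in doms) if doms else NONE_CANONICAL,
        has_EAD=any(r == "EAD" for _, r in doms),
        has_CBD=any(r == "CBD" for _, r in doms),
    )


def augment_architecture(
    arch: EndolysinArchitecture,
    supplemental: pd.DataFrame,
    lexicon: Optional[DomainLexicon] = None,
    e_cutoff: float = 0.01,
) -> EndolysinArchitecture:
    """Fold supplemental evidence rows (CDD/BLASTp-style) into an architecture.

    Qualifying subjects known to the lexicon are appended in row order (the
    tables carry no coordinates); flags and canonical string are rebuilt.
    Returns the architecture, annotated with the activities gained.
    """
    lexicon = lexicon or DomainLexicon.default()
    rows = supplemental[supplemental["protein_id"] == arch.protein_id]
    added = False
    for _, row in rows.iterrows():
        if not row["evalue"] < e_cutoff:
            logger.warning("%s: supplemental row %s skipped (E=%g)",
                           arch.protein_id, row["subject"], row["evalue"])
            continue
        name = str(row["subject"])
        arch.ordered_domains.append((name, lexicon.role(name)))
        added = True
    if added:
        arch.canonical = " & ".join(d for d, _ in arch.ordered_domains)
        arch.has_EAD = any(r == "EAD" for _, r in arch.ordered_domains)
        arch.has_CBD = any(r == "CBD" for _, r in arch.ordered_domains)
    return arch


def architecture_activities(
    arch: EndolysinArchitecture, lexicon: Optional[DomainLexicon] = None
) -> list[str]:
    """Catalytic activities of the architecture's EADs, N->C, deduplicated."""
    lexicon = lexicon or DomainLexicon.default()
    acts: list[str] = []
    for name, role in arch.ordered_domains:
        if role == "EAD":
            a = lexicon.activity(name)
            if a not in acts:
                acts.append(a)
    return acts


def rank_architectures(
    panel: list[EndolysinArchitecture],
    label_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[EndolysinArchitecture], pd.DataFrame]:
    """Label architectures by decreasing frequency (A1 = most common).

    Count ties break lexicographically on the canonical string. ``label_map``
    (canonical -> label) pins labels to a reference table instead; canonicals
    absent from the map get fresh labels after the mapped ones.
    """
    counts = Counter(a.canonical for a in panel)
    ordered = sorted(counts, key=lambda c: (-counts[c], c))
    if label_map is None:
        labels = {c: f"A{i}" for i, c in enumerate(ordered, start=1)}
    else:
        labels = dict(label_map)
        next_i = len(labels) + 1
        for c in ordered:
            if c not in labels:
                labels[c] = f"A{next_i}"
                next_i += 1
    for a in panel:
        a.label = labels[a.canonical]
    table = pd.DataFrame(
        [{"label": labels[c], "canonical": c, "count": counts[c]} for c in ordered],
        columns=["label", "canonical", "count"],
    )
    return panel, table


def upset_table(
    panel: list[EndolysinArchitecture],
) -> tuple[pd.DataFrame, pd.Series]:
    """Architecture-combination matrix plus per-domain marginal frequencies.

    Rows are distinct architectures (label, canonical, count) with 0/1 domain
    presence indicator columns; the marginal vector counts, for each domain,
    the endolysins containing it at least once.
    """
    all_domains = sorted({d for a in panel for d in a.domain_names})
    counts = Counter(a.canonical for a in panel)
    reps: dict[str, EndolysinArchitecture] = {}
    for a in panel:
        reps.setdefault(a.canonical, a)
    rows = []
    for canon in sorted(counts, key=lambda c: (-counts[c], c)):
        a = reps[canon]
        row = {"label": a.label, "canonical": canon, "count": counts[canon]}
        present = set(a.domain_names)
        for d in all_domains:
            row[d] = int(d in present)
        rows.append(row)
    matrix = pd.DataFrame(rows, columns=["label", "canonical", "count"] + all_domains)
    marginal = pd.Series(
        {d: sum(1 for a in panel if d in a.domain_names) for d in all_domains},
        name="n_endolysins", dtype=int,
    )
    return matrix, marginal


def flag_and_cooccur(
    phages: Mapping[str, list[EndolysinArchitecture]],
) -> dict:
    """Flag EAD-less / CBD-less architectures and report co-encoding partners.

    For every EAD-less endolysin, lists the catalytically active architectures
    co-encoded in the same genome; EAD-less endolysins with no active partner
    are reported as exceptions needing supplemental evidence (the lone
    CBD-only endolysin case).
    """
    no_ead_rows, no_cbd_rows, exceptions = [], [], []
    for genome_id, archs in phages.items():
        active = [a for a in archs if a.has_EAD]
        for a in archs:
            if not a.has_CBD:
                no_cbd_rows.append({"genome_id": genome_id,
                                    "protein_id": a.protein_id,
                                    "label": a.label, "canonical": a.canonical})
            if not a.has_EAD:
                partners = sorted({p.label or p.canonical for p in active})
                row = {"genome_id": genome_id, "protein_id": a.protein_id,
                       "label": a.label, "canonical": a.canonical,
                       "partners": ",".join(partners)}
                no_ead_rows.append(row)
                if not partners:
                    exceptions.append(row)
    return {
        "no_EAD": pd.DataFrame(no_ead_rows, columns=["genome_id", "protein_id",
                                                     "label", "canonical", "partners"]),
        "no_CBD": pd.DataFrame(no_cbd_rows, columns=["genome_id", "protein_id",
                                                     "label", "canonical"]),
        "exceptions": pd.DataFrame(exceptions, columns=["genome_id", "protein_id",
                                                        "label", "canonical", "partners"]),
    }


def check_endolysin_length(gene_len_nt: int, protein_id: str = "") -> bool:
    """Warn (never reject) when an endolysin gene falls outside 228-1386 bp."""
    lo, hi = ENDOLYSIN_LEN_BOUNDS_BP
    ok = lo <= gene_len_nt <= hi
    if not ok:
        logger.warning("endolysin gene %s length %d bp outside %d-%d bp",
                       protein_id, gene_len_nt, lo, hi)
    return ok
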