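"""Delineate lysis modules and classify their organization (A-E catalogue).

A lysis module is a run of holin/endolysin genes merged across at most
``max_intercalated`` non-lysis ORFs and at most ``max_gap_nt`` of intergenic
distance per junction. Organization labels come from an ordered catalogue of
signature patterns over {H, E} with optional endonuclease positions; A-C are
holin-first, D-E endolysin-first.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .config import default_catalogue_dict, load_yaml
from .model import GeneFeature, LysisModule, PhageGenome

ANCHOR_SYMBOLS = ("H", "E")  # roles that can open/close a module


@dataclass
class CatalogueEntry:
    label: str
    tokens: list[str]  # "H", "E", "N", or "[N]" for an optional endonuclease

    def regex(self) -> str:
        out = []
        for t in self.tokens:
            if t.startswith("["):
                out.append(f"{t[1]}?")
            else:
                out.append(t)
        return "".join(out)

    @property
    def holin_first(self) -> bool:
        for t in self.tokens:
            sym = t.strip("[]")
            if sym in ANCHOR_SYMBOLS:
                return sym == "H"
        return False


@dataclass
class OrganizationCatalogue:
    """Ordered label -> pattern catalogue; first match wins."""

    entries: list[CatalogueEntry]
    max_per_role: int = 2

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise ValueError("catalogue labels must be unique")

    @classmethod
    def default(cls) -> "OrganizationCatalogue":
        return cls.from_dict(default_catalogue_dict())

    @classmethod
    def from_yaml(cls, path=None) -> "OrganizationCatalogue":
        return cls.from_dict(load_yaml(path, "catalogue.yaml"))

    @classmethod
    def from_dict(cls, cfg: dict) -> "OrganizationCatalogue":
        entries = [CatalogueEntry(label=e["label"], tokens=str(e["pattern"]).split())
                   for e in cfg["catalogue"]]
        return cls(entries=entries, max_per_role=int(cfg.get("max_per_role", 2)))

    def match(self, signature: str) -> Optional[str]:
        """First catalogue label whose pattern matches the X-stripped signature."""
        projected = signature.replace("X", "")
        for entry in self.entries:
            if re.fullmatch(entry.regex(), projected):
                return entry.label
        return None

    def holin_first_labels(self) -> set[str]:
        return {e.label for e in self.entries if e.holin_first}


@dataclass
class DelineationDiagnostic:
    """Why a genome's lysis genes did not coalesce into one module."""

    genome_id: str
    reason: str
    intervening_count: int = 0
    gap_nt: int = 0


@dataclass
class DelineationResult:
    modules: list[LysisModule] = field(default_factory=list)
    diagnostics: list[DelineationDiagnostic] = field(default_factory=list)

    def __iter__(self):
        return iter(self.modules)

    def __len__(self) -> int:
        return len(self.modules)


def _module_direction(members: list[GeneFeature]) -> str:
    strands = {m.strand for m in members}
    if strands == {"+"}:
        return "forward"
    if strands == {"-"}:
        return "reverse"
    fwd = sum(1 for m in members if m.strand == "+")
    if fwd * 2 == len(members):
        return "mixed"
    return "forward" if fwd * 2 > len(members) else "reverse"


def _build_module(genome: PhageGenome, members: list[GeneFeature]) -> LysisModule:
    # trim non-lysis flanks: a module never starts or ends with an intercalated gene
    while members and members[0].role_symbol not in ANCHOR_SYMBOLS:
        members = members[1:]
    while members and members[-1].role_symbol not in ANCHOR_SYMBOLS:
        members = members[:-1]
    direction = _module_direction(members)
    ordered = list(reversed(members)) if direction == "reverse" else list(members)
    sig = "".join(m.role_symbol for m in ordered)
    return LysisModule(
        genome_id=genome.accession, members=ordered, role_signature=sig,
        intercalated_count=sum(1 for s in sig if s in "NX"),
        direction=direction,
    )


def delineate_modules(
    genome: PhageGenome,
    max_intercalated: int = 2,
    max_gap_nt: int = 1000,
) -> DelineationResult:
    """Group lysis-role genes into modules under the contiguity tolerance.

    Scans features in genomic order, merging successive holin/endolysin genes
    separated by at most ``max_intercalated`` non-lysis ORFs and at most
    ``max_gap_nt`` of intergenic distance per junction. A genome whose holin
    and endolysin genes exceed the tolerance yields zero modules plus a
    diagnostic carrying the intervening ORF count (the dispersed-cassette
    case). Requires roles to be assigned; each emitted module contains at
    least one H and one E.
    """
    anchors = [f for f in genome.features if f.role_symbol in ANCHOR_SYMBOLS]
    if not anchors:
        return DelineationResult()
    feats = genome.features
    index = {f.feature_id: i for i, f in enumerate(feats)}

    runs: list[list[GeneFeature]] = []
    current: list[GeneFeature] = [anchors[0]]
    broken: list[DelineationDiagnostic] = []
    for prev, nxt in zip(anchors, anchors[1:]):
        i, j = index[prev.feature_id], index[nxt.feature_id]
        intervening = j - i - 1
        gap = max(0, nxt.start - prev.end - 1)
        if intervening <= max_intercalated and gap <= max_gap_nt:
            current.extend(feats[i + 1 : j + 1])
        else:
            reason = ("intervening ORFs exceed tolerance"
                      if intervening > max_intercalated else "intergenic gap too large")
            broken.append(DelineationDiagnostic(
                genome_id=genome.accession, reason=reason,
                intervening_count=intervening, gap_nt=gap,
            ))
            runs.append(current)
            current = [nxt]
    runs.append(current)

    result = DelineationResult()
    for run in runs:
        symbols = {m.role_symbol for m in run}
        if "H" in symbols and "E" in symbols:
            result.modules.append(_build_module(genome, run))
    if not result.modules:
        result.diagnostics.extend(broken)
    return result


def classify_organization(
    module: LysisModule, catalogue: Optional[OrganizationCatalogue] = None
) -> LysisModule:
    """Fill ``organization_label`` from the catalogue (first match wins).

    Matching strips X (other/hypothetical) symbols from the signature and
    retains N, so patterns carrying an optional endonuclease position can
    claim endonuclease-intercalated modules; signatures matching no pattern
    are labeled "unclassified".
    """
    catalogue = catalogue or OrganizationCatalogue.default()
    sig = module.role_signature
    if (sig.count("H") > catalogue.max_per_role
            or sig.count("E") > catalogue.max_per_role):
        module.organization_label = "unclassified"
        return module
    module.organization_label = catalogue.match(sig) or "unclassified"
    return module


def order_statistics(panel: Iterable[LysisModule]) -> dict:
    """Holin-first / endolysin-first fractions and the label histogram."""
    mods = list(panel)
    if not mods:
        return {"n_modules": 0, "holin_first_fraction": 0.0,
                "endolysin_first_fraction": 0.0, "label_histogram": {}}
    n = len(mods)
    hf = sum(1 for m in mods if m.holin_first)
    hist: dict[str, int] = {}
    for m in mods:
        hist[m.organization_label] = hist.get(m.organization_label, 0) + 1
    return {
        "n_modules": n,
        "holin_first_fraction": hf / n,
        "endolysin_first_fraction": (n - hf) / n,
        "label_histogram": dict(sorted(hist.items())),
    }


def modules_table(modules: Iterable[LysisModule]) -> pd.DataFrame:
    rows = []
    for m in modules:
        rows.append({
            "genome_id": m.genome_id,
            "organization": m.organization_label,
            "signature": m.role_signature,
            "intercalated": m.intercalated_count,
            "direction": m.direction,
            "holin_first": m.holin_first,
            "members": ",".join(f.feature_id for f in m.members),
        })
    return pd.DataFrame(rows, columns=["genome_id", "organization", "signature",
                                       "intercalated", "direction", "holin_first",
                                       "members"])
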