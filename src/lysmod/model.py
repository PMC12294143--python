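"""Core data model for phage lysis-module analysis.

Coordinates are 1-based inclusive throughout (GenBank convention); any
half-open arithmetic is confined to private helpers in other modules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

ROLES = ("holin", "endolysin", "endonuclease", "hypothetical", "other", "unassigned")

#: one-letter role symbols used in module signatures
ROLE_SYMBOLS = {
    "holin": "H",
    "endolysin": "E",
    "endonuclease": "N",
}


@dataclass
class TaxonomyRecord:
    """ICTV-style rank assignments; any rank may be the sentinel "unassigned"."""

    v_class: str = "unassigned"
    family: str = "unassigned"
    subfamily: str = "unassigned"
    genus: str = "unassigned"
    species: str = "unassigned"


@dataclass
class GeneFeature:
    """One annotated ORF (CDS) on a phage genome.

    ``start``/``end`` are 1-based inclusive genomic coordinates in ascending
    order regardless of strand; ``strand`` is "+" or "-".
    """

    feature_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    protein_seq: Optional[str] = None
    role: str = "unassigned"
    role_evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature {self.feature_id}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: strand must be '+' or '-'")
        if self.role not in ROLES:
            raise ValueError(f"feature {self.feature_id}: unknown role {self.role!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def role_symbol(self) -> str:
        """Signature symbol: H/E/N for lysis roles, X for anything else."""
        return ROLE_SYMBOLS.get(self.role, "X")


@dataclass
class PhageGenome:
    """A single annotated phage genome with its CDS features sorted by start."""

    accession: str
    name: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    taxonomy: Optional[TaxonomyRecord] = None
    host_species: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError(f"{self.accession}: duplicate feature identifiers")
        for f in self.features:
            if f.end > self.length_nt:
                raise ValueError(
                    f"{self.accession}: feature {f.feature_id} exceeds genome length"
                )

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    def feature_by_id(self, feature_id: str) -> GeneFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)


@dataclass
class LysisModule:
    """An ordered run of features forming a lysis cassette.

    ``members`` are stored in transcription-direction order (reversed genomic
    order for reverse-strand modules); ``role_signature`` is the member-wise
    symbol string over {H, E, N, X}.
    """

    genome_id: str
    members: list[GeneFeature]
    role_signature: str
    organization_label: str = "unclassified"
    intercalated_count: int = 0
    direction: str = "forward"  # forward | reverse | mixed

    def __post_init__(self) -> None:
        if len(self.role_signature) != len(self.members):
            raise ValueError("signature length must equal member count")

    def role_count(self, symbol: str) -> int:
        return self.role_signature.count(symbol)

    @property
    def holin_first(self) -> bool:
        """True when the first lysis-role member (H or E) is a holin."""
        for s in self.role_signature:
            if s in "HE":
                return s == "H"
        return False


@dataclass
class DomainHit:
    """A filtered domain match on an endolysin protein (1-based aa coords)."""

    protein_id: str
    domain_name: str
    source_db: str
    ali_from: int
    ali_to: int
    e_value: float
    bit_score: float
    role: str = "unknown"  # EAD | CBD | unknown
    activity: str = "unknown"

    def __post_init__(self) -> None:
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValueError(
                f"hit {self.domain_name}@{self.protein_id}: bad alignment span"
            )
        if self.e_value <= 0:
            raise ValueError("E-value must be positive")

    @property
    def span_len(self) -> int:
        return self.ali_to - self.ali_from + 1


@dataclass
class EndolysinArchitecture:
    """Canonical N->C domain architecture of one endolysin."""

    protein_id: str
    ordered_domains: list[tuple[str, str]]  # (domain_name, role)
    canonical: str
    has_EAD: bool
    has_CBD: bool
    label: str = ""  # panel-relative frequency rank, e.g. "A1"

    @property
    def domain_names(self) -> list[str]:
        return [d for d, _ in self.ordered_domains]


@dataclass
class OverlapRecord:
    """A pair of genes whose nucleotide spans intersect.

    ``start_offset_nt`` is start(downstream) - start(upstream) measured 5'->3'
    on the upstream gene's coding strand; ``frame_offset`` is that offset mod 3
    for same-strand pairs and the sentinel -1 otherwise. Upstream/downstream
    spans are carried so stop-to-start distances can be recomputed.
    """

    genome_id: str
    upstream_id: str
    downstream_id: str
    start_offset_nt: int
    overlap_len_nt: int
    frame_offset: int
    same_strand: bool
    upstream_span: tuple[int, int] = (0, 0)
    downstream_span: tuple[int, int] = (0, 0)


@dataclass
class HolinProfile:
    """Predicted transmembrane segments and transporter-family assignment."""

    protein_id: str
    tmd_segments: list[tuple[int, int]]
    tcdb_family: str = "unclassified"
    genome_id: str = ""

    @property
    def tmd_count(self) -> int:
        return len(self.tmd_segments)
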