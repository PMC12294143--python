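"""Assign lysis roles (holin, endolysin, endonuclease) to annotated ORFs.

The primary signal is the curated product annotation, matched against a
keyword lexicon as whole case-insensitive tokens; domain evidence (filtered
HMMER-style hits) rescues unannotated proteins, and a supplemental-evidence
table (tabular BLASTp/CDD-style rows) covers domains the primary search
misses. Keyword beats domain evidence on conflict by default — annotation is
the curated signal and databases the cross-check — with ``evidence_first``
flipping that precedence.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .config import default_domain_lexicon_dict, default_role_lexicon_dict, load_yaml
from .model import DomainHit, GeneFeature, PhageGenome

logger = logging.getLogger(__name__)

LYSIS_ROLES = ("holin", "endolysin", "endonuclease")


@dataclass
class RoleLexicon:
    """Keyword -> role and domain-name -> role mappings (editable config)."""

    keywords: dict[str, str] = field(default_factory=dict)
    domain_roles: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "RoleLexicon":
        return cls.from_dicts(default_role_lexicon_dict(),
                              default_domain_lexicon_dict())

    @classmethod
    def from_dicts(cls, role_cfg: dict, domain_cfg: Optional[dict] = None) -> "RoleLexicon":
        keywords = {k.lower(): v for k, v in role_cfg.get("keywords", {}).items()}
        domain_roles: dict[str, str] = {}
        if domain_cfg:
            # every EAD/CBD lexicon domain implies endolysin
            for name in domain_cfg.get("domains", {}):
                domain_roles[name] = "endolysin"
        for name in role_cfg.get("holin_domains", []):
            domain_roles[name] = "holin"
        return cls(keywords=keywords, domain_roles=domain_roles)

    @classmethod
    def from_yaml(cls, role_path=None, domain_path=None) -> "RoleLexicon":
        return cls.from_dicts(
            load_yaml(role_path, "role_lexicon.yaml"),
            load_yaml(domain_path, "domain_lexicon.yaml"),
        )

    def keyword_role(self, product: str) -> Optional[str]:
        """Whole-token, case-insensitive keyword lookup over the product text.

        Lysis-role keywords take priority over the "hypothetical" fallback,
        which is handled separately by the classifier.
        """
        tokens = set(re.findall(r"[A-Za-z0-9_]+", product.lower()))
        hits = [self.keywords[t] for t in sorted(tokens) if t in self.keywords]
        for role in LYSIS_ROLES:  # fixed precedence keeps this deterministic
            if role in hits:
                return role
        if "hypothetical" in hits:
            return "hypothetical"
        return None

    def domain_role(self, hits: Iterable[DomainHit]) -> Optional[str]:
        roles = {self.domain_roles[h.domain_name]
                 for h in hits if h.domain_name in self.domain_roles}
        for role in LYSIS_ROLES:
            if role in roles:
                return role
        return None


def classify_gene_role(
    feature: GeneFeature,
    hits: Iterable[DomainHit] = (),
    lexicon: Optional[RoleLexicon] = None,
    supplemental: Optional[pd.DataFrame] = None,
    evidence_first: bool = False,
    e_cutoff: float = 0.01,
) -> GeneFeature:
    """Assign a lysis role to ``feature`` in place and return it.

    Precedence: (1) product keyword, (2) domain evidence, (3) supplemental
    evidence rows; a "hypothetical" product is a fallback only, never blocking
    evidence-based rescue. Keyword/domain conflicts resolve to the keyword
    role with a logged warning (``evidence_first=True`` flips this).
    """
    lexicon = lexicon or RoleLexicon.default()
    hits = list(hits)
    kw = lexicon.keyword_role(feature.product)
    kw_lysis = kw if kw in LYSIS_ROLES else None
    dom = lexicon.domain_role(hits)
    sup = None
    if supplemental is not None and not supplemental.empty:
        rows = supplemental[
            (supplemental["protein_id"] == feature.feature_id)
            & (supplemental["evalue"] < e_cutoff)
        ]
        sup_roles = {lexicon.domain_roles[s] for s in rows["subject"]
                     if s in lexicon.domain_roles}
        for role in LYSIS_ROLES:
            if role in sup_roles:
                sup = role
                break

    if kw_lysis and dom and kw_lysis != dom:
        logger.warning(
            "%s: keyword role %r conflicts with domain role %r; keeping %s",
            feature.feature_id, kw_lysis, dom,
            dom if evidence_first else kw_lysis,
        )
    ordered = ([(dom, "domain"), (kw_lysis, "keyword"), (sup, "supplemental")]
               if evidence_first
               else [(kw_lysis, "keyword"), (dom, "domain"), (sup, "supplemental")])
    for role, tag in ordered:
        if role:
            feature.role = role
            feature.role_evidence = [tag]
            return feature
    if kw == "hypothetical":
        feature.role = "hypothetical"
        feature.role_evidence = ["keyword"]
    else:
        feature.role = "other"
        feature.role_evidence = []
    return feature


def annotate_genome(
    genome: PhageGenome,
    hits_by_protein: Optional[dict[str, list[DomainHit]]] = None,
    lexicon: Optional[RoleLexicon] = None,
    supplemental: Optional[pd.DataFrame] = None,
    evidence_first: bool = False,
) -> PhageGenome:
    """Classify every feature of a genome (roles filled in place)."""
    lexicon = lexicon or RoleLexicon.default()
    hits_by_protein = hits_by_protein or {}
    for f in genome.features:
        classify_gene_role(f, hits_by_protein.get(f.feature_id, ()),
                           lexicon=lexicon, supplemental=supplemental,
                           evidence_first=evidence_first)
    return genome


def read_supplemental_table(path) -> pd.DataFrame:
    """Read a supplemental-evidence TSV (protein_id, subject, evalue, identity_pct)."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "subject", "evalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if "identity_pct" not in df.columns:
        df["identity_pct"] = float("nan")
    return df


def apply_supplemental_evidence(
    feature: GeneFeature,
    table: pd.DataFrame,
    lexicon: Optional[RoleLexicon] = None,
    e_cutoff: float = 0.01,
) -> GeneFeature:
    """Fold supplemental hit rows into a feature's role evidence.

    Rows referencing other proteins are ignored; rows at or above the E-value
    cutoff are skipped. Subjects known to the lexicon can upgrade an
    unresolved feature to the corresponding lysis role; all qualifying
    subjects are appended to the evidence tags (the dispersed-annotation
    rescue path for endolysins whose domains only show up in CDD/BLASTp-style
    searches).
    """
    lexicon = lexicon or RoleLexicon.default()
    if table is None or table.empty:
        return feature
    rows = table[table["protein_id"] == feature.feature_id]
    for _, row in rows.iterrows():
        if not row["evalue"] < e_cutoff:
            logger.warning(
                "%s: supplemental row %s skipped (E=%g >= %g)",
                feature.feature_id, row["subject"], row["evalue"], e_cutoff,
            )
            continue
        feature.role_evidence.append(f"supplemental:{row['subject']}")
        role = lexicon.domain_roles.get(row["subject"])
        if role and feature.role not in LYSIS_ROLES:
            feature.role = role
    return feature
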