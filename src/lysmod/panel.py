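"""Representative-panel selection from a taxonomy table.

One representative per named genus (highest priority score, ties to the
lexicographically smallest accession); every genus-unassigned phage is
systematically included. The selection criteria behind the priority score
(citation frequency, lysis-module complexity) are judgment calls that cannot
be computed from genomes alone, so they are injected as an optional mapping
and default to uniform.
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import TaxonomyRecord

UNASSIGNED = "unassigned"


def select_representatives(
    records: Sequence[tuple[str, TaxonomyRecord]],
    priority: Optional[Mapping[str, float]] = None,
) -> list[str]:
    """Accessions of the representative panel, sorted.

    Exactly one accession per named genus; all genus-unassigned accessions
    included. Duplicate accessions are rejected.
    """
    if not records:
        raise ValueError("records must be nonempty")
    accs = [a for a, _ in records]
    if len(set(accs)) != len(accs):
        raise ValueError("duplicate accessions in input")
    priority = priority or {}
    selected: list[str] = []
    by_genus: dict[str, list[str]] = {}
    for acc, tax in records:
        genus = (tax.genus or UNASSIGNED) if tax else UNASSIGNED
        if genus == UNASSIGNED:
            selected.append(acc)
        else:
            by_genus.setdefault(genus, []).append(acc)
    for genus in sorted(by_genus):
        # highest priority wins; ties -> lexicographically smallest accession
        best = min(by_genus[genus], key=lambda a: (-priority.get(a, 0.0), a))
        selected.append(best)
    return sorted(selected)


def read_taxonomy_tsv(path) -> list[tuple[str, TaxonomyRecord]]:
    """Read (accession, TaxonomyRecord) rows from a TSV.

    Expects an ``accession`` column; rank columns (v_class, family, subfamily,
    genus, species) default to "unassigned" when absent or empty.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(UNASSIGNED)
    if "accession" not in df.columns:
        raise ValueError(f"{path}: missing 'accession' column")
    out = []
    for _, row in df.iterrows():
        out.append((row["accession"], TaxonomyRecord(
            v_class=row.get("v_class", UNASSIGNED),
            family=row.get("family", UNASSIGNED),
            subfamily=row.get("subfamily", UNASSIGNED),
            genus=row.get("genus", UNASSIGNED),
            species=row.get("species", UNASSIGNED),
        )))
    return out
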