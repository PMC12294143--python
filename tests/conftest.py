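import textwrap

import pytest

from lysmod.architecture import hits_by_protein, parse_domtblout
from lysmod.modules import classify_organization, delineate_modules
from lysmod.roles import RoleLexicon, annotate_genome
from lysmod.simulate import PanelSpec, generate_panel


def make_genbank_text(accession: str, length: int, cds_specs, sequence=None) -> str:
    """Hand-rolled minimal GenBank flat-file text (independent of Biopython's
    writer) for parser tests. ``cds_specs`` = (start, end, strand, product)."""
    if sequence is None:
        sequence = ("ACGT" * (length // 4 + 1))[:length]
    lines = [
        f"LOCUS       {accession:<16} {length} bp    DNA     linear   PHG 01-JAN-2025",
        "DEFINITION  toy phage genome.",
        f"ACCESSION   {accession}",
        f"VERSION     {accession}.1",
        "FEATURES             Location/Qualifiers",
        f"     source          1..{length}",
    ]
    for i, (start, end, strand, product) in enumerate(cds_specs, 1):
        loc = f"{start}..{end}" if strand == "+" else f"complement({start}..{end})"
        lines.append(f"     CDS             {loc}")
        lines.append(f'                     /locus_tag="g{i}"')
        lines.append(f'                     /product="{product}"')
    lines.append("ORIGIN")
    for off in range(0, length, 60):
        chunk = sequence[off : off + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{off + 1:>9} {blocks.lower()}")
    lines.append("//")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def five_org_panel(tmp_path_factory):
    """Zero-noise panel with one genome per organization, fully annotated."""
    spec = PanelSpec(seed=42)
    genomes, evidence, truth = generate_panel(spec)
    d = tmp_path_factory.mktemp("panel")
    evidence.write(d / "hits.domtblout", d / "tcdb_hits.tsv")
    hits = parse_domtblout(d / "hits.domtblout")
    by_protein = hits_by_protein(hits)
    lexicon = RoleLexicon.default()
    for g in genomes:
        annotate_genome(g, by_protein, lexicon=lexicon)
    modules = []
    for g in genomes:
        res = delineate_modules(g)
        modules.extend(classify_organization(m) for m in res.modules)
    return {
        "spec": spec, "genomes": genomes, "evidence": evidence, "truth": truth,
        "hits_by_protein": by_protein, "modules": modules, "dir": d,
    }
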