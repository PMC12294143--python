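"""Reading annotated phage genomes (GenBank, GFF3+FASTA) and writing outputs.

All coordinates exposed by this module are 1-based inclusive; conversion from
Biopython/gffutils conventions happens here and nowhere else. On-the-fly
translation uses the bacterial/phage code (translation table 11).
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import GeneFeature, LysisModule, PhageGenome

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

TRANSLATION_TABLE = 11


def _translate_span(sequence: str, start: int, end: int, strand: str) -> Optional[str]:
    """Translate the 1-based inclusive span; None when not a codon multiple."""
    if (end - start + 1) % 3 != 0:
        return None
    nt = Seq(sequence[start - 1 : end])
    if strand == "-":
        nt = nt.reverse_complement()
    aa = str(nt.translate(table=TRANSLATION_TABLE))
    return aa[:-1] if aa.endswith("*") else aa


def read_genbank(path: PathLike) -> PhageGenome:
    """Read a single-record GenBank flat file into a :class:`PhageGenome`.

    CDS qualifiers ``product`` and ``translation`` populate the feature's
    product and protein sequence; a CDS lacking a translation is translated
    from its span when possible, otherwise kept with ``protein_seq=None``.
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise ValueError(
            f"{path}: expected a single-record GenBank file, found {len(records)} records"
        )
    rec = records[0]
    features: list[GeneFeature] = []
    n = 0
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        n += 1
        start = int(feat.location.start) + 1  # Biopython is 0-based half-open
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        product = feat.qualifiers.get("product", [""])[0]
        fid = feat.qualifiers.get("locus_tag", feat.qualifiers.get("protein_id", [f"cds_{n}"]))[0]
        protein = feat.qualifiers.get("translation", [None])[0]
        if protein is None:
            protein = _translate_span(str(rec.seq), start, end, strand)
            if protein is None:
                logger.warning(
                    "%s: CDS %s has no translation and a non-codon span; kept without protein",
                    path, fid,
                )
        features.append(
            GeneFeature(feature_id=fid, start=start, end=end, strand=strand,
                        product=product, protein_seq=protein)
        )
    return PhageGenome(
        accession=rec.id, name=rec.description or rec.id, sequence=str(rec.seq),
        features=features,
    )


def read_gff3(gff_path: PathLike, fasta_path: PathLike) -> PhageGenome:
    """Read a GFF3 + FASTA pair into the same data model as :func:`read_genbank`.

    The ``product=`` attribute (fallback ``Name=``) supplies the product string;
    missing attributes yield an empty product. A sequence-ID mismatch between
    the GFF3 and the FASTA is rejected.
    """
    fasta_records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(fasta_records) != 1:
        raise ValueError(f"{fasta_path}: expected a single FASTA record")
    rec = fasta_records[0]
    try:
        db = gffutils.create_db(
            str(gff_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return PhageGenome(accession=rec.id, name=rec.description or rec.id,
                           sequence=str(rec.seq), features=[])
    features: list[GeneFeature] = []
    n = 0
    for f in db.features_of_type("CDS", order_by="start"):
        if f.seqid != rec.id:
            raise ValueError(
                f"{gff_path}: sequence ID {f.seqid!r} does not match FASTA record {rec.id!r}"
            )
        n += 1
        product = f.attributes.get("product", f.attributes.get("Name", [""]))[0]
        fid = f.attributes.get("ID", [f"cds_{n}"])[0]
        strand = f.strand if f.strand in ("+", "-") else "+"
        protein = _translate_span(str(rec.seq), f.start, f.end, strand)
        features.append(
            GeneFeature(feature_id=fid, start=f.start, end=f.end, strand=strand,
                        product=product, protein_seq=protein)
        )
    return PhageGenome(
        accession=rec.id, name=rec.description or rec.id, sequence=str(rec.seq),
        features=features,
    )


def write_genbank(genome: PhageGenome, path: PathLike) -> None:
    """Write a genome back to a GenBank flat file (CDS features only)."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.accession, name=genome.accession[:16],
                    description=genome.name)
    rec.annotations["molecule_type"] = "DNA"
    for f in genome.features:
        loc = FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "-" else 1)
        quals = {"locus_tag": [f.feature_id], "product": [f.product],
                 "transl_table": [str(TRANSLATION_TABLE)]}
        if f.protein_seq:
            quals["translation"] = [f.protein_seq]
        rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def write_gff3(genome: PhageGenome, gff_path: PathLike, fasta_path: PathLike) -> None:
    """Write a genome as a GFF3 + FASTA pair (inverse of :func:`read_gff3`)."""
    with open(fasta_path, "w") as fh:
        SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.accession,
                               description=genome.name)], fh, "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.accession} 1 {genome.length_nt}\n")
        for f in genome.features:
            attrs = f"ID={f.feature_id};product={f.product}"
            fh.write(
                f"{genome.accession}\tlysmod\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t{attrs}\n"
            )


def _module_span(module: LysisModule) -> tuple[int, int]:
    return (min(m.start for m in module.members), max(m.end for m in module.members))


def write_modules_gff(
    genomes: Iterable[PhageGenome],
    modules: Iterable[LysisModule],
    out_gff: PathLike,
    out_tsv: Optional[PathLike] = None,
) -> None:
    """Write delineated lysis modules as GFF3 region rows with CDS children.

    Each module becomes one ``region`` row carrying its organization label,
    role signature and intercalated count, followed by one child row per
    member gene. A flat TSV twin is written alongside when ``out_tsv`` is set.
    """
    genomes = list(genomes)
    modules = list(modules)
    by_id = {g.accession: g for g in genomes}
    for mod in modules:
        g = by_id.get(mod.genome_id)
        if g is None:
            raise ValueError(f"module references unknown genome {mod.genome_id!r}")
        known = {f.feature_id for f in g.features}
        for m in mod.members:
            if m.feature_id not in known:
                raise ValueError(
                    f"module in {mod.genome_id} references unknown feature {m.feature_id!r}"
                )
    rows = []
    with open(out_gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, mod in enumerate(modules, start=1):
            span = _module_span(mod)
            mid = f"module_{i}"
            strand = {"forward": "+", "reverse": "-", "mixed": "."}[mod.direction]
            attrs = (
                f"ID={mid};organization={mod.organization_label};"
                f"signature={mod.role_signature};intercalated={mod.intercalated_count}"
            )
            fh.write(
                f"{mod.genome_id}\tlysmod\tregion\t{span[0]}\t{span[1]}\t.\t{strand}\t.\t{attrs}\n"
            )
            for m in mod.members:
                fh.write(
                    f"{mod.genome_id}\tlysmod\tCDS\t{m.start}\t{m.end}\t.\t{m.strand}\t0\t"
                    f"ID={m.feature_id};Parent={mid};role={m.role};product={m.product}\n"
                )
                rows.append({
                    "genome_id": mod.genome_id, "module_id": mid,
                    "organization": mod.organization_label,
                    "signature": mod.role_signature,
                    "intercalated": mod.intercalated_count,
                    "feature_id": m.feature_id, "start": m.start, "end": m.end,
                    "strand": m.strand, "role": m.role, "product": m.product,
                })
    if out_tsv is not None:
        cols = ["genome_id", "module_id", "organization", "signature", "intercalated",
                "feature_id", "start", "end", "strand", "role", "product"]
        pd.DataFrame(rows, columns=cols).to_csv(out_tsv, sep="\t", index=False)


def read_modules_gff(path: PathLike) -> list[dict]:
    """Read a modules GFF3 back into plain dicts (round-trip checking).

    Returns one dict per module with genome_id, organization, signature,
    intercalated count and the ordered member feature IDs.
    """
    mods: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = (
                line.rstrip("\n").split("\t")
            )
            kv = dict(a.split("=", 1) for a in attrs.split(";") if "=" in a)
            if ftype == "region":
                mid = kv["ID"]
                order.append(mid)
                mods[mid] = {
                    "genome_id": seqid,
                    "organization": kv.get("organization", "unclassified"),
                    "signature": kv.get("signature", ""),
                    "intercalated": int(kv.get("intercalated", 0)),
                    "members": [],
                }
            elif ftype == "CDS" and kv.get("Parent") in mods:
                mods[kv["Parent"]]["members"].append(kv["ID"])
    return [mods[m] for m in order]
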