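"""Synthetic phage-genome panels with planted ground truth.

Generates multi-ORF genomes carrying one lysis cassette each (organizations
A-E), endolysins with planted N->C domain layouts plus a matching HMMER-style
domain-hit table, holin proteins with 1-3 planted hydrophobic helices plus a
transporter-family hit table, overlapping ORF pairs at stated nucleotide
offsets, and decoy ORFs drawn from a phage-structural lexicon — so the entire
downstream analysis is testable with no external data.

Design notes
------------
* Nucleotide sequence under planted proteins is back-translated with uniform
  codon choice (table 11); the DNA itself is never analyzed downstream, only
  coordinates and proteins. For overlapping gene pairs the downstream gene's
  codons win on the shared span; planted translations are carried on the
  features and in GenBank ``/translation`` qualifiers.
* Transmembrane blocks are 21-aa shuffled multisets over the strongly
  hydrophobic core {L, I, V}; linkers are serine-rich shuffled multisets over
  {S, N, K, D, E}. This keeps every 19-residue Kyte-Doolittle window inside a
  block unambiguously above the 1.6 call threshold and every inter-block
  window below it, so planted helix counts are recoverable by construction.
* One RNG stream per panel, seeded from the spec: regeneration with the same
  spec is byte-identical.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .model import GeneFeature, PhageGenome

# transcription-order role layouts realizing each organization label
ORGANIZATION_LAYOUTS: dict[str, list[str]] = {
    "A": ["holin", "endolysin"],
    "B": ["holin", "holin", "endolysin"],
    "C": ["holin", "endonuclease", "endolysin"],
    "D": ["endolysin", "holin"],
    "E": ["endolysin", "endolysin", "holin"],
}

DECOY_PRODUCTS = (
    "hypothetical protein",
    "major capsid protein",
    "terminase",
    "portal protein",
)

#: TCDB holin families grouped by their conserved TMD count
FAMILIES_BY_TMD: dict[int, list[str]] = {
    1: ["1.E.26", "1.E.65"],
    2: ["1.E.11", "1.E.18", "1.E.24"],
    3: ["1.E.10", "1.E.16", "1.E.19", "1.E.21"],
}

HOLIN_DOMAIN = "Phage_holin_1"

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# TMD block: shuffled multiset of 21 strongly hydrophobic residues
_TMD_MULTISET = list("L" * 8 + "I" * 7 + "V" * 6)
# hydrophilic unit tiled to build linkers/flanks (serine-rich, net hydrophilic)
_LINKER_UNIT = list("SSSSSSNNKD")

_BACK_TABLE: dict[str, list[str]] = {}


def _back_table() -> dict[str, list[str]]:
    if not _BACK_TABLE:
        tbl = CodonTable.unambiguous_dna_by_id[11]
        for codon, aa in tbl.forward_table.items():
            _BACK_TABLE.setdefault(aa, []).append(codon)
        _BACK_TABLE["*"] = sorted(tbl.stop_codons)
        for v in _BACK_TABLE.values():
            v.sort()
    return _BACK_TABLE


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniform codon choice (table 11), appending a stop."""
    bt = _back_table()
    codons = [bt[aa][rng.integers(len(bt[aa]))] for aa in protein]
    codons.append(bt["*"][rng.integers(3)])
    return "".join(codons)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _random_protein(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(_AA20))[rng.integers(0, 20, size=n)])


def _linker(n: int, rng: np.random.Generator) -> str:
    unit = _LINKER_UNIT * (n // len(_LINKER_UNIT) + 1)
    res = np.array(unit[:n])
    rng.shuffle(res)
    return "".join(res)


@dataclass
class PanelSpec:
    """Parameters of a synthetic panel; counts are per organization label."""

    organization_mix: dict[str, int] = field(
        default_factory=lambda: {lab: 1 for lab in "ABCDE"}
    )
    decoy_orfs_range: tuple[int, int] = (3, 6)
    endolysin_architectures: Optional[list[list[str]]] = None
    holin_tmd_counts: Sequence[int] = (1, 2, 3)
    overlap_offsets: Sequence[int] = ()
    intercalate_c: bool = True
    obfuscate_fraction: float = 0.0
    noise: float = 0.0
    reverse_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.organization_mix.values()):
            raise ValueError("organization counts must be nonnegative")
        for p in (self.obfuscate_fraction, self.noise, self.reverse_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        unknown = set(self.organization_mix) - set(ORGANIZATION_LAYOUTS)
        if unknown:
            raise ValueError(f"unknown organization label(s): {sorted(unknown)}")

    @property
    def n_genomes(self) -> int:
        return sum(self.organization_mix.values())


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside a generated panel."""

    seed: int
    genomes: dict[str, dict] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)
    endolysins: dict[str, list[str]] = field(default_factory=dict)
    holins: dict[str, dict] = field(default_factory=dict)
    overlaps: list[dict] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        rows = []
        for acc, g in self.genomes.items():
            rows.append(("genome", acc, "organization", g["organization"]))
            rows.append(("genome", acc, "signature", g["signature"]))
            rows.append(("genome", acc, "intercalated", str(g["intercalated"])))
        for pid, role in self.roles.items():
            rows.append(("role", pid, "role", role))
        for pid, layout in self.endolysins.items():
            rows.append(("endolysin", pid, "architecture", " & ".join(layout)))
        for pid, h in self.holins.items():
            rows.append(("holin", pid, "tmd_count", str(h["tmd_count"])))
            rows.append(("holin", pid, "family", h["family"]))
        for ov in self.overlaps:
            rows.append(("overlap", f"{ov['upstream']}|{ov['downstream']}",
                         "start_offset_nt", str(ov["start_offset_nt"])))
        pd.DataFrame(rows, columns=["section", "key", "field", "value"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class EvidencePack:
    """Evidence tables accompanying a panel (in-memory; writable to disk)."""

    domtblout_text: str
    tcdb_hits: pd.DataFrame
    supplemental: pd.DataFrame

    def write(self, domtblout_path, tcdb_path=None, supplemental_path=None) -> None:
        with open(domtblout_path, "w") as fh:
            fh.write(self.domtblout_text)
        if tcdb_path is not None:
            self.tcdb_hits.to_csv(tcdb_path, sep="\t", index=False)
        if supplemental_path is not None:
            self.supplemental.to_csv(supplemental_path, sep="\t", index=False)


def generate_holin_protein(
    n_tmds: int, seed: Optional[int] = None, rng: Optional[np.random.Generator] = None
) -> tuple[str, list[tuple[int, int]]]:
    """A 60-160 aa holin-like protein with ``n_tmds`` planted 21-aa helices.

    Helices are separated by >=10-aa hydrophilic linkers; returns the protein
    and the 1-based inclusive coordinates of each planted segment.
    """
    if not 1 <= n_tmds <= 3:
        raise ValueError("n_tmds must be in 1..3")
    if rng is None:
        rng = np.random.default_rng(seed)
    parts: list[str] = []
    segments: list[tuple[int, int]] = []
    pos = 0
    nterm = int(rng.integers(12, 21))
    parts.append(_linker(nterm, rng))
    pos += nterm
    for i in range(n_tmds):
        if i > 0:
            gap = int(rng.integers(10, 15))
            parts.append(_linker(gap, rng))
            pos += gap
        block = list(_TMD_MULTISET)
        rng.shuffle(block)  # type: ignore[arg-type]
        parts.append("".join(block))
        segments.append((pos + 1, pos + 21))
        pos += 21
    cterm = int(rng.integers(12, 21))
    total = pos + cterm
    if total < 60:  # stay inside the 60-160 aa holin length envelope
        cterm += 60 - total
    parts.append(_linker(cterm, rng))
    return "".join(parts), segments


def generate_endolysin_protein(
    layout: Sequence[str], rng: np.random.Generator
) -> tuple[str, list[tuple[str, int, int]]]:
    """Random protein hosting the given N->C domain layout.

    Returns the protein and per-domain (name, ali_from, ali_to) intervals.
    """
    parts: list[str] = []
    intervals: list[tuple[str, int, int]] = []
    pos = 0
    nterm = int(rng.integers(8, 14))
    parts.append(_random_protein(nterm, rng))
    pos += nterm
    for i, dom in enumerate(layout):
        if i > 0:
            gap = int(rng.integers(6, 13))
            parts.append(_random_protein(gap, rng))
            pos += gap
        dlen = int(rng.integers(50, 81))
        parts.append(_random_protein(dlen, rng))
        intervals.append((dom, pos + 1, pos + dlen))
        pos += dlen
    cterm = int(rng.integers(8, 14))
    parts.append(_random_protein(cterm, rng))
    pos += cterm
    if pos < 80:  # keep genes above the short-endolysin warning bound
        parts.append(_random_protein(80 - pos, rng))
    return "".join(parts), intervals


def generate_overlap_pair(
    start_offset_nt: int,
    seed: Optional[int] = None,
    first_gene_len_nt: int = 300,
    rng: Optional[np.random.Generator] = None,
    start: int = 1,
    id_prefix: str = "ovl",
) -> tuple[GeneFeature, GeneFeature, dict]:
    """Two same-strand CDS where the second starts ``start_offset_nt`` into
    the first (an overprinted pair). Both spans are codon multiples."""
    if first_gene_len_nt % 3 != 0:
        raise ValueError("first gene length must be a multiple of 3")
    if not 0 < start_offset_nt < first_gene_len_nt:
        raise ValueError(
            "start offset must be positive and smaller than the first gene "
            f"length ({first_gene_len_nt} nt); got {start_offset_nt}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    second_len = first_gene_len_nt - start_offset_nt + 3 * int(rng.integers(10, 40))
    second_len -= second_len % 3
    f1 = GeneFeature(
        feature_id=f"{id_prefix}_up", start=start, end=start + first_gene_len_nt - 1,
        strand="+", product="endolysin",
        protein_seq=_random_protein(first_gene_len_nt // 3 - 1, rng),
    )
    s2 = start + start_offset_nt
    f2 = GeneFeature(
        feature_id=f"{id_prefix}_down", start=s2, end=s2 + second_len - 1,
        strand="+", product="endolysin",
        protein_seq=_random_protein(second_len // 3 - 1, rng),
    )
    truth = {
        "upstream": f1.feature_id, "downstream": f2.feature_id,
        "start_offset_nt": start_offset_nt,
        "overlap_len_nt": f1.end - f2.start + 1,
        "frame_offset": start_offset_nt % 3,
    }
    return f1, f2, truth


# ---------------------------------------------------------------------------
# panel assembly

_DOMTBL_HEADER = (
    "#                                                                            "
    "--- full sequence --- -------------- this domain -------------   "
    "hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           accession   qlen"
    "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
    "  from    to  from    to  acc description of target\n"
    "#------------------- ---------- ----- -------------------- ---------- -----"
    " --------- ------ ----- --- --- --------- --------- ------ ----- ----- -----"
    " ----- ----- ----- ----- ---- ---------------------\n"
)


def format_domtblout(rows: list[dict]) -> str:
    """Render hit rows in the HMMER3 per-domain tabular dialect."""
    buf = io.StringIO()
    buf.write(_DOMTBL_HEADER)
    for r in rows:
        span = r["ali_to"] - r["ali_from"] + 1
        buf.write(
            f"{r['target']:<20} -          {r['tlen']:>5} {r['query']:<20} "
            f"{r.get('acc', '-'):<10} {span:>5} {r['evalue']:>9.2g} "
            f"{r['score']:>6.1f}   0.0   1   1 {r['evalue'] / 10:>9.2g} "
            f"{r['evalue']:>9.2g} {r['score'] - 1:>6.1f}   0.0 "
            f"{1:>5} {span:>5} {r['ali_from']:>5} {r['ali_to']:>5} "
            f"{max(1, r['ali_from'] - 2):>5} {min(r['tlen'], r['ali_to'] + 2):>5} "
            f"0.95 planted\n"
        )
    return buf.getvalue()


def _plant_cassette_roles(label: str, intercalate_c: bool) -> list[str]:
    layout = list(ORGANIZATION_LAYOUTS[label])
    if label == "C" and not intercalate_c:
        layout = ["holin", "endolysin"]
    return layout


def generate_panel(
    spec: PanelSpec,
) -> tuple[list[PhageGenome], EvidencePack, SyntheticTruth]:
    """Generate a genome panel realizing ``spec`` with planted ground truth.

    Each genome carries exactly one lysis cassette in its assigned
    organization layout, flanked by decoy ORFs; evidence tables (domain hits,
    transporter-family hits) are consistent with the planted layouts, with
    noise hits added at the spec'd rate, all at E-values >= 0.01 so the
    standard filter removes them.
    """
    rng = np.random.default_rng(spec.seed)
    truth = SyntheticTruth(seed=spec.seed)
    genomes: list[PhageGenome] = []
    dom_rows: list[dict] = []
    tcdb_rows: list[dict] = []

    ref_archs = spec.endolysin_architectures
    if ref_archs is None:
        from .config import reference_architectures

        ref_archs = list(reference_architectures().values())

    assignments = [lab for lab in sorted(spec.organization_mix)
                   for _ in range(spec.organization_mix[lab])]
    arch_i = 0
    tmd_i = 0
    fam_cycle = {k: 0 for k in FAMILIES_BY_TMD}
    overlap_i = 0

    for gi, label in enumerate(assignments):
        acc = f"SYNPH{gi + 1:03d}"
        reverse = bool(rng.random() < spec.reverse_fraction)
        layout = _plant_cassette_roles(label, spec.intercalate_c)

        # build ORF descriptors in genomic order
        n_decoys = int(rng.integers(spec.decoy_orfs_range[0],
                                    spec.decoy_orfs_range[1] + 1))
        n_left = int(rng.integers(0, n_decoys + 1))
        cassette = layout if not reverse else list(reversed(layout))
        orf_plan = (["decoy"] * n_left + list(cassette)
                    + ["decoy"] * (n_decoys - n_left))

        # per-genome family bookkeeping so tandem holins differ in family
        genome_families: list[str] = []
        features: list[GeneFeature] = []
        planted_sig: list[str] = []
        cassette_ids: list[str] = []
        pos = int(rng.integers(60, 150))  # leading margin
        fi = 0
        overlap_offset: Optional[int] = None
        if spec.overlap_offsets and label == "E" and not reverse:
            overlap_offset = int(spec.overlap_offsets[overlap_i % len(spec.overlap_offsets)])
            overlap_i += 1
        prev_endolysin: Optional[GeneFeature] = None

        for kind in orf_plan:
            fi += 1
            fid = f"{acc}_cds{fi:02d}"
            strand = "-" if (reverse and kind != "decoy") else "+"
            if kind == "decoy":
                product = DECOY_PRODUCTS[int(rng.integers(0, len(DECOY_PRODUCTS)))]
                protein = _random_protein(int(rng.integers(80, 301)), rng)
                role_truth = "hypothetical" if product == "hypothetical protein" else "other"
            elif kind == "holin":
                n_tmds = int(spec.holin_tmd_counts[tmd_i % len(spec.holin_tmd_counts)])
                tmd_i += 1
                protein, segments = generate_holin_protein(n_tmds, rng=rng)
                fams = FAMILIES_BY_TMD[n_tmds]
                fam = fams[fam_cycle[n_tmds] % len(fams)]
                fam_cycle[n_tmds] += 1
                if fam in genome_families:  # tandem holins: force distinct families
                    fam = fams[(fams.index(fam) + 1) % len(fams)]
                genome_families.append(fam)
                obfuscated = bool(rng.random() < spec.obfuscate_fraction)
                product = "hypothetical protein" if obfuscated else "holin"
                if obfuscated:
                    dom_rows.append({
                        "target": fid, "query": HOLIN_DOMAIN, "tlen": len(protein),
                        "ali_from": max(1, segments[0][0] - 3),
                        "ali_to": min(len(protein), segments[-1][1] + 3),
                        "evalue": 10.0 ** -float(rng.uniform(6, 20)), "score": 60.0,
                    })
                tcdb_rows.append({
                    "qseqid": fid, "sseqid": f"{fam}.1.{int(rng.integers(1, 9))}",
                    "evalue": 10.0 ** -float(rng.uniform(8, 30)),
                    "bitscore": float(np.round(rng.uniform(80, 300), 1)),
                })
                truth.holins[fid] = {
                    "tmd_count": n_tmds, "segments": segments, "family": fam,
                }
                role_truth = "holin"
            elif kind == "endolysin":
                arch = list(ref_archs[arch_i % len(ref_archs)])
                arch_i += 1
                protein, intervals = generate_endolysin_protein(arch, rng)
                obfuscated = bool(rng.random() < spec.obfuscate_fraction)
                product = "hypothetical protein" if obfuscated else "endolysin"
                for dom, a, b in intervals:
                    dom_rows.append({
                        "target": fid, "query": dom, "tlen": len(protein),
                        "ali_from": a, "ali_to": b,
                        "evalue": 10.0 ** -float(rng.uniform(5, 30)),
                        "score": float(np.round(rng.uniform(30, 200), 1)),
                    })
                truth.endolysins[fid] = arch
                role_truth = "endolysin"
            else:  # endonuclease
                product = "endonuclease"
                protein = _random_protein(int(rng.integers(100, 200)), rng)
                role_truth = "endonuclease"

            gene_len = 3 * (len(protein) + 1)
            if (kind == "endolysin" and overlap_offset is not None
                    and prev_endolysin is not None):
                start = prev_endolysin.start + overlap_offset
            else:
                start = pos + int(rng.integers(20, 80))
            feat = GeneFeature(feature_id=fid, start=start,
                               end=start + gene_len - 1, strand=strand,
                               product=product, protein_seq=protein)
            if kind == "endolysin":
                if overlap_offset is not None and prev_endolysin is not None:
                    truth.overlaps.append({
                        "genome_id": acc,
                        "upstream": prev_endolysin.feature_id, "downstream": fid,
                        "start_offset_nt": overlap_offset,
                        "overlap_len_nt": prev_endolysin.end - feat.start + 1,
                        "frame_offset": overlap_offset % 3,
                    })
                prev_endolysin = feat
            features.append(feat)
            truth.roles[fid] = role_truth
            if kind != "decoy":
                planted_sig.append(
                    {"holin": "H", "endolysin": "E", "endonuclease": "N"}[kind]
                )
                cassette_ids.append(fid)
            pos = max(pos, feat.end)

            # sub-threshold noise hits (E >= 0.01): must be filtered downstream
            if rng.random() < spec.noise:
                lex_names = ["Amidase_5", "CHAP", "ZoocinA_TRD", "LysM", "DUF9999"]
                a = int(rng.integers(1, max(2, len(protein) - 30)))
                dom_rows.append({
                    "target": fid,
                    "query": lex_names[int(rng.integers(0, len(lex_names)))],
                    "tlen": len(protein), "ali_from": a,
                    "ali_to": min(len(protein), a + int(rng.integers(20, 60))),
                    "evalue": float(rng.uniform(0.01, 0.9)), "score": 8.0,
                })

        # lay genes onto a random backbone (later writes win on overlaps)
        total_len = pos + int(rng.integers(60, 150))
        backbone = list(_random_dna(total_len, rng))
        for f in features:
            cds = back_translate(f.protein_seq, rng)
            if f.strand == "-":
                from Bio.Seq import Seq

                cds = str(Seq(cds).reverse_complement())
            backbone[f.start - 1 : f.end] = list(cds)
        genome = PhageGenome(accession=acc, name=f"Synthetic phage {acc}",
                             sequence="".join(backbone), features=features)
        genomes.append(genome)

        # planted_sig is genomic order; signatures are transcription order
        sig = "".join(reversed(planted_sig)) if reverse else "".join(planted_sig)
        truth.genomes[acc] = {
            "organization": label, "signature": sig,
            "intercalated": sig.count("N") + sig.count("X"),
            "holin_first": sig.replace("N", "").replace("X", "").startswith("H"),
            "cassette": cassette_ids, "reverse": reverse,
        }

    evidence = EvidencePack(
        domtblout_text=format_domtblout(dom_rows),
        tcdb_hits=pd.DataFrame(
            tcdb_rows, columns=["qseqid", "sseqid", "evalue", "bitscore"]
        ),
        supplemental=pd.DataFrame(
            columns=["protein_id", "subject", "evalue", "identity_pct"]
        ),
    )
    return genomes, evidence, truth


def generate_sp_qs1_layout(
    n_intervening: int,
    seed: Optional[int] = None,
    intervening_products: Optional[Sequence[str]] = None,
    max_intercalated: int = 2,
) -> tuple[PhageGenome, dict]:
    """Genome with one holin, ``n_intervening`` decoy ORFs, then one endolysin.

    Emulates the dispersed-cassette case (holin and endolysin separated by
    many unrelated, mostly structural/hypothetical genes); with 0 intervening
    ORFs the layout collapses to a contiguous holin-endolysin cassette.
    """
    if n_intervening < 0:
        raise ValueError("n_intervening must be >= 0")
    rng = np.random.default_rng(seed)
    acc = "SYNSP001"
    features: list[GeneFeature] = []
    pos = 80
    truth_roles: dict[str, str] = {}

    def add(fid: str, product: str, protein: str) -> None:
        nonlocal pos
        start = pos + int(rng.integers(20, 60))
        features.append(GeneFeature(feature_id=fid, start=start,
                                    end=start + 3 * (len(protein) + 1) - 1,
                                    strand="+", product=product, protein_seq=protein))
        pos = features[-1].end

    hol, _ = generate_holin_protein(2, rng=rng)
    add(f"{acc}_cds01", "holin", hol)
    truth_roles[f"{acc}_cds01"] = "holin"
    for i in range(n_intervening):
        if intervening_products is not None and i < len(intervening_products):
            product = intervening_products[i]
        else:
            product = DECOY_PRODUCTS[int(rng.integers(0, len(DECOY_PRODUCTS)))]
        add(f"{acc}_cds{i + 2:02d}", product, _random_protein(int(rng.integers(80, 250)), rng))
        truth_roles[features[-1].feature_id] = (
            "endonuclease" if "endonuclease" in product
            else "hypothetical" if product == "hypothetical protein" else "other"
        )
    endo, _ = generate_endolysin_protein(["Amidase_5", "ZoocinA_TRD"], rng)
    add(f"{acc}_cds{n_intervening + 2:02d}", "endolysin", endo)
    truth_roles[features[-1].feature_id] = "endolysin"

    total = pos + 100
    backbone = list(_random_dna(total, rng))
    for f in features:
        backbone[f.start - 1 : f.end] = list(back_translate(f.protein_seq, rng))
    genome = PhageGenome(accession=acc, name="Synthetic dispersed-cassette phage",
                         sequence="".join(backbone), features=features)
    lysis_relevant = [p for p in truth_roles.values() if p in ("endonuclease",)]
    module_expected = n_intervening <= max_intercalated
    truth = {
        "n_intervening": n_intervening,
        "module_expected": module_expected,
        "intercalated_variant": module_expected and bool(lysis_relevant),
        "roles": truth_roles,
    }
    return genome, truth
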