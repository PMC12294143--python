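"""End-to-end orchestration: simulate/load -> identify -> delineate ->
classify -> summarize, writing every tabular output plus a summary text.

The pipeline is configured from one dict (YAML-friendly) surfacing every
threshold (E-value cutoff, intercalation tolerance, hydropathy parameters) so
each analysis choice is auditable in one place. Runs are deterministic under
a fixed seed/config; every run logs the package version, seed, and a config
hash.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import __version__
from .architecture import (DomainLexicon, architecture_activities,
                           build_architecture, check_endolysin_length,
                           flag_and_cooccur, hits_by_protein, parse_domtblout,
                           rank_architectures, resolve_overlaps, upset_table)
from .genome_io import read_genbank, write_modules_gff
from .holins import (HydropathyParams, holins_table, profile_holins,
                     tandem_and_consistency_report)
from .model import PhageGenome
from .modules import (OrganizationCatalogue, classify_organization,
                      delineate_modules, modules_table, order_statistics)
from .overlaps import detect_overlaps, overlaps_table
from .roles import RoleLexicon, annotate_genome
from .simulate import EvidencePack, PanelSpec, generate_panel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ReportBundle:
    """Everything a pipeline run produces, in memory plus on disk."""

    outdir: Path
    genomes: list[PhageGenome] = field(default_factory=list)
    modules: list = field(default_factory=list)
    diagnostics: list = field(default_factory=list)
    architectures: list = field(default_factory=list)
    architecture_table: Optional[pd.DataFrame] = None
    overlaps: list = field(default_factory=list)
    holin_profiles: list = field(default_factory=list)
    summary: dict[str, Any] = field(default_factory=dict)
    truth = None


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(config: dict, outdir) -> ReportBundle:
    """Run the full analysis and write the report bundle under ``outdir``.

    ``config`` keys: either ``simulate`` (a PanelSpec mapping) or ``input``
    (dir of GenBank files + ``hits`` domtblout path [+ ``tcdb`` TSV]);
    optional ``e_cutoff``, ``max_intercalated``, ``max_gap_nt``,
    ``hydropathy`` (param overrides), ``lexicon``/``catalogue`` paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("lysmod %s | config hash %s | seed %s", __version__,
                _config_hash(config), config.get("simulate", {}).get("seed"))

    e_cutoff = float(config.get("e_cutoff", 0.01))
    role_lex = RoleLexicon.from_yaml(config.get("role_lexicon"),
                                     config.get("domain_lexicon"))
    dom_lex = DomainLexicon.from_yaml(config.get("domain_lexicon"))
    catalogue = OrganizationCatalogue.from_yaml(config.get("catalogue"))
    bundle = ReportBundle(outdir=outdir)

    # ---- stage: inputs -----------------------------------------------------
    truth = None
    if "simulate" in config:
        spec = PanelSpec(**config["simulate"])
        genomes, evidence, truth = generate_panel(spec)
        evidence.write(outdir / "hits.domtblout", outdir / "tcdb_hits.tsv")
        truth.to_tsv(outdir / "truth.tsv")
        hits_path = outdir / "hits.domtblout"
        tcdb = evidence.tcdb_hits
    elif "input" in config:
        indir = Path(config["input"])
        paths = sorted(indir.glob("*.gb")) + sorted(indir.glob("*.gbk")) \
            + sorted(indir.glob("*.gbff"))
        if not paths:
            raise PipelineError("input", f"no GenBank files found in {indir}")
        genomes = [read_genbank(p) for p in paths]
        hits_path = config.get("hits")
        tcdb = pd.read_csv(config["tcdb"], sep="\t") if config.get("tcdb") else None
    else:
        raise PipelineError("input", "config needs a 'simulate' spec or an 'input' dir")
    bundle.genomes = genomes
    bundle.truth = truth

    # ---- stage: domain hits + roles ---------------------------------------
    hits = parse_domtblout(hits_path, e_cutoff=e_cutoff, lexicon=dom_lex) \
        if hits_path else []
    by_protein = hits_by_protein(hits)
    for g in genomes:
        annotate_genome(g, by_protein, lexicon=role_lex)

    # ---- stage: module delineation + classification ------------------------
    max_intercalated = int(config.get("max_intercalated", 2))
    max_gap_nt = int(config.get("max_gap_nt", 1000))
    for g in genomes:
        res = delineate_modules(g, max_intercalated=max_intercalated,
                                max_gap_nt=max_gap_nt)
        for m in res.modules:
            classify_organization(m, catalogue)
        bundle.modules.extend(res.modules)
        bundle.diagnostics.extend(res.diagnostics)
    modules_table(bundle.modules).to_csv(outdir / "modules.tsv", sep="\t",
                                         index=False)
    write_modules_gff(genomes, bundle.modules, outdir / "modules.gff3")

    # ---- stage: endolysin architectures ------------------------------------
    endolysin_ids = []
    genome_of: dict[str, str] = {}
    for g in genomes:
        for f in g.features:
            genome_of[f.feature_id] = g.accession
            if f.role == "endolysin":
                endolysin_ids.append(f.feature_id)
                check_endolysin_length(f.length_nt, f.feature_id)
    archs = []
    for pid in endolysin_ids:
        own = resolve_overlaps(by_protein.get(pid, []))
        archs.append(build_architecture(pid, own, dom_lex))
    archs, arch_table = rank_architectures(archs)
    bundle.architectures = archs
    bundle.architecture_table = arch_table
    arch_rows = pd.DataFrame(
        [{"protein_id": a.protein_id, "genome_id": genome_of[a.protein_id],
          "label": a.label, "canonical": a.canonical,
          "has_EAD": a.has_EAD, "has_CBD": a.has_CBD,
          "activities": ",".join(architecture_activities(a, dom_lex))}
         for a in archs],
        columns=["protein_id", "genome_id", "label", "canonical", "has_EAD",
                 "has_CBD", "activities"])
    arch_rows.to_csv(outdir / "architectures.tsv", sep="\t", index=False)
    matrix, marginal = upset_table(archs)
    matrix.to_csv(outdir / "upset.tsv", sep="\t", index=False)
    by_genome: dict[str, list] = {}
    for a in archs:
        by_genome.setdefault(genome_of[a.protein_id], []).append(a)
    cooc = flag_and_cooccur(by_genome)
    cooc["no_EAD"].to_csv(outdir / "cooccurrence.tsv", sep="\t", index=False)

    # ---- stage: overlaps ----------------------------------------------------
    for g in genomes:
        bundle.overlaps.extend(detect_overlaps(g))
    overlaps_table(bundle.overlaps).to_csv(outdir / "overlaps.tsv", sep="\t",
                                           index=False)

    # ---- stage: holins ------------------------------------------------------
    hp_cfg = config.get("hydropathy", {})
    params = HydropathyParams(**hp_cfg) if hp_cfg else HydropathyParams()
    holin_proteins = {
        f.feature_id: (g.accession, f.protein_seq)
        for g in genomes for f in g.features
        if f.role == "holin" and f.protein_seq
    }
    profiles = profile_holins(holin_proteins, tcdb_hits=tcdb, params=params)
    bundle.holin_profiles = profiles
    holins_table(profiles).to_csv(outdir / "holins.tsv", sep="\t", index=False)
    report = tandem_and_consistency_report(profiles)
    report["tandem"].to_csv(outdir / "tandem_report.tsv", sep="\t", index=False)
    report["family_consistency"].to_csv(outdir / "family_consistency.tsv",
                                        sep="\t", index=False)

    # ---- stage: summary -----------------------------------------------------
    stats = order_statistics(bundle.modules)
    fam_hist: dict[str, int] = {}
    tmd_hist: dict[int, int] = {}
    for p in profiles:
        fam_hist[p.tcdb_family] = fam_hist.get(p.tcdb_family, 0) + 1
        tmd_hist[p.tmd_count] = tmd_hist.get(p.tmd_count, 0) + 1
    bundle.summary = {
        "n_genomes": len(genomes),
        "n_modules": len(bundle.modules),
        "organization_histogram": stats["label_histogram"],
        "holin_first_fraction": stats["holin_first_fraction"],
        "n_endolysins": len(archs),
        "n_architectures": len(arch_table),
        "n_overlap_pairs": len(bundle.overlaps),
        "n_holins": len(profiles),
        "holin_family_histogram": dict(sorted(fam_hist.items())),
        "tmd_histogram": {str(k): v for k, v in sorted(tmd_hist.items())},
        "config_hash": _config_hash(config),
        "version": __version__,
    }
    with open(outdir / "summary.txt", "w") as fh:
        for k, v in bundle.summary.items():
            fh.write(f"{k}\t{json.dumps(v, sort_keys=True)}\n")
    return bundle
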