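"""Domain-hit filtering, architecture building, ranking, upset, co-occurrence."""
import itertools

import numpy as np
import pytest

from lysmod.architecture import (DomainLexicon, build_architecture,
                                 flag_and_cooccur, parse_domtblout,
                                 rank_architectures, resolve_overlaps,
                                 upset_table)
from lysmod.config import reference_architectures
from lysmod.model import DomainHit, EndolysinArchitecture
from lysmod.simulate import format_domtblout

LEX = DomainLexicon.default()


def hit(name, frm, to, e=1e-6, score=50.0, pid="p1"):
    return DomainHit(protein_id=pid, domain_name=name, source_db="hmmer",
                     ali_from=frm, ali_to=to, e_value=e, bit_score=score,
                     role=LEX.role(name), activity=LEX.activity(name))


def domtbl_rows(specs):
    return [{"target": pid, "query": name, "tlen": 400, "ali_from": frm,
             "ali_to": to, "evalue": e, "score": 50.0}
            for pid, name, frm, to, e in specs]


class TestParseDomtblout:
    def test_e_value_cutoff_drops_marginal_rows(self, tmp_path):
        p = tmp_path / "h.dom"
        p.write_text(format_domtblout(domtbl_rows([
            ("p1", "Amidase_5", 1, 120, 1e-6),
            ("p1", "NLPC_P60", 130, 240, 5e-3),
            ("p1", "CHAP", 250, 300, 0.02),
        ])))
        hits = parse_domtblout(p, e_cutoff=0.01)
        assert len(hits) == 2
        assert {h.domain_name for h in hits} == {"Amidase_5", "NLPC_P60"}

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "h.dom"
        p.write_text("# comment only\n")
        assert parse_domtblout(p) == []

    def test_lexicon_annotation(self, tmp_path):
        p = tmp_path / "h.dom"
        p.write_text(format_domtblout(domtbl_rows([("p1", "Amidase_5", 1, 100, 1e-8)])))
        (h,) = parse_domtblout(p)
        assert (h.role, h.activity) == ("EAD", "amidase")

    def test_unknown_domain_kept_with_unknown_role(self, tmp_path):
        p = tmp_path / "h.dom"
        p.write_text(format_domtblout(domtbl_rows([("p1", "DUF9999", 1, 50, 1e-8)])))
        (h,) = parse_domtblout(p)
        assert h.role == "unknown"

    def test_malformed_rows_skipped_all_malformed_errors(self, tmp_path):
        good = format_domtblout(domtbl_rows([("p1", "CHAP", 1, 60, 1e-8)]))
        p = tmp_path / "h.dom"
        p.write_text(good + "garbage row\n")
        assert len(parse_domtblout(p)) == 1
        p2 = tmp_path / "bad.dom"
        p2.write_text("garbage\nmore garbage\n")
        with pytest.raises(ValueError, match="no parseable rows"):
            parse_domtblout(p2)


class TestResolveOverlaps:
    def test_lower_evalue_dominates_heavy_overlap(self):
        kept = resolve_overlaps([hit("Amidase_5", 1, 120, e=1e-10),
                                 hit("DUF9999", 50, 130, e=1e-3)])
        assert [h.domain_name for h in kept] == ["Amidase_5"]

    def test_non_overlapping_hits_both_survive(self):
        kept = resolve_overlaps([hit("Amidase_5", 1, 120), hit("ZoocinA_TRD", 200, 260)])
        assert len(kept) == 2

    def test_exact_tie_duplicates_collapse_to_one(self):
        kept = resolve_overlaps([hit("CHAP", 1, 60), hit("CHAP", 1, 60)])
        assert len(kept) == 1

    def test_multiple_proteins_rejected(self):
        with pytest.raises(ValueError):
            resolve_overlaps([hit("CHAP", 1, 60, pid="a"), hit("CHAP", 1, 60, pid="b")])


class TestBuildArchitecture:
    def test_canonical_triple_with_flags(self):
        arch = build_architecture("p1", [hit("Amidase_5", 5, 120),
                                         hit("NLPC_P60", 130, 240),
                                         hit("ZoocinA_TRD", 250, 300)])
        assert arch.canonical == "Amidase_5 & NLPC_P60 & ZoocinA_TRD"
        assert arch.has_EAD and arch.has_CBD

    def test_cbd_only_architecture(self):
        arch = build_architecture("p1", [hit("ZoocinA_TRD", 10, 70)])
        assert arch.canonical == "ZoocinA_TRD"
        assert not arch.has_EAD and arch.has_CBD

    def test_central_cbd_order_preserved(self):
        # CW_7 sits between the catalytic domains and a Glucosaminidase
        arch = build_architecture("p1", [hit("Glucosaminidase", 300, 360),
                                         hit("Amidase_5", 5, 100),
                                         hit("CW_7", 220, 280),
                                         hit("NLPC_P60", 110, 210)])
        assert arch.canonical == "Amidase_5 & NLPC_P60 & CW_7 & Glucosaminidase"

    def test_empty_hits_give_none_canonical(self):
        arch = build_architecture("p1", [])
        assert arch.canonical == "(none)"
        assert not arch.has_EAD and not arch.has_CBD

    def test_repeated_domains_kept(self):
        arch = build_architecture("p1", [hit("CHAP", 1, 60), hit("CHAP", 100, 160)])
        assert arch.canonical == "CHAP & CHAP"

    @pytest.mark.parametrize("perm", list(itertools.permutations(range(3)))[:6])
    def test_canonical_invariant_to_hit_order(self, perm):
        hits = [hit("Amidase_5", 5, 120), hit("NLPC_P60", 130, 240),
                hit("ZoocinA_TRD", 250, 300)]
        arch = build_architecture("p1", [hits[i] for i in perm])
        assert arch.canonical == "Amidase_5 & NLPC_P60 & ZoocinA_TRD"


class TestRankArchitectures:
    def _arch(self, canonical, pid):
        doms = [(d, LEX.role(d)) for d in canonical.split(" & ")]
        return EndolysinArchitecture(
            protein_id=pid, ordered_domains=doms, canonical=canonical,
            has_EAD=any(r == "EAD" for _, r in doms),
            has_CBD=any(r == "CBD" for _, r in doms))

    def test_labels_follow_decreasing_frequency(self):
        panel = ([self._arch("CHAP", f"x{i}") for i in range(10)]
                 + [self._arch("LysM", f"y{i}") for i in range(3)]
                 + [self._arch("PlyCB", "z0")])
        _, table = rank_architectures(panel)
        assert list(table["label"]) == ["A1", "A2", "A3"]
        assert list(table["canonical"]) == ["CHAP", "LysM", "PlyCB"]
        assert list(table["count"]) == [10, 3, 1]

    def test_count_ties_break_lexicographically(self):
        panel = [self._arch("PlyCB", "a"), self._arch("CHAP", "b")]
        _, table = rank_architectures(panel)
        assert list(table["canonical"]) == ["CHAP", "PlyCB"]

    def test_single_type_gets_a1(self):
        panel = [self._arch("CHAP", "a")]
        panel, table = rank_architectures(panel)
        assert panel[0].label == "A1" and len(table) == 1

    def test_frequencies_non_increasing_in_label_index(self):
        rng = np.random.default_rng(5)
        names = ["CHAP", "LysM", "PlyCB", "Amidase_5", "CW_7"]
        panel = [self._arch(names[rng.integers(0, 5)], f"p{i}") for i in range(60)]
        _, table = rank_architectures(panel)
        counts = list(table["count"])
        assert counts == sorted(counts, reverse=True)

    def test_label_map_pins_labels_across_runs(self):
        panel = [self._arch("CHAP", "a"), self._arch("LysM", "b")]
        panel, _ = rank_architectures(panel, label_map={"LysM": "A7", "CHAP": "A9"})
        assert {a.canonical: a.label for a in panel} == {"CHAP": "A9", "LysM": "A7"}

    def test_reference_table_yields_25_distinct_canonicals(self):
        archs = []
        for i, (label, layout) in enumerate(reference_architectures().items()):
            hits = []
            pos = 1
            for dom in layout:
                hits.append(hit(dom, pos, pos + 59, pid=f"p{i}"))
                pos += 70
            archs.append(build_architecture(f"p{i}", hits))
        assert len({a.canonical for a in archs}) == 25


class TestUpsetAndCooccurrence:
    def _arch(self, canonical, pid):
        doms = [(d, LEX.role(d)) for d in canonical.split(" & ")] \
            if canonical != "(none)" else []
        return EndolysinArchitecture(
            protein_id=pid, ordered_domains=doms, canonical=canonical,
            has_EAD=any(r == "EAD" for _, r in doms),
            has_CBD=any(r == "CBD" for _, r in doms))

    def test_identical_proteins_collapse_to_one_row(self):
        panel = [self._arch("Amidase_5 & NLPC_P60 & ZoocinA_TRD", "a"),
                 self._arch("Amidase_5 & NLPC_P60 & ZoocinA_TRD", "b")]
        matrix, marginal = upset_table(panel)
        assert len(matrix) == 1
        assert matrix.iloc[0]["count"] == 2
        assert matrix.iloc[0][["Amidase_5", "NLPC_P60", "ZoocinA_TRD"]].sum() == 3

    def test_marginals_equal_brute_force_recount(self):
        rng = np.random.default_rng(11)
        names = ["CHAP", "LysM", "Amidase_5", "CW_7", "SH3_5"]
        panel = []
        for i in range(40):
            k = int(rng.integers(1, 4))
            layout = [names[j] for j in rng.choice(5, size=k, replace=False)]
            panel.append(self._arch(" & ".join(layout), f"p{i}"))
        _, marginal = upset_table(panel)
        for d in marginal.index:
            brute = sum(1 for a in panel if d in a.domain_names)
            assert marginal[d] == brute

    def test_cbd_less_partner_reporting(self):
        phages = {
            "g1": [self._arch("Amidase_5 & NLPC_P60 & ZoocinA_TRD", "e1"),
                   self._arch("ZoocinA_TRD", "e2")],
            "g2": [self._arch("CW_7", "e3")],
            "g3": [self._arch("CHAP", "e4"), self._arch("NLPC_P60", "e5")],
        }
        for g in phages.values():
            rank_architectures([a for v in phages.values() for a in v])
        report = flag_and_cooccur(phages)
        no_ead = report["no_EAD"].set_index("protein_id")
        # the CBD-only endolysin co-encoded with an active one lists its partner
        assert no_ead.loc["e2", "partners"] != ""
        # the lone CBD-only endolysin is an exception needing supplemental evidence
        assert list(report["exceptions"]["protein_id"]) == ["e3"]
        # both no-CBD endolysins of g3 are flagged
        g3 = report["no_CBD"][report["no_CBD"]["genome_id"] == "g3"]
        assert set(g3["protein_id"]) == {"e4", "e5"}


def test_zero_noise_panel_architectures_match_planted_truth(five_org_panel):
    from lysmod.architecture import resolve_overlaps

    truth = five_org_panel["truth"]
    by_protein = five_org_panel["hits_by_protein"]
    canonicals = set()
    for pid, layout in truth.endolysins.items():
        arch = build_architecture(pid, resolve_overlaps(by_protein.get(pid, [])))
        assert arch.domain_names == layout
        canonicals.add(arch.canonical)
    assert len(canonicals) == len({tuple(v) for v in truth.endolysins.values()})
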