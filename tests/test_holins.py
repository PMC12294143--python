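"""Hydropathy profiles, TMD calling, family assignment, consistency reports."""
import numpy as np
import pandas as pd
import pytest

from lysmod.holins import (HydropathyParams, assign_family, hydropathy_profile,
                           predict_tmds, profile_holins,
                           tandem_and_consistency_report)
from lysmod.model import HolinProfile
from lysmod.simulate import FAMILIES_BY_TMD, PanelSpec, generate_holin_protein, generate_panel


class TestHydropathyProfile:
    def test_poly_leucine_center_equals_scale_value(self):
        series = hydropathy_profile("L" * 19)
        assert series[9] == pytest.approx(3.8)  # Kyte-Doolittle L
        assert len(series) == 19

    def test_charged_stretch_is_everywhere_negative(self):
        series = hydropathy_profile("KD" * 20)
        assert (series < 0).all()

    def test_truncated_end_windows_are_finite(self):
        series = hydropathy_profile("L" * 30)
        assert np.isfinite(series).all()
        assert len(series) == 30

    def test_protein_shorter_than_window_collapses_to_global_mean(self):
        series = hydropathy_profile("LLLKKK")
        assert np.allclose(series, series[0])

    def test_unknown_residue_scored_zero_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            series = hydropathy_profile("X" * 25)
        assert np.allclose(series, 0.0)
        assert any("unknown residue" in r.message for r in caplog.records)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HydropathyParams(window=18)
        with pytest.raises(ValueError):
            HydropathyParams(window=3)


class TestPredictTmds:
    @pytest.mark.parametrize("n_tmds", [1, 2, 3])
    def test_planted_helix_count_recovered(self, n_tmds):
        seq, _ = generate_holin_protein(n_tmds, seed=100 + n_tmds)
        assert predict_tmds(seq).tmd_count == n_tmds

    def test_all_hydrophilic_protein_has_no_tmd(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            prof = predict_tmds("SNKDE" * 20, protein_id="p0")
        assert prof.tmd_count == 0
        assert any("no-TMD" in r.message for r in caplog.records)

    def test_invariant_to_flanking_hydrophilic_padding(self):
        seq, _ = generate_holin_protein(2, seed=12)
        padded = "SNKDESNKDE" + seq + "SNKDESNKDE"
        assert predict_tmds(seq).tmd_count == predict_tmds(padded).tmd_count == 2

    def test_full_synthetic_panel_recovery(self):
        hits = 0
        total = 0
        for seed in range(40):
            for n in (1, 2, 3):
                seq, _ = generate_holin_protein(n, seed=1000 * n + seed)
                total += 1
                hits += predict_tmds(seq).tmd_count == n
        assert hits == total


class TestAssignFamily:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["qseqid", "sseqid", "evalue", "bitscore"])

    def test_best_hit_family_extracted_from_accession(self):
        t = self.table([("h1", "1.E.10.1.2", 1e-12, 150.0)])
        assert assign_family("h1", t) == "1.E.10"

    def test_hit_above_cutoff_is_unclassified(self):
        t = self.table([("h1", "1.E.10.1.2", 0.2, 30.0)])
        assert assign_family("h1", t) == "unclassified"

    def test_evalue_tie_broken_by_bit_score(self):
        t = self.table([("h1", "1.E.10.1.2", 1e-10, 100.0),
                        ("h1", "1.E.16.2.1", 1e-10, 200.0)])
        assert assign_family("h1", t) == "1.E.16"

    def test_malformed_subject_skipped(self):
        t = self.table([("h1", "garbage", 1e-12, 100.0),
                        ("h1", "1.E.24.1.1", 1e-8, 90.0)])
        assert assign_family("h1", t) == "1.E.24"

    def test_permutation_invariance(self):
        rows = [("h1", "1.E.10.1.2", 1e-10, 100.0),
                ("h1", "1.E.16.2.1", 1e-12, 90.0),
                ("h1", "1.E.24.1.1", 1e-8, 300.0)]
        fams = {assign_family("h1", self.table(perm))
                for perm in ([rows[0], rows[1], rows[2]],
                             [rows[2], rows[0], rows[1]],
                             [rows[1], rows[2], rows[0]])}
        assert fams == {"1.E.16"}


class TestTandemAndConsistency:
    def prof(self, pid, gid, n, fam):
        return HolinProfile(protein_id=pid, genome_id=gid,
                            tmd_segments=[(10 + 30 * i, 30 + 30 * i) for i in range(n)],
                            tcdb_family=fam)

    def test_two_holin_genome_with_distinct_families_passes(self):
        rep = tandem_and_consistency_report([
            self.prof("a", "g1", 3, "1.E.10"), self.prof("b", "g1", 3, "1.E.16")])
        assert list(rep["tandem"]["status"]) == ["pass"]

    def test_same_family_pair_is_violation(self):
        rep = tandem_and_consistency_report([
            self.prof("a", "g1", 2, "1.E.11"), self.prof("b", "g1", 2, "1.E.11")])
        assert list(rep["tandem"]["status"]) == ["violation"]

    def test_unclassified_pair_is_indeterminate(self):
        rep = tandem_and_consistency_report([
            self.prof("a", "g1", 1, "unclassified"), self.prof("b", "g1", 1, "1.E.26")])
        assert list(rep["tandem"]["status"]) == ["indeterminate"]

    def test_family_tmd_count_conservation(self):
        rep = tandem_and_consistency_report([
            self.prof("a", "g1", 2, "1.E.11"), self.prof("b", "g2", 2, "1.E.11"),
            self.prof("c", "g3", 2, "1.E.11")])
        fam = rep["family_consistency"]
        assert list(fam["status"]) == ["pass"]

    def test_mixed_counts_within_family_reported_as_violation(self):
        rep = tandem_and_consistency_report([
            self.prof("a", "g1", 2, "1.E.11"), self.prof("b", "g2", 3, "1.E.11")])
        fam = rep["family_consistency"]
        assert list(fam["status"]) == ["violation"]
        assert fam.iloc[0]["tmd_counts"] == "2,3"

    def test_single_tmd_double_holin_genomes_listed(self):
        rep = tandem_and_consistency_report([
            self.prof("a", "g1", 1, "1.E.26"), self.prof("b", "g1", 1, "1.E.65"),
            self.prof("c", "g2", 3, "1.E.10"), self.prof("d", "g2", 1, "1.E.26")])
        assert rep["single_tmd_double_holin_genomes"] == ["g1"]


def test_panel_holins_recover_planted_counts_and_families(five_org_panel):
    truth = five_org_panel["truth"]
    evidence = five_org_panel["evidence"]
    proteins = {
        f.feature_id: (g.accession, f.protein_seq)
        for g in five_org_panel["genomes"] for f in g.features
        if truth.roles[f.feature_id] == "holin"
    }
    profiles = profile_holins(proteins, tcdb_hits=evidence.tcdb_hits)
    assert profiles
    for p in profiles:
        t = truth.holins[p.protein_id]
        assert p.tmd_count == t["tmd_count"]
        assert p.tcdb_family == t["family"]
    # planted panel respects the family -> TMD-count coupling
    rep = tandem_and_consistency_report(profiles)
    assert (rep["family_consistency"]["status"] == "pass").all()


def test_tmd_override_table_replaces_prediction():
    seq, _ = generate_holin_protein(3, seed=77)
    overrides = pd.DataFrame([{"protein_id": "h1", "tmd_from": 5, "tmd_to": 25}])
    profiles = profile_holins({"h1": ("g1", seq)}, tmd_overrides=overrides)
    assert profiles[0].tmd_segments == [(5, 25)]
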