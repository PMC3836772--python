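"""Empirical survey: quality filters, regions, grids, RSA reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from maxasa import geometry as geo, normtables, scan, survey
from maxasa.geometry import BackboneConformation


def _chain(n, seq=None, bonds=None):
    """A fake parsed chain with controllable peptide-bond lengths."""
    seq = seq or "A" * n
    residues = []
    x = 0.0
    for i in range(n):
        # place residues along x so that bond C(i)-N(i+1) has the requested
        # length; intra-residue geometry is irrelevant for the bond screen
        atoms = [geo.AtomSite("N", "N", (x, 0, 0)),
                 geo.AtomSite("CA", "C", (x + 1.0, 0.4, 0)),
                 geo.AtomSite("C", "C", (x + 2.0, 0, 0)),
                 geo.AtomSite("O", "O", (x + 2.2, -1.1, 0)),
                 geo.AtomSite("CB", "C", (x + 1.0, 1.2, 1.0))]
        if seq[i] == "G":
            atoms = atoms[:4]
        residues.append({"resseq": i + 1, "aa": seq[i], "atoms": atoms,
                         "occupancies": [1.0] * len(atoms)})
        bond = bonds[i] if bonds and i < len(bonds) else 1.33
        x += 2.0 + bond
    return residues


class TestFlagChainTerminators:
    def test_uniform_bonds_flag_only_ends(self):
        flags = survey.flag_chain_terminators(_chain(10))
        assert flags == {0, 9}

    def test_outlier_bond_flags_adjacent_pair(self):
        # one 10 A bond among 100 uniform 1.33 A bonds; the z-score
        # against the hand-computed mean/SD exceeds 6
        bonds = [1.33] * 100
        bonds[40] = 10.0
        arr = np.array(bonds)
        z = (10.0 - arr.mean()) / arr.std()
        assert z > 6
        flags = survey.flag_chain_terminators(_chain(101, bonds=bonds))
        assert flags == {0, 40, 41, 100}

    def test_three_residue_chain_keeps_middle(self):
        assert survey.flag_chain_terminators(_chain(3)) == {0, 2}

    def test_too_short_chain_fully_flagged(self):
        assert survey.flag_chain_terminators(_chain(2)) == {0, 1}


class TestFlagQuality:
    def test_clean_chain_unflagged(self):
        assert survey.flag_quality(_chain(5)) == set()

    def test_ambiguous_occupancy_flags_neighbours(self):
        residues = _chain(7)
        residues[3]["occupancies"][0] = 0.5
        assert survey.flag_quality(residues) == {2, 3, 4}

    def test_missing_sidechain_atom_flags_neighbours(self):
        residues = _chain(7)
        residues[2]["atoms"] = residues[2]["atoms"][:4]   # drop Ala CB
        assert survey.flag_quality(residues) == {1, 2, 3}

    def test_edge_defect_clipped(self):
        residues = _chain(5)
        residues[0]["occupancies"][1] = 0.8
        assert survey.flag_quality(residues) == {0, 1}


class TestDefineRegions:
    def test_single_bin_holds_everything(self):
        region = survey.define_regions({(0.0, 0.0): 50}, coverage=0.8)
        assert region.bins == frozenset({(0.0, 0.0)})

    def test_uniform_counts_need_all_bins(self):
        counts = {(float(20 * i), 0.0): 5 for i in range(10)}
        region = survey.define_regions(counts, coverage=0.97)
        assert len(region.bins) == 10

    def test_full_coverage_returns_all_nonempty(self):
        counts = {(0.0, 0.0): 99, (20.0, 0.0): 1}
        region = survey.define_regions(counts, coverage=1.0)
        assert region.bins == frozenset(counts)

    def test_threshold_selects_dense_bins(self):
        counts = {(0.0, 0.0): 80, (20.0, 0.0): 17, (40.0, 0.0): 3}
        core = survey.define_regions(counts, coverage=0.80, kind="CORE")
        assert core.bins == frozenset({(0.0, 0.0)})
        allowed = survey.define_regions(counts, coverage=0.97)
        assert allowed.bins == frozenset({(0.0, 0.0), (20.0, 0.0)})

    def test_generous_dilates_on_torus(self):
        counts = {(-180.0, 0.0): 10}
        gen = survey.define_regions(counts, kind="GENEROUS",
                                    bin_width=20.0, extension=20.0)
        assert (160.0, 0.0) in gen.bins        # wrapped neighbour
        assert (-180.0, 20.0) in gen.bins
        assert len(gen.bins) == 5

    def test_invalid_coverage(self):
        with pytest.raises(ValueError):
            survey.define_regions({(0.0, 0.0): 1}, coverage=1.5)
        with pytest.raises(ValueError):
            survey.define_regions({})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=500),
                    min_size=1, max_size=40))
    def test_region_nesting_property(self, raw_counts):
        """CORE is contained in ALLOWED is contained in GENEROUS."""
        counts = {(float(20 * (i % 18) - 180), float(20 * (i // 18) - 180)): c
                  for i, c in enumerate(raw_counts)}
        core = survey.define_regions(counts, coverage=0.80, kind="CORE")
        allowed = survey.define_regions(counts, coverage=0.97, kind="ALLOWED")
        generous = survey.define_regions(counts, kind="GENEROUS")
        every = survey.define_regions(counts, kind="ALL")
        assert core.bins <= allowed.bins <= generous.bins
        assert allowed.bins <= every.bins


class TestObservationPipeline:
    def test_planted_flags_recovered(self, corpus, observations):
        _, truth = corpus
        for name, t in truth["structures"].items():
            sub = observations[observations.structure == name]
            got = set(sub[sub.flag_terminal | sub.flag_quality].position - 1)
            # first/last residues never enter the table (no phi or no psi)
            expected = {p for p in t["expected_flagged"]
                        if p in set(sub.position - 1)}
            assert got == expected

    def test_ground_truth_recovered_exactly(self, corpus, observations):
        """phi, psi and ASA match values computed outside the reader."""
        _, truth = corpus
        uf = survey.unflagged(observations)
        assert len(uf) > 50
        for row in uf.itertuples():
            ref = truth["structures"][row.structure]["residues"][row.position - 1]
            assert row.aa == ref["aa"]
            assert row.phi == pytest.approx(ref["phi"], abs=1e-9)
            assert row.psi == pytest.approx(ref["psi"], abs=1e-9)
            assert row.asa == pytest.approx(ref["asa"], abs=1e-9)

    def test_pipeline_deterministic(self, corpus, observations):
        root, _ = corpus
        again = survey.collect_observations(root)
        pd.testing.assert_frame_equal(observations, again)

    def test_empirical_max_grid_recovery(self, corpus, observations):
        """Per-bin maxima equal the ground-truth maxima exactly."""
        _, truth = corpus
        uf = survey.unflagged(observations)
        aa = uf.aa.value_counts().idxmax()
        grid = survey.empirical_max_grid(observations, aa, bin_width=20.0)
        expected = {}
        for name, t in truth["structures"].items():
            sub = uf[uf.structure == name]
            for row in sub.itertuples():
                ref = t["residues"][row.position - 1]
                if ref["aa"] != aa:
                    continue
                key = (float(survey.bin_origin(ref["phi"], 20.0)),
                       float(survey.bin_origin(ref["psi"], 20.0)))
                expected[key] = max(expected.get(key, 0.0), ref["asa"])
        assert set(grid.cells) == set(expected)
        for key, want in expected.items():
            assert grid.cells[key]["asa"] == pytest.approx(want, abs=1e-9)

    def test_empirical_never_exceeds_theory_on_matched_bins(
            self, observations, ala_grid):
        """Observed Ala ASA never beats the tripeptide bound per bin."""
        uf = survey.unflagged(observations)
        sub = uf[uf.aa == "A"]
        if sub.empty:
            pytest.skip("corpus drew no unflagged alanines")
        width = 20.0
        # theoretical per-20-degree-bin maxima from the 5-degree grid
        theo = {}
        for (p, s), c in ala_grid.cells.items():
            key = (float(survey.bin_origin(p, width)),
                   float(survey.bin_origin(s, width)))
            theo[key] = max(theo.get(key, 0.0), c["asa"])
        for row in sub.itertuples():
            key = (float(survey.bin_origin(row.phi, width)),
                   float(survey.bin_origin(row.psi, width)))
            assert key in theo
            assert row.asa <= theo[key] + 1.0


class TestRsa:
    def test_identity_and_zero(self):
        rose = normtables.get_scale("rose1985")
        assert survey.rsa(rose["A"], "A", rose) == pytest.approx(1.0)
        assert survey.rsa(0.0, "W", rose) == 0.0

    def test_can_exceed_one(self):
        miller = normtables.get_scale("miller1987")
        assert survey.rsa(135.6, "A", miller) == pytest.approx(1.2, abs=0.01)

    def test_missing_amino_acid(self):
        with pytest.raises(KeyError):
            survey.rsa(10.0, "A", {"G": 104.0})

    def test_negative_asa_rejected(self):
        with pytest.raises(ValueError):
            survey.rsa(-1.0, "A", normtables.get_scale("rose1985"))


class TestExceedanceReport:
    def _obs(self, asa_by_aa):
        rows = []
        for aa, asas in asa_by_aa.items():
            for i, a in enumerate(asas):
                rows.append(("s", "A", i + 2, aa, -60.0, -40.0, a,
                             "unknown", False, False))
        return pd.DataFrame(rows, columns=survey.OBS_COLUMNS)

    def test_planted_fractions(self):
        obs = self._obs({"A": [50.0, 130.0, 110.0, 100.0],
                         "G": [90.0, 80.0]})
        scales = {"miller": normtables.get_scale("miller1987")}
        rep = survey.rsa_exceedance_report(obs, scales)
        assert rep.loc["A", "miller"] == pytest.approx(0.25)   # only 130 > 113
        assert rep.loc["G", "miller"] == pytest.approx(0.5)    # 90 > 85

    def test_zero_asa_corpus(self):
        obs = self._obs({"A": [0.0, 0.0], "G": [0.0]})
        rep = survey.rsa_exceedance_report(
            obs, {"rose": normtables.get_scale("rose1985")})
        assert (rep["rose"] == 0).all()

    def test_halved_scale_monotone(self):
        obs = self._obs({"A": [50.0, 130.0, 110.0], "G": [90.0, 40.0]})
        full = normtables.get_scale("miller1987")
        halved = {aa: v / 2 for aa, v in full.values_by_aa.items()}
        rep = survey.rsa_exceedance_report(obs, {"full": full, "half": halved})
        assert (rep["half"] >= rep["full"]).all()
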