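import numpy as np
import pytest

from protmod import fixtures
from protmod.backbone import backbone_from_chain, backbone_from_torsions, ca_rmsd
from protmod.io_formats import Alignment, attach_view, write_structure
from protmod.modelling import (Gap, ModellingError, PipelineConfig,
                               build_from_raw_model, build_raw_model,
                               extend_gap, fill_loops_by_database,
                               fill_loops_monte_carlo, handle_deletions,
                               regularize)
from protmod.scoring import train_potentials


def _identity_alignment(bb):
    tpl = fixtures.structure_from_backbone(bb)
    aln = Alignment([bb.sequence, bb.sequence])
    attach_view(aln, 1, tpl, "A")
    return aln


@pytest.fixture(scope="module")
def db_tables():
    homologue = fixtures.helix_loop_helix(30, seed=10)
    others = [fixtures.make_ideal_helix(30, seed=k) for k in (1, 2)]
    sdb, fdb = fixtures.make_mini_db([homologue] + others, lengths=range(3, 9))
    cbeta, reduced, torsion, packing = train_potentials(sdb)
    tables = {"cbeta": cbeta, "reduced": reduced, "torsion": torsion,
              "packing": packing}
    return sdb, fdb, tables


class TestBuildRawModel:
    def test_identity_preserves_coordinates(self, hlh24):
        mh = build_raw_model(_identity_alignment(hlh24))
        assert len(mh.gaps) == 0
        assert mh.present.all()
        assert np.array_equal(mh.ca, hlh24.ca)
        assert np.array_equal(mh.n, hlh24.n)

    def test_deletion_gap(self, hlh24):
        tpl = fixtures.structure_from_backbone(hlh24)
        seq = hlh24.sequence
        tgt = seq[:12] + seq[13:]
        aln = Alignment([tgt[:12] + "-" + tgt[12:], seq])
        attach_view(aln, 1, tpl, "A")
        mh = build_raw_model(aln)
        assert mh.gaps == [Gap(11, 12, "")]

    def test_insertion_gap(self, hlh24):
        tpl = fixtures.structure_from_backbone(hlh24)
        seq = hlh24.sequence
        tgt = seq[:12] + "EF" + seq[12:]
        aln = Alignment([tgt, seq[:12] + "--" + seq[12:]])
        attach_view(aln, 1, tpl, "A")
        mh = build_raw_model(aln)
        assert len(mh.gaps) == 1
        gap = mh.gaps[0]
        assert gap.target_seq == "EF"
        assert (gap.before, gap.after) == (11, 14)

    def test_terminal_overhang_gap(self, hlh24):
        tpl = fixtures.structure_from_backbone(hlh24)
        seq = hlh24.sequence
        tgt = "MM" + seq
        aln = Alignment([tgt, "--" + seq])
        attach_view(aln, 1, tpl, "A")
        mh = build_raw_model(aln)
        assert mh.gaps[0].before == -1
        assert mh.gaps[0].target_seq == "MM"

    def test_mismatched_residue_stripped_to_cb(self, hlh24):
        tpl = fixtures.structure_from_backbone(hlh24)
        # put a sidechain on the template residue 5
        from protmod.sidechain import build_rotamer
        res = tpl.chains[0].residues[5]
        frame = {"N": hlh24.n[5], "CA": hlh24.ca[5], "C": hlh24.c[5],
                 "CB": hlh24.cb[5]}
        rot = build_rotamer("L", frame, [-65.0, 175.0])
        res.name = "LEU"
        for name, pos in zip(rot.atom_names, rot.positions):
            res.atoms[name] = pos
        seq = tpl.chains[0].one_letter_sequence
        tgt = seq[:5] + "V" + seq[6:]  # different aa at 5
        aln = Alignment([tgt, seq])
        attach_view(aln, 1, tpl, "A")
        mh = build_raw_model(aln)
        assert 5 not in mh.sidechains
        assert not np.isnan(mh.cb[5]).any()

    def test_identical_residue_keeps_sidechain(self, hlh24):
        tpl = fixtures.structure_from_backbone(hlh24)
        from protmod.sidechain import build_rotamer
        res = tpl.chains[0].residues[5]
        frame = {"N": hlh24.n[5], "CA": hlh24.ca[5], "C": hlh24.c[5],
                 "CB": hlh24.cb[5]}
        rot = build_rotamer("L", frame, [-65.0, 175.0])
        res.name = "LEU"
        for name, pos in zip(rot.atom_names, rot.positions):
            res.atoms[name] = pos
        seq = tpl.chains[0].one_letter_sequence
        aln = Alignment([seq, seq])
        attach_view(aln, 1, tpl, "A")
        mh = build_raw_model(aln)
        assert "CG" in mh.sidechains[5]

    def test_no_attachment_error(self, hlh24):
        aln = Alignment([hlh24.sequence, hlh24.sequence])
        with pytest.raises(ValueError, match="attached"):
            build_raw_model(aln)


class TestHandleDeletions:
    def _deletion_case(self, tpl_bb, pos):
        tpl = fixtures.structure_from_backbone(tpl_bb)
        seq = tpl_bb.sequence
        tgt = seq[:pos] + seq[pos + 1:]
        aln = Alignment([tgt[:pos] + "-" + tgt[pos:], seq])
        attach_view(aln, 1, tpl, "A")
        return build_raw_model(aln)

    def test_flexible_coil_resolved(self, slack_coil_template):
        mh = self._deletion_case(slack_coil_template, 12)
        handle_deletions(mh, PipelineConfig())
        assert mh.gaps == []
        # model is continuous: peptide bonds in range
        bb = mh.backbone_view(0, len(mh))
        for i in range(len(bb) - 1):
            assert 1.2 <= np.linalg.norm(bb.n[i + 1] - bb.c[i]) <= 1.5

    def test_helix_core_retained(self):
        mh = self._deletion_case(fixtures.make_ideal_helix(20), 10)
        handle_deletions(mh, PipelineConfig())
        assert len(mh.gaps) == 1

    def test_no_deletions_noop(self, hlh24):
        mh = build_raw_model(_identity_alignment(hlh24))
        before = mh.ca.copy()
        handle_deletions(mh, PipelineConfig())
        assert np.array_equal(mh.ca, before)


class TestExtendGap:
    def _handle_with_ss(self, n=24):
        bb = fixtures.helix_loop_helix(n, seed=3)
        mh = build_raw_model(_identity_alignment(bb))
        return mh

    def test_lengths_ordered(self):
        mh = self._handle_with_ss()
        mh.ss = ["C"] * len(mh)
        gap = Gap(9, 13, mh.target_seq[10:13])
        extents = extend_gap(gap, mh, 5)
        lengths = [e.after - e.before - 1 for e in extents]
        assert lengths == sorted(lengths)
        assert lengths[0] == 3
        assert sorted(lengths) == [3, 4, 4, 5, 5, 5]

    def test_coil_preferred_over_helix(self):
        mh = self._handle_with_ss()
        # N-side helix, C-side coil
        mh.ss = ["H"] * 12 + ["C"] * 12
        gap = Gap(11, 14, mh.target_seq[12:14])
        extents = extend_gap(gap, mh, 4)
        # among length-3 extents, the C-side (coil-consuming) one comes first
        len3 = [e for e in extents if e.after - e.before - 1 == 3]
        assert len3[0].after == 15  # consumed C-side coil residue

    def test_n_side_tie_break(self):
        mh = self._handle_with_ss()
        mh.ss = ["C"] * len(mh)
        gap = Gap(9, 13, mh.target_seq[10:13])
        extents = extend_gap(gap, mh, 4)
        len4 = [e for e in extents if e.after - e.before - 1 == 4]
        assert len4[0].before == 8  # N-side extension first on ties

    def test_over_cap_empty(self):
        mh = self._handle_with_ss()
        gap = Gap(9, 16, mh.target_seq[10:16])
        assert extend_gap(gap, mh, 4) == []


class TestFillLoopsByDatabase:
    def test_native_loop_recovered(self, db_tables):
        sdb, fdb, tables = db_tables
        target_bb = fixtures.helix_loop_helix(30, seed=10)
        s = fixtures.structure_from_backbone(target_bb)
        mh, ref = fixtures.make_loop_case(s, (13, 17))
        fill_loops_by_database(mh, fdb, sdb, tables, PipelineConfig())
        assert mh.gaps == []
        filled = mh.backbone_view(12, 18)
        assert ca_rmsd(filled, ref) < 0.5

    def test_empty_fragdb_unresolved(self, db_tables):
        sdb, _, tables = db_tables
        from protmod.fragdb import FragDB
        target_bb = fixtures.helix_loop_helix(30, seed=10)
        s = fixtures.structure_from_backbone(target_bb)
        mh, _ = fixtures.make_loop_case(s, (13, 17))
        fill_loops_by_database(mh, FragDB(), sdb, tables, PipelineConfig())
        assert len(mh.gaps) == 1

    def test_deterministic(self, db_tables):
        sdb, fdb, tables = db_tables
        target_bb = fixtures.helix_loop_helix(30, seed=10)
        s = fixtures.structure_from_backbone(target_bb)
        mh1, _ = fixtures.make_loop_case(s, (13, 17))
        mh2, _ = fixtures.make_loop_case(s, (13, 17))
        fill_loops_by_database(mh1, fdb, sdb, tables, PipelineConfig())
        fill_loops_by_database(mh2, fdb, sdb, tables, PipelineConfig())
        assert np.array_equal(mh1.ca, mh2.ca)

    def test_outside_gap_untouched(self, db_tables):
        sdb, fdb, tables = db_tables
        target_bb = fixtures.helix_loop_helix(30, seed=10)
        s = fixtures.structure_from_backbone(target_bb)
        mh, _ = fixtures.make_loop_case(s, (13, 17))
        before = mh.ca.copy()
        fill_loops_by_database(mh, fdb, sdb, tables, PipelineConfig())
        # residues outside the widest possible extent are untouched
        assert np.array_equal(mh.ca[:5], before[:5])
        assert np.array_equal(mh.ca[-5:], before[-5:])


class TestFillLoopsMonteCarlo:
    def test_seeded_reproducible(self, db_tables):
        sdb, _, tables = db_tables
        target_bb = fixtures.helix_loop_helix(24, seed=5)
        s = fixtures.structure_from_backbone(target_bb)
        cfg = PipelineConfig(mc_sweeps=10)
        results = []
        for _ in range(2):
            mh, _ = fixtures.make_loop_case(s, (10, 14))
            fill_loops_monte_carlo(mh, tables["torsion"], tables, cfg, seed=3)
            results.append(mh.ca.copy())
        assert np.array_equal(results[0], results[1], equal_nan=True)

    def test_zero_sweeps_keeps_gap_open_or_closes_initial(self, db_tables):
        sdb, _, tables = db_tables
        target_bb = fixtures.helix_loop_helix(24, seed=5)
        s = fixtures.structure_from_backbone(target_bb)
        mh, _ = fixtures.make_loop_case(s, (10, 14))
        cfg = PipelineConfig(mc_sweeps=12)
        fill_loops_monte_carlo(mh, tables["torsion"], tables, cfg, seed=1)
        if not mh.gaps:  # closed: continuity restored
            bb = mh.backbone_view(9, 15)
            for i in range(len(bb) - 1):
                assert 1.2 <= np.linalg.norm(bb.n[i + 1] - bb.c[i]) <= 1.5


class TestRegularize:
    def test_ideal_unchanged(self, helix10):
        s = fixtures.structure_from_backbone(helix10)
        out = regularize(s)
        for r1, r2 in zip(s.chains[0].residues, out.chains[0].residues):
            for name in r1.atoms:
                assert np.abs(np.asarray(r1.atoms[name])
                              - np.asarray(r2.atoms[name])).max() < 0.05

    def test_stretched_bond_restored(self, helix10):
        s = fixtures.structure_from_backbone(helix10)
        r4 = s.chains[0].residues[4]
        r3 = s.chains[0].residues[3]
        direction = (np.asarray(r4.atoms["N"]) - np.asarray(r3.atoms["C"]))
        direction /= np.linalg.norm(direction)
        r4.atoms["N"] = np.asarray(r3.atoms["C"]) + 1.6 * direction
        out = regularize(s)
        d = np.linalg.norm(np.asarray(out.chains[0].residues[4].atoms["N"])
                           - np.asarray(out.chains[0].residues[3].atoms["C"]))
        assert d == pytest.approx(1.329, abs=0.05)

    def test_ca_cap(self, helix10):
        s = fixtures.structure_from_backbone(helix10)
        # grossly stretch one residue
        for name in ("N", "CA", "C", "O"):
            s.chains[0].residues[5].atoms[name] = \
                np.asarray(s.chains[0].residues[5].atoms[name]) + 0.8
        out = regularize(s)
        for r_in, r_out in zip(s.chains[0].residues, out.chains[0].residues):
            d = np.linalg.norm(np.asarray(r_in.atoms["CA"])
                               - np.asarray(r_out.atoms["CA"]))
            assert d <= 0.5 + 1e-9


class TestBuildFromRawModel:
    def test_identity_pipeline(self, hlh24, mini_lib):
        mh = build_raw_model(_identity_alignment(hlh24))
        model = build_from_raw_model(mh, PipelineConfig(), mini_lib)
        out_bb = backbone_from_chain(model, "A")
        assert ca_rmsd(out_bb, hlh24) <= 0.5
        assert out_bb.sequence == hlh24.sequence

    def test_deterministic_reruns(self, hlh24, mini_lib, tmp_path):
        texts = []
        for _ in range(2):
            mh = build_raw_model(_identity_alignment(hlh24))
            model = build_from_raw_model(mh, PipelineConfig(seed=4), mini_lib)
            p = tmp_path / "m.pdb"
            write_structure(model, str(p))
            texts.append(p.read_text())
        assert texts[0] == texts[1]

    def test_unresolved_gap_raises(self, mini_lib):
        # helix-core deletion cannot be bridged and no dbs/MC success:
        # an impossible 0-residue bridge across a huge break
        bb = fixtures.make_ideal_helix(20)
        tpl = fixtures.structure_from_backbone(bb)
        seq = bb.sequence
        # remove 6 helix residues -> far anchors, no database
        tgt = seq[:7] + seq[13:]
        aln = Alignment([tgt[:7] + "------" + tgt[7:], seq])
        attach_view(aln, 1, tpl, "A")
        mh = build_raw_model(aln)
        cfg = PipelineConfig(mc_sweeps=2)
        with pytest.raises(ModellingError, match="unresolved"):
            build_from_raw_model(mh, cfg, mini_lib)
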