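"""Reaction state machine: stages, cut/link bookkeeping, products and repair."""

import pytest

import bridgekit as bk
from bridgekit.recombine import ProductsUnavailable, Stage, StepWarning

_RC = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def splice_oracle(t_top: str, d_top: str):
    """Independent concatenate-and-cut oracle for the two junction windows.

    Top strands cross over between positions 9|10, bottom strands between
    starred 9*|10*.
    """
    return {
        "A": (t_top[:9] + d_top[9:], rc(d_top)[:9] + rc(t_top)[9:]),
        "B": (d_top[:9] + t_top[9:], rc(t_top)[:9] + rc(d_top)[9:]),
    }


class TestSynapsis:
    def test_target_donor_synapses_with_four_protomers(self, designed, target_window, donor_window):
        b, _ = designed
        state = bk.form_synapse((b, target_window), (b, donor_window))
        assert state.stage is Stage.SYNAPSED
        assert set(state.protomers) == {1, 2, 3, 4}

    def test_two_target_halves_are_refused(self, designed, target_window):
        b, _ = designed
        other = bk.make_window("TTCAGATCTTGATT", role="target")
        with pytest.raises(bk.SynapsisError, match="DBL-SL"):
            bk.form_synapse((b, target_window), (b, other))

    def test_two_donor_halves_synapse_with_a_provenance_note(self, designed, donor_window):
        b, _ = designed
        other = bk.make_window("ACGTACGCTGACTA", role="donor")
        state = bk.form_synapse((b, other), (b, donor_window))
        assert state.stage is Stage.SYNAPSED
        assert "donor-donor" in state.provenance


class TestTrajectory:
    def test_post_hsb_design_visits_all_productive_stages(self, designed, target_window, donor_window):
        b, _ = designed
        traj = bk.run(bk.form_synapse((b, target_window), (b, donor_window)))
        assert [s.stage for s in traj] == [
            Stage.SYNAPSED,
            Stage.TOP_CLEAVED,
            Stage.HJ_INTERMEDIATE,
            Stage.HJ_RESOLVED,
            Stage.PRODUCTS,
        ]

    def test_top_cuts_and_serine_links_at_top_cleaved(self, designed, target_window, donor_window):
        b, _ = designed
        state = bk.step(bk.form_synapse((b, target_window), (b, donor_window)))
        cuts = {(c.slot, c.strand): (c.five_prime, c.three_prime) for c in state.cuts}
        assert cuts == {("target", "top"): (9, 10), ("donor", "top"): (9, 10)}
        links = {l.serine: (l.slot, l.strand, l.position) for l in state.covalent_links}
        assert links == {
            "S241.4": ("target", "top", 10),
            "S241.2": ("donor", "top", 10),
        }

    def test_bottom_cuts_and_links_at_hj_resolved(self, designed, target_window, donor_window):
        b, _ = designed
        traj = bk.run(bk.form_synapse((b, target_window), (b, donor_window)))
        resolved = next(s for s in traj if s.stage is Stage.HJ_RESOLVED)
        bottom_cuts = {
            (c.slot, c.strand): (c.five_prime, c.three_prime, c.starred)
            for c in resolved.cuts
            if c.strand == "bottom"
        }
        assert bottom_cuts == {
            ("target", "bottom"): (9, 10, True),
            ("donor", "bottom"): (9, 10, True),
        }
        links = {l.serine: (l.slot, l.strand, l.position, l.starred) for l in resolved.covalent_links}
        assert links == {
            "S241.3": ("target", "bottom", 10, True),
            "S241.1": ("donor", "bottom", 10, True),
        }

    def test_active_site_assignment_spans_the_two_dimers(self, designed, target_window, donor_window):
        b, _ = designed
        traj = bk.run(bk.form_synapse((b, target_window), (b, donor_window)))
        sites = {(c.slot, c.strand): c.active_site for s in traj for c in s.cuts}
        assert sites[("target", "top")] == "RuvC.1-Tnp.4"
        assert sites[("donor", "top")] == "RuvC.3-Tnp.2"
        assert sites[("target", "bottom")] == "RuvC.2-Tnp.3"
        assert sites[("donor", "bottom")] == "RuvC.4-Tnp.1"

    def test_pre_hsb_design_locks_and_lock_is_absorbing(self, scaffold177, target_window, donor_window):
        with pytest.warns(Warning):
            b, _ = bk.design_bridge_rna(
                scaffold177, target_window, donor_window, bk.DesignOptions(hsg_mode="pre-hsb")
            )
        traj = bk.run(bk.form_synapse((b, target_window), (b, donor_window)))
        assert traj[-1].stage is Stage.LOCKED
        with pytest.warns(StepWarning):
            assert bk.step(traj[-1]) is traj[-1]

    def test_donor_donor_run_completes(self, designed, donor_window):
        b, _ = designed
        # both halves donor-role; the designed HSG-D pairs target 6-7 which
        # differs from the donor's own 6-7, so no cognate pairing arises
        other = bk.DnaWindow(top=donor_window.top, bottom=donor_window.bottom, role="donor")
        traj = bk.run(bk.form_synapse((b, other), (b, donor_window)))
        assert traj[-1].stage is Stage.PRODUCTS


class TestJunctions:
    def test_worked_example_junction_sequences_and_flags(self, designed, target_window, donor_window):
        b, _ = designed
        ja, jb = bk.run(bk.form_synapse((b, target_window), (b, donor_window)))[-1].junctions()
        assert (ja.top, ja.bottom) == ("ACGTACGCTTGATT", "AATCAAGATTACGT")
        assert (jb.top, jb.bottom) == ("TTCAGATCTGACTA", "TAGTCAGCGCTGAA")
        assert ja.heteroduplex == jb.heteroduplex == frozenset({6, 7})

    def test_identical_windows_give_flag_free_complementary_junctions(self, scaffold177):
        w = bk.make_window("GGAATTCCTGGGCC")
        t = bk.DnaWindow(top=w.top, bottom=w.bottom, role="target")
        d = bk.DnaWindow(top=w.top, bottom=w.bottom, role="donor")
        b, _ = bk.design_bridge_rna(scaffold177, t, d, bk.DesignOptions(hsg_mode="keep-scaffold"))
        # identical windows always cognate-pair under post-HSB programming, so
        # keep the scaffold's HSGs and force them to bases that cannot pair
        # this window's positions 6-7 (C pairs neither C nor T)
        b = b.with_bases({81: "C", 82: "C", 166: "C", 167: "C"})
        traj = bk.run(bk.form_synapse((b, t), (b, d)))
        assert traj[-1].stage is Stage.PRODUCTS
        ja, jb = traj[-1].junctions()
        assert ja.heteroduplex == jb.heteroduplex == frozenset()
        assert ja.as_window().is_complementary()


class TestFullMolecules:
    def test_linear_x_linear_gives_two_products_with_window_6_7_flags(
        self, designed, target_window, donor_window
    ):
        b, _ = designed
        tm = bk.SubstrateMolecule("GGGGG" + target_window.top + "CCCCC", "linear", 6, "target")
        dm = bk.SubstrateMolecule("AAAA" + donor_window.top + "TTTT", "linear", 5, "donor")
        prods = bk.recombine_molecules(tm, dm, b)
        assert len(prods.molecules) == 2
        pa, pb = prods.molecules
        assert pa.top == "GGGGG" + "ACGTACGCT" + "TGATT" + "TTTT"
        assert pb.top == "AAAA" + "TTCAGATCT" + "GACTA" + "CCCCC"
        # heteroduplex flags sit at window positions 6-7 of each junction
        assert pa.heteroduplex == frozenset({5 + 6, 5 + 7})
        assert pb.heteroduplex == frozenset({4 + 6, 4 + 7})
        assert prods.total_top_length == tm.length + dm.length
        assert prods.total_bottom_length == tm.length + dm.length

    def test_circular_donor_integration_conserves_nucleotides(
        self, designed, target_window, donor_window
    ):
        b, _ = designed
        tm = bk.SubstrateMolecule("G" * 18 + target_window.top + "C" * 18, "linear", 19, "target")
        dm = bk.SubstrateMolecule("A" * 30 + donor_window.top + "T" * 16, "circular", 31, "donor")
        prods = bk.recombine_molecules(tm, dm, b)
        (product,) = prods.molecules
        assert product.topology == "linear"
        assert product.length == tm.length + dm.length
        assert {"target", "donor"} == set(product.parents_top)
        # donor block is contiguous and full-length
        donor_run = [i for i, p in enumerate(product.parents_top) if p == "donor"]
        assert len(donor_run) == dm.length
        assert donor_run == list(range(donor_run[0], donor_run[0] + dm.length))

    def test_locked_reaction_raises_with_trajectory(self, scaffold177, target_window, donor_window):
        with pytest.warns(Warning):
            b, _ = bk.design_bridge_rna(
                scaffold177, target_window, donor_window, bk.DesignOptions(hsg_mode="pre-hsb")
            )
        tm = bk.SubstrateMolecule("GGGGG" + target_window.top + "CCCCC", "linear", 6, "target")
        dm = bk.SubstrateMolecule("AAAA" + donor_window.top + "TTTT", "linear", 5, "donor")
        with pytest.raises(ProductsUnavailable) as exc:
            bk.recombine_molecules(tm, dm, b)
        assert exc.value.trajectory[-1].stage is Stage.LOCKED

    def test_excision_yields_circle_plus_shortened_backbone(self, scaffold177):
        t_top = "ACGTACGCTGACTA"
        d_top = "TTCAGATCTTGATT"
        seq = "GG" + t_top + "AAAAAA" + d_top + "CC"
        mol = bk.SubstrateMolecule(seq, "linear", 3, "target")
        b, _ = bk.design_bridge_rna(
            scaffold177,
            bk.make_window(t_top, role="target"),
            bk.make_window(d_top, role="donor"),
        )
        prods = bk.recombine_intramolecular(mol, 3 + 14 + 6, b)
        backbone, circle = prods.molecules
        assert circle.topology == "circular"
        assert backbone.length + circle.length == len(seq)
        # backbone: up to target cut (window pos 9) then from donor cut on
        assert backbone.top == seq[: 2 + 9] + seq[2 + 14 + 6 + 9 :]
        assert circle.top == seq[2 + 9 : 2 + 14 + 6 + 9]

    def test_inversion_reverse_complements_the_intervening_segment(self, scaffold177):
        t_top = "ACGTACGCTGACTA"
        d_top = "TTCAGATCTTGATT"
        spacer = "AAAAAA"
        seq = "GG" + t_top + spacer + rc(d_top) + "CC"
        mol = bk.SubstrateMolecule(seq, "linear", 3, "target")
        b, _ = bk.design_bridge_rna(
            scaffold177,
            bk.make_window(t_top, role="target"),
            bk.make_window(d_top, role="donor"),
        )
        prods = bk.recombine_intramolecular(mol, 3 + 14 + 6, b, inverted=True)
        (product,) = prods.molecules
        assert product.length == len(seq)
        pa = 3
        c1 = pa + 8
        assert product.top[:c1] == seq[:c1]
        # the segment between the crossovers is reverse-complemented in place
        assert product.top[c1 : c1 + 20] == rc(seq[pa + 4 : pa + 24])


class TestRepair:
    @pytest.fixture
    def products(self, designed, target_window, donor_window):
        b, _ = designed
        tm = bk.SubstrateMolecule("GGGGG" + target_window.top + "CCCCC", "linear", 6, "target")
        dm = bk.SubstrateMolecule("AAAA" + donor_window.top + "TTTT", "linear", 5, "donor")
        return bk.recombine_molecules(tm, dm, b)

    def test_top_wins_rewrites_bottom_to_complement(self, products):
        fixed = bk.repair(products, "top-wins")
        ja = fixed.junction_a
        assert ja.heteroduplex == frozenset()
        assert ja.top == products.junction_a.top
        # bottom 9*, 8* now complement target top 6, 7
        assert ja.bottom[8] == "G"  # comp of target top 6 = C
        assert ja.bottom[7] == "C"  # comp of target top 7 = G
        assert all(m.heteroduplex == frozenset() for m in fixed.molecules)

    def test_bottom_wins_rewrites_top(self, products):
        fixed = bk.repair(products, "bottom-wins")
        assert fixed.junction_a.heteroduplex == frozenset()
        assert fixed.junction_a.bottom == products.junction_a.bottom

    def test_leave_returns_input_unchanged(self, products):
        assert bk.repair(products, "leave") is products

    def test_flag_free_products_are_invariant_under_repair(self, products):
        once = bk.repair(products, "top-wins")
        again = bk.repair(once, "top-wins")
        assert again.junction_a == once.junction_a
        assert [m.top for m in again.molecules] == [m.top for m in once.molecules]
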