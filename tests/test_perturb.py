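import numpy as np
import pytest

from cgpathway import (
    EnergyParams,
    MorphConfig,
    MutationError,
    MutationSpec,
    classify,
    ddg_scan,
    evaluate_energy,
    make_interpolating_morph_fn,
    make_toy_two_state,
    mutate_to_ala,
    set_sidechain_from_reference,
)
from cgpathway.perturb import ALA_CB_DISTANCE


def burial_only():
    return EnergyParams(
        contact_epsilon=0.0, repulsion_k=0.0, residue_charges={}
    )


@pytest.fixture
def toy():
    # seed 5: switch TRP at A:7 (helix 1), an ALA at A:9, LEU at A:3
    return make_toy_two_state(24, 10.0, seed=5)


class TestMutateToAla:
    def test_ala_site_is_noop(self, toy, default_params):
        site = MutationSpec("A", 9)
        out = mutate_to_ala(toy.inactive, site)
        assert evaluate_energy(out, default_params).total == evaluate_energy(
            toy.inactive, default_params
        ).total

    def test_burial_difference_closed_form(self):
        from cgpathway.structures import CGStructure, Residue

        p = burial_only()
        r = Residue("A", 1, "", "TRP", np.zeros(3), np.array([0, 0, 1.0]), 5)
        s = CGStructure([r], label="w")
        mut = mutate_to_ala(s, MutationSpec("A", 1))
        delta = (
            evaluate_energy(mut, p).total - evaluate_energy(s, p).total
        )
        assert delta == pytest.approx(
            p.hydrophobicity_scale["ALA"] - p.hydrophobicity_scale["TRP"],
            rel=1e-12,
        )

    def test_locality_and_geometry(self, toy):
        site = MutationSpec("A", 7)
        out = mutate_to_ala(toy.inactive, site)
        diffs = [
            i
            for i, (ra, rb) in enumerate(
                zip(toy.inactive.residues, out.residues)
            )
            if ra.res_name != rb.res_name
            or not np.array_equal(ra.centroid, rb.centroid)
        ]
        idx = toy.inactive.index_of(site.key)
        assert diffs == [idx]
        r = out.residues[idx]
        assert r.res_name == "ALA"
        assert np.linalg.norm(r.centroid - r.ca) == pytest.approx(
            ALA_CB_DISTANCE, rel=1e-9
        )
        # direction preserved
        old = toy.inactive.residues[idx]
        cos = np.dot(r.centroid - r.ca, old.centroid - old.ca) / (
            np.linalg.norm(r.centroid - r.ca)
            * np.linalg.norm(old.centroid - old.ca)
        )
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_absent_site_and_gly(self, toy):
        with pytest.raises(KeyError):
            mutate_to_ala(toy.inactive, MutationSpec("A", 999))
        gly = toy.inactive.copy()
        gly.residues[0].res_name = "GLY"
        gly.residues[0].centroid = None
        gly.residues[0].n_sidechain_atoms = 0
        with pytest.raises(MutationError):
            mutate_to_ala(gly, MutationSpec("A", 1))


class TestRotamerTransfer:
    def test_self_reference_identity(self, toy):
        site = MutationSpec(
            "A", 7, mode="ROTAMER_FROM_REFERENCE", reference_label="x"
        )
        out = set_sidechain_from_reference(toy.inactive, site, toy.inactive)
        idx = toy.inactive.index_of(site.key)
        np.testing.assert_allclose(
            out.residues[idx].centroid,
            toy.inactive.residues[idx].centroid,
            atol=1e-9,
        )

    def test_transfer_contract_local_vector(self, toy):
        site = MutationSpec(
            "A", 7, mode="ROTAMER_FROM_REFERENCE", reference_label="x"
        )
        out = set_sidechain_from_reference(toy.inactive, site, toy.active)
        idx = toy.inactive.index_of(site.key)
        # local backbone window is identical between toy endpoints at the
        # switch site (it sits on the static helix), so the transferred
        # CA->centroid vector must equal the reference's exactly
        got = out.residues[idx].centroid - out.residues[idx].ca
        want = (
            toy.active.residues[idx].centroid - toy.active.residues[idx].ca
        )
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_switch_residue_reaches_active_centroid(self, toy):
        site = MutationSpec(
            "A", 7, mode="ROTAMER_FROM_REFERENCE", reference_label="x"
        )
        out = set_sidechain_from_reference(toy.inactive, site, toy.active)
        idx = toy.inactive.index_of(site.key)
        dist = np.linalg.norm(
            out.residues[idx].centroid - toy.active.residues[idx].centroid
        )
        assert dist < 0.1

    def test_type_mismatch_rejected(self, toy):
        site = MutationSpec(
            "A", 3, mode="ROTAMER_FROM_REFERENCE", reference_label="x"
        )
        ref = toy.active.copy()
        ref.residues[toy.active.index_of(("A", 3, ""))].res_name = "VAL"
        with pytest.raises(MutationError):
            set_sidechain_from_reference(toy.inactive, site, ref)


def planted_scan(toy, sites, tau=0.25):
    """Run a ddG scan on a pathway with a planted mid-path membrane exit.

    Two residues leave the membrane slab only in transition-region
    frames: the switch tryptophan (the scanned site, contributing
    +2.09 kcal/mol to the barrier) and a leucine anchor that gives the
    mutant profile a transition state of its own.  Only those two
    residues carry transfer free energies, so the planted contribution
    is recovered exactly.
    """
    p = EnergyParams(
        contact_epsilon=0.0,
        repulsion_k=0.0,
        residue_charges={},
        hydrophobicity_scale={"TRP": -2.09, "LEU": -1.25},
    )
    lifts = {toy.switch_residue: 40.0, ("A", 3, ""): 40.0}
    fn = make_interpolating_morph_fn(lifts=lifts)
    cfg = MorphConfig(n_steps=61)
    return ddg_scan(
        toy.inactive, toy.active, sites, p, cfg,
        tau=tau, n_intermediates=31, morph_fn=fn, endpoint_relax_iters=0,
    ), p


class TestDDGScan:
    def test_empty_site_list(self, toy):
        report, _ = planted_scan(toy, [])
        assert report.results == []
        assert "TS1" in report.wt_barriers

    def test_identity_mutation_exactly_zero(self, toy):
        report, _ = planted_scan(toy, [MutationSpec("A", 9)])
        recs = report.results[0].ts_records
        assert recs, "wild-type pipeline found no transition states"
        for rec in recs:
            assert rec.ddg == 0.0
            assert rec.classification == "neutral"

    def test_planted_contribution_recovered(self, toy):
        report, p = planted_scan(toy, [MutationSpec("A", 7)])
        rec = report.results[0].ts_records[0]
        # the planted contribution c = -h(TRP); truncation to (burial-
        # neutral) alanine removes it, so ddG = -c exactly
        expected = p.hydrophobicity_scale["TRP"]
        assert rec.ddg == pytest.approx(expected, abs=1e-9)
        assert expected < -report.tau
        assert rec.classification == "facilitates"

    def test_order_independence(self, toy):
        sites = [MutationSpec("A", 7), MutationSpec("A", 9)]
        a, _ = planted_scan(toy, sites)
        b, _ = planted_scan(toy, sites[::-1])
        key = lambda r: (r.site.chain_id, r.site.res_number)
        for ra, rb in zip(sorted(a.results, key=key), sorted(b.results, key=key)):
            assert [t.ddg for t in ra.ts_records] == [
                t.ddg for t in rb.ts_records
            ]

    def test_scan_reproducibility(self, toy):
        a, _ = planted_scan(toy, [MutationSpec("A", 7)])
        b, _ = planted_scan(toy, [MutationSpec("A", 7)])
        assert [t.ddg for t in a.results[0].ts_records] == [
            t.ddg for t in b.results[0].ts_records
        ]

    def test_failed_site_recorded_scan_continues(self, toy):
        report, _ = planted_scan(
            toy, [MutationSpec("A", 999), MutationSpec("A", 7)]
        )
        assert report.results[0].error
        assert not report.results[1].error

    def test_sign_convention(self, toy):
        report, _ = planted_scan(
            toy, [MutationSpec("A", 7), MutationSpec("A", 9)]
        )
        for res in report.results:
            for rec in res.ts_records:
                if rec.ddg is None:
                    continue
                if rec.ddg > report.tau:
                    assert rec.classification == "inhibits"
                elif rec.ddg < -report.tau:
                    assert rec.classification == "facilitates"
                else:
                    assert rec.classification == "neutral"


def test_classify_thresholds():
    assert classify(0.3, 0.25) == "inhibits"
    assert classify(-0.3, 0.25) == "facilitates"
    assert classify(0.1, 0.25) == "neutral"
    assert classify(0.25, 0.25) == "neutral"
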