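import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from conftest import make_ca_structure
from ditps3d.io_model import ResidueShell
from ditps3d.motif3d import (
    Motif3D,
    align_sites,
    conservation_profile,
    extract_motif,
    search_motif,
)
from ditps3d.struct_align import extract_shell, kabsch
from ditps3d.synthetic_data import MOTIF_TEMPLATE, motif_benchmark_config, build_cohort


def _shell_from(coords, letters, sid="s"):
    st = make_ca_structure(coords, sid, letters)
    return ResidueShell(structure_id=sid, radius_A=6.0, residues=list(st.residues))


TEMPLATE_LETTERS = "DWFYSR"


class TestAlignSites:
    def test_identical_shells_identity_mapping(self):
        a = _shell_from(MOTIF_TEMPLATE, TEMPLATE_LETTERS, "a")
        b = _shell_from(MOTIF_TEMPLATE, TEMPLATE_LETTERS, "b")
        aln = align_sites([a, b])
        assert aln.matches["b"] == list(range(6))
        assert np.allclose(aln.agreement, 1.0)

    def test_order_independence(self):
        a = _shell_from(MOTIF_TEMPLATE, TEMPLATE_LETTERS, "a")
        rev = _shell_from(MOTIF_TEMPLATE[::-1], TEMPLATE_LETTERS[::-1], "b")
        aln = align_sites([a, rev])
        # column c of the reference must map to the same residue despite the
        # reversed input order
        mapped = aln.matches["b"]
        for c, m in enumerate(mapped):
            assert m is not None
            assert rev.residues[m].letter == a.residues[c].letter
            assert np.allclose(rev.residues[m].ca, a.residues[c].ca)

    def test_small_site_skipped_with_warning(self):
        a = _shell_from(MOTIF_TEMPLATE, TEMPLATE_LETTERS, "a")
        b = _shell_from(MOTIF_TEMPLATE, TEMPLATE_LETTERS, "b")
        tiny = _shell_from(MOTIF_TEMPLATE[:3], TEMPLATE_LETTERS[:3], "tiny")
        with pytest.warns(UserWarning, match="skipped"):
            aln = align_sites([a, b, tiny])
        assert "tiny" not in aln.site_ids

    def test_fewer_than_two_usable_sites_fails(self):
        tiny = _shell_from(MOTIF_TEMPLATE[:3], TEMPLATE_LETTERS[:3], "t1")
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                align_sites([tiny, tiny])

    def test_planted_cohort_correspondences_recovered(self, bench_cohort):
        c = bench_cohort
        train = [a for a in c.structures if a not in set(c.truth.held_out)]
        shells = [extract_shell(c.structures[a], c.ligands[a], 6.0) for a in train]
        aln = align_sites(shells)
        planted = set(c.truth.pocket_positions[aln.reference_id])
        total = correct = 0
        ref_numbers = [k[1] for k in aln.columns]
        for sid in aln.site_ids:
            for col, m in enumerate(aln.matches[sid]):
                if ref_numbers[col] not in planted:
                    continue
                total += 1
                if m is not None and aln.shells[sid].residues[m].number == ref_numbers[col]:
                    correct += 1
        assert correct / total >= 0.90


class TestExtractMotif:
    def test_identical_sites_keep_all_columns(self):
        shells = [_shell_from(MOTIF_TEMPLATE, TEMPLATE_LETTERS, f"s{i}") for i in range(4)]
        motif = extract_motif(align_sites(shells))
        assert len(motif.positions) == 6
        assert [p[0] for p in motif.positions] == list(TEMPLATE_LETTERS)
        assert all(p[1] == frozenset() for p in motif.positions)

    def test_low_coverage_column_dropped(self):
        # 5 sites; one extra residue present in only 2 of them (c = 0.4)
        extra = np.array([[0.0, 0.0, 6.0]])
        full = np.vstack([MOTIF_TEMPLATE, extra])
        shells = [_shell_from(full, TEMPLATE_LETTERS + "K", "ref")]
        for i in range(5):
            if i < 2:
                shells.append(_shell_from(full, TEMPLATE_LETTERS + "K", f"s{i}"))
            else:
                shells.append(_shell_from(MOTIF_TEMPLATE, TEMPLATE_LETTERS, f"s{i}"))
        aln = align_sites(shells)
        assert aln.reference_id == "ref"
        motif = extract_motif(aln)
        assert len(motif.positions) == 6  # the 0.4-coverage column is gone

    def test_too_few_columns_fail(self):
        a = _shell_from(MOTIF_TEMPLATE[:4], "DWFY", "a")
        b = _shell_from(MOTIF_TEMPLATE[:4] + 5.0, "DWFY", "b")  # rigid shift, fine
        aln = align_sites([a, b])
        with pytest.raises(ValueError, match="representative"):
            extract_motif(aln, m_dist_min=1.01)

    def test_jittered_planted_positions_recovered(self, bench_cohort):
        c = bench_cohort
        train = [a for a in c.structures if a not in set(c.truth.held_out)]
        shells = [extract_shell(c.structures[a], c.ligands[a], 6.0) for a in train]
        aln = align_sites(shells)
        motif = extract_motif(aln)
        found = {n for (_c, n, _n) in motif.reference_keys}
        assert found == set(c.truth.pocket_positions[aln.reference_id])

    def test_json_roundtrip(self, tmp_path, bench_cohort):
        c = bench_cohort
        train = [a for a in c.structures if a not in set(c.truth.held_out)]
        shells = [extract_shell(c.structures[a], c.ligands[a], 6.0) for a in train]
        motif = extract_motif(align_sites(shells))
        p = tmp_path / "m.json"
        motif.to_json(p)
        back = Motif3D.from_json(p)
        assert back.positions == motif.positions
        assert np.allclose(back.template_distances, motif.template_distances)
        assert back.reference_keys == motif.reference_keys


class TestConservationProfile:
    def test_uniform_column(self):
        shells = [_shell_from(MOTIF_TEMPLATE, TEMPLATE_LETTERS, f"s{i}") for i in range(3)]
        prof = conservation_profile(align_sites(shells))
        assert prof.loc[1, "W"] == pytest.approx(1.0)

    def test_split_column_frequencies(self):
        a = _shell_from(MOTIF_TEMPLATE, "DWFYSR", "a")
        b = _shell_from(MOTIF_TEMPLATE, "DWFYSR", "b")
        c = _shell_from(MOTIF_TEMPLATE, "DWYYSR", "c")
        d = _shell_from(MOTIF_TEMPLATE, "DWYYSR", "d")
        prof = conservation_profile(align_sites([a, b, c, d]))
        assert prof.loc[2, "F"] == pytest.approx(0.5)
        assert prof.loc[2, "Y"] == pytest.approx(0.5)

    def test_rows_sum_to_one(self, bench_cohort):
        c = bench_cohort
        train = [a for a in c.structures if a not in set(c.truth.held_out)][:4]
        shells = [extract_shell(c.structures[a], c.ligands[a], 6.0) for a in train]
        prof = conservation_profile(align_sites(shells))
        sums = prof.drop(columns=["gap"]).sum(axis=1)
        assert np.allclose(sums, 1.0)


def _train_motif(cohort):
    train = [a for a in cohort.structures if a not in set(cohort.truth.held_out)]
    shells = [extract_shell(cohort.structures[a], cohort.ligands[a], 6.0) for a in train]
    return extract_motif(align_sites(shells))


class TestSearchMotif:
    def test_self_recovery(self, bench_cohort):
        motif = _train_motif(bench_cohort)
        train = [a for a in bench_cohort.structures if a not in set(bench_cohort.truth.held_out)]
        query = bench_cohort.structures[train[0]]
        matches = search_motif(motif, query, "strict")
        assert matches and matches[0].mismatches == 0 and matches[0].rmsd_A < 0.5

    def test_planted_substitution_found_only_relaxed(self, bench_cohort):
        c = bench_cohort
        motif = _train_motif(c)
        held = c.truth.held_out[0]
        strict = search_motif(motif, c.structures[held], "strict")
        relaxed = search_motif(motif, c.structures[held], "relaxed")
        assert strict == []
        assert relaxed and relaxed[0].mismatches == 1

    def test_scrambled_geometry_rejected(self, bench_cohort):
        motif = _train_motif(bench_cohort)
        # same letters, distances inflated: no candidate survives pruning
        coords = motif.template_coords * 2.5
        letters = "".join(p[0] for p in motif.positions)
        decoy = make_ca_structure(coords, "decoy", letters)
        assert search_motif(motif, decoy, "relaxed") == []

    def test_strict_subset_of_relaxed(self, bench_cohort):
        c = bench_cohort
        motif = _train_motif(c)
        for acc in list(c.structures)[:4]:
            strict = {m.residue_keys for m in search_motif(motif, c.structures[acc], "strict")}
            relaxed = {m.residue_keys for m in search_motif(motif, c.structures[acc], "relaxed")}
            assert strict <= relaxed

    def test_motif_larger_than_query(self, bench_cohort):
        motif = _train_motif(bench_cohort)
        tiny = make_ca_structure(MOTIF_TEMPLATE[:4], "tiny", "DWFY")
        assert search_motif(motif, tiny, "relaxed") == []

    @pytest.mark.parametrize("policy", ["strict", "relaxed"])
    def test_enumeration_matches_brute_force(self, policy):
        rng = np.random.default_rng(0)
        tmpl = MOTIF_TEMPLATE[:4]
        motif = Motif3D(
            positions=[(l, frozenset()) for l in "DWFY"],
            template_distances=cdist(tmpl, tmpl),
            template_coords=tmpl,
            reference_keys=[("A", i + 1, "XXX") for i in range(4)],
            support=2,
            m_dist_min=0.6,
            m_dist_max=0.4,
        )
        # 12-residue query: jittered motif + random letters elsewhere
        extra = rng.normal(0, 6, size=(8, 3)) + 8.0
        coords = np.vstack([tmpl + rng.normal(0, 0.2, tmpl.shape), extra])
        letters = "DWFY" + "".join(rng.choice(list("DWFYAK"), size=8))
        query = make_ca_structure(coords, "q", letters)
        impl = {
            (m.residue_keys, m.mismatches): round(m.rmsd_A, 9)
            for m in search_motif(motif, query, policy)
        }
        # brute force over all ordered residue 4-tuples
        budget = 0 if policy == "strict" else 1
        residues = list(query.residues)
        dmat = cdist(coords, coords)
        brute = {}
        for tup in itertools.permutations(range(12), 4):
            miss = sum(
                1 for p, i in enumerate(tup) if residues[i].letter != motif.positions[p][0]
            )
            if miss > budget:
                continue
            ok = all(
                abs(dmat[tup[p], tup[q]] - motif.template_distances[p, q])
                <= motif.tol_distance_A
                for p in range(4)
                for q in range(p)
            )
            if not ok:
                continue
            _, _, rmsd = kabsch(coords[list(tup)], tmpl)
            if rmsd <= motif.tol_rmsd_A:
                keys = tuple(residues[i].key for i in tup)
                brute[(keys, miss)] = round(rmsd, 9)
        assert impl == brute and brute  # non-empty: the planted placement exists
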