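"""Binding-site extraction, distance matrices, distogram labels, mapping."""

import itertools

import numpy as np
import pytest

from metacpi.geometry import (AlignmentMapping, BindingSite, ComplexStructure,
                              Residue, assign_bins, atom_residue_min_distances,
                              ca_distance_matrix, contact_labels,
                              equalize_histogram, extract_binding_site,
                              filter_binding_records, map_to_alignment,
                              read_complexes_pdb, read_site_annotations,
                              site_from_annotation, write_complex_pdb,
                              write_site_annotations)
from metacpi.msa import AlignedFamily, InputError, select_columns


def _res(i, name="ALA", atoms=None):
    atoms = atoms or (("CA", "C", (float(i), 0.0, 0.0)),)
    return Residue(res_id=i + 1, name=name, atoms=tuple(atoms))


def _complex(residues, ligand_atoms, kind="small_molecule", lig="LIG1"):
    return ComplexStructure(complex_id="cx", residues=tuple(residues),
                            ligand_id=lig, ligand_atoms=tuple(ligand_atoms),
                            ligand_kind=kind)


class TestFilterRecords:
    def _rec(self, kind, cid="p1", lig="l1"):
        cx = ComplexStructure(complex_id=cid, residues=(_res(0),),
                              ligand_id=lig, ligand_atoms=(("C", (0, 0, 0)),),
                              ligand_kind=kind)
        return cx, BindingSite((0,), lig)

    def test_metal_ion_removed_small_molecule_kept(self):
        records = [self._rec("metal_ion"), self._rec("small_molecule"),
                   self._rec("nucleic_acid")]
        kept = filter_binding_records(records)
        assert len(kept) == 1
        assert kept[0][0].ligand_kind == "small_molecule"

    def test_multiple_ligands_give_multiple_pockets(self):
        records = [self._rec("small_molecule", lig=f"l{i}") for i in range(3)]
        assert len(filter_binding_records(records)) == 3

    def test_duplicate_protein_ligand_pair_collapsed(self):
        records = [self._rec("small_molecule"), self._rec("small_molecule")]
        assert len(filter_binding_records(records)) == 1


class TestExtractSite:
    def test_inclusive_cutoff_boundaries(self):
        near = _res(0, atoms=(("CA", "C", (3.0, 0, 0)),))
        far = _res(1, atoms=(("CA", "C", (4.6, 0, 0)),))
        cx = _complex([near, far], [("C", (0.0, 0.0, 0.0))])
        site = extract_binding_site(cx, 4.5)
        assert site.residue_indices == (0,)

    def test_matches_exhaustive_scan_on_random_pocket(self, rng):
        residues = []
        for i in range(20):
            atoms = [(f"A{k}", "C", tuple(rng.uniform(-8, 8, 3)))
                     for k in range(3)]
            atoms.append(("CA", "C", tuple(rng.uniform(-8, 8, 3))))
            residues.append(Residue(i + 1, "GLY", tuple(atoms)))
        lig = [("C", tuple(rng.uniform(-2, 2, 3))) for _ in range(4)]
        cx = _complex(residues, lig)
        site = extract_binding_site(cx, 4.5)
        expected = []
        for idx, r in enumerate(residues):
            dmin = min(np.linalg.norm(np.array(a[2]) - np.array(l[1]))
                       for a in r.atoms for l in lig)
            if dmin <= 4.5:
                expected.append(idx)
        assert list(site.residue_indices) == expected

    def test_empty_site_is_an_error(self):
        cx = _complex([_res(0, atoms=(("CA", "C", (50.0, 0, 0)),))],
                      [("C", (0.0, 0.0, 0.0))])
        with pytest.raises(InputError):
            extract_binding_site(cx, 4.5)


class TestDistances:
    def test_three_four_five_triangle(self):
        r1 = _res(0, atoms=(("CA", "C", (0.0, 0.0, 0.0)),))
        r2 = _res(1, atoms=(("CA", "C", (3.0, 4.0, 0.0)),))
        cx = _complex([r1, r2], [("C", (0, 0, 0))])
        d = ca_distance_matrix(cx, BindingSite((0, 1), "LIG1"))
        assert np.isclose(d[0, 1], 5.0) and d[0, 0] == 0.0 and d[1, 1] == 0.0

    def test_missing_ca_excluded_with_warning(self):
        r1 = _res(0)
        r2 = Residue(2, "GLY", (("CB", "C", (1.0, 0.0, 0.0)),))
        cx = _complex([r1, r2], [("C", (0, 0, 0))])
        with pytest.warns(UserWarning):
            d = ca_distance_matrix(cx, BindingSite((0, 1), "LIG1"))
        assert d.shape == (1, 1)

    def test_matrix_matches_nested_loop_oracle(self, rng):
        residues = [_res(i, atoms=(("CA", "C", tuple(rng.uniform(-9, 9, 3))),))
                    for i in range(10)]
        cx = _complex(residues, [("C", (0, 0, 0))])
        d = ca_distance_matrix(cx, BindingSite(tuple(range(10)), "LIG1"))
        for i, j in itertools.product(range(10), repeat=2):
            manual = np.linalg.norm(np.array(residues[i].atoms[0][2]) -
                                    np.array(residues[j].atoms[0][2]))
            assert np.isclose(d[i, j], manual, atol=1e-12)

    def test_triangle_inequality_holds(self, rng):
        residues = [_res(i, atoms=(("CA", "C", tuple(rng.uniform(-9, 9, 3))),))
                    for i in range(8)]
        cx = _complex(residues, [("C", (0, 0, 0))])
        d = ca_distance_matrix(cx, BindingSite(tuple(range(8)), "LIG1"))
        for i, j, k in itertools.permutations(range(8), 3):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-9

    def test_min_rule_takes_smallest_atom_distance(self):
        res = Residue(1, "ALA", (("CA", "C", (2.0, 0, 0)),
                                 ("CB", "C", (7.0, 0, 0))))
        cx = _complex([res], [("C", (0.0, 0.0, 0.0))])
        d = atom_residue_min_distances(cx, BindingSite((0,), "LIG1"))
        assert np.isclose(d[0, 0], 2.0)

    def test_min_distances_match_triple_loop_oracle(self, rng):
        residues = []
        for i in range(8):
            atoms = [(f"A{k}", "C", tuple(rng.uniform(-9, 9, 3)))
                     for k in range(1 + int(rng.integers(3)))]
            residues.append(Residue(i + 1, "GLY", tuple(atoms)))
        lig = [("C", tuple(rng.uniform(-3, 3, 3))) for _ in range(5)]
        cx = _complex(residues, lig)
        d = atom_residue_min_distances(cx, BindingSite(tuple(range(8)), "LIG1"))
        for i, l in enumerate(lig):
            for j, r in enumerate(residues):
                manual = min(np.linalg.norm(np.array(l[1]) - np.array(a[2]))
                             for a in r.atoms)
                assert np.isclose(d[i, j], manual, atol=1e-12)

    def test_adding_an_atom_never_increases_min_distance(self, rng):
        atoms = [("A0", "C", tuple(rng.uniform(-5, 5, 3)))]
        lig = [("C", tuple(rng.uniform(-2, 2, 3))) for _ in range(3)]
        before = atom_residue_min_distances(
            _complex([Residue(1, "GLY", tuple(atoms))], lig),
            BindingSite((0,), "LIG1"))
        atoms.append(("A1", "C", tuple(rng.uniform(-5, 5, 3))))
        after = atom_residue_min_distances(
            _complex([Residue(1, "GLY", tuple(atoms))], lig),
            BindingSite((0,), "LIG1"))
        assert (after <= before + 1e-12).all()


class TestDistogram:
    def test_hundred_distinct_values_ten_per_bin(self, rng):
        values = rng.permutation(100).astype(float)
        bins = equalize_histogram(values, 10)
        counts = np.bincount(bins.labels, minlength=10)
        assert (counts == 10).all()

    def test_labels_within_range(self, rng):
        bins = equalize_histogram(rng.normal(size=500), 10)
        assert bins.labels.min() >= 0 and bins.labels.max() <= 9

    def test_all_identical_values_all_label_zero(self):
        with pytest.warns(UserWarning):
            bins = equalize_histogram(np.full(50, 3.3), 10)
        assert (bins.labels == 0).all()

    @pytest.mark.parametrize("n", [20, 203, 1000, 9999])
    def test_bin_populations_differ_by_at_most_one(self, n, rng):
        values = rng.permutation(n).astype(float)
        bins = equalize_histogram(values, 10)
        counts = np.bincount(bins.labels, minlength=10)
        assert counts.max() - counts.min() <= 1

    def test_frozen_edges_reused(self, rng):
        train = rng.uniform(0, 10, 300)
        bins = equalize_histogram(train, 10)
        fresh = rng.uniform(0, 10, 50)
        labels = assign_bins(fresh, bins.edges)
        # half-open convention: label = number of edges <= value
        manual = np.array([int((bins.edges <= v).sum()) for v in fresh])
        assert (labels == manual).all()


class TestContactLabels:
    def test_threshold_is_inclusive(self):
        labels = contact_labels(np.array([3.9, 8.0, 8.1]), 8.0)
        assert labels.tolist() == [1, 1, 0]

    def test_complement_under_inverted_comparison(self, rng):
        values = rng.uniform(0, 16, (6, 7))
        labels = contact_labels(values, 8.0)
        assert ((1 - labels) == (values > 8.0).astype(int)).all()


class TestMapToAlignment:
    def _build(self, row, other="ACDEFGHI"):
        fam = AlignedFamily("f", ["m", "o"], [row, other[:len(row)].ljust(len(row), "A")])
        sel = select_columns(fam, 0.5)
        seq = row.replace("-", "")
        residues = [Residue(i + 1, {"A": "ALA", "C": "CYS", "D": "ASP",
                                    "E": "GLU", "F": "PHE", "G": "GLY",
                                    "H": "HIS", "I": "ILE"}[aa],
                            (("CA", "C", (float(i), 0.0, 0.0)),))
                    for i, aa in enumerate(seq)]
        cx = _complex(residues, [("C", (0, 0, 0))])
        return fam, sel, cx

    def test_first_residue_gapless_maps_to_triplet_zero_slot_zero(self):
        fam, sel, cx = self._build("ACDEFG")
        site = BindingSite((0,), "LIG1")
        mapping = map_to_alignment(site, cx, fam, "m", sel)
        assert mapping.slots == ((0, 0),)

    def test_residue_in_discarded_column_maps_to_none(self):
        # column 1 is gapped in both rows -> discarded; member 'm' has a
        # residue there
        fam = AlignedFamily("f", ["m", "o"], ["AC-DEFGH", "A--DEFGH"])
        sel = select_columns(fam, 0.4)
        assert 1 not in sel.retained and 2 not in sel.retained
        cx = self._build("ACDEFGH")[2]  # structure reads ACDEFGH... rebuild:
        seq = "ACDEFGH"
        residues = [Residue(i + 1, "ALA", (("CA", "C", (float(i), 0, 0)),))
                    for i in range(len(seq))]
        # names don't matter for mapping except sequence check; build matching
        fam_m_seq = fam.aligned_rows[0].replace("-", "")
        assert fam_m_seq == seq
        from metacpi.geometry import ONE_TO_THREE
        residues = [Residue(i + 1, ONE_TO_THREE[aa],
                            (("CA", "C", (float(i), 0, 0)),))
                    for i, aa in enumerate(seq)]
        cx = _complex(residues, [("C", (0, 0, 0))])
        mapping = map_to_alignment(BindingSite((1,), "LIG1"), cx, fam, "m", sel)
        assert mapping.slots == (None,)

    def test_hand_walked_mapping_with_internal_gaps(self):
        # member row: A C - D E - F G  (8 columns, 2 internal gaps)
        fam = AlignedFamily("f", ["m", "o"], ["AC-DE-FG", "ACHDEIFG"])
        sel = select_columns(fam, 0.5)   # all columns retained (gap frac 1/2)
        assert sel.retained == tuple(range(8))
        from metacpi.geometry import ONE_TO_THREE
        seq = "ACDEFG"                    # ungapped member sequence
        residues = [Residue(i + 1, ONE_TO_THREE[aa],
                            (("CA", "C", (float(i), 0, 0)),))
                    for i, aa in enumerate(seq)]
        cx = _complex(residues, [("C", (0, 0, 0))])
        mapping = map_to_alignment(BindingSite(tuple(range(6)), "LIG1"),
                                   cx, fam, "m", sel)
        # residue k sits at the k-th non-gap column: columns 0,1,3,4,6,7
        # ranks among retained = same; triplet = rank // 3, slot = rank % 3
        assert mapping.slots == ((0, 0), (0, 1), (1, 0), (1, 1), (2, 0), (2, 1))

    def test_structure_alignment_mismatch_raises(self):
        fam, sel, _ = self._build("ACDEFG")
        from metacpi.geometry import ONE_TO_THREE
        residues = [Residue(i + 1, ONE_TO_THREE[aa],
                            (("CA", "C", (float(i), 0, 0)),))
                    for i, aa in enumerate("GGGGGG")]
        cx = _complex(residues, [("C", (0, 0, 0))])
        with pytest.raises(InputError, match="mismatch"):
            map_to_alignment(BindingSite((0,), "LIG1"), cx, fam, "m", sel)

    def test_roundtrip_with_distillation(self, small_dataset, small_corpus):
        """The residue's letter equals the mapped triplet's character at
        the mapped slot."""
        checked = 0
        for sc in small_dataset.complexes[:6]:
            fam = next(sf.family for sf in small_dataset.families
                       if sf.family.family_id == sc.family_id)
            sel = small_corpus.selections[sc.family_id]
            mapping = map_to_alignment(sc.site, sc.complex_structure, fam,
                                       sc.member_id, sel)
            seq = sc.complex_structure.sequence()
            triplets = small_corpus.by_member[sc.member_id].triplets
            for res_idx, slot in zip(sc.site.residue_indices, mapping.slots):
                if slot is None:
                    continue
                t, k = slot
                assert triplets[t][k] == seq[res_idx]
                checked += 1
        assert checked > 10


class TestPdbIO:
    def test_write_read_roundtrip(self, tmp_path, small_dataset):
        sc = small_dataset.complexes[0]
        path = tmp_path / "cx.pdb"
        write_complex_pdb(sc.complex_structure, path)
        back = read_complexes_pdb(path)
        assert len(back) == 1
        cx = back[0]
        assert len(cx.residues) == len(sc.complex_structure.residues)
        assert len(cx.ligand_atoms) == len(sc.complex_structure.ligand_atoms)
        orig = np.array([a[2] for r in sc.complex_structure.residues
                         for a in r.atoms])
        got = np.array([a[2] for r in cx.residues for a in r.atoms])
        assert np.allclose(orig, got, atol=1e-3)   # PDB has 3 decimals
        assert cx.sequence() == sc.complex_structure.sequence()

    def test_annotation_tsv_roundtrip(self, tmp_path):
        rows = [("cx1", "A", "LIG", [2, 5, 9]), ("cx2", "A", "MOL", [1])]
        path = tmp_path / "sites.tsv"
        write_site_annotations(path, rows)
        assert read_site_annotations(path) == rows

    def test_site_from_annotation_uses_source_ids(self, small_dataset):
        sc = small_dataset.complexes[0]
        res_ids = [sc.complex_structure.residues[i].res_id
                   for i in sc.site.residue_indices]
        site = site_from_annotation(sc.complex_structure, res_ids)
        assert site.residue_indices == sc.site.residue_indices
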