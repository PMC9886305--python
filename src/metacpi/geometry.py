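"""Binding-site extraction, distance matrices and distogram labels.

A protein-ligand complex contributes two distance matrices: pairwise
Cα-Cα distances between the pocket residues, and the minimum atom-to-
residue distance between each ligand atom and each pocket residue (the
distance between ligand atom *i* and residue *j* is the smallest distance
from *i* to any atom of *j*). The atom-residue matrix is discretized into
10 histogram-equalized bins — bin edges at empirical quantiles of the
pooled training distances, so every bin carries the same mass — and those
bin indices are the classification target of structure pretraining. A
binary contact variant (distance below a fixed threshold) is also
provided. Pocket residues are mapped into distilled-sequence coordinates
(triplet index, within-triplet slot) so that structure supervision lands
on the right rows of the protein embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .msa import AlignedFamily, ColumnSelection, GAP, InputError

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_METAL_ELEMENTS = {"LI", "NA", "K", "MG", "CA", "ZN", "FE", "MN", "CU", "CO",
                   "NI", "CD", "HG"}
_NUCLEIC_RESNAMES = {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU", "I"}


@dataclass(frozen=True)
class Residue:
    res_id: int               # 1-based id as in the source file
    name: str                 # three-letter residue name
    atoms: tuple[tuple[str, str, tuple[float, float, float]], ...]  # (atom name, element, xyz)

    def coord(self, atom_name: str) -> np.ndarray | None:
        for name, _, xyz in self.atoms:
            if name == atom_name:
                return np.asarray(xyz)
        return None

    def heavy_coords(self) -> np.ndarray:
        return np.array([xyz for _, el, xyz in self.atoms if el.upper() != "H"])


@dataclass(frozen=True)
class ComplexStructure:
    complex_id: str
    residues: tuple[Residue, ...]
    ligand_id: str
    ligand_atoms: tuple[tuple[str, tuple[float, float, float]], ...]  # (element, xyz)
    ligand_kind: str = "small_molecule"  # or nucleic_acid / metal_ion

    def __post_init__(self):
        if self.ligand_kind not in {"small_molecule", "nucleic_acid", "metal_ion"}:
            raise InputError(f"unknown ligand kind {self.ligand_kind!r}")

    def ligand_coords(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.ligand_atoms])

    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues)


@dataclass(frozen=True)
class BindingSite:
    residue_indices: tuple[int, ...]   # 0-based indices into ComplexStructure.residues
    ligand_id: str

    def __post_init__(self):
        idx = self.residue_indices
        if not idx:
            raise InputError("binding site has no residues")
        if list(idx) != sorted(set(idx)):
            raise InputError("residue indices must be unique and sorted")


@dataclass(frozen=True)
class DistanceData:
    resres_ca: np.ndarray    # (n_site, n_site) Cα distances
    atomres_min: np.ndarray  # (n_ligand_atoms, n_site) min atom-residue distances


@dataclass(frozen=True)
class DistogramBins:
    n_bins: int
    edges: np.ndarray        # interior bin boundaries, strictly ascending
    labels: np.ndarray       # integer bins, shaped like the source matrix


# ---------------------------------------------------------------------------

def filter_binding_records(
        records: list[tuple[ComplexStructure, BindingSite]],
) -> list[tuple[ComplexStructure, BindingSite]]:
    """Drop nucleic-acid and metal-ion sites; keep one record per
    (protein, ligand) pair. A protein with several small-molecule ligands
    legitimately contributes several pockets."""
    seen: set[tuple[str, str]] = set()
    out = []
    for cx, site in records:
        if cx.ligand_kind in {"nucleic_acid", "metal_ion"}:
            continue
        key = (cx.complex_id, cx.ligand_id)
        if key in seen:
            continue
        seen.add(key)
        out.append((cx, site))
    return out


def extract_binding_site(complex_: ComplexStructure,
                         contact_cutoff: float = 4.5) -> BindingSite:
    """Geometric pocket definition for complexes without annotations:
    residues with any heavy atom within ``contact_cutoff`` of any ligand
    atom (inclusive)."""
    lig = complex_.ligand_coords()
    if lig.size == 0:
        raise InputError("complex has no ligand atoms")
    hits = []
    for idx, res in enumerate(complex_.residues):
        coords = res.heavy_coords()
        if coords.size and cdist(lig, coords).min() <= contact_cutoff:
            hits.append(idx)
    if not hits:
        raise InputError(
            f"no residue within {contact_cutoff} A of ligand {complex_.ligand_id!r}")
    return BindingSite(residue_indices=tuple(hits), ligand_id=complex_.ligand_id)


def ca_distance_matrix(complex_: ComplexStructure, site: BindingSite) -> np.ndarray:
    """Pairwise Cα-Cα distances between the pocket residues.

    Residues lacking a Cα are excluded with a warning (the matrix shrinks
    accordingly)."""
    coords, dropped = [], []
    for idx in site.residue_indices:
        ca = complex_.residues[idx].coord("CA")
        if ca is None:
            dropped.append(idx)
        else:
            coords.append(ca)
    if dropped:
        warnings.warn(f"{complex_.complex_id}: residues {dropped} lack CA; excluded")
    coords = np.array(coords)
    return cdist(coords, coords)


def atom_residue_min_distances(complex_: ComplexStructure,
                               site: BindingSite) -> np.ndarray:
    """Matrix (n_ligand_atoms, n_site_residues): entry (i, r) is the
    smallest distance from ligand atom i to any atom of residue r."""
    lig = complex_.ligand_coords()
    out = np.empty((len(lig), len(site.residue_indices)))
    for col, idx in enumerate(site.residue_indices):
        coords = np.array([xyz for _, _, xyz in complex_.residues[idx].atoms])
        out[:, col] = cdist(lig, coords).min(axis=1)
    return out


def equalize_histogram(values: np.ndarray, n_bins: int = 10) -> DistogramBins:
    """Histogram-equalized discretization: interior edges at the k/n_bins
    empirical quantiles, so the classes carry (near-)equal mass.

    Labels follow half-open intervals [edge_k, edge_{k+1}) with the last
    interval closed. Duplicate or empty-leading edges (ties in the data)
    are collapsed with a warning; with fewer distinct values than bins the
    effective number of classes shrinks.
    """
    flat = np.asarray(values, dtype=float).ravel()
    if flat.size == 0:
        raise InputError("cannot equalize an empty value set")
    if n_bins < 2:
        raise InputError("n_bins must be at least 2")
    qs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(flat, qs)
    uniq = np.unique(edges)
    uniq = uniq[uniq > flat.min()]  # an edge at the global min leaves bin 0 empty
    if len(uniq) < len(edges):
        warnings.warn(f"degenerate bins: {len(edges) - len(uniq)} duplicate "
                      "edges collapsed")
    labels = assign_bins(values, uniq)
    return DistogramBins(n_bins=n_bins, edges=uniq, labels=labels)


def assign_bins(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Label values with frozen edges (training-pool edges are reused for
    validation/test so classes are comparable across complexes)."""
    return np.searchsorted(np.asarray(edges), np.asarray(values, dtype=float),
                           side="right").astype(np.intp)


def contact_labels(values: np.ndarray, threshold: float = 8.0) -> np.ndarray:
    """Binary contact map: 1 where distance <= threshold (inclusive)."""
    if threshold <= 0:
        raise InputError("contact threshold must be positive")
    return (np.asarray(values, dtype=float) <= threshold).astype(np.intp)


# ---- alignment mapping ----------------------------------------------------

@dataclass(frozen=True)
class AlignmentMapping:
    """Per pocket residue: (triplet index, within-triplet slot) in the
    member's distilled sequence, or None if its column was discarded."""

    slots: tuple[tuple[int, int] | None, ...]


def map_to_alignment(site: BindingSite, complex_: ComplexStructure,
                     family: AlignedFamily, member_id: str,
                     selection: ColumnSelection) -> AlignmentMapping:
    row = family.row(member_id)
    nongap_columns = [c for c, ch in enumerate(row) if ch != GAP]
    seq = complex_.sequence()
    aligned_seq = "".join(row[c] for c in nongap_columns)
    if aligned_seq != seq:
        raise InputError(
            f"structure/alignment mismatch for {member_id!r}: "
            f"alignment row reads {aligned_seq!r}, structure reads {seq!r}")
    rank_of_column = {c: r for r, c in enumerate(selection.retained)}
    slots: list[tuple[int, int] | None] = []
    for idx in site.residue_indices:
        column = nongap_columns[idx]
        rank = rank_of_column.get(column)
        slots.append(None if rank is None else (rank // 3, rank % 3))
    return AlignmentMapping(slots=tuple(slots))


# ---- PDB I/O (minimal dialect via gemmi) ----------------------------------

def _ligand_kind(resname: str, atoms: list) -> str:
    if resname.upper() in _NUCLEIC_RESNAMES:
        return "nucleic_acid"
    if len(atoms) == 1 and atoms[0][0].upper() in _METAL_ELEMENTS:
        return "metal_ion"
    return "small_molecule"


def read_complexes_pdb(path: str | Path) -> list[ComplexStructure]:
    """Read ATOM/HETATM records (altloc blank or 'A' only); one
    ComplexStructure per non-water HETATM ligand, sharing the protein
    residues."""
    st = gemmi.read_pdb(str(path))
    if not st:
        raise InputError(f"{path}: no models")
    model = st[0]
    residues: list[Residue] = []
    ligands: list[tuple[str, list[tuple[str, tuple[float, float, float]]], str]] = []
    for chain in model:
        for res in chain:
            atoms = [(a.name, a.element.name,
                      (a.pos.x, a.pos.y, a.pos.z))
                     for a in res if a.altloc in ("\x00", "", "A")]
            if not atoms:
                continue
            if res.name in THREE_TO_ONE and res.het_flag != "H":
                residues.append(Residue(res_id=res.seqid.num, name=res.name,
                                        atoms=tuple(atoms)))
            elif res.name in {"HOH", "WAT"}:
                continue
            else:
                lig_atoms = [(el, xyz) for _, el, xyz in atoms]
                lig_id = f"{res.name}:{chain.name}:{res.seqid.num}"
                ligands.append((lig_id, lig_atoms, res.name))
    out = []
    for lig_id, lig_atoms, resname in ligands:
        out.append(ComplexStructure(
            complex_id=Path(path).stem, residues=tuple(residues),
            ligand_id=lig_id, ligand_atoms=tuple(lig_atoms),
            ligand_kind=_ligand_kind(resname, lig_atoms)))
    if not out:
        raise InputError(f"{path}: no ligand HETATM records")
    return out


def write_complex_pdb(complex_: ComplexStructure, path: str | Path) -> None:
    st = gemmi.Structure()
    st.name = complex_.complex_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for res in complex_.residues:
        r = gemmi.Residue()
        r.name = res.name
        r.seqid = gemmi.SeqId(res.res_id, " ")
        for name, element, xyz in res.atoms:
            a = gemmi.Atom()
            a.name = name
            a.element = gemmi.Element(element)
            a.pos = gemmi.Position(*xyz)
            r.add_atom(a)
        chain.add_residue(r)
    model.add_chain(chain)
    lchain = gemmi.Chain("L")
    lr = gemmi.Residue()
    lr.name = "LIG"
    lr.seqid = gemmi.SeqId(1, " ")
    lr.het_flag = "H"
    for i, (element, xyz) in enumerate(complex_.ligand_atoms):
        a = gemmi.Atom()
        a.name = f"{element}{i + 1}"
        a.element = gemmi.Element(element)
        a.pos = gemmi.Position(*xyz)
        lr.add_atom(a)
    lchain.add_residue(lr)
    model.add_chain(lchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# binding-site annotation table: pdb_id, chain, ligand id, comma-joined residue ids

def write_site_annotations(path: str | Path,
                           rows: list[tuple[str, str, str, list[int]]]) -> None:
    with open(path, "w") as fh:
        fh.write("pdb_id\tchain\tligand_id\tresidue_ids\n")
        for pdb_id, chain, lig, res_ids in rows:
            fh.write(f"{pdb_id}\t{chain}\t{lig}\t{','.join(map(str, res_ids))}\n")


def read_site_annotations(path: str | Path) -> list[tuple[str, str, str, list[int]]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("pdb_id"):
            raise InputError(f"{path}: missing annotation header")
        for line in fh:
            pdb_id, chain, lig, res_ids = line.rstrip("\n").split("\t")
            out.append((pdb_id, chain, lig, [int(x) for x in res_ids.split(",")]))
    return out


def site_from_annotation(complex_: ComplexStructure,
                         residue_ids: list[int]) -> BindingSite:
    """Convert 1-based source residue ids to 0-based structure indices."""
    id_to_idx = {r.res_id: i for i, r in enumerate(complex_.residues)}
    try:
        idx = sorted(id_to_idx[r] for r in residue_ids)
    except KeyError as exc:
        raise InputError(f"annotated residue {exc} absent from structure") from None
    return BindingSite(residue_indices=tuple(idx), ligand_id=complex_.ligand_id)
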