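"""Synthetic protein families, molecules, complexes and activities.

Every stage of the pipeline needs data a desk can hold: multi-member
MSAs with point mutations and indels, small valence-respecting molecular
graphs with SMILES, 3D pockets whose geometry is recoverable by the
default binding-site cutoff, and family-clustered binary activity labels
generated by a *planted rule shared across families*. The rule reads a
family latent vector off a conserved 6-column sequence motif and a
molecule latent vector off graph statistics — both visible to the model
through its actual inputs — takes their inner product and thresholds at
zero, flipping the label with probability ``label_noise``. Because the
rule is identical in held-out families, cross-family (out-of-cluster)
generalization is learnable in principle, and the Bayes-optimal accuracy
is exactly ``1 - label_noise``.

Pocket geometry deliberately couples coordinates to identities: a pocket
residue's closest-approach distance to the ligand grows with its
amino-acid index, and a ligand atom's distance from the ligand centroid
depends on its element. Without such coupling the histogram-equalized
distogram would be uninformative by construction (equal bin masses) and
no predictor could beat the ln 10 uniform baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .encoders import MoleculeGraph, smiles_to_graph
from .geometry import (BindingSite, ComplexStructure, ONE_TO_THREE, Residue)
from .msa import GAP, AMINO_ACIDS, AlignedFamily, InputError

MOTIF_LENGTH = 6
LATENT_DIM = 4
_N_STATS = 8


@dataclass(frozen=True)
class GeneratorConfig:
    n_families: int = 40
    members_per_family: int = 6
    seq_length: int = 48
    mutation_rate: float = 0.1
    indel_rate: float = 0.05
    n_molecules: int = 60
    atoms_range: tuple[int, int] = (6, 14)
    pairs_per_family: int = 40
    pocket_size_range: tuple[int, int] = (8, 12)
    ligand_atoms_range: tuple[int, int] = (4, 8)
    coordinate_scale: float = 8.0
    label_noise: float = 0.1
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for rate in (self.mutation_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise InputError("rates must lie in [0, 1]")
        if not 0.0 <= self.label_noise < 0.5:
            raise InputError("label_noise must lie in [0, 0.5)")
        for lo, hi in (self.atoms_range, self.pocket_size_range,
                       self.ligand_atoms_range):
            if lo < 1 or hi < lo:
                raise InputError("ranges must be nonempty")
        if self.pocket_size_range[1] > self.seq_length:
            raise InputError("pocket cannot exceed the sequence length")


# ---- planted rule ---------------------------------------------------------

def _molecule_stats(graph: MoleculeGraph) -> np.ndarray:
    """Observable graph statistics feeding the molecule latent."""
    elements = [a[0] for a in graph.atoms]
    degrees = [a[1] for a in graph.atoms]
    orders = [b[2] for b in graph.bonds]
    return np.array([
        graph.n_atoms,
        len(graph.bonds),
        elements.count("C"),
        elements.count("N"),
        elements.count("O"),
        sum(1 for o in orders if o == 2.0),
        float(np.mean(degrees)) if degrees else 0.0,
        len(graph.bonds) - graph.n_atoms + 1,  # cycle rank (connected graph)
    ], dtype=float)


@dataclass
class PlantedRule:
    """Cross-family binding rule: sign of <family latent, molecule latent>.

    ``residue_table[s, a]`` maps (motif slot s, amino acid a) to a latent
    contribution; ``stat_proj`` maps standardized graph statistics to the
    molecule latent. Both are frozen functions of the rule seed, so the
    rule is identical across families, including held-out ones.
    """

    residue_table: np.ndarray          # (MOTIF_LENGTH, 20, LATENT_DIM)
    stat_proj: np.ndarray              # (_N_STATS, LATENT_DIM)
    stat_center: np.ndarray            # (_N_STATS,)
    stat_scale: np.ndarray             # (_N_STATS,)

    @classmethod
    def create(cls, rng: np.random.Generator,
               config: GeneratorConfig) -> "PlantedRule":
        mid_atoms = (config.atoms_range[0] + config.atoms_range[1]) / 2
        center = np.array([mid_atoms, mid_atoms, 0.7 * mid_atoms,
                           0.15 * mid_atoms, 0.15 * mid_atoms,
                           0.15 * mid_atoms, 2.0, 0.5])
        scale = np.maximum(center * 0.5, 0.5)
        return cls(
            residue_table=rng.normal(size=(MOTIF_LENGTH, 20, LATENT_DIM)),
            stat_proj=rng.normal(size=(_N_STATS, LATENT_DIM)),
            stat_center=center, stat_scale=scale)

    def family_latent(self, motif: str) -> np.ndarray:
        idx = [AMINO_ACIDS.index(ch) for ch in motif]
        return sum(self.residue_table[s, a] for s, a in enumerate(idx)) / np.sqrt(MOTIF_LENGTH)

    def molecule_latent(self, graph: MoleculeGraph) -> np.ndarray:
        z = (_molecule_stats(graph) - self.stat_center) / self.stat_scale
        return z @ self.stat_proj

    def score(self, motif: str, graph: MoleculeGraph) -> float:
        return float(self.family_latent(motif) @ self.molecule_latent(graph))

    def decide(self, motif: str, graph: MoleculeGraph) -> int:
        return int(self.score(motif, graph) > 0)


# ---- families -------------------------------------------------------------

def motif_positions(seq_length: int) -> list[int]:
    """Fixed, evenly spread positions of the conserved motif columns."""
    return [int(round((k + 1) * seq_length / (MOTIF_LENGTH + 1)))
            for k in range(MOTIF_LENGTH)]


@dataclass
class SyntheticFamily:
    family: AlignedFamily
    motif: str                      # conserved 6-letter motif (family identity)


def gen_families(config: GeneratorConfig,
                 rng: np.random.Generator) -> list[SyntheticFamily]:
    """Each family: a random ancestral sequence with a mutation-free
    6-column motif; members differ by point mutations and short indels.
    Deletions become gaps in the member's row; insertions add a column
    (gap in every other row), so the result is a consistent MSA."""
    out = []
    positions = motif_positions(config.seq_length)
    for f in range(config.n_families):
        ancestor = rng.choice(list(AMINO_ACIDS), size=config.seq_length)
        motif = "".join(ancestor[p] for p in positions)
        protected = set(positions)
        rows = []
        for m in range(config.members_per_family):
            row = ancestor.copy()
            for i in range(config.seq_length):
                if i not in protected and rng.random() < config.mutation_rate:
                    row[i] = rng.choice(list(AMINO_ACIDS))
            row = list(row)
            if rng.random() < config.indel_rate:        # deletion of 1-2 residues
                span = int(rng.integers(1, 3))
                cand = [i for i in range(config.seq_length - span)
                        if not (set(range(i, i + span)) & protected)]
                if cand:
                    start = int(rng.choice(cand))
                    for i in range(start, start + span):
                        row[i] = GAP
            rows.append(row)
        # insertions: occasionally add a column carried by a single member
        n_insert = rng.binomial(config.members_per_family, config.indel_rate)
        for _ in range(n_insert):
            col = int(rng.integers(0, len(rows[0])))
            carrier = int(rng.integers(0, len(rows)))
            for i, row in enumerate(rows):
                row.insert(col, rng.choice(list(AMINO_ACIDS)) if i == carrier else GAP)
        fam = AlignedFamily(
            family_id=f"FAM{f:04d}",
            member_ids=[f"FAM{f:04d}_M{m}" for m in range(len(rows))],
            aligned_rows=["".join(r) for r in rows])
        out.append(SyntheticFamily(family=fam, motif=motif))
    return out


# ---- molecules ------------------------------------------------------------

_VALENCE = {"C": 4, "N": 3, "O": 2}


def _random_molecule(n_atoms: int, rng: np.random.Generator) -> str:
    """Grow a random valence-safe C/N/O graph (tree plus occasional
    single-bond ring closure) and return its canonical SMILES.

    Draws whose rings get perceived as aromatic are rejected (the grammar
    promises plain single/double bonds); the acyclic retry cannot
    aromatize."""
    smiles = _grow_molecule(n_atoms, rng, allow_ring=True)
    mol = Chem.MolFromSmiles(smiles)
    if any(a.GetIsAromatic() for a in mol.GetAtoms()):
        smiles = _grow_molecule(n_atoms, rng, allow_ring=False)
    return smiles


def _grow_molecule(n_atoms: int, rng: np.random.Generator,
                   allow_ring: bool) -> str:
    mol = Chem.RWMol()
    elements = []
    free = []
    for i in range(n_atoms):
        el = str(rng.choice(["C", "N", "O"], p=[0.7, 0.15, 0.15]))
        mol.AddAtom(Chem.Atom(el))
        elements.append(el)
        free.append(_VALENCE[el])
        if i > 0:
            anchors = [j for j in range(i) if free[j] >= 1]
            if not anchors:        # saturated early (e.g. O=C=O); stop growing
                mol.RemoveAtom(i)
                elements.pop()
                free.pop()
                break
            j = int(rng.choice(anchors))
            order = 1
            if free[j] >= 2 and free[i] >= 2 and rng.random() < 0.2:
                order = 2
            mol.AddBond(j, i, Chem.BondType.DOUBLE if order == 2
                        else Chem.BondType.SINGLE)
            free[i] -= order
            free[j] -= order
    # one optional ring closure with a single bond between non-adjacent atoms
    n_grown = mol.GetNumAtoms()
    if allow_ring and n_grown >= 4 and rng.random() < 0.4:
        open_atoms = [i for i in range(n_grown) if free[i] >= 1]
        rng.shuffle(open_atoms)
        for i in open_atoms:
            partners = [j for j in open_atoms
                        if j > i and mol.GetBondBetweenAtoms(i, j) is None]
            if partners:
                mol.AddBond(i, int(rng.choice(partners)), Chem.BondType.SINGLE)
                break
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    return Chem.MolToSmiles(m)


@dataclass
class SyntheticMolecule:
    molecule_id: str
    smiles: str
    graph: MoleculeGraph


def gen_molecules(config: GeneratorConfig,
                  rng: np.random.Generator) -> list[SyntheticMolecule]:
    out = []
    for i in range(config.n_molecules):
        n = int(rng.integers(config.atoms_range[0], config.atoms_range[1] + 1))
        smiles = _random_molecule(n, rng)
        out.append(SyntheticMolecule(molecule_id=f"MOL{i:04d}", smiles=smiles,
                                     graph=smiles_to_graph(smiles)))
    return out


# ---- complexes ------------------------------------------------------------

# distance of a ligand atom from the ligand centroid, by element
_ELEMENT_RADIUS = {"C": 1.0, "N": 1.8, "O": 2.6}


def _closest_approach(aa: str) -> float:
    """Planted geometric signal: bulkier-indexed residues sit farther out
    (closest heavy-atom distance in [2.6, 4.4] A, inside the 4.5 cutoff)."""
    return 2.6 + 1.8 * AMINO_ACIDS.index(aa) / 19.0


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


@dataclass
class SyntheticComplex:
    complex_structure: ComplexStructure
    site: BindingSite
    family_id: str
    member_id: str
    molecule_id: str


def gen_complexes(families: list[SyntheticFamily],
                  molecules: list[SyntheticMolecule],
                  config: GeneratorConfig, rng: np.random.Generator,
                  n_complexes: int | None = None) -> list[SyntheticComplex]:
    """Place the ligand near the origin (element-dependent radii) and the
    intended pocket residues on a 3-8 A shell, each with a side-chain
    atom at its identity-dependent closest approach; remaining residues
    sit on a 15-30 A shell so the default 4.5 A cutoff recovers exactly
    the intended pocket."""
    if not families or not molecules:
        raise InputError("need at least one family and one molecule")
    n_complexes = n_complexes or config.n_families
    out = []
    for c in range(n_complexes):
        sf = families[int(rng.integers(len(families)))]
        member_idx = int(rng.integers(len(sf.family.member_ids)))
        member_id = sf.family.member_ids[member_idx]
        sequence = sf.family.aligned_rows[member_idx].replace(GAP, "")
        mol = molecules[int(rng.integers(len(molecules)))]
        # the "pose" exposes the first n_lig atoms of the molecule, so the
        # atom selector picks distinct rows of the GIN output
        n_lig = min(mol.graph.n_atoms,
                    int(rng.integers(config.ligand_atoms_range[0],
                                     config.ligand_atoms_range[1] + 1)))
        lig_elements = [mol.graph.atoms[i][0] for i in range(n_lig)]
        lig_coords = np.array([
            _unit(rng) * (_ELEMENT_RADIUS.get(el, 1.5) + rng.uniform(-0.2, 0.2))
            for el in lig_elements])
        n_res = len(sequence)
        pocket_size = int(rng.integers(config.pocket_size_range[0],
                                       min(config.pocket_size_range[1], n_res) + 1))
        pocket = np.sort(rng.choice(n_res, size=pocket_size, replace=False))
        residues = []
        for i, aa in enumerate(sequence):
            if i in pocket:
                anchor = lig_coords[int(rng.integers(n_lig))]
                direction = _unit(rng)
                approach = _closest_approach(aa)
                cb = anchor + direction * approach
                ca = anchor + direction * min(approach + rng.uniform(1.0, 3.0),
                                              config.coordinate_scale)
            else:
                ca = _unit(rng) * rng.uniform(15.0, 30.0)
                cb = ca + _unit(rng) * 1.5
            residues.append(Residue(
                res_id=i + 1, name=ONE_TO_THREE[aa],
                atoms=(("CA", "C", tuple(ca)), ("CB", "C", tuple(cb)))))
        cx = ComplexStructure(
            complex_id=f"CPLX{c:04d}", residues=tuple(residues),
            ligand_id=mol.molecule_id,
            ligand_atoms=tuple((el, tuple(xyz))
                               for el, xyz in zip(lig_elements, lig_coords)),
            ligand_kind="small_molecule")
        site = BindingSite(residue_indices=tuple(int(i) for i in pocket),
                           ligand_id=mol.molecule_id)
        out.append(SyntheticComplex(complex_structure=cx, site=site,
                                    family_id=sf.family.family_id,
                                    member_id=member_id,
                                    molecule_id=mol.molecule_id))
    return out


# ---- activities -----------------------------------------------------------

@dataclass
class ActivityRecord:
    family_id: str
    member_id: str
    molecule_id: str
    label: int
    rule_score: float


def gen_activities(families: list[SyntheticFamily],
                   molecules: list[SyntheticMolecule], rule: PlantedRule,
                   config: GeneratorConfig,
                   rng: np.random.Generator) -> list[ActivityRecord]:
    """Family-clustered labels from the planted rule, flipped with
    probability ``label_noise``."""
    out = []
    for sf in families:
        for _ in range(config.pairs_per_family):
            mol = molecules[int(rng.integers(len(molecules)))]
            member_id = sf.family.member_ids[int(rng.integers(len(sf.family.member_ids)))]
            label = rule.decide(sf.motif, mol.graph)
            if rng.random() < config.label_noise:
                label = 1 - label
            out.append(ActivityRecord(
                family_id=sf.family.family_id, member_id=member_id,
                molecule_id=mol.molecule_id, label=label,
                rule_score=rule.score(sf.motif, mol.graph)))
    fraction = float(np.mean([r.label for r in out])) if out else float("nan")
    import logging
    logging.getLogger(__name__).info("achieved positive fraction: %.3f", fraction)
    return out


# ---- one-call dataset -----------------------------------------------------

@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    families: list[SyntheticFamily]
    molecules: list[SyntheticMolecule]
    complexes: list[SyntheticComplex]
    activities: list[ActivityRecord]
    rule: PlantedRule | None

    @property
    def molecule_by_id(self) -> dict[str, SyntheticMolecule]:
        return {m.molecule_id: m for m in self.molecules}


def generate_dataset(config: GeneratorConfig,
                     n_complexes: int | None = None) -> SyntheticDataset:
    """Pure function of the config (whose seed drives all randomness)."""
    rng = np.random.default_rng(config.seed)
    rule = PlantedRule.create(np.random.default_rng(config.seed + 1), config)
    families = gen_families(config, rng)
    molecules = gen_molecules(config, rng)
    complexes = gen_complexes(families, molecules, config, rng,
                              n_complexes=n_complexes)
    activities = gen_activities(families, molecules, rule, config, rng)
    return SyntheticDataset(config=config, families=families,
                            molecules=molecules, complexes=complexes,
                            activities=activities, rule=rule)


# ---- writers --------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict:
    """Write the dataset directory: MSAs (aligned FASTA), molecules
    (SMILES TSV), complexes (PDB), site annotations (TSV), activities
    (TSV). Returns the manifest dict."""
    from . import geometry, msa
    out = Path(out_dir)
    (out / "msa").mkdir(parents=True, exist_ok=True)
    (out / "pdb").mkdir(exist_ok=True)
    for sf in dataset.families:
        msa.write_alignment_fasta(sf.family, out / "msa" / f"{sf.family.family_id}.fasta")
    with open(out / "molecules.tsv", "w") as fh:
        fh.write("molecule_id\tsmiles\n")
        for m in dataset.molecules:
            fh.write(f"{m.molecule_id}\t{m.smiles}\n")
    rows = []
    for sc in dataset.complexes:
        geometry.write_complex_pdb(sc.complex_structure,
                                   out / "pdb" / f"{sc.complex_structure.complex_id}.pdb")
        rows.append((sc.complex_structure.complex_id, "A", sc.molecule_id,
                     [sc.complex_structure.residues[i].res_id
                      for i in sc.site.residue_indices]))
    geometry.write_site_annotations(out / "sites.tsv", rows)
    with open(out / "complexes.tsv", "w") as fh:
        fh.write("complex_id\tfamily_id\tmember_id\tmolecule_id\n")
        for sc in dataset.complexes:
            fh.write(f"{sc.complex_structure.complex_id}\t{sc.family_id}\t"
                     f"{sc.member_id}\t{sc.molecule_id}\n")
    with open(out / "activities.tsv", "w") as fh:
        fh.write("family_id\tmember_id\tmolecule_id\tlabel\n")
        for r in dataset.activities:
            fh.write(f"{r.family_id}\t{r.member_id}\t{r.molecule_id}\t{r.label}\n")
    import json
    manifest = {"config": {**vars(dataset.config),
                           "atoms_range": list(dataset.config.atoms_range),
                           "pocket_size_range": list(dataset.config.pocket_size_range),
                           "ligand_atoms_range": list(dataset.config.ligand_atoms_range)},
                "n_families": len(dataset.families),
                "n_molecules": len(dataset.molecules),
                "n_complexes": len(dataset.complexes),
                "n_activities": len(dataset.activities)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_dataset_dir(data_dir: str | Path) -> SyntheticDataset:
    """Rebuild a dataset from the directory written by
    :func:`write_dataset` (planted rule and motifs are not serialized;
    the loaded object supports distillation, structure preparation and
    CPI training, not re-labelling)."""
    import csv
    from . import geometry, msa
    root = Path(data_dir)
    if not (root / "manifest.json").exists():
        raise InputError(f"{root}: not a dataset directory (no manifest.json)")
    import json
    manifest = json.loads((root / "manifest.json").read_text())
    cfg_raw = dict(manifest["config"])
    for key in ("atoms_range", "pocket_size_range", "ligand_atoms_range"):
        cfg_raw[key] = tuple(cfg_raw[key])
    config = GeneratorConfig(**cfg_raw)
    families = [SyntheticFamily(family=msa.read_alignment(p), motif="")
                for p in sorted((root / "msa").glob("*.fasta"))]
    molecules = []
    with open(root / "molecules.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            molecules.append(SyntheticMolecule(
                molecule_id=row["molecule_id"], smiles=row["smiles"],
                graph=smiles_to_graph(row["smiles"])))
    meta = {}
    with open(root / "complexes.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            meta[row["complex_id"]] = row
    sites = {pdb_id: res_ids for pdb_id, _, _, res_ids
             in geometry.read_site_annotations(root / "sites.tsv")}
    complexes = []
    for pdb_path in sorted((root / "pdb").glob("*.pdb")):
        cx = geometry.read_complexes_pdb(pdb_path)[0]
        info = meta[cx.complex_id]
        cx = ComplexStructure(complex_id=cx.complex_id, residues=cx.residues,
                              ligand_id=info["molecule_id"],
                              ligand_atoms=cx.ligand_atoms,
                              ligand_kind=cx.ligand_kind)
        site = geometry.site_from_annotation(cx, sites[cx.complex_id])
        complexes.append(SyntheticComplex(
            complex_structure=cx, site=site, family_id=info["family_id"],
            member_id=info["member_id"], molecule_id=info["molecule_id"]))
    activities = []
    with open(root / "activities.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            activities.append(ActivityRecord(
                family_id=row["family_id"], member_id=row["member_id"],
                molecule_id=row["molecule_id"], label=int(row["label"]),
                rule_score=float("nan")))
    return SyntheticDataset(config=config, families=families,
                            molecules=molecules, complexes=complexes,
                            activities=activities, rule=None)
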