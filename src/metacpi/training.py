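"""Stage training loops and pipeline plumbing.

Three stages, in order: (1) masked-language-model pretraining of the
protein encoder on the distilled triplet corpus; (2) structure
pretraining, where the protein and chemical encoders are tuned to
classify histogram-equalized atom-residue distance bins of binding
pockets; (3) CPI training with out-of-cluster meta-learning (see
:mod:`metacpi.oocml`). Weights cross stage boundaries through
:func:`metacpi.model.transfer_weights`.

Stages 1-2 use Adam; the meta-learning stage uses the plain gradient
steps its pseudocode prescribes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoders import encode_protein, mlm_loss
from .geometry import (AlignmentMapping, atom_residue_min_distances,
                       equalize_histogram, assign_bins, map_to_alignment)
from .model import (ModelConfig, StageWeights, attentive_pool, build_selector,
                    distogram_loss, init_stage, interaction_features,
                    transfer_weights)
from .msa import (AlignedFamily, ColumnSelection, DistilledSequence,
                  InputError, TripletVocabulary, build_vocabulary,
                  distill, mask_for_mlm, select_columns)
from .oocml import DivergenceError, FamilyDataset, LabeledPair
from .synthetic import SyntheticComplex, SyntheticDataset


class Adam:
    """Standard Adam on a flat weight dict (functional: step returns a
    fresh dict)."""

    def __init__(self, lr: float = 1e-2, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, Tensor],
             grads: dict[str, Tensor]) -> dict[str, Tensor]:
        self.t += 1
        out = {}
        for k in params:
            g = grads[k].data
            self.m[k] = self.beta1 * self.m.get(k, 0.0) + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v.get(k, 0.0) + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            out[k] = Tensor(params[k].data - self.lr * mhat / (np.sqrt(vhat) + self.eps),
                            requires_grad=True)
        return out


# ---- distillation plumbing -------------------------------------------------

@dataclass
class DistilledCorpus:
    sequences: list[DistilledSequence]
    vocab: TripletVocabulary
    selections: dict[str, ColumnSelection]          # family_id -> selection
    by_member: dict[str, DistilledSequence] = field(default_factory=dict)

    def __post_init__(self):
        self.by_member = {s.member_id: s for s in self.sequences}

    def encode(self, member_id: str) -> np.ndarray:
        return self.vocab.encode(self.by_member[member_id].triplets)


def distill_corpus(families: list[AlignedFamily], max_gap_fraction: float = 0.5,
                   min_count: int = 1) -> DistilledCorpus:
    sequences, selections = [], {}
    for fam in families:
        sel = select_columns(fam, max_gap_fraction)
        selections[fam.family_id] = sel
        for member in fam.member_ids:
            sequences.append(distill(fam, member, sel))
    vocab = build_vocabulary(sequences, min_count=min_count)
    return DistilledCorpus(sequences=sequences, vocab=vocab,
                           selections=selections)


# ---- stage 1: MLM ----------------------------------------------------------

def pretrain_mlm(corpus: DistilledCorpus, config: ModelConfig, steps: int,
                 rng: np.random.Generator, lr: float = 1e-2,
                 mask_rate: float = 0.15, batch_size: int = 4,
                 weights: StageWeights | None = None,
                 ) -> tuple[StageWeights, list[float]]:
    """Adam steps on the masked-triplet objective, a few randomly drawn
    sequences per step (single-sequence gradients are too noisy for the
    adaptive optimizer at this scale). Returns mlm-stage weights and the
    per-step loss trace."""
    if weights is None:
        weights = init_stage("mlm", config, rng)
    params = dict(weights.params)
    keys = sorted(params)
    opt = Adam(lr=lr)
    losses = []
    enc_params = lambda p: {k[len("protein_encoder."):]: v for k, v in p.items()}
    for step in range(steps):
        total = None
        for _ in range(batch_size):
            seq = corpus.sequences[int(rng.integers(len(corpus.sequences)))]
            inst = mask_for_mlm(seq, corpus.vocab, mask_rate, rng)
            emb = encode_protein(inst.input_ids, enc_params(params), config.protein)
            loss = mlm_loss(emb, inst, enc_params(params))
            total = loss if total is None else total + loss
        total = total * (1.0 / batch_size)
        if not np.isfinite(total.data).all():
            raise DivergenceError(f"non-finite MLM loss at step {step}")
        grads = dict(zip(keys, ad.grad(total, [params[k] for k in keys])))
        params = opt.step(params, grads)
        losses.append(float(total.data))
    return StageWeights("mlm", config, params), losses


def mlm_eval_loss(weights: StageWeights, corpus: DistilledCorpus,
                  rng: np.random.Generator, n_sequences: int = 20,
                  mask_rate: float = 0.15) -> float:
    """Mean MLM loss over freshly masked sequences, no weight updates."""
    enc = weights.component("protein_encoder")
    total = 0.0
    with ad.no_grad():
        for _ in range(n_sequences):
            seq = corpus.sequences[int(rng.integers(len(corpus.sequences)))]
            inst = mask_for_mlm(seq, corpus.vocab, mask_rate, rng)
            emb = encode_protein(inst.input_ids, enc, weights.config.protein)
            total += float(mlm_loss(emb, inst, enc).data)
    return total / n_sequences


# ---- stage 2: structure ----------------------------------------------------

@dataclass
class StructureInstance:
    """One pocket ready for distogram training: distilled token ids, the
    ligand molecule graph, selector matrices and per-pair bin labels
    (n_selected_residues, n_ligand_atoms)."""

    protein_ids: np.ndarray
    molecule_graph: object
    protein_selector: np.ndarray
    atom_selector: np.ndarray
    labels: np.ndarray


def prepare_structure_instances(dataset: SyntheticDataset,
                                corpus: DistilledCorpus,
                                n_bins: int = 10,
                                ) -> tuple[list[StructureInstance], np.ndarray]:
    """Build training instances from complexes and freeze the distogram
    bin edges on the pooled training distances.

    Residues whose alignment column was discarded are dropped; when two
    site residues land in the same triplet row only the first is kept
    (selector rows must be distinct).
    """
    families = {sf.family.family_id: sf.family for sf in dataset.families}
    raw = []
    pooled = []
    for sc in dataset.complexes:
        fam = families[sc.family_id]
        sel = corpus.selections[sc.family_id]
        mapping = map_to_alignment(sc.site, sc.complex_structure, fam,
                                   sc.member_id, sel)
        dmat = atom_residue_min_distances(sc.complex_structure, sc.site)
        keep_cols, triplet_rows, seen = [], [], set()
        for col, slot in enumerate(mapping.slots):
            if slot is None or slot[0] in seen:
                continue
            seen.add(slot[0])
            keep_cols.append(col)
            triplet_rows.append(slot[0])
        if not keep_cols:
            continue
        dists = dmat[:, keep_cols].T          # (n_res_kept, n_atoms)
        raw.append((sc, triplet_rows, dists))
        pooled.append(dists.ravel())
    if not raw:
        raise InputError("no mappable complexes")
    bins = equalize_histogram(np.concatenate(pooled), n_bins=n_bins)
    molecules = dataset.molecule_by_id
    instances = []
    for sc, triplet_rows, dists in raw:
        ids = corpus.encode(sc.member_id)
        graph = molecules[sc.molecule_id].graph
        n_lig = len(sc.complex_structure.ligand_atoms)
        instances.append(StructureInstance(
            protein_ids=ids, molecule_graph=graph,
            protein_selector=build_selector(triplet_rows, len(ids)),
            atom_selector=build_selector(list(range(n_lig)), graph.n_atoms),
            labels=assign_bins(dists, bins.edges)))
    return instances, bins.edges


def structure_instance_loss(inst: StructureInstance, params: dict[str, Tensor],
                            config: ModelConfig) -> Tensor:
    from .encoders import gin_encode
    enc = {k[len("protein_encoder."):]: v for k, v in params.items()
           if k.startswith("protein_encoder.")}
    chem = {k[len("chemical_encoder."):]: v for k, v in params.items()
            if k.startswith("chemical_encoder.")}
    pool = {k[len("pooling."):]: v for k, v in params.items()
            if k.startswith("pooling.")}
    head = {k[len("distogram_head."):]: v for k, v in params.items()
            if k.startswith("distogram_head.")}
    Hp = encode_protein(inst.protein_ids, enc, config.protein)
    Hc, _ = gin_encode(inst.molecule_graph, chem, config.chemical)
    pair = interaction_features(Hp, Hc, inst.protein_selector,
                                inst.atom_selector, mode="pairwise")
    pooled, _, _ = attentive_pool(pair, pool)
    return distogram_loss(pair, pooled, inst.labels, head)


def pretrain_structure(instances: list[StructureInstance],
                       weights: StageWeights, steps: int,
                       rng: np.random.Generator, lr: float = 1e-2,
                       ) -> tuple[StageWeights, list[float]]:
    """Adam steps on the 10-way distogram objective, one complex per step."""
    if weights.stage != "structure":
        raise InputError("pretrain_structure expects structure-stage weights")
    params = dict(weights.params)
    keys = sorted(params)
    opt = Adam(lr=lr)
    losses = []
    for step in range(steps):
        inst = instances[int(rng.integers(len(instances)))]
        loss = structure_instance_loss(inst, params, weights.config)
        if not np.isfinite(loss.data).all():
            raise DivergenceError(f"non-finite distogram loss at step {step}")
        grads = dict(zip(keys, ad.grad(loss, [params[k] for k in keys])))
        params = opt.step(params, grads)
        losses.append(float(loss.data))
    return StageWeights("structure", weights.config, params), losses


def structure_eval_loss(instances: list[StructureInstance],
                        weights: StageWeights,
                        n_eval: int | None = None) -> float:
    with ad.no_grad():
        chosen = instances if n_eval is None else instances[:n_eval]
        return float(np.mean([
            structure_instance_loss(i, weights.params, weights.config).data
            for i in chosen]))


# ---- stage 3 plumbing ------------------------------------------------------

def build_family_dataset(dataset: SyntheticDataset,
                         corpus: DistilledCorpus) -> FamilyDataset:
    """Turn synthetic activity records into meta-learning tasks."""
    molecules = dataset.molecule_by_id
    families: dict[str, list[LabeledPair]] = {}
    for rec in dataset.activities:
        families.setdefault(rec.family_id, []).append(LabeledPair(
            molecule=molecules[rec.molecule_id].graph,
            protein_ids=corpus.encode(rec.member_id),
            label=rec.label, molecule_id=rec.molecule_id,
            member_id=rec.member_id))
    return FamilyDataset(families)
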