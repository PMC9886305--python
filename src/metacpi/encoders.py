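"""Protein and chemical encoders.

The protein side is a small Transformer over distilled triplet tokens with
ALBERT-style cross-layer parameter sharing and a masked-language-model
head; the chemical side converts SMILES to heavy-atom graphs and encodes
them with a Graph Isomorphism Network (GIN), whose sum aggregation is
injective on multisets of neighbour features and therefore invariant to
atom relabelling.

All models are functional: weights live in a flat ``dict[str, Tensor]``
and forward passes take the weight dict explicitly, which is what the
meta-learning inner loop needs (adapted weights are just another dict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from . import autodiff as ad
from .autodiff import Tensor
from .msa import InputError, MlmInstance

RDLogger.DisableLog("rdApp.*")


class TruncationError(ValueError):
    """Input longer than the encoder's positional table."""


@dataclass(frozen=True)
class ProteinEncoderConfig:
    vocab_size: int
    embedding_dim: int = 64
    n_layers: int = 2
    n_heads: int = 4
    max_positions: int = 512
    share_layer_parameters: bool = True
    ffn_dim: int | None = None

    def __post_init__(self):
        if min(self.vocab_size, self.embedding_dim, self.n_layers,
               self.n_heads, self.max_positions) <= 0:
            raise InputError("all encoder dimensions must be positive")
        if self.embedding_dim % self.n_heads:
            raise InputError("embedding_dim must be divisible by n_heads")

    @property
    def hidden_ffn(self) -> int:
        return self.ffn_dim or 2 * self.embedding_dim


def _normal(rng, *shape, scale=0.02):
    return Tensor(rng.normal(scale=scale, size=shape), requires_grad=True)


def _zeros(*shape):
    return Tensor(np.zeros(shape), requires_grad=True)


def _ones(*shape):
    return Tensor(np.ones(shape), requires_grad=True)


def init_protein_params(config: ProteinEncoderConfig,
                        rng: np.random.Generator) -> dict[str, Tensor]:
    d = config.embedding_dim
    p = {
        "tok_emb": _normal(rng, config.vocab_size, d),
        "pos_emb": _normal(rng, config.max_positions, d),
    }
    n_unique = 1 if config.share_layer_parameters else config.n_layers
    for l in range(n_unique):
        pre = f"layer{l}."
        for name in ("wq", "wk", "wv", "wo"):
            p[pre + name] = _normal(rng, d, d)
        p[pre + "ffn_w1"] = _normal(rng, d, config.hidden_ffn)
        p[pre + "ffn_b1"] = _zeros(config.hidden_ffn)
        p[pre + "ffn_w2"] = _normal(rng, config.hidden_ffn, d)
        p[pre + "ffn_b2"] = _zeros(d)
        p[pre + "ln1_g"], p[pre + "ln1_b"] = _ones(d), _zeros(d)
        p[pre + "ln2_g"], p[pre + "ln2_b"] = _ones(d), _zeros(d)
    # untied MLM output head
    p["mlm_w"] = _normal(rng, d, config.vocab_size)
    p["mlm_b"] = _zeros(config.vocab_size)
    return p


def _layer_norm(x: Tensor, g: Tensor, b: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered ** 2).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * g + b


def _attention(x: Tensor, p: dict[str, Tensor], pre: str, n_heads: int) -> Tensor:
    n, d = x.shape
    dh = d // n_heads
    q, k, v = x @ p[pre + "wq"], x @ p[pre + "wk"], x @ p[pre + "wv"]
    outs = []
    for h in range(n_heads):
        sl = (slice(None), slice(h * dh, (h + 1) * dh))
        qh, kh, vh = q[sl], k[sl], v[sl]
        scores = (qh @ ad.transpose(kh)) * (dh ** -0.5)
        outs.append(ad.softmax(scores, axis=-1) @ vh)
    return ad.concat(outs, axis=1) @ p[pre + "wo"]


def encode_protein(input_ids: np.ndarray, params: dict[str, Tensor],
                   config: ProteinEncoderConfig) -> Tensor:
    """Contextual embedding of a distilled token sequence: (n, d) matrix."""
    ids = np.asarray(input_ids, dtype=np.intp)
    if ids.ndim != 1:
        raise InputError("input_ids must be one-dimensional")
    n = len(ids)
    if n > config.max_positions:
        raise TruncationError(
            f"sequence length {n} exceeds max_positions={config.max_positions}")
    if ids.size and ids.max() >= config.vocab_size:
        raise InputError("token id outside vocabulary")
    x = params["tok_emb"][ids] + params["pos_emb"][np.arange(n)]
    for l in range(config.n_layers):
        pre = "layer0." if config.share_layer_parameters else f"layer{l}."
        x = _layer_norm(x + _attention(x, params, pre, config.n_heads),
                        params[pre + "ln1_g"], params[pre + "ln1_b"])
        h = ad.relu(x @ params[pre + "ffn_w1"] + params[pre + "ffn_b1"])
        x = _layer_norm(x + h @ params[pre + "ffn_w2"] + params[pre + "ffn_b2"],
                        params[pre + "ln2_g"], params[pre + "ln2_b"])
    return x


def mlm_loss(embeddings: Tensor, instance: MlmInstance,
             params: dict[str, Tensor]) -> Tensor:
    """Mean cross-entropy of the MLM head over the masked positions."""
    pos = np.asarray(instance.target_positions, dtype=np.intp)
    if pos.size == 0:
        warnings.warn("MLM instance has no masked positions; loss defined as 0")
        return Tensor(0.0)
    if pos.max() >= embeddings.shape[0]:
        raise InputError("target position outside the sequence")
    logits = embeddings[pos] @ params["mlm_w"] + params["mlm_b"]
    return ad.cross_entropy(logits, instance.target_ids)


# ---- chemistry ------------------------------------------------------------

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


@dataclass(frozen=True)
class MoleculeGraph:
    """Heavy-atom graph: per-atom (element, degree, formal charge, aromatic)
    and undirected bonds (i, j, order) with order 1/2/3/1.5 (aromatic)."""

    atoms: tuple[tuple[str, int, int, bool], ...]
    bonds: tuple[tuple[int, int, float], ...]
    smiles: str | None = None

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise InputError(f"bond ({i},{j}) has an invalid endpoint")
            if i == j:
                raise InputError("self-bonds are not allowed")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise InputError(f"duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for i, j, _ in self.bonds:
            a[i, j] = a[j, i] = 1.0
        return a


def smiles_to_graph(smiles: str) -> MoleculeGraph:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"could not parse SMILES string {smiles!r}")
    atoms = tuple(
        (a.GetSymbol(), a.GetDegree(), a.GetFormalCharge(), a.GetIsAromatic())
        for a in mol.GetAtoms())
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER[b.GetBondType()])
        for b in mol.GetBonds())
    return MoleculeGraph(atoms=atoms, bonds=bonds, smiles=smiles)


# atom featurization: element one-hot over the common organic subset,
# degree, formal charge, aromatic flag
_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
ATOM_FEATURE_DIM = len(_ELEMENTS) + 1 + 3  # +other slot, degree, charge, aromatic


def atom_features(graph: MoleculeGraph) -> np.ndarray:
    feats = np.zeros((graph.n_atoms, ATOM_FEATURE_DIM))
    for idx, (symbol, degree, charge, aromatic) in enumerate(graph.atoms):
        try:
            feats[idx, _ELEMENTS.index(symbol)] = 1.0
        except ValueError:
            feats[idx, len(_ELEMENTS)] = 1.0
        feats[idx, len(_ELEMENTS) + 1] = float(degree)
        feats[idx, len(_ELEMENTS) + 2] = float(charge)
        feats[idx, len(_ELEMENTS) + 3] = float(aromatic)
    return feats


@dataclass(frozen=True)
class ChemicalEncoderConfig:
    embedding_dim: int = 64
    n_rounds: int = 2

    def __post_init__(self):
        if self.embedding_dim <= 0 or self.n_rounds <= 0:
            raise InputError("chemical encoder dimensions must be positive")


def init_chemical_params(config: ChemicalEncoderConfig,
                         rng: np.random.Generator) -> dict[str, Tensor]:
    d = config.embedding_dim
    p = {"atom_proj_w": _normal(rng, ATOM_FEATURE_DIM, d, scale=0.2),
         "atom_proj_b": _zeros(d)}
    for k in range(config.n_rounds):
        pre = f"gin{k}."
        p[pre + "eps"] = _zeros(1)  # learnable epsilon, starts at 0
        p[pre + "w1"] = _normal(rng, d, d, scale=0.2)
        p[pre + "b1"] = _zeros(d)
        p[pre + "w2"] = _normal(rng, d, d, scale=0.2)
        p[pre + "b2"] = _zeros(d)
    return p


def gin_encode(graph: MoleculeGraph, params: dict[str, Tensor],
               config: ChemicalEncoderConfig) -> tuple[Tensor, Tensor]:
    """GIN message passing: per-atom embeddings (n_atoms, d) and the
    sum-pooled graph vector (d,).

    Each round applies h_v <- MLP((1 + eps) h_v + sum_{u in N(v)} h_u).
    """
    if graph.n_atoms == 0:
        raise InputError("cannot encode an empty molecular graph")
    adj = Tensor(graph.adjacency())
    h = Tensor(atom_features(graph)) @ params["atom_proj_w"] + params["atom_proj_b"]
    for k in range(config.n_rounds):
        pre = f"gin{k}."
        agg = h * (1.0 + params[pre + "eps"]) + adj @ h
        h = ad.relu(agg @ params[pre + "w1"] + params[pre + "b1"])
        h = h @ params[pre + "w2"] + params[pre + "b2"]
    pooled = h.sum(axis=0)
    return h, pooled
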