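"""Assembly of the chemical-protein interaction model.

The protein and chemical encoders emit position-specific embeddings
(one row per distilled triplet, one row per atom). Binding-site rows are
picked out by 0/1 *selector matrices*; the selected rows are combined
into a pairwise interaction tensor (elementwise products, the default)
or a Gram matrix (the compact alternative), pooled by two-way attentive
pooling, and fed to either the 10-way distogram head (structure stage)
or the two-linear-layer residual binary classifier (CPI stage).

Weights travel across the three training stages as a :class:`StageWeights`
bundle: the protein encoder is carried from sequence pretraining into
structure pretraining; protein encoder, chemical encoder and pooling are
carried into the CPI stage; the distogram head is dropped and the binary
classifier is freshly initialized.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoders import (ChemicalEncoderConfig, MoleculeGraph,
                       ProteinEncoderConfig, encode_protein, gin_encode,
                       init_chemical_params, init_protein_params)
from .msa import InputError

logger = logging.getLogger(__name__)

STAGES = ("mlm", "structure", "cpi")
STAGE_COMPONENTS = {
    "mlm": frozenset({"protein_encoder"}),
    "structure": frozenset({"protein_encoder", "chemical_encoder", "pooling",
                            "distogram_head"}),
    "cpi": frozenset({"protein_encoder", "chemical_encoder", "pooling",
                      "cpi_head"}),
}
# components carried over on each stage transition
STAGE_CARRY = {
    ("mlm", "structure"): frozenset({"protein_encoder"}),
    ("structure", "cpi"): frozenset({"protein_encoder", "chemical_encoder",
                                     "pooling"}),
}


class TransferError(ValueError):
    """Stage-order violation in weight transfer."""


@dataclass(frozen=True)
class ModelConfig:
    protein: ProteinEncoderConfig
    chemical: ChemicalEncoderConfig
    attention_dim: int = 32
    n_distogram_bins: int = 10
    interaction_mode: str = "pairwise"  # or "gram"

    def __post_init__(self):
        if self.protein.embedding_dim != self.chemical.embedding_dim:
            raise InputError("protein and chemical embedding dims must match")
        if self.interaction_mode not in {"pairwise", "gram"}:
            raise InputError(f"unknown interaction mode {self.interaction_mode!r}")

    @property
    def embedding_dim(self) -> int:
        return self.protein.embedding_dim


@dataclass
class StageWeights:
    stage: str
    config: ModelConfig
    params: dict[str, Tensor] = field(default_factory=dict)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise InputError(f"unknown stage {self.stage!r}")
        missing = {c for c in STAGE_COMPONENTS[self.stage]
                   if not any(k.startswith(c + ".") for k in self.params)}
        if missing:
            raise InputError(f"stage {self.stage!r} missing components {sorted(missing)}")

    def component(self, name: str) -> dict[str, Tensor]:
        pre = name + "."
        return {k[len(pre):]: v for k, v in self.params.items() if k.startswith(pre)}

    def copy(self) -> "StageWeights":
        return StageWeights(stage=self.stage, config=self.config,
                            params={k: v.copy() for k, v in self.params.items()})

    def checksum(self) -> float:
        return float(sum(np.abs(v.data).sum() for v in self.params.values()))


def _prefix(component: str, params: dict[str, Tensor]) -> dict[str, Tensor]:
    return {f"{component}.{k}": v for k, v in params.items()}


def _init_pooling(config: ModelConfig, rng) -> dict[str, Tensor]:
    d, a = config.embedding_dim, config.attention_dim
    return {"w": Tensor(rng.normal(scale=0.2, size=(d, a)), requires_grad=True),
            "u": Tensor(rng.normal(scale=0.2, size=(a, 1)), requires_grad=True)}


def _init_distogram_head(config: ModelConfig, rng) -> dict[str, Tensor]:
    d = config.embedding_dim
    inp = 3 * d  # pair feature (d) + pooled context (2d)
    return {"w1": Tensor(rng.normal(scale=0.2, size=(inp, d)), requires_grad=True),
            "b1": Tensor(np.zeros(d), requires_grad=True),
            "w2": Tensor(rng.normal(scale=0.2, size=(d, config.n_distogram_bins)),
                         requires_grad=True),
            "b2": Tensor(np.zeros(config.n_distogram_bins), requires_grad=True)}


def _init_cpi_head(config: ModelConfig, rng) -> dict[str, Tensor]:
    d2 = 2 * config.embedding_dim
    return {"w1": Tensor(rng.normal(scale=0.2, size=(d2, d2)), requires_grad=True),
            "b1": Tensor(np.zeros(d2), requires_grad=True),
            "w2": Tensor(rng.normal(scale=0.2, size=(d2, d2)), requires_grad=True),
            "b2": Tensor(np.zeros(d2), requires_grad=True),
            "wo": Tensor(rng.normal(scale=0.2, size=(d2, 1)), requires_grad=True),
            "bo": Tensor(np.zeros(1), requires_grad=True)}


_COMPONENT_INIT = {
    "protein_encoder": lambda cfg, rng: init_protein_params(cfg.protein, rng),
    "chemical_encoder": lambda cfg, rng: init_chemical_params(cfg.chemical, rng),
    "pooling": _init_pooling,
    "distogram_head": _init_distogram_head,
    "cpi_head": _init_cpi_head,
}


def init_stage(stage: str, config: ModelConfig,
               rng: np.random.Generator) -> StageWeights:
    params: dict[str, Tensor] = {}
    for comp in sorted(STAGE_COMPONENTS[stage]):
        params.update(_prefix(comp, _COMPONENT_INIT[comp](config, rng)))
    return StageWeights(stage=stage, config=config, params=params)


def transfer_weights(source: StageWeights, target_stage: str,
                     rng: np.random.Generator) -> StageWeights:
    """Carry encoder weights forward one stage; re-initialize the rest.

    mlm -> structure carries the protein encoder; structure -> cpi carries
    protein encoder, chemical encoder and pooling, drops the distogram
    head and randomly initializes the binary classifier.
    """
    key = (source.stage, target_stage)
    if key not in STAGE_CARRY:
        raise TransferError(
            f"cannot transfer {source.stage!r} -> {target_stage!r}; "
            f"stage order is {' -> '.join(STAGES)}")
    carried = STAGE_CARRY[key]
    dropped = STAGE_COMPONENTS[source.stage] - carried
    initialized = STAGE_COMPONENTS[target_stage] - carried
    logger.info("transfer %s->%s: carried=%s dropped=%s initialized=%s",
                source.stage, target_stage, sorted(carried), sorted(dropped),
                sorted(initialized))
    params: dict[str, Tensor] = {}
    for comp in sorted(carried):
        params.update(_prefix(comp, {k: v.copy()
                                     for k, v in source.component(comp).items()}))
    for comp in sorted(initialized):
        params.update(_prefix(comp, _COMPONENT_INIT[comp](source.config, rng)))
    return StageWeights(stage=target_stage, config=source.config, params=params)


# ---- selector matrices and interaction features ---------------------------

def build_selector(indices: list[int], total: int) -> np.ndarray:
    """0/1 matrix A with A @ H extracting the indexed rows of H in order."""
    if len(indices) == 0:
        raise InputError("selector needs at least one index")
    if len(set(indices)) != len(indices):
        raise InputError("selector indices must be distinct")
    if min(indices) < 0 or max(indices) >= total:
        raise InputError("selector index out of range")
    a = np.zeros((len(indices), total))
    a[np.arange(len(indices)), np.asarray(indices, dtype=np.intp)] = 1.0
    return a


def interaction_features(Hp: Tensor, Hc: Tensor, Ap: np.ndarray, Ac: np.ndarray,
                         mode: str = "pairwise") -> Tensor:
    """Binding-site interaction features.

    pairwise: tensor (n_res, n_atoms, d), entry (i, j, :) the elementwise
    product of the i-th selected residue vector and j-th selected atom
    vector. gram: (d, d) matrix (A_p H_p)^T (A_c H_c).
    """
    if Ap.shape[1] != Hp.shape[0]:
        raise InputError(f"protein selector {Ap.shape} does not match "
                         f"embeddings {Hp.shape}")
    if Ac.shape[1] != Hc.shape[0]:
        raise InputError(f"chemical selector {Ac.shape} does not match "
                         f"embeddings {Hc.shape}")
    if Hp.shape[1] != Hc.shape[1]:
        raise InputError("protein and chemical embedding dims differ")
    Hp_sel = Tensor(Ap) @ Hp
    Hc_sel = Tensor(Ac) @ Hc
    if mode == "gram":
        if Ap.shape[0] != Ac.shape[0]:
            raise InputError(
                f"gram mode needs equal selected counts, got {Ap.shape[0]} "
                f"residues vs {Ac.shape[0]} atoms")
        return ad.transpose(Hp_sel) @ Hc_sel
    if mode == "pairwise":
        n, m, d = Hp_sel.shape[0], Hc_sel.shape[0], Hp_sel.shape[1]
        return ad.reshape(Hp_sel, (n, 1, d)) * ad.reshape(Hc_sel, (1, m, d))
    raise InputError(f"unknown interaction mode {mode!r}")


def attentive_pool(tensor: Tensor, params: dict[str, Tensor]) -> tuple[Tensor, Tensor, Tensor]:
    """Two-way attentive pooling of a pairwise feature grid.

    Scores s_ij = u^T tanh(W f_ij); residue attention = softmax over the
    row-wise max scores, atom attention = softmax over the column-wise
    max; output is the concatenation of the attention-weighted residue-
    side and atom-side mean feature vectors (length 2d). Returns
    (pooled, row_weights, col_weights).
    """
    if tensor.ndim != 3:
        raise InputError("attentive pooling expects a pairwise (n, m, d) tensor")
    n, m, d = tensor.shape
    scores = ad.reshape(ad.tanh(ad.reshape(tensor, (n * m, d)) @ params["w"])
                        @ params["u"], (n, m))
    row_w = ad.softmax(ad.tensor_max(scores, axis=1), axis=0)   # (n,)
    col_w = ad.softmax(ad.tensor_max(scores, axis=0), axis=0)   # (m,)
    res_side = tensor.mean(axis=1)   # (n, d) residue-side representations
    atom_side = tensor.mean(axis=0)  # (m, d)
    pooled = ad.concat([
        ad.reshape(ad.reshape(row_w, (1, n)) @ res_side, (d,)),
        ad.reshape(ad.reshape(col_w, (1, m)) @ atom_side, (d,)),
    ], axis=0)
    return pooled, row_w, col_w


def distogram_logits(pair_features: Tensor, context: Tensor,
                     params: dict[str, Tensor]) -> Tensor:
    """Per-pair 10-way logits from the pair feature concatenated with the
    pooled complex context."""
    n, m, d = pair_features.shape
    flat = ad.reshape(pair_features, (n * m, d))
    ctx = ad.reshape(context, (1, context.shape[0])) * np.ones((n * m, 1))
    h = ad.relu(ad.concat([flat, ctx], axis=1) @ params["w1"] + params["b1"])
    return ad.reshape(h @ params["w2"] + params["b2"], (n, m, params["b2"].shape[0]))


def distogram_loss(pair_features: Tensor, context: Tensor,
                   labels: np.ndarray, params: dict[str, Tensor]) -> Tensor:
    """Mean cross-entropy over the (residue, atom) pair grid; labels are
    shaped (n_res, n_atoms) with entries in [0, n_bins)."""
    logits = distogram_logits(pair_features, context, params)
    labels = np.asarray(labels, dtype=np.intp)
    if labels.shape != logits.shape[:2]:
        raise InputError(f"labels {labels.shape} do not match pair grid "
                         f"{logits.shape[:2]}")
    n_bins = logits.shape[-1]
    if labels.size and (labels.min() < 0 or labels.max() >= n_bins):
        raise InputError(f"distogram label outside [0, {n_bins})")
    return ad.cross_entropy(ad.reshape(logits, (-1, n_bins)), labels.ravel())


def cpi_logit(protein_summary: Tensor, chemical_summary: Tensor,
              params: dict[str, Tensor]) -> Tensor:
    """Residual two-linear-layer classifier: scalar pre-sigmoid logit."""
    x = ad.reshape(ad.concat([protein_summary, chemical_summary], axis=0), (1, -1))
    h = ad.relu(x @ params["w1"] + params["b1"])
    z = x + h @ params["w2"] + params["b2"]       # skip connection
    return ad.reshape(z @ params["wo"] + params["bo"], ())


def cpi_head(protein_summary: Tensor, chemical_summary: Tensor,
             params: dict[str, Tensor]) -> Tensor:
    """Binding probability in (0, 1)."""
    return ad.sigmoid(cpi_logit(protein_summary, chemical_summary, params))


# ---- whole-model forward passes -------------------------------------------

def protein_summary(input_ids: np.ndarray, params: dict[str, Tensor],
                    config: ModelConfig) -> Tensor:
    """Mean over distilled positions of the protein encoder output."""
    comp = {k[len("protein_encoder."):]: v for k, v in params.items()
            if k.startswith("protein_encoder.")}
    return encode_protein(input_ids, comp, config.protein).mean(axis=0)


def chemical_summary(graph: MoleculeGraph, params: dict[str, Tensor],
                     config: ModelConfig) -> Tensor:
    """Sum over atoms of the GIN output."""
    comp = {k[len("chemical_encoder."):]: v for k, v in params.items()
            if k.startswith("chemical_encoder.")}
    _, pooled = gin_encode(graph, comp, config.chemical)
    return pooled


def cpi_forward(graph: MoleculeGraph, input_ids: np.ndarray,
                params: dict[str, Tensor], config: ModelConfig,
                protein_cache: dict | None = None) -> Tensor:
    """Pre-sigmoid CPI logit for one (molecule, protein) pair.

    ``protein_cache`` memoizes protein summaries within a batch keyed by
    the token-id bytes (proteins repeat heavily inside a family batch).
    """
    key = np.asarray(input_ids).tobytes()
    if protein_cache is not None and key in protein_cache:
        ps = protein_cache[key]
    else:
        ps = protein_summary(input_ids, params, config)
        if protein_cache is not None:
            protein_cache[key] = ps
    cs = chemical_summary(graph, params, config)
    head = {k[len("cpi_head."):]: v for k, v in params.items()
            if k.startswith("cpi_head.")}
    return cpi_logit(ps, cs, head)


def cpi_batch_loss(batch, params: dict[str, Tensor],
                   config: ModelConfig) -> Tensor:
    """Mean binary cross-entropy over labelled pairs.

    Accepts (molecule, protein_ids, label) tuples or any objects exposing
    ``molecule`` / ``protein_ids`` / ``label`` attributes.
    """
    if not batch:
        raise InputError("empty batch")
    items = [(p if isinstance(p, tuple)
              else (p.molecule, p.protein_ids, p.label)) for p in batch]
    cache: dict = {}
    logits = ad.concat([ad.reshape(cpi_forward(g, ids, params, config, cache), (1,))
                        for g, ids, _ in items], axis=0)
    labels = np.array([y for _, _, y in items], dtype=np.float64)
    return ad.binary_cross_entropy_with_logits(logits, labels)


# ---- checkpoints ----------------------------------------------------------

def save_checkpoint(weights: StageWeights, path: str | Path) -> None:
    """Single-file .npz with a JSON config header and stage tag."""
    header = {
        "stage": weights.stage,
        "protein": vars(weights.config.protein),
        "chemical": vars(weights.config.chemical),
        "attention_dim": weights.config.attention_dim,
        "n_distogram_bins": weights.config.n_distogram_bins,
        "interaction_mode": weights.config.interaction_mode,
    }
    arrays = {k: v.data for k, v in weights.params.items()}
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> StageWeights:
    with np.load(path) as z:
        header = json.loads(bytes(z["__header__"].tobytes()).decode())
        params = {k: Tensor(z[k], requires_grad=True)
                  for k in z.files if k != "__header__"}
    config = ModelConfig(
        protein=ProteinEncoderConfig(**{k: v for k, v in header["protein"].items()}),
        chemical=ChemicalEncoderConfig(**header["chemical"]),
        attention_dim=header["attention_dim"],
        n_distogram_bins=header["n_distogram_bins"],
        interaction_mode=header["interaction_mode"])
    return StageWeights(stage=header["stage"], config=config, params=params)
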