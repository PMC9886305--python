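"""Out-of-cluster meta-learning (MAML-style) over family-clustered CPI data.

Each protein family is a task. An outer step samples a handful of
families; for each, the inner loop takes ``L`` plain gradient steps of
size ``alpha`` on balanced mini-batches from the family's *support* set,
producing adapted weights; the *query*-set losses of the adapted weights
are summed across the sampled families and a single outer gradient step
of size ``beta`` updates the shared initialization. In first-order mode
the adapted weights are treated as constants of the outer parameters
(standard memory-light MAML practice); second-order mode differentiates
through the inner gradient steps.

Everything is functional — weights are ``dict[str, Tensor]`` and every
update returns a fresh dict — so the inner loop can never mutate the
outer parameters.

RNG contract (relied on by the exact plain-SGD reduction): each outer
step draws, in order, (1) the family ids for the meta-batch, then per
family (2) ``L`` balanced support batches and (3) one balanced query
batch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoders import MoleculeGraph
from .model import ModelConfig, StageWeights, cpi_batch_loss, cpi_forward
from .msa import InputError


class BalanceError(ValueError):
    """A class needed for a balanced batch is entirely absent."""


class DivergenceError(FloatingPointError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class LabeledPair:
    molecule: MoleculeGraph
    protein_ids: np.ndarray
    label: int
    molecule_id: str = ""
    member_id: str = ""


@dataclass
class FamilyDataset:
    """family_id -> labelled (molecule, distilled protein, y) pairs."""

    families: dict[str, list[LabeledPair]]

    def __post_init__(self):
        self.families = {f: list(p) for f, p in self.families.items()}

    def family_ids(self) -> list[str]:
        return sorted(self.families)

    def sizes(self) -> dict[str, int]:
        return {f: len(p) for f, p in self.families.items()}

    def subset(self, family_ids: Sequence[str]) -> "FamilyDataset":
        return FamilyDataset({f: self.families[f] for f in family_ids})

    def all_pairs(self) -> list[LabeledPair]:
        return [p for f in self.family_ids() for p in self.families[f]]


@dataclass(frozen=True)
class MetaConfig:
    alpha: float = 0.05
    beta: float = 0.05
    L: int = 2
    T: int = 60
    K: int = 8
    families_per_meta_batch: int = 4
    first_order: bool = True
    family_sampling: str = "proportional"  # or "uniform"
    checkpoint_interval: int = 10
    max_grad_norm: float | None = 1.0  # None = the pseudocode's raw steps
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise InputError("step sizes must be nonnegative")
        if min(self.L, self.T, self.K) < 0:
            raise InputError("L, T, K must be nonnegative")
        if self.K % 2:
            raise InputError("K must be even for positive-negative balance")


@dataclass
class SupportQuerySplit:
    support: dict[str, list[LabeledPair]]
    query: dict[str, list[LabeledPair]]
    single_class: dict[str, bool]
    ratio: tuple[int, int] = (5, 1)

    def eligible_families(self) -> list[str]:
        return sorted(f for f, flag in self.single_class.items() if not flag)


def split_support_query(pairs: Sequence[LabeledPair],
                        rng: np.random.Generator,
                        ratio: tuple[int, int] = (5, 1),
                        ) -> tuple[list[LabeledPair], list[LabeledPair], bool]:
    """Random support/query partition at ``ratio`` (default 5:1).

    Families with only one label class are returned unsplit (everything
    in support) with the single-class flag set; they are excluded from
    meta-training because no balanced batch exists.
    """
    pairs = list(pairs)
    if not pairs:
        warnings.warn("empty family skipped in support/query split")
        return [], [], True
    labels = {p.label for p in pairs}
    if len(labels) < 2:
        return pairs, [], True
    perm = rng.permutation(len(pairs))
    n_query = int(round(len(pairs) * ratio[1] / (ratio[0] + ratio[1])))
    query_idx = set(perm[:n_query].tolist())
    support = [p for i, p in enumerate(pairs) if i not in query_idx]
    query = [p for i, p in enumerate(pairs) if i in query_idx]
    return support, query, False


def make_support_query_split(data: FamilyDataset, rng: np.random.Generator,
                             ratio: tuple[int, int] = (5, 1)) -> SupportQuerySplit:
    support, query, flags = {}, {}, {}
    for fid in data.family_ids():
        s, q, single = split_support_query(data.families[fid], rng, ratio)
        support[fid], query[fid], flags[fid] = s, q, single
    return SupportQuerySplit(support=support, query=query, single_class=flags,
                             ratio=ratio)


def sample_family(family_ids: Sequence[str], sizes: dict[str, int],
                  rng: np.random.Generator,
                  mode: str = "proportional") -> str:
    if not family_ids:
        raise InputError("no families to sample from")
    if mode == "uniform":
        p = np.full(len(family_ids), 1.0 / len(family_ids))
    elif mode == "proportional":
        w = np.array([sizes[f] for f in family_ids], dtype=float)
        p = w / w.sum()
    else:
        raise InputError(f"unknown family sampling mode {mode!r}")
    return family_ids[int(rng.choice(len(family_ids), p=p))]


def sample_balanced_batch(pairs: Sequence[LabeledPair], k: int,
                          rng: np.random.Generator) -> list[LabeledPair]:
    """k/2 positives and k/2 negatives, with replacement when a class is
    smaller than k/2."""
    if k < 2:
        raise InputError("K must be at least 2")
    pos = [p for p in pairs if p.label == 1]
    neg = [p for p in pairs if p.label == 0]
    if not pos or not neg:
        raise BalanceError("balanced batch needs both classes present "
                           "(single-class families must stay unsplit)")
    half = k // 2
    batch = []
    for pool in (pos, neg):
        replace = len(pool) < half
        idx = rng.choice(len(pool), size=half, replace=replace)
        batch.extend(pool[int(i)] for i in idx)
    return batch


def sample_uniform_batch(pairs: Sequence[LabeledPair], k: int,
                         rng: np.random.Generator) -> list[LabeledPair]:
    """k uniform draws with replacement (query-side mini-batch; balance is
    only required of the support batches)."""
    if not pairs:
        raise InputError("cannot sample from an empty pair list")
    idx = rng.integers(0, len(pairs), size=k)
    return [pairs[int(i)] for i in idx]


# ---- inner loop and meta update -------------------------------------------

LossFn = Callable[[dict[str, Tensor]], Tensor]


def clip_gradients(grads: dict[str, Tensor],
                   max_norm: float | None) -> dict[str, Tensor]:
    """Rescale so the global gradient norm is at most ``max_norm`` (the
    scale factor is treated as a constant when differentiating through)."""
    if max_norm is None:
        return grads
    total = math.sqrt(sum(float((g.data ** 2).sum()) for g in grads.values()))
    if total <= max_norm or total == 0.0:
        return grads
    scale = max_norm / total
    return {k: g * scale for k, g in grads.items()}


def sgd_params(params: dict[str, Tensor], grads: dict[str, Tensor],
               lr: float, create_graph: bool = False) -> dict[str, Tensor]:
    """One gradient step, returning a fresh weight dict."""
    if create_graph:
        return {k: params[k] - lr * grads[k] for k in params}
    return {k: Tensor(params[k].data - lr * grads[k].data, requires_grad=True)
            for k in params}


def inner_adapt(params: dict[str, Tensor], loss_fns: Sequence[LossFn],
                alpha: float, create_graph: bool = False,
                max_grad_norm: float | None = None) -> dict[str, Tensor]:
    """L successive gradient steps (one per loss_fn), starting from and
    never mutating ``params``.

    With ``create_graph=True`` the adapted weights remain differentiable
    functions of ``params`` (second-order meta-learning).
    """
    current = dict(params)
    keys = sorted(params)
    for step, loss_fn in enumerate(loss_fns):
        loss = loss_fn(current)
        if not np.isfinite(loss.data).all():
            raise DivergenceError(f"non-finite inner loss at step {step}")
        grads = ad.grad(loss, [current[k] for k in keys],
                        create_graph=create_graph)
        clipped = clip_gradients(dict(zip(keys, grads)), max_grad_norm)
        current = sgd_params(current, clipped, alpha,
                             create_graph=create_graph)
    return current


def meta_update(params: dict[str, Tensor],
                query_losses: Sequence[tuple[Tensor, dict[str, Tensor]]],
                beta: float, first_order: bool = True,
                max_grad_norm: float | None = None) -> dict[str, Tensor]:
    """Outer step: theta <- theta - beta * grad of the summed query losses.

    ``query_losses`` pairs each family's query loss with the adapted
    weights it was evaluated at. First-order mode takes gradients at the
    adapted weights and applies them to ``params``; second-order mode
    differentiates through the inner trajectory back to ``params``.
    """
    if not query_losses:
        raise InputError("meta_update needs at least one family's query loss")
    keys = sorted(params)
    total_grad = {k: np.zeros(params[k].shape) for k in keys}
    if first_order:
        for loss, adapted in query_losses:
            grads = ad.grad(loss, [adapted[k] for k in keys])
            for k, g in zip(keys, grads):
                total_grad[k] += g.data
    else:
        total = query_losses[0][0]
        for loss, _ in query_losses[1:]:
            total = total + loss
        grads = ad.grad(total, [params[k] for k in keys])
        for k, g in zip(keys, grads):
            total_grad[k] += g.data
    clipped = clip_gradients({k: Tensor(v) for k, v in total_grad.items()},
                             max_grad_norm)
    return {k: Tensor(params[k].data - beta * clipped[k].data,
                      requires_grad=True) for k in keys}


# ---- the full training loop -----------------------------------------------

@dataclass
class Checkpoint:
    step: int
    weights: StageWeights
    dev_report: "object | None" = None  # MetricReport, attached by the caller

    @property
    def dev_pr_auc(self) -> float | None:
        return None if self.dev_report is None else self.dev_report.pr_auc


@dataclass
class TrainState:
    weights: StageWeights
    step: int
    checkpoints: list[Checkpoint] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)
    seed: int = 0


def predict_scores(weights: StageWeights, pairs: Sequence[LabeledPair]) -> np.ndarray:
    """Binding probabilities for labelled pairs (no gradient recording)."""
    with ad.no_grad():
        cache: dict = {}
        out = np.empty(len(pairs))
        for i, p in enumerate(pairs):
            logit = cpi_forward(p.molecule, p.protein_ids, weights.params,
                                weights.config, cache)
            out[i] = 1.0 / (1.0 + math.exp(-float(logit.data)))
    return out


def train(model: StageWeights, data: FamilyDataset, config: MetaConfig,
          split: SupportQuerySplit | None = None,
          dev_eval: Callable[[StageWeights, int], "object | None"] | None = None,
          ) -> TrainState:
    """Algorithm: T outer steps of out-of-cluster meta-learning.

    Checkpoints (deep weight copies, with the caller's OOD-dev report
    attached via ``dev_eval``) are emitted every ``checkpoint_interval``
    outer steps and at the end.
    """
    if model.stage != "cpi":
        raise InputError("OOC-ML training expects cpi-stage weights "
                         "(transfer from the structure stage first)")
    rng = np.random.default_rng(config.seed)
    if split is None:
        split = make_support_query_split(data, rng)
    eligible = [f for f in split.eligible_families()
                if split.query[f]
                and len({p.label for p in split.support[f]}) == 2]
    if not eligible:
        raise InputError("no two-class families with a query set; "
                         "nothing to meta-train on")
    sizes = data.sizes()
    params = {k: v.copy() for k, v in model.params.items()}
    mcfg: ModelConfig = model.config
    state = TrainState(weights=StageWeights("cpi", mcfg, params), step=0,
                       seed=config.seed)

    def emit(step: int):
        w = StageWeights("cpi", mcfg, {k: v.copy() for k, v in params.items()})
        report = dev_eval(w, step) if dev_eval is not None else None
        state.checkpoints.append(Checkpoint(step=step, weights=w,
                                            dev_report=report))

    for t in range(config.T):
        fams = [sample_family(eligible, sizes, rng, config.family_sampling)
                for _ in range(config.families_per_meta_batch)]
        query_losses = []
        support_loss_acc = []
        for fid in fams:
            support_batches = [sample_balanced_batch(split.support[fid],
                                                     config.K, rng)
                               for _ in range(config.L)]

            def loss_of(batch):
                return lambda p: cpi_batch_loss(batch, p, mcfg)

            adapted = inner_adapt(params, [loss_of(b) for b in support_batches],
                                  config.alpha,
                                  create_graph=not config.first_order,
                                  max_grad_norm=config.max_grad_norm)
            query_batch = sample_uniform_batch(split.query[fid], config.K, rng)
            qloss = cpi_batch_loss(query_batch, adapted, mcfg)
            if not np.isfinite(qloss.data).all():
                raise DivergenceError(f"non-finite query loss at outer step {t}")
            query_losses.append((qloss, adapted))
            support_loss_acc.append(float(qloss.data))
        params = meta_update(params, query_losses, config.beta,
                             first_order=config.first_order,
                             max_grad_norm=config.max_grad_norm)
        state.weights = StageWeights("cpi", mcfg, params)
        state.step = t + 1
        state.log.append({"step": t + 1, "families": fams,
                          "query_loss": float(np.mean(support_loss_acc))})
        if config.checkpoint_interval and (t + 1) % config.checkpoint_interval == 0:
            emit(t + 1)
    if not state.checkpoints or state.checkpoints[-1].step != config.T:
        emit(config.T)
    state.weights = StageWeights("cpi", mcfg, params)
    return state
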