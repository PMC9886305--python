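"""Canned desk-scale experiments: the full three-stage pipeline and the
planted-rule out-of-distribution benchmark.

These are the package's reference workloads: a complete
simulate -> distill -> MLM -> structure -> transfer -> OOC-ML ->
stress-select -> evaluate chain at small dimensions (embedding 16, two
shared transformer layers), and a generalization trial on the synthetic
dataset's held-out families. Both are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import ChemicalEncoderConfig, ProteinEncoderConfig
from .evaluation import (deployment_gap, make_ood_split, metric_report,
                         stress_select)
from .model import ModelConfig, init_stage, transfer_weights
from .oocml import MetaConfig, predict_scores, train
from .synthetic import GeneratorConfig, generate_dataset
from .training import (build_family_dataset, distill_corpus,
                       prepare_structure_instances, pretrain_mlm,
                       pretrain_structure)

#: study conditions of the OOD benchmark: 40 families split 30/5/5,
#: 40 labelled pairs per family, 10% label noise
BENCHMARK_GENERATOR = dict(n_families=40, members_per_family=6,
                           pairs_per_family=40, n_molecules=60,
                           label_noise=0.1)
BENCHMARK_SPLIT_FRACTIONS = (0.75, 0.125, 0.125)


def tiny_model_config(vocab_size: int) -> ModelConfig:
    return ModelConfig(
        protein=ProteinEncoderConfig(vocab_size=vocab_size, embedding_dim=16,
                                     n_layers=2, n_heads=2, max_positions=64),
        chemical=ChemicalEncoderConfig(embedding_dim=16),
        attention_dim=16)


@dataclass
class OodTrialResult:
    seed: int
    untrained_roc_auc: float
    final_roc_auc: float
    final_pr_auc: float
    selected_step: int
    final_step: int
    selected_gap_roc: float
    final_gap_roc: float
    selected_roc_auc: float

    @property
    def selection_shrinks_gap(self) -> bool:
        return abs(self.selected_gap_roc) < abs(self.final_gap_roc)


def ood_generalization_trial(seed: int, outer_steps: int = 120) -> OodTrialResult:
    """One planted-rule OOD benchmark run.

    Families are split 30/5/5 (train / OOD-dev / OOD-test); a fresh
    CPI-stage model is meta-trained on the training families and scored
    on the held-out test families; the stress-selected checkpoint's
    deployment gap is compared with the final checkpoint's.
    """
    dataset = generate_dataset(GeneratorConfig(seed=seed, **BENCHMARK_GENERATOR))
    corpus = distill_corpus([sf.family for sf in dataset.families])
    config = tiny_model_config(len(corpus.vocab))
    data = build_family_dataset(dataset, corpus)
    split_rng = np.random.default_rng(seed + 1000)
    plan = make_ood_split(data.family_ids(), split_rng,
                          fractions=BENCHMARK_SPLIT_FRACTIONS,
                          pairs_by_family=data.families)
    dev_pairs, test_pairs = plan.ood_dev_pairs, plan.ood_test_pairs
    test_labels = [p.label for p in test_pairs]

    weights0 = init_stage("cpi", config, np.random.default_rng(seed + 2000))
    untrained = metric_report(predict_scores(weights0, test_pairs), test_labels)

    def dev_eval(w, step):
        return metric_report(predict_scores(w, dev_pairs),
                             [p.label for p in dev_pairs])

    mcfg = MetaConfig(alpha=0.05, beta=0.1, L=2, T=outer_steps, K=8,
                      families_per_meta_batch=4, checkpoint_interval=10,
                      max_grad_norm=1.0, seed=seed)
    state = train(weights0, data.subset(sorted(plan.ood_train_families)),
                  mcfg, dev_eval=dev_eval)
    selected = stress_select(state.checkpoints)
    final = state.checkpoints[-1]

    def test_and_gap(ckpt):
        rep = metric_report(predict_scores(ckpt.weights, test_pairs), test_labels)
        return rep, deployment_gap(rep, ckpt.dev_report)

    sel_rep, sel_gap = test_and_gap(selected)
    fin_rep, fin_gap = test_and_gap(final)
    return OodTrialResult(
        seed=seed, untrained_roc_auc=untrained.roc_auc,
        final_roc_auc=fin_rep.roc_auc, final_pr_auc=fin_rep.pr_auc,
        selected_step=selected.step, final_step=final.step,
        selected_gap_roc=sel_gap.gap_roc, final_gap_roc=fin_gap.gap_roc,
        selected_roc_auc=sel_rep.roc_auc)


def pipeline_smoke(seed: int, n_families: int = 20, mlm_steps: int = 200,
                   structure_steps: int = 300, outer_steps: int = 30) -> dict:
    """The full three-stage chain on one small dataset; returns the loss
    traces and OOD metrics of every stage."""
    dataset = generate_dataset(GeneratorConfig(
        seed=seed, n_families=n_families, members_per_family=6,
        pairs_per_family=40, n_molecules=60, label_noise=0.1))
    corpus = distill_corpus([sf.family for sf in dataset.families])
    config = tiny_model_config(len(corpus.vocab))
    rng = np.random.default_rng(seed)

    mlm_weights, mlm_losses = pretrain_mlm(corpus, config, mlm_steps, rng)
    structure_weights = transfer_weights(mlm_weights, "structure", rng)
    instances, edges = prepare_structure_instances(dataset, corpus)
    structure_weights, structure_losses = pretrain_structure(
        instances, structure_weights, structure_steps, rng)
    cpi_weights = transfer_weights(structure_weights, "cpi", rng)

    data = build_family_dataset(dataset, corpus)
    plan = make_ood_split(data.family_ids(), np.random.default_rng(seed + 1),
                          fractions=(0.6, 0.2, 0.2),
                          pairs_by_family=data.families)
    dev_pairs, test_pairs = plan.ood_dev_pairs, plan.ood_test_pairs

    def dev_eval(w, step):
        return metric_report(predict_scores(w, dev_pairs),
                             [p.label for p in dev_pairs])

    state = train(cpi_weights, data.subset(sorted(plan.ood_train_families)),
                  MetaConfig(T=outer_steps, seed=seed, beta=0.1,
                             checkpoint_interval=10),
                  dev_eval=dev_eval)
    selected = stress_select(state.checkpoints)
    test_rep = metric_report(predict_scores(selected.weights, test_pairs),
                             [p.label for p in test_pairs])
    gap = deployment_gap(test_rep, selected.dev_report)
    return {
        "vocab_size": len(corpus.vocab),
        "mlm_loss": float(np.mean(mlm_losses[-20:])),
        "mlm_uniform_baseline": float(np.log(len(corpus.vocab))),
        "distogram_loss": float(np.mean(structure_losses[-20:])),
        "distogram_uniform_baseline": float(np.log(10)),
        "n_distogram_edges": len(edges),
        "n_complexes": len(instances),
        "ood_test_roc_auc": test_rep.roc_auc,
        "ood_test_pr_auc": test_rep.pr_auc,
        "ood_dev_roc_auc": selected.dev_report.roc_auc,
        "deployment_gap_roc": gap.gap_roc,
        "deployment_gap_pr": gap.gap_pr,
        "selected_step": selected.step,
        "n_test_pairs": len(test_pairs),
    }
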