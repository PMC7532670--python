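"""Cross-cohort generalization: zero-shot scoring, fine-tuning, fraction sweep.

A model trained on one cohort degrades on a domain-shifted cohort (different
slide preparation, population).  Transfer learning bridges the gap with a
small labeled fraction of the new cohort: when a patch-level CNN is present,
its weights are reused and fine-tuned at a reduced learning rate; the
WSI-level aggregators (vocabulary, PALHI, BoW, ensemble weight, cutoff) are
always refit from scratch on the tuning subset.  Evaluation is on the
complement of the tuning subset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import EplaModel, bags_from_table, fit_epla
from .cohort_io import SlideRecord, labels_series, stratified_split
from .evaluation import delong_ci, roc_auc
from .patch_mil import PatchModel, PatchStore, predict_patch_likelihoods


@dataclass
class TransferConfig:
    """Fine-tuning schedule for the new cohort."""

    fractions: tuple[float, ...] = (0.1, 0.3, 0.4, 0.6, 0.7)
    fine_tune_lr_scale: float = 0.1
    fine_tune_epochs: int = 3
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        if any(not 0 < f < 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0,1)")
        if list(self.fractions) != sorted(self.fractions):
            raise ValueError("fractions must be strictly increasing")


@dataclass
class TransferResult:
    epla: EplaModel
    patch_model: PatchModel | None
    tune_ids: list[str]
    eval_ids: list[str]


def zero_shot_scores(
    model: EplaModel, new_bags: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Apply a source-trained model to a new cohort without touching its labels."""
    return model.score_bags(new_bags)


def _split_tuning(records: list[SlideRecord], fraction: float, seed: int):
    part = stratified_split(records, train_fraction=fraction, seed=seed)
    return sorted(part.train_ids), sorted(part.test_ids)


def fine_tune(
    model: PatchModel | None,
    new_records: list[SlideRecord],
    fraction: float,
    cfg: TransferConfig,
    new_bags: dict[str, np.ndarray] | None = None,
    new_patches: PatchStore | None = None,
) -> TransferResult:
    """Adapt to a new cohort using a stratified ``fraction`` of its slides.

    With image patches and a source CNN, the CNN is fine-tuned (all layers,
    learning rate scaled by ``fine_tune_lr_scale``) on the tuning subset and
    likelihoods are recomputed; in likelihood mode (``new_bags``), the
    existing bags are used directly.  The WSI-level stack is refit on the
    tuning subset; the held-out complement is returned for evaluation.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0,1)")
    tune_ids, eval_ids = _split_tuning(new_records, fraction, cfg.seed)
    labels = labels_series(new_records)
    if labels.loc[tune_ids].nunique() < 2:
        raise ValueError("tuning subset is single-class")

    tuned_model = model
    if new_patches is not None and model is not None:
        ft_cfg = dataclasses.replace(
            model.cfg,
            epochs=cfg.fine_tune_epochs,
            learning_rate=model.cfg.learning_rate * cfg.fine_tune_lr_scale,
            seed=cfg.seed,
        )
        tune_records = [r for r in new_records if r.slide_id in set(tune_ids)]
        tuned_model = _fine_tune_from(model, new_patches.subset(tune_ids),
                                      tune_records, ft_cfg)
        table = predict_patch_likelihoods(tuned_model, new_patches)
        new_bags = bags_from_table(table)
    if new_bags is None:
        raise ValueError("provide new_bags (likelihood mode) or new_patches + model")

    tune_bags = {s: new_bags[s] for s in tune_ids}
    epla = fit_epla(tune_bags, labels, cv_folds=cfg.cv_folds, seed=cfg.seed)
    return TransferResult(epla=epla, patch_model=tuned_model,
                          tune_ids=tune_ids, eval_ids=eval_ids)


def _fine_tune_from(source: PatchModel, patches: PatchStore,
                    records: list[SlideRecord], ft_cfg) -> PatchModel:
    """Continue SGD from the source model's weights on the tuning patches."""
    import copy

    from ._nn import SGDMomentum, bce_with_logits
    from .patch_mil import _prepare_tensors
    from .cohort_io import MSI

    net = copy.deepcopy(source.net)
    opt = SGDMomentum(ft_cfg.learning_rate, ft_cfg.momentum)
    label_of = {r.slide_id: 1 if r.ms_label == MSI else 0 for r in records}
    rng = np.random.default_rng(ft_cfg.seed)
    x = _prepare_tensors(patches, source.channel_mean, source.channel_std,
                         ft_cfg.input_size)
    y = np.array([label_of[k[0]] for k in patches.keys], dtype=float)
    trace = []
    for _ in range(ft_cfg.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(order), ft_cfg.batch_size):
            sl = order[start : start + ft_cfg.batch_size]
            z = net.forward(x[sl])
            loss, dz = bce_with_logits(z, y[sl])
            net.backward(dz)
            opt.step(net.all_layers)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return PatchModel(net=net, cfg=ft_cfg, channel_mean=source.channel_mean,
                      channel_std=source.channel_std, loss_trace=trace)


def evaluate_transfer(
    result: TransferResult,
    new_bags: dict[str, np.ndarray],
    new_records: list[SlideRecord],
) -> tuple[float, tuple[float, float]]:
    """AUC (with DeLong CI) of the adapted model on the held-out complement."""
    labels = labels_series(new_records)
    scores = result.epla.score_bags({s: new_bags[s] for s in result.eval_ids})
    y = labels.loc[scores.index].to_numpy()
    s = scores["ensemble_score"].to_numpy()
    return roc_auc(s, y), delong_ci(s, y)


def fraction_sweep(
    model: PatchModel | None,
    new_records: list[SlideRecord],
    cfg: TransferConfig,
    new_bags: dict[str, np.ndarray] | None = None,
    new_patches: PatchStore | None = None,
) -> pd.DataFrame:
    """Fine-tune at each configured fraction; rows sorted by fraction ascending.

    Each fraction is evaluated on its own held-out complement under the same
    seed policy, so rows are comparable.
    """
    rows = []
    for fraction in cfg.fractions:
        res = fine_tune(model, new_records, fraction, cfg,
                        new_bags=new_bags, new_patches=new_patches)
        bags = new_bags
        if bags is None:
            table = predict_patch_likelihoods(res.patch_model, new_patches)
            bags = bags_from_table(table)
        auc, (lo, hi) = evaluate_transfer(res, bags, new_records)
        rows.append(
            {
                "fraction": fraction,
                "n_tune": len(res.tune_ids),
                "n_eval": len(res.eval_ids),
                "auc": auc,
                "ci_low": lo,
                "ci_high": hi,
                "seed": cfg.seed,
            }
        )
    return pd.DataFrame(rows, columns=["fraction", "n_tune", "n_eval", "auc",
                                       "ci_low", "ci_high", "seed"])
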