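"""End-to-end desk-scale experiment: synthesize a cohort, train the MIL
model, evaluate on held-out slides, and quantify attention localization.

This composes the package's modules into the reference experiment used by
the test suite and the reproduction script: an 80-slide synthetic cohort at
50% prevalence, a stratified 75:25 development/test split, the ``tiny_cnn``
attention-MIL transformer trained for 15 epochs, whole-slide inference on
the test slides, and the interpretability statistics (attention enrichment
on ground-truth-positive tiles, normalized attention entropy by class, and
TFF3 stain-attention correlation on true-positive slides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import interpret, mil_model as mm, stain_correspondence as sc, tiling
from .evaluation import auroc, stratified_splits
from .synthdata import SyntheticSpec, generate_cohort, generate_pair
from .types import GroundTruthMask, SlidePrediction


def attention_enrichment(pred: SlidePrediction,
                         truth: GroundTruthMask) -> float:
    """Attention mass on ground-truth-positive tiles over their count share.

    1.0 means attention is no more concentrated on goblet-cell tiles than a
    uniform distribution; NaN when the prediction covers no positive tile.
    """
    tsize = truth.tile_size
    pos_coords = {(j * tsize, i * tsize)
                  for i in range(truth.tile_positive.shape[0])
                  for j in range(truth.tile_positive.shape[1])
                  if truth.tile_positive[i, j]}
    mask = np.array([tuple(c) in pos_coords for c in pred.coords])
    if not mask.any():
        return float("nan")
    return float(pred.attention[mask].sum() / mask.mean())


@dataclass
class DeskRunResult:
    spec: SyntheticSpec
    model: mm.TransMIL
    config: mm.MILConfig
    train_log: mm.TrainLog
    test_indices: list[int]
    predictions: list[SlidePrediction]
    labels: list[int]
    truths: list[GroundTruthMask]
    test_auroc: float
    enrichment: list[float] = field(default_factory=list)
    entropy_positive: list[float] = field(default_factory=list)
    entropy_negative: list[float] = field(default_factory=list)

    @property
    def mean_enrichment(self) -> float:
        return float(np.nanmean(self.enrichment))

    def positive_test_indices(self) -> list[int]:
        return [i for i, lbl in zip(self.test_indices, self.labels) if lbl]


def desk_scale_run(data_seed: int = 11, model_seed: int = 0,
                   n_slides: int = 80, prevalence: float = 0.5,
                   epochs: int = 15, bag_size: int = 20,
                   lr: float = 2e-3, test_fraction: float = 0.25,
                   split_seed: int = 0) -> DeskRunResult:
    """Train and evaluate the reference desk-scale experiment.

    Completes in a few minutes on one CPU.  Deterministic given the seeds.
    """
    spec = SyntheticSpec(n_slides=n_slides, prevalence=prevalence,
                         seed=data_seed)
    cohort = list(generate_cohort(spec, with_tff3=False))
    labels_df = pd.DataFrame({
        "slide_id": [truth.slide_id for _, _, truth, _ in cohort],
        "label": [he.label for he, _, _, _ in cohort],
        "pathway": [pathway for _, _, _, pathway in cohort],
    })
    plan = stratified_splits(labels_df, n_folds=4,
                             test_fraction=test_fraction, seed=split_seed)
    test_ids = set(plan.loc[plan["split"] == "test", "slide_id"])

    train_set = [(he, he.label) for he, _, truth, _ in cohort
                 if truth.slide_id not in test_ids]
    test = [(i, he, truth) for i, (he, _, truth, _) in enumerate(cohort)
            if truth.slide_id in test_ids]

    cfg = mm.MILConfig(encoder="tiny_cnn", bag_size=bag_size, lr=lr,
                       epochs=epochs, seed=model_seed, chunk_size=32)
    model = mm.build_model(cfg)
    log = mm.train(model, train_set, cfg)

    result = DeskRunResult(
        spec=spec, model=model, config=cfg, train_log=log,
        test_indices=[i for i, _, _ in test],
        predictions=[], labels=[], truths=[], test_auroc=float("nan"))
    for _, he, truth in test:
        pred = mm.infer_slide(model, he)
        result.predictions.append(pred)
        result.labels.append(int(he.label))
        result.truths.append(truth)
        entropy = interpret.normalized_entropy(pred.attention)
        if he.label:
            result.entropy_positive.append(entropy)
            result.enrichment.append(attention_enrichment(pred, truth))
        else:
            result.entropy_negative.append(entropy)
    result.test_auroc = auroc([p.probability for p in result.predictions],
                              result.labels)
    return result


def correspondence_for_slide(result: DeskRunResult, slide_index: int
                             ) -> sc.CorrespondenceResult:
    """Register the slide's TFF3 section and correlate stain with attention.

    ``slide_index`` is a cohort index; the paired TFF3 image is regenerated
    bit-identically from the cohort seed.
    """
    he, tff3, _ = generate_pair(result.spec, slide_index)
    pos = result.test_indices.index(slide_index)
    pred = result.predictions[pos]
    fg, stain = sc.dab_mask(tff3)
    reg = sc.register(he, tff3)
    shape = he.pixels.shape[:2]
    fg_reg = sc.apply_transform(reg, fg, shape, he.mpp, is_mask=True)
    stain_reg = sc.apply_transform(reg, stain, shape, he.mpp, is_mask=True)
    grid = tiling.TileGrid(origin_offset=(0, 0), tile_size=224,
                           coords=pred.coords)
    ratio_map = sc.tile_stain_ratio(stain_reg, fg_reg, grid,
                                    slide_id=pred.slide_id)
    # registration quality: overlap of comparable whole-tissue masks
    from .preprocess import he_foreground_mask

    tff3_tissue = he_foreground_mask(tff3).mask
    tissue_reg = sc.apply_transform(reg, tff3_tissue, shape, he.mpp,
                                    is_mask=True)
    quality = sc.dice(he_foreground_mask(he).mask, tissue_reg)
    return sc.stain_attention_correlation(ratio_map, pred,
                                          registration_quality=quality)
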