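"""Attention-MIL slide classifier with a transformer dependency module.

A slide is a bag of tile instances sharing one diagnostic label.  Each tile
is encoded to an embedding, four transformer encoder layers model
dependencies between tiles in the bag, attention-MIL pooling produces a
single bag embedding as the attention-weighted sum of tile embeddings, and a
linear classifier maps it to the slide probability.  The whole stack is
trained end to end with class-reweighted binary cross-entropy using only
slide-level labels; the learned attention distribution is the
interpretability signal.

Training hyperparameter defaults follow the reference protocol for the
full-scale encoders (lr 3e-5, weight decay 0.1, batch of 8 slides, 50
epochs); desk-scale runs with the bundled ``tiny_cnn`` encoder typically
override ``lr`` and ``epochs``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .tiling import (
    TILE_SIZE,
    augment,
    extract_bag_tiles,
    filter_background,
    grid_tiles,
    select_bag,
    whole_slide_bag,
)
from .types import SlideImage, SlidePrediction, TileBag

#: bag sizes used with each encoder at full scale (GPU memory bound);
#: tiny_cnn covers the whole synthetic grid at desk scale
ENCODER_BAG_SIZES = {
    "resnet50": 1200,
    "resnet18": 2300,
    "swin_tiny": 1100,
    "densenet121": 700,
    "tiny_cnn": 48,
}

PRETRAINED_ENCODERS = ("resnet50", "resnet18", "swin_tiny", "densenet121")


class EncoderUnavailableError(RuntimeError):
    """Raised for encoder names that need pretrained vision weights."""


@dataclass
class MILConfig:
    """Architecture and optimization settings for the MIL model."""

    encoder: str = "tiny_cnn"
    embed_dim: int = 64
    n_transformer_layers: int = 4
    n_heads: int = 4
    attention_hidden: int = 2048
    chunk_size: int = 64
    bag_size: Optional[int] = None  # resolved per encoder when None
    tile_size: int = TILE_SIZE
    lr: float = 3e-5
    weight_decay: float = 0.1
    batch_slides: int = 8
    epochs: int = 50
    dropout: float = 0.1
    ff_multiplier: int = 2
    gated_attention: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bag_size is None:
            self.bag_size = ENCODER_BAG_SIZES.get(self.encoder, 48)
        if self.bag_size <= 0:
            raise ValueError("bag size K must be positive")
        if self.n_transformer_layers < 0 or self.chunk_size < 1:
            raise ValueError("invalid transformer/chunk configuration")


class TransMIL(nn.Module):
    """Encoder -> transformer layers -> attention pooling -> classifier."""

    def __init__(self, cfg: MILConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.encoder = nn.TinyCNN(rng, embed_dim=cfg.embed_dim)
        self.layers = [
            nn.TransformerEncoderLayer(
                cfg.embed_dim, cfg.n_heads, cfg.ff_multiplier * cfg.embed_dim,
                rng, dropout_p=cfg.dropout)
            for _ in range(cfg.n_transformer_layers)
        ]
        self.pool = nn.AttentionMILPooling(cfg.embed_dim, cfg.attention_hidden,
                                           rng, gated=cfg.gated_attention)
        self.classifier = nn.Linear(cfg.embed_dim, 1, rng)

    # -- forward pieces -------------------------------------------------------
    @staticmethod
    def tiles_to_input(tiles: np.ndarray) -> nn.Tensor:
        """uint8 (K, t, t, 3) tiles -> centered float Tensor (K, 3, t, t).

        Centering at mid-gray matters: with all-positive inputs the
        ReLU/max-pool encoder is positively homogeneous at init and the
        transformer's LayerNorm is scale-invariant, which together make the
        untrained model nearly blind to intensity differences between tiles.
        """
        x = np.asarray(tiles, dtype=np.float64) / 255.0 - 0.5
        return nn.Tensor(x.transpose(0, 3, 1, 2))

    def encode(self, tiles: np.ndarray, chunk_size: Optional[int] = None) -> nn.Tensor:
        """Tile embeddings, optionally computed in chunks (order preserved)."""
        if len(tiles) == 0:
            raise ValueError("cannot encode an empty tile list")
        chunk = chunk_size or len(tiles)
        if chunk >= len(tiles):
            return self.encoder(self.tiles_to_input(tiles))
        parts = [self.encoder(self.tiles_to_input(tiles[i:i + chunk]))
                 for i in range(0, len(tiles), chunk)]
        return nn.concat(parts, axis=0)

    def forward(self, tiles: np.ndarray, rng: Optional[np.random.Generator] = None,
                chunk_size: Optional[int] = None):
        """Return (logit Tensor, attention Tensor) for a bag of tiles."""
        if rng is None:
            rng = np.random.default_rng(0)
        h = self.encode(tiles, chunk_size)
        for layer in self.layers:
            h = layer(h, rng)
        z, attn = self.pool(h)
        logit = self.classifier(z.reshape(1, -1)).reshape(())
        return logit, attn

    def predict_bag(self, tiles: np.ndarray,
                    chunk_size: Optional[int] = None) -> tuple[float, np.ndarray]:
        """Probability and attention weights in eval mode (no dropout)."""
        was_training = self.training
        self.eval()
        try:
            logit, attn = self.forward(tiles, chunk_size=chunk_size
                                       or self.cfg.chunk_size)
        finally:
            self.train(was_training)
        prob = 1.0 / (1.0 + np.exp(-logit.data))
        return float(prob), attn.data.copy()


def build_model(cfg: MILConfig) -> TransMIL:
    """Construct the MIL model for the configured encoder."""
    if cfg.encoder == "tiny_cnn":
        return TransMIL(cfg, np.random.default_rng(cfg.seed))
    if cfg.encoder in PRETRAINED_ENCODERS:
        raise EncoderUnavailableError(
            f"encoder {cfg.encoder!r} requires pretrained vision weights that "
            "are not bundled with this package; use encoder='tiny_cnn'")
    raise ValueError(
        f"unknown encoder {cfg.encoder!r}; choose from "
        f"{('tiny_cnn',) + PRETRAINED_ENCODERS}")


def attention_pool(pool: nn.AttentionMILPooling,
                   embeddings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply attention-MIL pooling to plain numpy embeddings (K, dim)."""
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=float))
    if len(embeddings) < 1:
        raise ValueError("need at least one embedding")
    z, attn = pool(nn.Tensor(embeddings))
    return z.data.copy(), attn.data.copy()


def encode_chunked(tiles: np.ndarray, model: TransMIL,
                   chunk_size: int) -> np.ndarray:
    """Embeddings computed chunk-by-chunk; equals single-pass encoding."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    was_training = model.training
    model.eval()
    try:
        return model.encode(np.asarray(tiles), chunk_size).data.copy()
    finally:
        model.train(was_training)


def class_weights(labels: Sequence[int]) -> dict[int, float]:
    """Balanced class weights n / (2 * n_class) for binary labels."""
    labels = np.asarray(labels)
    n = len(labels)
    weights = {}
    for cls in (0, 1):
        n_cls = int((labels == cls).sum())
        if n_cls == 0:
            raise ValueError("both classes must be present")
        weights[cls] = n / (2.0 * n_cls)
    return weights


@dataclass
class TrainLog:
    """Per-epoch optimization trace."""

    epochs: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    val_auroc: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": self.epochs,
            "train_loss": self.train_loss,
            "val_auroc": self.val_auroc if self.val_auroc else np.nan,
        })


def _training_bag(image, cfg: MILConfig, rng: np.random.Generator) -> TileBag:
    grid = grid_tiles(image, cfg.tile_size, random_offset=True, rng=rng)
    try:
        grid = filter_background(image, grid)
    except ValueError:
        # an unlucky offset on a small slide can leave only background
        # tiles; fall back to the zero-offset grid
        grid = filter_background(image, grid_tiles(image, cfg.tile_size))
    return select_bag(image, grid, cfg.bag_size)


def train(model: TransMIL, train_set: Sequence[tuple], cfg: MILConfig,
          val_set: Optional[Sequence[tuple]] = None,
          eval_every: int = 0) -> TrainLog:
    """End-to-end training from slide-level labels.

    ``train_set`` / ``val_set`` are sequences of ``(image, label)`` where
    image is a :class:`SlideImage` or a plain HxWx3 uint8 array.  Each epoch
    re-tiles every slide from a fresh random offset, keeps the ``bag_size``
    darkest foreground tiles and applies random 90-degree rotations/flips.
    The loss is class-reweighted binary cross-entropy; optimization is AdamW.
    Deterministic given ``cfg.seed``.
    """
    labels = [int(lbl) for _, lbl in train_set]
    counts = {c: labels.count(c) for c in (0, 1)}
    if min(counts.values()) < 2:
        raise ValueError("need at least 2 slides per class for training")
    weights = class_weights(labels)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    opt = nn.AdamW(model.parameters(), lr=cfg.lr,
                   weight_decay=cfg.weight_decay)
    log = TrainLog()
    n = len(train_set)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_slides):
            batch = order[start:start + cfg.batch_slides]
            opt.zero_grad()
            losses = []
            for idx in batch:
                image, label = train_set[idx]
                bag = _training_bag(image, cfg, rng)
                tiles = extract_bag_tiles(image, bag)
                tiles = np.stack([augment(t, rng) for t in tiles])
                logit, _ = model.forward(tiles, rng=rng)
                losses.append(nn.bce_with_logits(
                    logit, float(label), weights[int(label)]))
            batch_loss = losses[0]
            for extra in losses[1:]:
                batch_loss = batch_loss + extra
            batch_loss = batch_loss * (1.0 / len(losses))
            batch_loss.backward()
            opt.step()
            epoch_losses.append(batch_loss.item())
        log.epochs.append(epoch)
        log.train_loss.append(float(np.mean(epoch_losses)))
        if val_set is not None and eval_every and (epoch + 1) % eval_every == 0:
            from sklearn.metrics import roc_auc_score

            scores = [infer_slide(model, img).probability
                      for img, _ in val_set]
            log.val_auroc.append(
                float(roc_auc_score([lbl for _, lbl in val_set], scores)))
        elif val_set is not None:
            log.val_auroc.append(np.nan)
    model.eval()
    return log


def infer_slide(model: TransMIL, image, threshold: float = 0.5,
                slide_id: Optional[str] = None) -> SlidePrediction:
    """Whole-slide inference: zero-offset tiling, all foreground tiles,
    chunked encoding, attention over the full tile set."""
    sid = slide_id if slide_id is not None else (
        image.slide_id if isinstance(image, SlideImage) else "")
    bag = whole_slide_bag(image, model.cfg.tile_size, slide_id=sid)
    tiles = extract_bag_tiles(image, bag)
    prob, attn = model.predict_bag(tiles, chunk_size=model.cfg.chunk_size)
    return SlidePrediction(slide_id=sid, probability=prob,
                           attention=attn, coords=bag.coords)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: TransMIL, path) -> None:
    """Self-describing archive: config JSON plus weight arrays."""
    state = model.state_dict()
    np.savez_compressed(
        str(path), __config__=np.frombuffer(
            json.dumps(asdict(model.cfg)).encode(), dtype=np.uint8),
        **state)


def load_checkpoint(path) -> TransMIL:
    with np.load(str(path)) as archive:
        cfg = MILConfig(**json.loads(bytes(archive["__config__"]).decode()))
        model = build_model(cfg)
        model.load_state_dict({k: archive[k] for k in archive.files
                               if k != "__config__"})
    model.eval()
    return model
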