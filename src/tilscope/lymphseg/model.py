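"""The encoder-decoder lymphocyte segmenter and its training loop.

Architecture: a ResNet18-style encoder (7x7 stride-2 stem, 2x2 max pool,
four residual stages doubling channels and halving resolution) followed by
five upsampling blocks, each a 2x2 transposed convolution, concatenation
with the matching encoder feature map, and two 3x3 convolutions. The final
1x1 convolution emits per-pixel lymphocyte logits aligned with the input.

Encoder weights are He-initialized (random init is the desk-scale default;
there is a hook for loading pretrained weights), decoder weights are
Xavier-initialized. Loss is pixelwise binary cross-entropy (Dice available
via config). Inputs of arbitrary size are reflect-padded to a multiple of 32.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ..errors import SpecValidationError, TrainingDivergedError
from . import nn
from .masks import augment, centers_to_mask

N_STAGES = 5  # encoder downsampling stages == decoder upsampling blocks


@dataclass
class SegModelConfig:
    base_width: int = 8  # channels after the stem (64 in full ResNet18)
    blocks_per_stage: int = 1  # 2 in full ResNet18
    loss: str = "bce"  # "bce" | "dice"
    learning_rate: float = 2e-3
    epochs: int = 20
    batch_size: int = 8
    crop_size: int = 64  # training crop; must be a multiple of 32
    steps_per_epoch: int | None = None  # default: ceil(n_train / batch_size)
    threshold: float = 0.5
    lymph_diameter: int = 32
    seed: int = 0

    def validate(self):
        if self.crop_size % 32:
            raise SpecValidationError("crop_size must be a multiple of 32")
        if self.loss not in ("bce", "dice"):
            raise SpecValidationError(f"unknown loss {self.loss!r}")
        if self.base_width < 1 or self.blocks_per_stage < 1:
            raise SpecValidationError("width/depth must be positive")


class UNet(nn.Module):
    """Encoder-decoder with skip concatenations at every resolution."""

    def __init__(self, config: SegModelConfig, rng):
        super().__init__()
        B = config.base_width
        self.stem = self.add("stem", nn.Conv2d(3, B, 7, stride=2, pad=3, rng=rng))
        self.stem_relu = self.add("stem_relu", nn.ReLU())
        self.pool = self.add("pool", nn.MaxPool2())
        widths = [B, 2 * B, 4 * B, 8 * B]
        strides = [1, 2, 2, 2]
        cin = B
        self.stages = []
        for si, (w, s) in enumerate(zip(widths, strides)):
            blocks = [nn.BasicBlock(cin, w, stride=s, rng=rng)]
            for _ in range(config.blocks_per_stage - 1):
                blocks.append(nn.BasicBlock(w, w, rng=rng))
            stage = self.add(f"stage{si + 1}", nn.Sequential(*blocks))
            self.stages.append(stage)
            cin = w
        # decoder: (input channels, skip channels, output channels)
        skip_ch = [widths[2], widths[1], widths[0], B, 3]
        out_ch = [widths[2], widths[1], widths[0], B, B]
        self.ups = []
        cin = widths[3]
        for i, (sc, oc) in enumerate(zip(skip_ch, out_ch)):
            up = self.add(f"up{i + 1}", UpBlock(cin, sc, oc, rng=rng))
            self.ups.append(up)
            cin = oc
        self.head = self.add(
            "head", nn.Conv2d(cin, 1, 1, pad=0, rng=rng, init="xavier")
        )

    def forward(self, x):
        s1 = self.stem_relu(self.stem(x))  # 1/2
        e1 = self.stages[0](self.pool(s1))  # 1/4
        e2 = self.stages[1](e1)  # 1/8
        e3 = self.stages[2](e2)  # 1/16
        e4 = self.stages[3](e3)  # 1/32
        d = self.ups[0](e4, e3)
        d = self.ups[1](d, e2)
        d = self.ups[2](d, e1)
        d = self.ups[3](d, s1)
        d = self.ups[4](d, x)
        return self.head(d)

    def backward(self, dy):
        d = self.head.backward(dy)
        d, _dx_skip = self.ups[4].backward(d)
        d, ds1_a = self.ups[3].backward(d)
        d, de1_a = self.ups[2].backward(d)
        d, de2_a = self.ups[1].backward(d)
        de4, de3_a = self.ups[0].backward(d)
        de3 = self.stages[3].backward(de4) + de3_a
        de2 = self.stages[2].backward(de3) + de2_a
        de1 = self.stages[1].backward(de2) + de1_a
        dp = self.stages[0].backward(de1)
        ds1 = self.pool.backward(dp) + ds1_a
        return self.stem.backward(self.stem_relu.backward(ds1))


class UpBlock(nn.Module):
    """Deconv x2, concat encoder skip, two 3x3 convs (Xavier init)."""

    def __init__(self, cin, cskip, cout, rng):
        super().__init__()
        self.cskip = cskip
        self.deconv = self.add("deconv", nn.ConvTranspose2x2(cin, cout, rng=rng))
        self.conv1 = self.add(
            "conv1", nn.Conv2d(cout + cskip, cout, 3, rng=rng, init="xavier")
        )
        self.relu1 = self.add("relu1", nn.ReLU())
        self.conv2 = self.add("conv2", nn.Conv2d(cout, cout, 3, rng=rng, init="xavier"))
        self.relu2 = self.add("relu2", nn.ReLU())

    def forward(self, x, skip):
        up = self.deconv(x)
        cat = np.concatenate([up, skip], axis=1)
        return self.relu2(self.conv2(self.relu1(self.conv1(cat))))

    def backward(self, dy):
        dcat = self.conv1.backward(
            self.relu1.backward(self.conv2.backward(self.relu2.backward(dy)))
        )
        n_up = dcat.shape[1] - self.cskip
        dup, dskip = dcat[:, :n_up], dcat[:, n_up:]
        return self.deconv.backward(dup), dskip


@dataclass
class Checkpoint:
    """Trained weights plus config echo, training log and stage tag."""

    state: dict
    config: SegModelConfig
    log: list = field(default_factory=list)
    stage: str = "initial"  # "initial" after first training, "cascade-N" later

    def build(self) -> UNet:
        model = UNet(self.config, rng=np.random.default_rng(0))
        model.load_state_dict(self.state)
        return model


def build_model(config: SegModelConfig) -> UNet:
    config.validate()
    return UNet(config, rng=np.random.default_rng(config.seed))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _to_input(img):
    """uint8 HWC -> float32 CHW in [0, 1]."""
    x = np.asarray(img, dtype=np.float32) / 255.0
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def _pad_to_multiple(x, m=32):
    h, w = x.shape[1:]
    ph, pw = (-h) % m, (-w) % m
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw)), mode="reflect")
    return x, (h, w)


def _loss_and_grad(logits, targets, kind):
    if kind == "bce":
        return nn.bce_with_logits(logits, targets)
    # soft Dice on probabilities
    p = nn.sigmoid(logits)
    inter = (p * targets).sum()
    denom = p.sum() + targets.sum() + 1.0
    dice = (2 * inter + 1.0) / denom
    dp = (2 * targets * denom - (2 * inter + 1.0)) / denom**2
    dlogits = -(dp * p * (1 - p)).astype(np.float32)
    return float(1.0 - dice), dlogits


def _prepare(patch_set, diameter):
    pairs = []
    for img, centers in patch_set.patches:
        mask = centers_to_mask(centers, img.shape[:2], diameter)
        pairs.append((img, mask))
    return pairs


def _prepare_masked(patch_set, masks):
    return [(img, m) for (img, _c), m in zip(patch_set.patches, masks)]


def train_model(config: SegModelConfig, train_set, val_set, initial=None,
                stage="initial"):
    """Train the segmenter; returns a :class:`Checkpoint` with the loss log.

    ``train_set``/``val_set`` are :class:`~tilscope.synthfix.AnnotatedPatchSet`
    instances; masks are built by dilating annotated centers. Weights with
    the best validation loss are restored at the end, so the checkpoint's
    final validation loss never exceeds the initial one.
    """
    config.validate()
    if len(train_set) == 0 or len(val_set) == 0:
        raise SpecValidationError("train and validation sets must be nonempty")
    train_pairs = _prepare(train_set, config.lymph_diameter)
    val_pairs = _prepare(val_set, config.lymph_diameter)
    return _fit(config, train_pairs, val_pairs, initial=initial, stage=stage)


def train_on_masks(config, patch_set, masks, val_pairs, initial=None,
                   stage="cascade"):
    """Train against explicit target masks (cascade refinement rounds)."""
    config.validate()
    pairs = _prepare_masked(patch_set, masks)
    return _fit(config, pairs, val_pairs, initial=initial, stage=stage)


def _fit(config, train_pairs, val_pairs, initial=None, stage="initial"):
    rng = np.random.default_rng(config.seed)
    if initial is not None:
        model = initial.build()
    else:
        model = UNet(config, rng=np.random.default_rng(config.seed))
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    n = len(train_pairs)
    steps = config.steps_per_epoch or -(-n // config.batch_size)
    log = []
    val0 = _validation_loss(model, val_pairs, config)
    best = (val0, model.state_dict())
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        pos = 0
        ep_loss = 0.0
        for _step in range(steps):
            xs, ys = [], []
            for _b in range(config.batch_size):
                img, mask = train_pairs[order[pos % n]]
                pos += 1
                pc, mc = augment(img, mask, crop_size=config.crop_size, rng=rng)
                xs.append(_to_input(pc))
                ys.append(mc.astype(np.float32))
            x = np.stack(xs)
            y = np.stack(ys)[:, None]
            logits = model(x)
            loss, dlogits = _loss_and_grad(logits, y, config.loss)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            ep_loss += loss
        val = _validation_loss(model, val_pairs, config)
        log.append({"epoch": epoch, "train_loss": ep_loss / steps, "val_loss": val})
        if val < best[0]:
            best = (val, model.state_dict())
    state = {k: v.copy() for k, v in best[1].items()}
    log.insert(0, {"epoch": -1, "train_loss": None, "val_loss": val0})
    return Checkpoint(state=state, config=config, log=log, stage=stage)


def _validation_loss(model, val_pairs, config):
    total, count = 0.0, 0
    for img, mask in val_pairs:
        x, (h, w) = _pad_to_multiple(_to_input(img))
        logits = model(x[None])[0, 0, :h, :w]
        loss, _ = _loss_and_grad(
            logits[None, None], mask[None, None].astype(np.float32), config.loss
        )
        total += loss
        count += 1
    return total / max(count, 1)


def predict_mask(ckpt: Checkpoint, patch, model=None):
    """Probability map and thresholded binary mask for one RGB patch."""
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise SpecValidationError("patch must be HxWx3 RGB")
    if model is None:
        model = ckpt.build()
    x, (h, w) = _pad_to_multiple(_to_input(patch))
    logits = model(x[None])[0, 0, :h, :w]
    prob = nn.sigmoid(logits)
    return prob, prob >= ckpt.config.threshold


# ---------------------------------------------------------------------------
# persistence: weights in .npz with a JSON sidecar
# ---------------------------------------------------------------------------


def save_checkpoint(ckpt: Checkpoint, path):
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz", **ckpt.state)
    sidecar = path[: -len(".npz")] if path.endswith(".npz") else path
    with open(sidecar + ".json", "w") as fh:
        json.dump(
            {"config": asdict(ckpt.config), "log": ckpt.log, "stage": ckpt.stage},
            fh,
            indent=2,
        )


def load_checkpoint(path) -> Checkpoint:
    path = str(path)
    base = path[: -len(".npz")] if path.endswith(".npz") else path
    with np.load(base + ".npz") as npz:
        state = {k: npz[k] for k in npz.files}
    with open(base + ".json") as fh:
        meta = json.load(fh)
    config = SegModelConfig(**meta["config"])
    return Checkpoint(
        state=state, config=config, log=meta["log"], stage=meta["stage"]
    )
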