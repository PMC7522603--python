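"""Conditional GAN for paired image regression.

The generator is a U-Net-style encoder-decoder: an initial stride-2
convolution, encoder blocks (LeakyReLU - Conv/stride 2 - BatchNorm), decoder
blocks (ReLU - transposed Conv/stride 2 - BatchNorm) with skip connections,
and a final Tanh so predictions live in [-1, 1].  The discriminator scores a
candidate image concatenated with the generator's conditioning input: an
initial stride-2 convolution plus BatchNorm, three Conv-BN-LeakyReLU blocks,
a fully connected layer and a sigmoid.

The generator minimizes the weighted composite loss

    l = lambda1 * l_MAE + lambda2 * l_adv + lambda3 * ||theta_G||_1

where l_MAE is the mean absolute difference per pixel, l_adv = -log D(I, G(I)),
and the last term is the L1 norm of all generator parameters.  Default
weights (0.99, 0.01, 0.001); both networks use the adaptive-momentum (Adam)
optimizer at learning rate 2e-4.  Training alternates one discriminator step
(binary cross-entropy, real=1 / fake=0) with one generator step per batch,
and snapshots the generator/discriminator at the best validation loss.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .dataset import PairedSample
from .image_io import normalize

_EPS = 1e-7


class SpecError(ValueError):
    """Architecture hyperparameters inconsistent with the data shape."""


class TrainingDivergedError(RuntimeError):
    """Raised when a loss becomes non-finite; carries the history so far."""

    def __init__(self, message: str, history: list[dict]):
        super().__init__(message)
        self.history = history


@dataclass
class GeneratorSpec:
    in_channels: int = 1
    out_channels: int = 1
    kernel_size: int = 3
    stride: int = 2
    depth: int = 4
    base_filters: int = 32
    skip_connections: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_filters < 1 or self.in_channels < 1:
            raise SpecError("depth, base_filters and in_channels must be >= 1")


@dataclass
class DiscriminatorSpec:
    in_channels: int = 2  # generator inputs + 1 conditioned candidate
    kernel_size: int = 5
    stride: int = 2
    n_conv_blocks: int = 3
    base_filters: int = 16


@dataclass
class LossConfig:
    lambda1: float = 0.99
    lambda2: float = 0.01
    lambda3: float = 0.001

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class TrainConfig:
    learning_rate: float = 2e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    max_epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate > 0, batch_size >= 1, max_epochs >= 1 required")


@dataclass
class LossBreakdown:
    total: float
    l_mae: float
    l_adv: float
    l_reg: float


class UNetGenerator:
    """Encoder-decoder with stride-2 (transposed) convolutions and skips."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f, d, k, s = spec.base_filters, spec.depth, spec.kernel_size, spec.stride
        self.enc0 = nn.Conv2d(spec.in_channels, f, k, s, rng)
        self.enc_blocks = []
        for lvl in range(1, d):
            self.enc_blocks.append(nn.Sequential([
                nn.LeakyReLU(0.2),
                nn.Conv2d(f * 2 ** (lvl - 1), f * 2 ** lvl, k, s, rng),
                nn.BatchNorm2d(f * 2 ** lvl),
            ]))
        self.dec_blocks = []
        self._dec_out_ch = []
        cur = f * 2 ** (d - 1)
        for lvl in range(d - 1, 0, -1):
            out_ch = f * 2 ** (lvl - 1)
            self.dec_blocks.append(nn.Sequential([
                nn.ReLU(),
                nn.ConvTranspose2d(cur, out_ch, k, s, rng),
                nn.BatchNorm2d(out_ch),
            ]))
            self._dec_out_ch.append(out_ch)
            cur = out_ch * (2 if spec.skip_connections else 1)
        self.final = nn.Sequential([
            nn.ReLU(),
            nn.ConvTranspose2d(cur, spec.out_channels, k, s, rng),
            nn.Tanh(),
        ])

    # -- wiring -------------------------------------------------------------

    def _modules(self):
        mods = {"enc0": self.enc0}
        for i, b in enumerate(self.enc_blocks):
            mods[f"enc{i + 1}"] = b
        for i, b in enumerate(self.dec_blocks):
            mods[f"dec{i}"] = b
        mods["final"] = self.final
        return mods

    def params(self):
        return {f"{n}/{k}": v for n, m in self._modules().items()
                for k, v in m.params().items()}

    def grads(self):
        return {f"{n}/{k}": v for n, m in self._modules().items()
                for k, v in m.grads().items()}

    def state(self):
        return {f"{n}/{k}": v for n, m in self._modules().items()
                for k, v in m.state().items()}

    def load_state(self, state):
        own = self.state()
        if set(own) != set(state):
            raise ValueError("generator state keys do not match architecture")
        for k, v in state.items():
            own[k][...] = v

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        d = self.spec.depth
        size = x.shape[2]
        if size % (2 ** d) or x.shape[3] % (2 ** d):
            raise SpecError(f"patch size {x.shape[2:]} not divisible by 2^depth = {2 ** d}")
        feats = [self.enc0.forward(x, train)]
        cur = feats[0]
        for blk in self.enc_blocks:
            cur = blk.forward(cur, train)
            feats.append(cur)
        for j, blk in enumerate(self.dec_blocks):
            cur = blk.forward(cur, train)
            if self.spec.skip_connections:
                cur = np.concatenate([cur, feats[d - 2 - j]], axis=1)
        return self.final.forward(cur, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.spec.depth
        d_cur = self.final.backward(dy)
        skip_grads: dict[int, np.ndarray] = {}
        for j in reversed(range(len(self.dec_blocks))):
            if self.spec.skip_connections:
                c = self._dec_out_ch[j]
                skip_grads[d - 2 - j] = d_cur[:, c:]
                d_cur = d_cur[:, :c]
            d_cur = self.dec_blocks[j].backward(d_cur)
        for lvl in range(d - 1, 0, -1):
            d_cur = self.enc_blocks[lvl - 1].backward(d_cur)
            if lvl - 1 in skip_grads:
                d_cur = d_cur + skip_grads[lvl - 1]
        return self.enc0.backward(d_cur)

    def zero_grads(self):
        for g in self.grads().values():
            g[...] = 0.0

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward (BatchNorm uses running statistics)."""
        single = x.ndim == 3
        if single:
            x = x[None]
        y = self.forward(x, train=False)
        return y[0] if single else y


def build_generator(spec: GeneratorSpec, seed: int = 0) -> UNetGenerator:
    """Construct a generator with deterministic, seed-derived initial weights."""
    return UNetGenerator(spec, seed)


def build_discriminator(dspec: DiscriminatorSpec, patch_size: int,
                        seed: int = 0) -> nn.Sequential:
    """Construct the conditional discriminator for a given square patch size."""
    rng = np.random.default_rng(seed)
    f, k, s = dspec.base_filters, dspec.kernel_size, dspec.stride
    layers: list[nn.Layer] = [
        nn.Conv2d(dspec.in_channels, f, k, s, rng),
        nn.BatchNorm2d(f),
    ]
    size = -(-patch_size // s)
    ch = f
    for _ in range(dspec.n_conv_blocks):
        layers += [nn.Conv2d(ch, ch * 2, k, s, rng), nn.BatchNorm2d(ch * 2), nn.LeakyReLU(0.2)]
        ch *= 2
        size = -(-size // s)
    if size < 1:
        raise SpecError(f"patch size {patch_size} too small for {dspec.n_conv_blocks} blocks")
    layers += [nn.Flatten(), nn.Dense(ch * size * size, 1, rng), nn.Sigmoid()]
    return nn.Sequential(layers)


def discriminator_score(disc: nn.Sequential, inputs: np.ndarray,
                        candidate: np.ndarray) -> float:
    """Score one candidate image conditioned on the generator inputs.

    ``inputs``: (k, H, W) normalized conditioning stack; ``candidate``:
    (H, W) or (1, H, W).  Returns a scalar strictly inside (0, 1).
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    candidate = np.asarray(candidate, dtype=np.float64)
    if candidate.ndim == 2:
        candidate = candidate[None]
    if candidate.shape[1:] != inputs.shape[1:]:
        raise ValueError(f"candidate shape {candidate.shape[1:]} != input shape {inputs.shape[1:]}")
    x = np.concatenate([inputs, candidate], axis=0)[None]
    p = disc.forward(x, train=False)
    return float(np.clip(p[0, 0], _EPS, 1 - _EPS))


def generator_loss(pred: np.ndarray, target: np.ndarray, d_score: float,
                   params_l1: float, cfg: LossConfig) -> LossBreakdown:
    """Composite generator loss and its components.

    l_MAE is the per-pixel mean absolute difference (the L1 norm of the
    residual divided by W*H, averaged over any batch axis); the adversarial
    term is -log(d_score); the regularizer is the L1 norm of the generator
    parameters.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes differ")
    if not 0.0 < d_score < 1.0:
        raise ValueError(f"d_score must be in (0, 1), got {d_score}")
    l_mae = float(np.mean(np.abs(pred - target)))
    l_adv = float(-np.log(d_score))
    l_reg = float(params_l1)
    total = cfg.lambda1 * l_mae + cfg.lambda2 * l_adv + cfg.lambda3 * l_reg
    return LossBreakdown(total, l_mae, l_adv, l_reg)


@dataclass
class TrainState:
    """Trained generator/discriminator pair plus the training record."""

    generator: UNetGenerator
    discriminator: nn.Sequential
    gspec: GeneratorSpec
    dspec: DiscriminatorSpec
    lcfg: LossConfig
    tcfg: TrainConfig
    history: list[dict] = field(default_factory=list)
    best_checkpoint: dict | None = None
    best_val_loss: float = np.inf
    best_epoch: int = -1

    def history_frame(self):
        import pandas as pd
        return pd.DataFrame(self.history)

    def restore_best(self) -> None:
        """Load the parameters recorded at the minimal validation loss."""
        if self.best_checkpoint is None:
            raise RuntimeError("no checkpoint recorded")
        self.generator.load_state(self.best_checkpoint["generator"])
        self.discriminator.load_state(self.best_checkpoint["discriminator"])

    def save(self, path: str) -> None:
        arrays = {}
        for prefix, net in (("G", self.generator), ("D", self.discriminator)):
            for k, v in net.state().items():
                arrays[f"{prefix}::{k}"] = v
        if self.best_checkpoint is not None:
            for prefix in ("generator", "discriminator"):
                tag = "BG" if prefix == "generator" else "BD"
                for k, v in self.best_checkpoint[prefix].items():
                    arrays[f"{tag}::{k}"] = v
        meta = {
            "gspec": asdict(self.gspec), "dspec": asdict(self.dspec),
            "lcfg": asdict(self.lcfg), "tcfg": asdict(self.tcfg),
            "history": self.history, "best_val_loss": self.best_val_loss,
            "best_epoch": self.best_epoch,
            "patch_size": self.best_checkpoint.get("patch_size") if self.best_checkpoint else None,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path: str) -> TrainState:
    """Rebuild a :class:`TrainState` from a ``.npz`` archive written by ``save``."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__meta__"}
    gspec = GeneratorSpec(**meta["gspec"])
    dspec = DiscriminatorSpec(**meta["dspec"])
    tcfg = TrainConfig(**meta["tcfg"])
    patch = meta.get("patch_size") or 32
    state = TrainState(
        generator=build_generator(gspec, tcfg.seed),
        discriminator=build_discriminator(dspec, patch, tcfg.seed + 1),
        gspec=gspec, dspec=dspec, lcfg=LossConfig(**meta["lcfg"]), tcfg=tcfg,
        history=meta["history"], best_val_loss=meta["best_val_loss"],
        best_epoch=meta["best_epoch"],
    )
    state.generator.load_state({k[3:]: v for k, v in arrays.items() if k.startswith("G::")})
    state.discriminator.load_state({k[3:]: v for k, v in arrays.items() if k.startswith("D::")})
    bg = {k[4:]: v for k, v in arrays.items() if k.startswith("BG::")}
    bd = {k[4:]: v for k, v in arrays.items() if k.startswith("BD::")}
    if bg:
        state.best_checkpoint = {"generator": bg, "discriminator": bd,
                                 "epoch": meta["best_epoch"],
                                 "val_loss": meta["best_val_loss"],
                                 "patch_size": patch}
    return state


def pairs_to_arrays(pairs: list[PairedSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack paired samples into normalized (N, k, H, W) / (N, 1, H, W) arrays."""
    xs, ys = [], []
    for p in pairs:
        xs.append(np.stack([normalize(im).pixels for im in p.inputs]))
        ys.append(normalize(p.target).pixels[None])
    return np.stack(xs), np.stack(ys)


def _val_losses(gen: UNetGenerator, disc: nn.Sequential, xv: np.ndarray,
                yv: np.ndarray, lcfg: LossConfig, batch: int = 16) -> LossBreakdown:
    """Inference-mode composite loss over the validation set."""
    n = len(xv)
    mae_sum = adv_sum = 0.0
    for i in range(0, n, batch):
        xb, yb = xv[i:i + batch], yv[i:i + batch]
        fake = gen.forward(xb, train=False)
        p = np.clip(disc.forward(np.concatenate([xb, fake], axis=1), train=False),
                    _EPS, 1 - _EPS)
        mae_sum += np.abs(fake - yb).mean(axis=(1, 2, 3)).sum()
        adv_sum += (-np.log(p[:, 0])).sum()
    l_mae, l_adv = mae_sum / n, adv_sum / n
    l_reg = nn.l1_norm(gen.params())
    total = lcfg.lambda1 * l_mae + lcfg.lambda2 * l_adv + lcfg.lambda3 * l_reg
    return LossBreakdown(float(total), float(l_mae), float(l_adv), float(l_reg))


def train(train_pairs: list[PairedSample], val_pairs: list[PairedSample],
          gspec: GeneratorSpec, dspec: DiscriminatorSpec,
          lcfg: LossConfig | None = None, tcfg: TrainConfig | None = None) -> TrainState:
    """Alternating cGAN training, fully seeded and CPU-deterministic.

    Per batch: one discriminator update (binary cross-entropy on
    real/predicted candidates conditioned on the inputs), then one generator
    update on the composite loss.  After each epoch the inference-mode
    validation loss is recorded and the parameter snapshot with the lowest
    value so far is kept as ``best_checkpoint``.
    """
    lcfg = lcfg or LossConfig()
    tcfg = tcfg or TrainConfig()
    if not train_pairs or not val_pairs:
        raise ValueError("train and val sets must be nonempty")
    x_tr, y_tr = pairs_to_arrays(train_pairs)
    x_va, y_va = pairs_to_arrays(val_pairs)
    patch = x_tr.shape[2]
    if gspec.in_channels != x_tr.shape[1]:
        raise SpecError(f"gspec.in_channels={gspec.in_channels} but pairs have {x_tr.shape[1]}")
    if dspec.in_channels != x_tr.shape[1] + 1:
        raise SpecError("dspec.in_channels must equal generator inputs + 1")

    gen = build_generator(gspec, tcfg.seed)
    disc = build_discriminator(dspec, patch, tcfg.seed + 1)
    opt_g = nn.Adam(tcfg.learning_rate, tcfg.beta1, tcfg.beta2)
    opt_d = nn.Adam(tcfg.learning_rate, tcfg.beta1, tcfg.beta2)
    rng = np.random.default_rng(tcfg.seed + 2)

    state = TrainState(gen, disc, gspec, dspec, lcfg, tcfg)
    n = len(x_tr)
    hw = float(patch * x_tr.shape[3])

    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(n)
        ep = {"l": 0.0, "l_mae": 0.0, "l_g": 0.0, "l_reg": 0.0, "d_loss": 0.0}
        n_batches = 0
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            nb = len(idx)

            # ---- discriminator step (real=1, fake=0)
            fake = gen.forward(xb, train=True)
            nn.zero_grads(disc)
            p_real = np.clip(disc.forward(np.concatenate([xb, yb], axis=1), train=True),
                             _EPS, 1 - _EPS)
            disc.backward(-1.0 / (p_real * nb))
            p_fake = np.clip(disc.forward(np.concatenate([xb, fake], axis=1), train=True),
                             _EPS, 1 - _EPS)
            disc.backward(1.0 / ((1.0 - p_fake) * nb))
            d_loss = float(np.mean(-np.log(p_real)) + np.mean(-np.log(1 - p_fake)))
            opt_d.step(disc.params(), disc.grads())

            # ---- generator step on the composite loss
            gen.zero_grads()
            nn.zero_grads(disc)
            fake = gen.forward(xb, train=True)
            p = np.clip(disc.forward(np.concatenate([xb, fake], axis=1), train=True),
                        _EPS, 1 - _EPS)
            l_mae = float(np.abs(fake - yb).mean())
            l_adv = float(np.mean(-np.log(p)))
            l_reg = nn.l1_norm(gen.params())
            total = lcfg.lambda1 * l_mae + lcfg.lambda2 * l_adv + lcfg.lambda3 * l_reg
            d_concat = disc.backward(-lcfg.lambda2 / (p * nb))
            d_fake = (lcfg.lambda1 * np.sign(fake - yb) / (nb * hw)
                      + d_concat[:, xb.shape[1]:])
            gen.backward(d_fake)
            if lcfg.lambda3 > 0:
                gparams = gen.params()
                ggrads = gen.grads()
                for k in gparams:
                    ggrads[k] += lcfg.lambda3 * np.sign(gparams[k])
            opt_g.step(gen.params(), gen.grads())

            if not np.isfinite(total) or not np.isfinite(d_loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: l={total}, d={d_loss}", state.history)
            ep["l"] += total
            ep["l_mae"] += l_mae
            ep["l_g"] += l_adv
            ep["l_reg"] += l_reg
            ep["d_loss"] += d_loss
            n_batches += 1

        val = _val_losses(gen, disc, x_va, y_va, lcfg)
        if not np.isfinite(val.total):
            raise TrainingDivergedError(f"non-finite validation loss at epoch {epoch}",
                                        state.history)
        row = {"epoch": epoch}
        row.update({k: v / n_batches for k, v in ep.items()})
        row.update({"val_l": val.total, "val_l_mae": val.l_mae, "val_l_g": val.l_adv})
        state.history.append(row)
        if val.total < state.best_val_loss:
            state.best_val_loss = val.total
            state.best_epoch = epoch
            state.best_checkpoint = {
                "generator": copy.deepcopy(gen.state()),
                "discriminator": copy.deepcopy(disc.state()),
                "epoch": epoch, "val_loss": val.total, "patch_size": patch,
            }
    return state
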