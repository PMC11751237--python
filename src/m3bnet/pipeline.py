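"""Four-stage training orchestration.

Stage 1 pre-trains the style-transfer branch on paired small patches.
Stages 2 and 3 pre-train the middle- and large-scale extractors against the
vessel masks through a disposable 1×1-conv + upsample head.  Stage 4 freezes
everything trained so far (verified by weight hashing) and trains the
remaining segmentation branch — small extractor, LPFM scalars, SFM
projection, AUM decoder, refiner — end to end with the combined
BCE + soft-Dice loss.

Optimization follows the published recipe: Adam, learning rate 4e-4, weight
decay 5e-4, 200 epochs at full scale (batch 5 for the in-house UWF set,
batch 2 for PRIME-FP20-style data); the `tiny` preset shrinks every shape
so the whole pipeline runs on one CPU core in minutes.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .imaging import clahe_enhance
from .metrics import MetricsReport, evaluate_images
from .nn import functional as F
from .patches import extract_triplet, extract_window, make_tile_grid, sample_training_centers, stitch, _window
from .phantom import SamplePair, load_dataset
from .imaging import resize_array
from .segnet import SegModel, SfmConfig
from .transfer import TransferLossWeights, TransferNets, discriminator_losses, encode_z2, transfer_losses


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    preset: str = "tiny"
    learning_rate: float = 4e-4
    weight_decay: float = 5e-4
    epochs: int = 200
    stage_epochs: tuple[int, int, int, int] | None = None
    batch_size: int = 5
    small_side: int = 256
    common_side: int = 256
    fg_fraction: float = 0.5
    patches_per_image: int = 1
    augment: bool = True
    pretext: str = "mask"          # stage-2/3 objective: mask | autoencode
    sfm_mode: str = "block"
    sfm_threshold: float = 0.5
    sfm_grid: tuple[int, int] = (4, 4)
    lambda_cyc: float = 10.0
    lambda_pair: float = 10.0
    lambda_id: float = 5.0
    seed: int = 0

    def epochs_for(self, stage: int) -> int:
        if self.stage_epochs is not None:
            return self.stage_epochs[stage - 1]
        return self.epochs

    def transfer_weights(self) -> TransferLossWeights:
        return TransferLossWeights(lambda_cyc=self.lambda_cyc, lambda_pair=self.lambda_pair,
                                   lambda_id=self.lambda_id)

    def sfm_config(self) -> SfmConfig:
        return SfmConfig(mode=self.sfm_mode, threshold=self.sfm_threshold, grid=tuple(self.sfm_grid))

    # -- flat key:value round-trip -------------------------------------------
    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["sfm_grid"] = list(self.sfm_grid)
        if self.stage_epochs is not None:
            d["stage_epochs"] = list(self.stage_epochs)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        d = yaml.safe_load(text)
        if d.get("sfm_grid") is not None:
            d["sfm_grid"] = tuple(d["sfm_grid"])
        if d.get("stage_epochs") is not None:
            d["stage_epochs"] = tuple(d["stage_epochs"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "TrainConfig":
        return cls.from_yaml(Path(path).read_text())

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def train_defaults(dataset_tag: str) -> TrainConfig:
    """Published defaults per dataset family, plus the desk-scale preset."""
    if dataset_tag == "uwf_seg":
        return TrainConfig(preset="full", batch_size=5)
    if dataset_tag == "prime_fp20":
        return TrainConfig(preset="full", batch_size=2)
    if dataset_tag == "tiny":
        return TrainConfig(preset="tiny", batch_size=5, small_side=64, common_side=64,
                           epochs=10, stage_epochs=(3, 2, 2, 10), lambda_id=0.0)
    raise ValueError(f"unknown dataset tag {dataset_tag!r}")


@dataclass
class StagePlan:
    stage: int
    trainable: tuple[str, ...]
    frozen: tuple[str, ...]
    patch_scale: str           # small | middle | large
    epochs: int
    batch_size: int
    seed: int


_STAGE_SPECS = {
    1: (("transfer",), (), "small"),
    2: (("bank.middle",), ("transfer",), "middle"),
    3: (("bank.large",), ("transfer", "bank.middle"), "large"),
    4: (("bank.small", "lpfm", "z2_proj", "decoder", "decoder_norms", "coarse_head", "refiner"),
        ("transfer", "bank.middle", "bank.large"), "small"),
}


def make_stage_plan(stage: int, config: TrainConfig) -> StagePlan:
    if stage not in _STAGE_SPECS:
        raise ValueError(f"unknown stage {stage}")
    trainable, frozen, scale = _STAGE_SPECS[stage]
    return StagePlan(stage=stage, trainable=trainable, frozen=frozen, patch_scale=scale,
                     epochs=config.epochs_for(stage), batch_size=config.batch_size,
                     seed=config.seed)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def segmentation_loss(probability, mask, class_balance: bool = True) -> tuple[nn.Tensor, dict[str, float]]:
    """Binary cross-entropy + (1 − soft Dice), equally weighted.

    With ``class_balance`` the BCE terms are reweighted so foreground and
    background contribute equally (weights normalized to mean 1, so a
    balanced mask reduces exactly to plain BCE).  Thin vessels cover well
    under 10% of pixels; unweighted BCE drives the optimum into the
    all-background corner on short training schedules.
    """
    prob = probability if isinstance(probability, nn.Tensor) else nn.Tensor(np.asarray(probability, dtype=np.float32))
    m = np.asarray(mask)
    if m.shape != prob.data.shape:
        raise ValueError(f"shape mismatch: {prob.data.shape} vs {m.shape}")
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary")
    if class_balance and 0 < m.mean() < 1:
        pos = m.mean()
        w = np.where(m > 0, 0.5 / pos, 0.5 / (1.0 - pos)).astype(np.float32)
        eps = 1e-6
        p = prob.clip(eps, 1.0 - eps)
        t = m.astype(np.float32)
        bce = -((nn.Tensor(w) * (nn.Tensor(t) * p.log()
                                 + nn.Tensor(1.0 - t) * (1.0 - p).log())).mean())
    else:
        bce = F.bce_loss(prob, m)
    dice = F.soft_dice_loss(prob, m)
    total = bce + dice
    return total, {"bce": float(bce.data), "soft_dice": float(dice.data),
                   "total": float(total.data)}


# ---------------------------------------------------------------------------
# model bundle + checkpoints
# ---------------------------------------------------------------------------

class ModelBundle(nn.Module):
    """All trainable components of the framework under one namespace."""

    def __init__(self, config: TrainConfig, init_seed: int | None = None):
        seed = config.seed if init_seed is None else init_seed
        self.transfer = TransferNets(np.random.default_rng([seed, 10]), preset=config.preset,
                                     weights=config.transfer_weights())
        self.seg = SegModel(np.random.default_rng([seed, 11]), preset=config.preset,
                            sfm=config.sfm_config())

    def component(self, name: str) -> nn.Module:
        obj = self
        for part in name.split("."):
            obj = getattr(obj, part)
        return obj

    def component_params(self, name: str):
        comp = self.component("seg." + name if not name.startswith(("transfer", "seg")) else name)
        if isinstance(comp, list):
            params = []
            for m in comp:
                params += m.parameters()
            return params
        return comp.parameters()

    def component_hash(self, name: str) -> str:
        h = hashlib.sha256()
        for p in self.component_params(name):
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()


def save_checkpoint(path: str | Path, bundle: ModelBundle, meta: dict,
                    extra_state: dict | None = None) -> None:
    """Opaque .npz with an embedded JSON header (preset, stage, seed, hash)."""
    payload = {f"param::{k}": v for k, v in bundle.state_dict().items()}
    if extra_state:
        for group, state in extra_state.items():
            payload[f"extra::{group}"] = np.frombuffer(
                json.dumps({k: (v.tolist() if isinstance(v, np.ndarray) else v)
                            for k, v in state.items()}, default=_np_default).encode(), dtype=np.uint8)
    payload["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def _np_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating)):
        return o.item()
    raise TypeError(type(o))


def load_checkpoint(path: str | Path, bundle: ModelBundle) -> tuple[dict, dict]:
    with np.load(path) as z:
        state = {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
        meta = json.loads(bytes(z["meta"]).decode())
        extra = {k[len("extra::"):]: json.loads(bytes(z[k]).decode())
                 for k in z.files if k.startswith("extra::")}
    bundle.load_state_dict(state)
    return meta, extra


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def prepare_pairs(pairs: list[SamplePair]) -> list[SamplePair]:
    """Apply the standard preprocessing (CLAHE on the UWF image) once."""
    out = []
    for p in pairs:
        out.append(SamplePair(uwf=clahe_enhance(p.uwf), ffa=p.ffa, mask=p.mask,
                              valid_mask=p.valid_mask, meta=dict(p.meta)))
    return out


def _resolve_pairs(data, preprocess: bool = True) -> list[SamplePair]:
    if isinstance(data, (str, Path)):
        data = load_dataset(data)
    return prepare_pairs(data) if preprocess else list(data)


def _epoch_rng(seed: int, stage: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng([seed, stage, epoch])


def _sample_batches(pairs, scale: str, config: TrainConfig, stage: int, epoch: int):
    """Yield (uwf_windows, ffa_windows, mask_windows) batches for one epoch.

    One fg-biased centre per image per epoch (``patches_per_image``); the
    windowed crops of the chosen scale are resized to the common side.
    """
    rng = _epoch_rng(config.seed, stage, epoch)
    factor = {"small": 1, "middle": 2, "large": 3}[scale]
    side = factor * config.small_side
    items = []
    order = rng.permutation(len(pairs))
    for idx in order:
        p = pairs[idx]
        for _ in range(config.patches_per_image):
            centers = sample_training_centers(p.mask.shape, 1, int(rng.integers(2 ** 31)),
                                              vessel_mask=p.mask, fg_fraction=config.fg_fraction)
            r, c = centers[0]
            win = _window((r, c), side)
            uwf = resize_array(extract_window(p.uwf, win), config.common_side)
            ffa = resize_array(extract_window(p.ffa, win), config.common_side) if p.ffa is not None else None
            mask = resize_array(extract_window(p.mask, win), config.common_side, is_mask=True)
            if config.augment:
                k = int(rng.integers(4))
                flip = bool(rng.integers(2))
                def rig(a):
                    if a is None:
                        return None
                    out = a[:, ::-1] if flip else a
                    return np.ascontiguousarray(np.rot90(out, k))
                uwf, ffa, mask = rig(uwf), rig(ffa), rig(mask)
            items.append((uwf, ffa, mask))
    for i in range(0, len(items), config.batch_size):
        chunk = items[i:i + config.batch_size]
        uwf = np.stack([c[0] for c in chunk])
        ffa = np.stack([c[1] for c in chunk]) if chunk[0][1] is not None else None
        mask = np.stack([c[2] for c in chunk])
        yield uwf, ffa, mask


def _triplet_batches(pairs, config: TrainConfig, stage: int, epoch: int):
    """Stage-4 batches: co-centred triplets + small-window masks."""
    rng = _epoch_rng(config.seed, stage, epoch)
    items = []
    order = rng.permutation(len(pairs))
    for idx in order:
        p = pairs[idx]
        for _ in range(config.patches_per_image):
            centers = sample_training_centers(p.mask.shape, 1, int(rng.integers(2 ** 31)),
                                              vessel_mask=p.mask, fg_fraction=config.fg_fraction)
            r, c = centers[0]
            trip = extract_triplet(p.uwf, (r, c), config.small_side, config.common_side)
            mask = resize_array(extract_window(p.mask, _window((r, c), config.small_side)),
                                config.common_side, is_mask=True)
            items.append((trip, mask))
    for i in range(0, len(items), config.batch_size):
        chunk = items[i:i + config.batch_size]
        small = np.stack([t.small for t, _ in chunk])
        middle = np.stack([t.middle for t, _ in chunk])
        large = np.stack([t.large for t, _ in chunk])
        mask = np.stack([m for _, m in chunk])
        yield (small, middle, large), mask


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

class _PretextHead(nn.Module):
    """Disposable 1×1-conv + ×8 upsample head for encoder pre-training."""

    def __init__(self, cin: int, rng):
        self.conv = nn.Conv2d(cin, 1, 1, rng, padding=0)

    def forward(self, feats, out_side: int):
        logits = self.conv(feats)
        return F.resize_bilinear(logits, out_side, out_side)


def _freeze_hashes(bundle: ModelBundle, names) -> dict[str, str]:
    return {n: bundle.component_hash(n) for n in names}


def run_stage(plan: StagePlan, data, config: TrainConfig, work_dir: str | Path,
              bundle: ModelBundle | None = None, resume_from: str | Path | None = None,
              log_rows: list | None = None) -> tuple[ModelBundle, list[dict], Path]:
    """Train one stage; returns the bundle, its loss log and the checkpoint path.

    Stage k > 1 requires the stage-(k−1) checkpoint in ``work_dir`` unless a
    live bundle is passed.  The frozen set is verified by weight hashing.
    """
    work_dir = Path(work_dir)
    work_dir.mkdir(parents=True, exist_ok=True)
    pairs = _resolve_pairs(data)
    if bundle is None:
        bundle = ModelBundle(config)
        if plan.stage > 1:
            prev = work_dir / f"stage{plan.stage - 1}.npz"
            if not prev.exists():
                raise FileNotFoundError(
                    f"stage {plan.stage} depends on stage {plan.stage - 1}: missing checkpoint {prev}")
            load_checkpoint(prev, bundle)

    frozen_before = _freeze_hashes(bundle, plan.frozen)
    log: list[dict] = log_rows if log_rows is not None else []
    start_epoch = 0
    opt_states = None
    if resume_from is not None:
        meta, extra = load_checkpoint(resume_from, bundle)
        start_epoch = int(meta.get("epochs_done", 0))
        opt_states = extra or None

    runner = {1: _run_stage1, 2: _run_stage2, 3: _run_stage3, 4: _run_stage4}[plan.stage]
    runner(bundle, pairs, plan, config, log, start_epoch, opt_states)

    frozen_after = _freeze_hashes(bundle, plan.frozen)
    changed = [n for n in plan.frozen if frozen_before[n] != frozen_after[n]]
    if changed:
        raise RuntimeError(f"freeze violation in stage {plan.stage}: {changed} changed")

    ckpt = work_dir / f"stage{plan.stage}.npz"
    extra = getattr(bundle, "_opt_state", None)
    save_checkpoint(ckpt, bundle, meta={
        "stage": plan.stage, "seed": config.seed, "preset": config.preset,
        "config_hash": config.config_hash(), "epochs_done": plan.epochs,
    }, extra_state=extra)
    log_path = work_dir / f"stage{plan.stage}_log.csv"
    write_log(log_path, log)
    return bundle, log, ckpt


def write_log(path: str | Path, rows: list[dict]) -> None:
    if not rows:
        Path(path).write_text("")
        return
    keys = sorted({k for row in rows for k in row})
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(rows)


def _mean_log(stage, epoch, comps: list[dict]) -> dict:
    keys = comps[0].keys()
    row = {"stage": stage, "epoch": epoch}
    for k in keys:
        row[k] = float(np.mean([c[k] for c in comps]))
    return row


def _run_stage1(bundle, pairs, plan, config, log, start_epoch, opt_states):
    nets = bundle.transfer
    opt_g = nn.Adam(nets.generator_parameters(), lr=config.learning_rate,
                    weight_decay=config.weight_decay)
    opt_d = nn.Adam(nets.discriminator_parameters(), lr=config.learning_rate,
                    weight_decay=config.weight_decay)
    if opt_states:
        opt_g.load_state_dict(opt_states["opt_g"])
        opt_d.load_state_dict(opt_states["opt_d"])
    for epoch in range(start_epoch, plan.epochs):
        comps = []
        for uwf, ffa, _ in _sample_batches(pairs, "small", config, 1, epoch):
            g_losses = transfer_losses(nets, uwf, ffa)
            opt_g.zero_grad()
            g_losses["total"].backward()
            opt_g.step()
            d_losses = discriminator_losses(nets, uwf, ffa)
            opt_d.zero_grad()
            d_losses["total"].backward()
            opt_d.step()
            comps.append({f"g_{k}": float(v.data) for k, v in g_losses.items()}
                         | {f"d_{k}": float(v.data) for k, v in d_losses.items()})
        log.append(_mean_log(1, epoch, comps))
    bundle._opt_state = {"opt_g": opt_g.state_dict(), "opt_d": opt_d.state_dict()}


def _run_encoder_stage(bundle, pairs, plan, config, log, start_epoch, opt_states, which: str):
    encoder = bundle.component(f"seg.bank.{which}")
    rng = np.random.default_rng([config.seed, plan.stage, 999])
    head = _PretextHead(encoder.channels, rng)
    if opt_states and "head" in opt_states:
        head.load_state_dict({k: np.asarray(v, dtype=np.float32)
                              for k, v in opt_states["head"].items()})
    opt = nn.Adam(encoder.parameters() + head.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    if opt_states and "opt" in opt_states:
        opt.load_state_dict(opt_states["opt"])
    for epoch in range(start_epoch, plan.epochs):
        comps = []
        for uwf, _, mask in _sample_batches(pairs, plan.patch_scale, config, plan.stage, epoch):
            feats = encoder(nn.Tensor(uwf[:, None]))
            logits = head(feats, config.common_side)
            prob = logits.sigmoid().reshape(mask.shape)
            if config.pretext == "autoencode":
                loss = F.l1_loss(prob, uwf.astype(np.float32))
                parts = {"recon_l1": float(loss.data), "total": float(loss.data)}
            elif config.pretext == "mask":
                loss, parts = segmentation_loss(prob, mask)
            else:
                raise ValueError(f"unknown pretext {config.pretext!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            comps.append(parts)
        log.append(_mean_log(plan.stage, epoch, comps))
    bundle._opt_state = {"opt": opt.state_dict(),
                         "head": {k: v for k, v in head.state_dict().items()}}


def _run_stage2(bundle, pairs, plan, config, log, start_epoch, opt_states):
    _run_encoder_stage(bundle, pairs, plan, config, log, start_epoch, opt_states, "middle")


def _run_stage3(bundle, pairs, plan, config, log, start_epoch, opt_states):
    _run_encoder_stage(bundle, pairs, plan, config, log, start_epoch, opt_states, "large")


def _stage4_params(bundle, plan):
    params = []
    for name in plan.trainable:
        params += bundle.component_params(name)
    return params


def _run_stage4(bundle, pairs, plan, config, log, start_epoch, opt_states):
    seg = bundle.seg
    use_sfm = config.sfm_mode != "off"
    opt = nn.Adam(_stage4_params(bundle, plan), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    if opt_states and "opt" in opt_states:
        opt.load_state_dict(opt_states["opt"])
    for epoch in range(start_epoch, plan.epochs):
        comps = []
        for (small, middle, large), mask in _triplet_batches(pairs, config, 4, epoch):
            z2 = encode_z2(bundle.transfer, small, frozen=True) if use_sfm else None
            out = seg((small, middle, large), z2=z2, frozen_context=True)
            prob = out.probability.reshape(mask.shape)
            loss, parts = segmentation_loss(prob, mask)
            if out.fusion is not None and out.fusion.provenance:
                reports = out.fusion.provenance
                parts["sfm_fused_blocks"] = float(np.mean([r.n_fused for r in reports]))
            opt.zero_grad()
            loss.backward()
            opt.step()
            comps.append(parts)
        log.append(_mean_log(4, epoch, comps))
    bundle._opt_state = {"opt": opt.state_dict()}


def run_full_pipeline(data, config: TrainConfig, work_dir: str | Path,
                      stages=(1, 2, 3, 4)) -> tuple[ModelBundle, list[dict]]:
    """Run the staged curriculum in order, chaining checkpoints."""
    work_dir = Path(work_dir)
    pairs = _resolve_pairs(data)
    bundle = None
    log: list[dict] = []
    for stage in stages:
        plan = make_stage_plan(stage, config)
        bundle, stage_log, _ = run_stage(plan, pairs, replace(config), work_dir,
                                         bundle=bundle)
        log.extend(stage_log)
    write_log(work_dir / "train_log.csv", log)
    return bundle, log


# ---------------------------------------------------------------------------
# inference + evaluation
# ---------------------------------------------------------------------------

def predict_image(bundle: ModelBundle, uwf_image: np.ndarray, config: TrainConfig,
                  preprocess: bool = True) -> np.ndarray:
    """Tile with 50% overlap, segment each triplet, stitch probabilities."""
    img = clahe_enhance(uwf_image) if preprocess else uwf_image
    grid = make_tile_grid(img.shape, config.small_side)
    use_sfm = config.sfm_mode != "off"
    preds = []
    half = config.small_side // 2
    for i in range(0, len(grid.tile_origins), config.batch_size):
        origins = grid.tile_origins[i:i + config.batch_size]
        trips = [extract_triplet(img, (r + half, c + half), config.small_side, config.common_side)
                 for r, c in origins]
        small = np.stack([t.small for t in trips])
        middle = np.stack([t.middle for t in trips])
        large = np.stack([t.large for t in trips])
        with nn.no_grad():
            z2 = encode_z2(bundle.transfer, small) if use_sfm else None
            out = bundle.seg((small, middle, large), z2=z2)
        prob = out.probability.data[:, 0]
        for p in prob:
            preds.append(resize_array(p.astype(np.float64), config.small_side))
    return stitch(preds, grid)


def evaluate_pairs(bundle: ModelBundle, pairs: list[SamplePair], config: TrainConfig,
                   threshold: float = 0.5, preprocess: bool = True) -> MetricsReport:
    pairs = _resolve_pairs(pairs, preprocess=preprocess)
    preds = [predict_image(bundle, p.uwf, config, preprocess=False) for p in pairs]
    return evaluate_images(preds, [p.mask for p in pairs],
                           [p.valid_mask for p in pairs], threshold=threshold,
                           ids=[p.meta.get("id", str(i)) for i, p in enumerate(pairs)])
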