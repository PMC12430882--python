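"""End-to-end orchestration: the three-step inversion, supervised training,
evaluation, the plain U-Net baseline, and the ablation matrix.

Inference composes the three subnetworks exactly along the physical
factorisation of the imaging model:

1. sample RGB  → sample branch   → radiance cube  I(λ)·S(x,y,λ)
2. light RGB   → light branch    → illuminant cube I(λ)
3. concat(1,2) → fusion decoder  → reflectance    S(x,y,λ)

Training supervises the decoded reflectance with the structure–pixel loss and
(optionally, on by default) the two intermediate cubes with weighted MSE
terms against their ground-truth counterparts, all under one Adam optimiser.
A single seed fans out deterministically to initialisation and batch order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .core import ReflectanceCube, RGBImage, WavelengthGrid
from .metrics import BandMetrics, LossConfig, evaluate_bands
from .nn import Adam, Tensor, concat, mse_loss, structure_pixel_loss
from .networks import (AttentionSpectralNet, PlainUNet, PlainUNetConfig,
                       RadianceNetConfig, RadianceUNet, SpectralNetConfig)
from .synthetic import PairedSample, SceneParams

__all__ = [
    "TrainConfig",
    "AblationSpec",
    "ReflectanceModel",
    "build_model",
    "predict_reflectance",
    "train",
    "evaluate_model",
    "run_ablation",
    "desk_scene_params",
    "desk_train_config",
    "save_model",
    "load_model",
    "VARIANTS",
]

VARIANTS = (
    "full",
    "no_dsa",
    "no_lgf",
    "p_only",
    "l_only",
    "const_illumination",
    "baseline_unet",
    "mse_loss_only",
)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol (Adam, constant learning rate)."""

    learning_rate: float = 4e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.0
    batch_size: int = 8
    epochs: int = 54
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    aux_weight: float = 0.1  # weight of each intermediate-cube MSE term

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")


@dataclass(frozen=True)
class AblationSpec:
    """Selects one model variant from the ablation matrix."""

    variant: str = "full"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")


class ReflectanceModel:
    """A model variant plus its subnetworks and working grid."""

    def __init__(self, variant: str, grid: WavelengthGrid, nets: dict,
                 configs: dict, dtype=np.float64):
        self.variant = variant
        self.grid = grid
        self.nets = nets  # name -> Module
        self.configs = configs  # name -> config dataclass
        self.dtype = dtype

    def parameters(self):
        params = []
        for net in self.nets.values():
            params.extend(net.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def forward(self, sample: Tensor, light: Tensor) -> dict[str, Tensor]:
        """Run the variant; returns at least ``reflectance``, plus
        ``radiance``/``illuminant`` where the corresponding branch exists."""
        out: dict[str, Tensor] = {}
        if self.variant == "baseline_unet":
            out["reflectance"] = self.nets["unet"](sample)
            return out
        if self.variant == "const_illumination":
            light = Tensor(np.ones_like(light.data))
        if self.variant != "l_only":
            out["radiance"] = self.nets["p_net"](sample)
        if self.variant not in ("p_only", "l_only"):
            out["illuminant"] = self.nets["l_light"](light)
        if self.variant == "l_only":
            out["illuminant"] = self.nets["l_light"](light)
            fused = out["illuminant"]
        elif self.variant == "p_only":
            fused = out["radiance"]
        else:
            fused = concat([out["radiance"], out["illuminant"]], axis=1)
        out["reflectance"] = self.nets["l_decoder"](fused)
        return out

    def predict(self, sample_rgb: np.ndarray, light_rgb: np.ndarray) -> np.ndarray:
        """Numpy convenience wrapper: (H,W,3) pair in, (H,W,B) reflectance out."""
        sample = Tensor(_to_nchw(_unit_max(sample_rgb), self.dtype))
        light = Tensor(_to_nchw(_unit_max(light_rgb), self.dtype))
        refl = self.forward(sample, light)["reflectance"].data[0]
        return np.maximum(refl.transpose(1, 2, 0), 0.0).astype(float)


def build_model(
    spec: AblationSpec | str,
    grid: WavelengthGrid,
    seed: int = 0,
    p_base_width: int = 32,
    l_width: int = 64,
    n_stages: int = 3,
    n_lblocks: int = 3,
    dtype=np.float64,
) -> ReflectanceModel:
    """Construct the networks for one variant with a fanned-out seed."""
    spec = AblationSpec(spec) if isinstance(spec, str) else spec
    bands = grid.band_count
    seeds = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    nets: dict = {}
    configs: dict = {}
    if spec.variant == "baseline_unet":
        cfg = PlainUNetConfig(out_channels=bands, base_width=p_base_width,
                              n_stages=n_stages)
        nets["unet"] = PlainUNet(cfg, seed=int(seeds[0]), dtype=dtype)
        configs["unet"] = cfg
        return ReflectanceModel(spec.variant, grid, nets, configs, dtype)

    p_cfg = RadianceNetConfig(
        out_channels=bands,
        base_width=p_base_width,
        n_stages=n_stages,
        use_dsa=spec.variant != "no_dsa",
        use_lgf=spec.variant != "no_lgf",
    )
    l_light_cfg = SpectralNetConfig(in_channels=3, out_channels=bands,
                                    width=l_width, n_lblocks=n_lblocks)
    decoder_in = {"p_only": bands, "l_only": bands}.get(spec.variant, 2 * bands)
    l_dec_cfg = SpectralNetConfig(in_channels=decoder_in, out_channels=bands,
                                  width=l_width, n_lblocks=n_lblocks)
    if spec.variant != "l_only":
        nets["p_net"] = RadianceUNet(p_cfg, seed=int(seeds[0]), dtype=dtype)
        configs["p_net"] = p_cfg
    if spec.variant != "p_only":
        nets["l_light"] = AttentionSpectralNet(l_light_cfg, seed=int(seeds[1]),
                                               dtype=dtype)
        configs["l_light"] = l_light_cfg
    nets["l_decoder"] = AttentionSpectralNet(l_dec_cfg, seed=int(seeds[2]),
                                             dtype=dtype)
    configs["l_decoder"] = l_dec_cfg
    return ReflectanceModel(spec.variant, grid, nets, configs, dtype)


# ---------------------------------------------------------------------------
# data marshalling


def _unit_max(img: np.ndarray) -> np.ndarray:
    peak = img.max()
    return img / peak if peak > 0 else img


def _to_nchw(img: np.ndarray, dtype) -> np.ndarray:
    return np.ascontiguousarray(img.transpose(2, 0, 1)[None]).astype(dtype)


def _stack_pairs(pairs: list[PairedSample], dtype) -> dict[str, np.ndarray]:
    """Normalise (unit max per image) and stack a pair list into NCHW arrays."""

    def stack(images: list[np.ndarray], normalize: bool) -> np.ndarray:
        arrs = []
        for img in images:
            arr = _unit_max(img) if normalize else img
            arrs.append(arr.transpose(2, 0, 1))
        return np.stack(arrs).astype(dtype)

    return {
        "sample_rgb": stack([p.sample_rgb.values for p in pairs], True),
        "light_rgb": stack([p.light_rgb.values for p in pairs], True),
        "radiance": stack([p.sample_hsi.values for p in pairs], True),
        "illuminant": stack([p.light_hsi.values for p in pairs], True),
        "reflectance": stack([p.reflectance_gt.values for p in pairs], False),
    }


def predict_reflectance(
    model: ReflectanceModel, sample_rgb: RGBImage, light_rgb: RGBImage
) -> ReflectanceCube:
    """Full three-step inversion for one RGB pair (inputs unit-max normalised).

    Negative network outputs are clipped at zero so the result is a valid
    reflectance cube.
    """
    if sample_rgb.shape != light_rgb.shape:
        raise ValueError(
            f"sample and light images differ in size: "
            f"{sample_rgb.shape} vs {light_rgb.shape}"
        )
    values = model.predict(sample_rgb.values, light_rgb.values)
    return ReflectanceCube(values, model.grid)


# ---------------------------------------------------------------------------
# training


def _batch_loss(model: ReflectanceModel, data: dict, idx: np.ndarray,
                cfg: TrainConfig) -> Tensor:
    sample = Tensor(data["sample_rgb"][idx])
    light = Tensor(data["light_rgb"][idx])
    out = model.forward(sample, light)
    loss = structure_pixel_loss(out["reflectance"],
                                Tensor(data["reflectance"][idx]), cfg.loss)
    if cfg.aux_weight > 0:
        for key in ("radiance", "illuminant"):
            if key in out:
                loss = loss + cfg.aux_weight * mse_loss(out[key],
                                                        Tensor(data[key][idx]))
    return loss


def _epoch_loss(model: ReflectanceModel, data: dict, cfg: TrainConfig) -> float:
    """Mean loss over a split without gradient updates."""
    n = data["sample_rgb"].shape[0]
    losses = []
    for start in range(0, n, cfg.batch_size):
        idx = np.arange(start, min(start + cfg.batch_size, n))
        losses.append(_batch_loss(model, data, idx, cfg).item())
    return float(np.mean(losses))


def train(
    model: ReflectanceModel,
    train_pairs: list[PairedSample],
    cfg: TrainConfig,
    val_pairs: list[PairedSample] | None = None,
) -> dict:
    """Optimise a model; returns a history dict.

    ``history["val_loss"][0]`` is the validation loss of the untrained model;
    entry ``e`` is the loss after epoch ``e``.  Raises on empty data or a
    non-finite loss.
    """
    if not train_pairs:
        raise ValueError("empty training set")
    data = _stack_pairs(train_pairs, model.dtype)
    val_data = _stack_pairs(val_pairs, model.dtype) if val_pairs else None
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate, betas=cfg.betas,
                     weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    n = len(train_pairs)
    history: dict = {"train_loss": [], "val_loss": []}
    if val_data is not None:
        history["val_loss"].append(_epoch_loss(model, val_data, cfg))
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            optimizer.zero_grad()
            loss = _batch_loss(model, data, idx, cfg)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size}"
                )
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if val_data is not None:
            history["val_loss"].append(_epoch_loss(model, val_data, cfg))
    return history


def evaluate_model(
    model: ReflectanceModel,
    pairs: list[PairedSample],
    loss_cfg: LossConfig | None = None,
) -> BandMetrics:
    """Mean per-band MSE/SSIM of model predictions over a pair list."""
    if not pairs:
        raise ValueError("empty evaluation set")
    loss_cfg = LossConfig() if loss_cfg is None else loss_cfg
    mses, ssims = [], []
    for pair in pairs:
        pred = model.predict(pair.sample_rgb.values, pair.light_rgb.values)
        metrics = evaluate_bands(pred, pair.reflectance_gt.values, loss_cfg)
        mses.append(metrics.mse_per_band)
        ssims.append(metrics.ssim_per_band)
    return BandMetrics(np.mean(mses, axis=0), np.mean(ssims, axis=0))


def run_ablation(
    spec: AblationSpec | str,
    pairs: list[PairedSample],
    manifest: list[dict],
    cfg: TrainConfig,
    grid: WavelengthGrid | None = None,
    **model_kwargs,
) -> tuple[BandMetrics, dict]:
    """Train one ablation variant on the dataset's train split with the shared
    config and seed, and evaluate it on the shared test split."""
    spec = AblationSpec(spec) if isinstance(spec, str) else spec
    if spec.variant == "mse_loss_only":
        cfg = replace(cfg, loss=replace(cfg.loss, beta=0.0))
    splits: dict[str, list[PairedSample]] = {"train": [], "val": [], "test": []}
    for pair, record in zip(pairs, manifest):
        splits[record["split"]].append(pair)
    grid = pairs[0].reflectance_gt.grid if grid is None else grid
    model = build_model(spec, grid, seed=cfg.seed, **model_kwargs)
    history = train(model, splits["train"], cfg, val_pairs=splits["val"] or None)
    metrics = evaluate_model(model, splits["test"] or splits["val"], cfg.loss)
    return metrics, {"history": history, "model": model}


# ---------------------------------------------------------------------------
# desk presets: small problem sizes for CPU-only experimentation


#: Desk-study dataset size (pairs); split 3000/300/100-proportionally.
DESK_N_PAIRS = 128


def desk_scene_params() -> SceneParams:
    """32×32 scenes with 16 bands — the reduced experimentation preset."""
    return SceneParams(image_size=32, n_bands=16)


def desk_train_config(seed: int = 0, epochs: int = 12) -> TrainConfig:
    return TrainConfig(epochs=epochs, seed=seed)


def desk_model_kwargs() -> dict:
    """Narrow widths for CPU training (sample branch 8, attention branch 8)."""
    return {"p_base_width": 8, "l_width": 8, "n_stages": 3, "n_lblocks": 2,
            "dtype": np.float32}


# ---------------------------------------------------------------------------
# checkpoints


def save_model(model: ReflectanceModel, path) -> None:
    """Single-file checkpoint: parameters plus embedded JSON config."""
    arrays = {}
    for name, net in model.nets.items():
        for pname, value in net.state_dict().items():
            arrays[f"{name}/{pname}"] = value
    meta = {
        "variant": model.variant,
        "band_centers": list(map(float, model.grid.band_centers)),
        "dtype": np.dtype(model.dtype).name,
        "configs": {name: asdict(cfg) for name, cfg in model.configs.items()},
    }
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> ReflectanceModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    grid = WavelengthGrid(np.asarray(meta["band_centers"]))
    dtype = np.dtype(meta["dtype"]).type
    cfgs = meta["configs"]
    p_kwargs = {}
    if "p_net" in cfgs:
        p_kwargs["p_base_width"] = cfgs["p_net"]["base_width"]
        p_kwargs["n_stages"] = cfgs["p_net"]["n_stages"]
    elif "unet" in cfgs:
        p_kwargs["p_base_width"] = cfgs["unet"]["base_width"]
        p_kwargs["n_stages"] = cfgs["unet"]["n_stages"]
    if "l_decoder" in cfgs:
        p_kwargs["l_width"] = cfgs["l_decoder"]["width"]
        p_kwargs["n_lblocks"] = cfgs["l_decoder"]["n_lblocks"]
    model = build_model(meta["variant"], grid, dtype=dtype, **p_kwargs)
    for name, net in model.nets.items():
        state = {
            key.split("/", 1)[1]: value
            for key, value in arrays.items()
            if key.startswith(name + "/")
        }
        net.load_state_dict(state)
    return model
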