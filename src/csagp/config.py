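"""Model and run configuration records.

``ModelConfig`` is the full architectural hyperparameter record: the block
count K, the per-branch encoder depths (MRI branch deeper than the PET
branch, reflecting the higher spatial resolution and information content of
structural MRI), the pooling rate r, and the token geometry.  Defaults
follow the reference configuration K=3, M=1, N=3, r=0.5; the embedding
width and head count are engineering choices (small-ViT conventions).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["ModelConfig", "TrainConfig", "RunConfig", "token_schedule"]

_FBLM_VARIANTS = ("conv", "mlp")       # "mlp" is the FBLM* ablation arm
_SFLM_VARIANTS = ("conv", "linear")    # "linear" is the SFLM* ablation arm
_HEAD_MODES = ("concat", "dual")
_ACTIVATIONS = ("gelu", "relu")


@dataclass
class ModelConfig:
    """Architecture hyperparameters for the dual-branch network."""

    K: int = 3                 # number of fusion/pooling blocks
    M: int = 1                 # encoder depth per block, PET branch
    N_enc: int = 3             # encoder depth per block, MRI branch
    r: float = 0.5             # pooling rate: fraction of patch tokens kept
    D: int = 192               # token embedding dimension
    h: int = 4                 # attention heads
    ffn_mult: int = 4          # FFN hidden width = ffn_mult * D
    C: int = 2                 # number of classes
    img_size: tuple[int, int] = (224, 224)
    seed: int = 0
    # -- behavioural switches -------------------------------------------------
    share_stem: bool = False           # share patch-embed weights across branches
    disable_cafm: bool = False         # ablation: remove cross-attention fusion
    activation: str = "gelu"           # FFN nonlinearity
    conventional_prenorm: bool = False  # use standard pre-norm in CAFM FFN stage
    add_self_loops: bool = False       # force A_ii=1 before GCN normalization
                                       # (thresholding already gives A_ii=1 when mu>0)
    gat_heads: int = 2                 # attention heads in the feature-fusion GAT
    fblm_variant: str = "conv"         # "conv" (1-D CNN + BN) or "mlp" (FBLM*)
    sflm_variant: str = "conv"         # "conv" (1-D CNN + BN) or "linear" (SFLM*)
    head_mode: str = "concat"          # classifier head over the two class tokens
    rpr_blocks: tuple[int, ...] | None = None  # block indices with RPR (None=all)

    def __post_init__(self):
        if not (0.0 < self.r <= 1.0):
            raise ValueError(f"pooling rate r must be in (0, 1], got {self.r}")
        if self.D % self.h != 0:
            raise ValueError(f"D={self.D} must be divisible by h={self.h}")
        if min(self.K, self.M, self.N_enc) < 1:
            raise ValueError("K, M and N_enc must all be >= 1")
        if self.fblm_variant not in _FBLM_VARIANTS:
            raise ValueError(f"fblm_variant must be one of {_FBLM_VARIANTS}")
        if self.sflm_variant not in _SFLM_VARIANTS:
            raise ValueError(f"sflm_variant must be one of {_SFLM_VARIANTS}")
        if self.head_mode not in _HEAD_MODES:
            raise ValueError(f"head_mode must be one of {_HEAD_MODES}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        self.img_size = tuple(self.img_size)
        h, w = self.img_size
        if h % 16 or w % 16 or h < 16 or w < 16:
            raise ValueError(
                f"img_size {self.img_size} must have sides >= 16 and divisible "
                "by 16 (the stem downsamples by 4*2*2)")

    @property
    def n_patches(self) -> int:
        return (self.img_size[0] // 16) * (self.img_size[1] // 16)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["img_size"] = list(self.img_size)
        if self.rpr_blocks is not None:
            d["rpr_blocks"] = list(self.rpr_blocks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if d.get("rpr_blocks") is not None:
            d["rpr_blocks"] = tuple(d["rpr_blocks"])
        return cls(**d)


def token_schedule(n_patches: int, r: float, K: int) -> list[int]:
    """Sequence lengths (class token included) entering each block and after.

    Returns ``K + 1`` lengths: the input length ``n_patches + 1`` followed by
    the length after each pooling stage, where each stage keeps
    ``max(1, floor(r * n))`` of its ``n`` patch tokens.
    """
    lengths = [n_patches + 1]
    for _ in range(K):
        n = lengths[-1] - 1
        lengths.append(max(1, int(r * n)) + 1)
    return lengths


@dataclass
class TrainConfig:
    """Optimizer and loop settings (reference protocol: Adam, cross-entropy,
    batch 128, 300 epochs, lr 1e-5, weight decay 5e-4)."""

    lr: float = 1e-5
    weight_decay: float = 5e-4
    batch_size: int = 128
    epochs: int = 300
    seed: int = 0


@dataclass
class RunConfig:
    """Everything one CLI run needs: model, optimizer, data, output."""

    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    data: dict = field(default_factory=dict)   # SynthConfig kwargs or dataset path
    out_dir: str = "runs/run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"model", "train", "data", "out_dir", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        model = ModelConfig.from_dict(raw.get("model", {}))
        train = TrainConfig(**raw.get("train", {}))
        return cls(model=model, train=train, data=dict(raw.get("data", {})),
                   out_dir=raw.get("out_dir", "runs/run"),
                   seed=int(raw.get("seed", 0)))

    def to_yaml(self, path: str) -> None:
        d = {
            "model": self.model.to_dict(),
            "train": dataclasses.asdict(self.train),
            "data": self.data,
            "out_dir": self.out_dir,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
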