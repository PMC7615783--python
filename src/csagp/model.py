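"""The full dual-branch network.

Two convolutional patch embeds (one per modality) feed K stacked blocks;
each block runs the per-branch encoders (the MRI branch deeper than the
PET branch), exchanges class-token information through the cross-attention
fusion module, and prunes patch tokens with the graph-pooling RPR stage.
The two terminal class tokens are combined into the shared representation
that the classifier head maps to class logits.
"""

from __future__ import annotations

import io
import zipfile
from dataclasses import dataclass

import numpy as np
import yaml

from .attention import CAFM, EncoderBlock
from .config import ModelConfig
from .nn import LayerNorm, Linear, Module, ModuleList, Tensor, concat
from .pooling import RPR, pooled_size
from .tokenizer import PatchEmbed
from .types import ImagePair, Prediction, TokenSequence

__all__ = ["CsAGPBlock", "CsAGPNet", "CsAGPState"]


@dataclass
class CsAGPState:
    """The two token streams between blocks."""

    mri_seq: TokenSequence
    pet_seq: TokenSequence
    block_index: int = 0


class CsAGPBlock(Module):
    """Encoders -> cross-attention fusion -> per-branch graph pooling."""

    def __init__(self, cfg: ModelConfig, n_patches_in: int, block_index: int,
                 rng: np.random.Generator):
        super().__init__()
        self.block_index = block_index
        self.mri_encoders = ModuleList(
            EncoderBlock(cfg.D, cfg.h, cfg.ffn_mult, rng, cfg.activation)
            for _ in range(cfg.N_enc))
        self.pet_encoders = ModuleList(
            EncoderBlock(cfg.D, cfg.h, cfg.ffn_mult, rng, cfg.activation)
            for _ in range(cfg.M))
        self.cafm = None
        if not cfg.disable_cafm:
            self.cafm = CAFM(cfg.D, cfg.h, cfg.ffn_mult, rng, cfg.activation,
                             cfg.conventional_prenorm)
        self.use_rpr = (cfg.rpr_blocks is None
                        or block_index in cfg.rpr_blocks)
        if self.use_rpr:
            self.mri_rpr = RPR(cfg.D, n_patches_in, cfg.r, rng,
                               gat_heads=cfg.gat_heads,
                               fblm_variant=cfg.fblm_variant,
                               sflm_variant=cfg.sflm_variant,
                               add_self_loops=cfg.add_self_loops,
                               activation=cfg.activation)
            self.pet_rpr = RPR(cfg.D, n_patches_in, cfg.r, rng,
                               gat_heads=cfg.gat_heads,
                               fblm_variant=cfg.fblm_variant,
                               sflm_variant=cfg.sflm_variant,
                               add_self_loops=cfg.add_self_loops,
                               activation=cfg.activation)
            self.n_patches_out = self.mri_rpr.n_patches_out
        else:
            self.n_patches_out = n_patches_in

    def forward(self, state: CsAGPState) -> CsAGPState:
        mri, pet = state.mri_seq, state.pet_seq
        for enc in self.mri_encoders:
            mri = enc(mri)
        for enc in self.pet_encoders:
            pet = enc(pet)
        if self.cafm is not None:
            mri, pet = self.cafm(mri, pet)
        if self.use_rpr:
            mri = self.mri_rpr(mri)
            pet = self.pet_rpr(pet)
        return CsAGPState(mri, pet, state.block_index + 1)


class CsAGPNet(Module):
    """Dual patch embeds, K blocks, classifier head."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
        self.mri_embed = PatchEmbed(cfg.img_size, cfg.D, rng)
        if cfg.share_stem:
            self.pet_embed = self.mri_embed
        else:
            self.pet_embed = PatchEmbed(cfg.img_size, cfg.D, rng)
        self.blocks = ModuleList()
        n = self.mri_embed.n_patches
        self.patch_schedule = [n]
        for b in range(cfg.K):
            block = CsAGPBlock(cfg, n, b, rng)
            self.blocks.append(block)
            n = block.n_patches_out
            self.patch_schedule.append(n)
        if cfg.head_mode == "concat":
            self.head_norm = LayerNorm(2 * cfg.D)
            self.head = Linear(2 * cfg.D, cfg.C, rng)
        else:  # dual heads, averaged logits
            self.head_mri = Linear(cfg.D, cfg.C, rng)
            self.head_pet = Linear(cfg.D, cfg.C, rng)

    # -- forward passes -------------------------------------------------------

    def forward_features(self, mri: np.ndarray, pet: np.ndarray
                         ) -> tuple[Tensor, Tensor]:
        """Run both streams through all blocks; return the two class tokens."""
        state = CsAGPState(self.mri_embed(mri), self.pet_embed(pet))
        for block in self.blocks:
            state = block(state)
        return state.mri_seq.cls, state.pet_seq.cls

    def forward_logits(self, mri: np.ndarray, pet: np.ndarray) -> Tensor:
        mri_cls, pet_cls = self.forward_features(mri, pet)
        if self.cfg.head_mode == "concat":
            shared = concat([mri_cls, pet_cls], axis=1)     # (1, 2D)
            logits = self.head(self.head_norm(shared))
        else:
            logits = (self.head_mri(mri_cls) + self.head_pet(pet_cls)) * 0.5
        return logits.reshape(-1)

    def forward(self, pair: ImagePair) -> Prediction:
        if pair.spatial_shape != self.cfg.img_size:
            raise ValueError(f"image size {pair.spatial_shape} does not match "
                             f"model config {self.cfg.img_size}")
        logits = self.forward_logits(pair.mri, pair.pet)
        return Prediction(logits=logits.data.copy())

    def predict_proba(self, pairs: list[ImagePair]) -> np.ndarray:
        self.eval()
        return np.stack([self.forward(p).probabilities for p in pairs])

    # -- checkpointing --------------------------------------------------------

    def save(self, path: str) -> None:
        """Single-archive checkpoint: weights (npz) + YAML config."""
        buf = io.BytesIO()
        np.savez(buf, **self.state_dict())
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("weights.npz", buf.getvalue())
            zf.writestr("config.yaml", yaml.safe_dump(self.cfg.to_dict()))

    @classmethod
    def load(cls, path: str) -> "CsAGPNet":
        with zipfile.ZipFile(path) as zf:
            cfg = ModelConfig.from_dict(
                yaml.safe_load(zf.read("config.yaml").decode()))
            with zf.open("weights.npz") as fh:
                state = dict(np.load(io.BytesIO(fh.read())))
        model = cls(cfg)
        model.load_state_dict(state)
        return model

    # -- introspection --------------------------------------------------------

    def token_lengths(self) -> list[int]:
        """Sequence lengths entering block 0 and leaving each block."""
        return [n + 1 for n in self.patch_schedule]

    def n_parameters_excluding_rpr_pe(self) -> int:
        return sum(p.size for name, p in self.named_parameters()
                   if not (("rpr" in name) and name.endswith("pos_embed")))
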