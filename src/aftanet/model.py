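"""The frequency-time attention Transformer: blocks, encoder, heads.

Each encoder block chains adaptive frequency filtering, frequency-gated
multi-head self-attention and a feed-forward network, with residual paths
and layer normalization arranged pre-norm.  The filtering stage returns
both the fused sequence and a per-token gate (the time-domain energy
profile of the filtered signal, mean-normalized); the gate rescales the
attention value vectors, so spectral salience modulates temporal mixing.
With the filter bypassed (alpha -> 1) and the gate disabled, a block is
exactly a standard pre-norm Transformer block — a reduction the test suite
verifies against an independent reference.

The self-supervised heads follow the masked-autoencoder scheme: a
predictor infers features for masked slots from the visible context via a
cross-attention read, and a reconstructor (two plain Transformer blocks
plus a linear projection) maps encoder features and predicted features,
each re-tagged with their positional embeddings, back to patch samples.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .nn import (Tensor, Parameter, Module, Linear, LayerNorm, MLP,
                 MultiHeadAttention, Dropout, concat, softmax, no_grad)
from .affm import AFFMLayer
from .patching import MaskSpec, EmbedParams

__all__ = ["ModelConfig", "TokenEmbedder", "AFTABlock", "PlainBlock",
           "Encoder", "Predictor", "Reconstructor", "AFTAModel"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale configuration (256-dim tokens, 8 heads,
    8 blocks, patches of 200 samples); `tiny` is the desk-scale preset used
    throughout the tests.
    """

    n_channels: int = 19
    n_time_patches: int = 4
    patch_len: int = 200
    d_model: int = 256
    n_heads: int = 8
    n_blocks: int = 8
    mlp_ratio: int = 4
    n_summary: int = 4
    n_classes: int | None = None
    n_outputs: int = 1
    dropout: float = 0.3
    use_affm: bool = True
    use_freq_gate: bool = True
    local_cutoff_fraction: float = 0.5
    mask_temperature: float = 0.1
    lambda_theta: float = 1e-4
    epsilon: float = 1e-12
    alpha_init: float = 0.5
    hard_mask_eval: bool = True
    n_reconstructor_blocks: int = 2
    seed: int = 0

    @classmethod
    def tiny(cls, **kwargs) -> "ModelConfig":
        base = dict(n_channels=4, n_time_patches=4, patch_len=64, d_model=64,
                    n_heads=4, n_blocks=2, n_summary=4, dropout=0.0)
        base.update(kwargs)
        return cls(**base)

    @property
    def n_grid(self) -> int:
        return self.n_channels * self.n_time_patches

    @property
    def max_seq_len(self) -> int:
        return self.n_grid + self.n_summary

    def to_dict(self) -> dict:
        return asdict(self)


class TokenEmbedder(Module):
    """Learnable patch projection, channel/position embeddings, summary and
    mask tokens."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        d, dm = cfg.patch_len, cfg.d_model
        scale = 0.02
        self.w_p = Parameter(rng.normal(0, np.sqrt(2.0 / (d + dm)), (d, dm)))
        self.b_p = Parameter(np.zeros(dm))
        self.zeta = Parameter(rng.normal(0, scale, (cfg.n_channels, dm)))
        self.pi = Parameter(rng.normal(0, scale, (cfg.n_time_patches, dm)))
        self.summary = Parameter(rng.normal(0, scale, (cfg.n_summary, dm)))
        self.mask_token = Parameter(rng.normal(0, scale, dm))
        self.cfg = cfg

    def as_embed_params(self) -> EmbedParams:
        return EmbedParams(w_p=self.w_p.data, b_p=self.b_p.data,
                           zeta=self.zeta.data, pi=self.pi.data,
                           summary=self.summary.data,
                           mask_token=self.mask_token.data)

    def _positional(self) -> Tensor:
        cfg = self.cfg
        pos = (self.zeta.reshape(cfg.n_channels, 1, cfg.d_model)
               + self.pi.reshape(1, cfg.n_time_patches, cfg.d_model))
        return pos.reshape(cfg.n_grid, cfg.d_model)

    def full_sequence(self, patches: np.ndarray,
                      mask: MaskSpec | None = None) -> Tensor:
        """Tokens for the whole grid plus summary tokens, shape
        (B, n_grid + n_summary, d_model).  Masked grid positions carry
        positional terms plus the mask token and no signal term."""
        cfg = self.cfg
        B = patches.shape[0]
        flat = Tensor(patches.reshape(B, cfg.n_grid, cfg.patch_len))
        signal = flat @ self.w_p + self.b_p
        pos = self._positional()
        if mask is not None:
            flags = mask.mask_grid.reshape(cfg.n_grid, 1).astype(np.float64)
            patch_tok = (signal * (1.0 - flags)
                         + self.mask_token * flags + pos)
        else:
            patch_tok = signal + pos
        summary = self.summary + Tensor(np.zeros((B, 1, 1)))
        return concat([patch_tok, summary], axis=1)

    def visible_sequence(self, patches: np.ndarray, mask: MaskSpec) -> Tensor:
        """Unmasked patch tokens plus summary tokens (the encoder input)."""
        cfg = self.cfg
        full = self.full_sequence(patches, mask=None)
        vis_flat = np.flatnonzero(~mask.mask_grid.reshape(-1))
        keep = np.concatenate(
            [vis_flat, cfg.n_grid + np.arange(cfg.n_summary)])
        return full[:, keep, :]

    def query_tokens(self, pairs: np.ndarray) -> Tensor:
        """zeta_i + pi_j + mask_token for each (i, j) pair — predictor
        queries for masked slots."""
        z = self.zeta[pairs[:, 0]]
        p = self.pi[pairs[:, 1]]
        return z + p + self.mask_token

    def positional_for(self, pairs: np.ndarray) -> Tensor:
        return self.zeta[pairs[:, 0]] + self.pi[pairs[:, 1]]


class PlainBlock(Module):
    """Standard pre-norm Transformer block (attention + FFN)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dm = cfg.d_model
        self.ln1 = LayerNorm(dm)
        self.attn = MultiHeadAttention(dm, cfg.n_heads, rng)
        self.ln2 = LayerNorm(dm)
        self.mlp = MLP(dm, cfg.mlp_ratio * dm, rng)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        x = x + self.drop(self.attn(self.ln1(x)), training, rng)
        return x + self.drop(self.mlp(self.ln2(x)), training, rng)


class AFTABlock(Module):
    """Adaptive filtering -> gated attention -> FFN, all residual."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dm = cfg.d_model
        self.use_affm = cfg.use_affm
        self.use_gate = cfg.use_freq_gate
        if cfg.use_affm:
            self.affm = AFFMLayer(
                n_ref_bins=cfg.max_seq_len // 2 + 1,
                local_cutoff_fraction=cfg.local_cutoff_fraction,
                mask_temperature=cfg.mask_temperature,
                lambda_theta=cfg.lambda_theta, epsilon=cfg.epsilon,
                alpha_init=cfg.alpha_init, hard_mask_eval=cfg.hard_mask_eval)
        self.ln1 = LayerNorm(dm)
        self.attn = MultiHeadAttention(dm, cfg.n_heads, rng)
        self.ln2 = LayerNorm(dm)
        self.mlp = MLP(dm, cfg.mlp_ratio * dm, rng)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        gate = None
        if self.use_affm:
            x, gate = self.affm(x, training=training)
        if not self.use_gate:
            gate = None
        x = x + self.drop(self.attn(self.ln1(x), gate=gate), training, rng)
        return x + self.drop(self.mlp(self.ln2(x)), training, rng)


class Encoder(Module):
    """Stack of frequency-time attention blocks with a final LayerNorm.

    Zero blocks means the identity map (no final normalization either)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.blocks = [AFTABlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.final_ln = LayerNorm(cfg.d_model) if cfg.n_blocks else None

    def __call__(self, x: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        for block in self.blocks:
            x = block(x, training, rng)
        return self.final_ln(x) if self.final_ln is not None else x

    def theta_penalty(self) -> Tensor | float:
        total = 0.0
        for block in self.blocks:
            if block.use_affm:
                total = total + block.affm.theta_penalty()
        return total


class Predictor(Module):
    """Predict features for masked slots: a cross-attention read of the
    encoder output from positional queries, then a feed-forward refinement."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dm = cfg.d_model
        self.ln_q = LayerNorm(dm)
        self.ln_ctx = LayerNorm(dm)
        self.cross = MultiHeadAttention(dm, cfg.n_heads, rng)
        self.ln2 = LayerNorm(dm)
        self.mlp = MLP(dm, cfg.mlp_ratio * dm, rng)

    def __call__(self, queries: Tensor, enc: Tensor) -> Tensor:
        q = queries + self.cross(self.ln_q(queries), context=self.ln_ctx(enc))
        return q + self.mlp(self.ln2(q))


class Reconstructor(Module):
    """Plain Transformer blocks over [encoder features | predicted features]
    (each plus positional embeddings), projected to patch samples."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.blocks = [PlainBlock(cfg, rng)
                       for _ in range(cfg.n_reconstructor_blocks)]
        self.final_ln = LayerNorm(cfg.d_model)
        self.proj = Linear(cfg.d_model, cfg.patch_len, rng)

    def __call__(self, seq: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        for block in self.blocks:
            seq = block(seq, training, rng)
        return self.proj(self.final_ln(seq))


class AFTAModel(Module):
    """Embedder + encoder + self-supervised heads + task heads."""

    def __init__(self, cfg: ModelConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        # amplitude normalization applied to incoming patches (set once from
        # the pretraining data); losses and reconstructions live on this scale
        self.input_scale = 1.0
        self.embedder = TokenEmbedder(cfg, rng)
        self.encoder = Encoder(cfg, rng)
        self.predictor = Predictor(cfg, rng)
        self.reconstructor = Reconstructor(cfg, rng)
        if cfg.n_classes:
            self.cls_head = Linear(cfg.d_model, cfg.n_classes, rng)
        self.reg_head = Linear(cfg.d_model, cfg.n_outputs, rng)

    def _scaled(self, patches: np.ndarray) -> np.ndarray:
        return patches if self.input_scale == 1.0 else patches / self.input_scale

    # -- self-supervised pass ------------------------------------------------
    def forward_pretrain(self, patches: np.ndarray, mask: MaskSpec,
                         training: bool = True,
                         rng: np.random.Generator | None = None) -> dict:
        """One masked-reconstruction pass.

        patches : (B, C, n_time, d).  Returns encoder features over visible
        tokens, predictor features and reconstructions for each masked slot.
        """
        patches = self._scaled(patches)
        B = patches.shape[0]
        cfg = self.cfg
        tokens = self.embedder.visible_sequence(patches, mask)
        enc = self.encoder(tokens, training, rng)
        pairs = mask.masked_pairs
        out = {"enc": enc, "mask_pairs": pairs}
        if len(pairs) == 0:
            out["pred"] = Tensor(np.zeros((B, 0, cfg.d_model)))
            out["rec"] = Tensor(np.zeros((B, 0, cfg.patch_len)))
            return out
        queries = (self.embedder.query_tokens(pairs)
                   + Tensor(np.zeros((B, 1, 1))))
        pred = self.predictor(queries, enc)
        n_vis_patches = enc.shape[1] - cfg.n_summary
        enc_patches = enc[:, :n_vis_patches, :]
        pos_vis = self.embedder.positional_for(mask.unmasked_pairs)
        pos_masked = self.embedder.positional_for(pairs)
        rec_in = concat([enc_patches + pos_vis, pred + pos_masked], axis=1)
        rec_out = self.reconstructor(rec_in, training, rng)
        out["pred"] = pred
        out["rec"] = rec_out[:, n_vis_patches:, :]
        return out

    def encode_targets(self, patches: np.ndarray, mask: MaskSpec) -> Tensor:
        """Momentum-target features at the masked slots: encode the fully
        visible sequence and gather the masked grid positions.  Run this on
        the momentum copy under no_grad."""
        with no_grad():
            tokens = self.embedder.full_sequence(self._scaled(patches),
                                                 mask=None)
            enc = self.encoder(tokens, training=False)
            flat = mask.masked_pairs[:, 0] * self.cfg.n_time_patches \
                + mask.masked_pairs[:, 1]
            return Tensor(enc.data[:, flat, :])

    # -- downstream ----------------------------------------------------------
    def features(self, patches: np.ndarray, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        """Summary-token features of the fully visible sequence, (B, d_model)."""
        tokens = self.embedder.full_sequence(self._scaled(patches), mask=None)
        enc = self.encoder(tokens, training, rng)
        return enc[:, -self.cfg.n_summary:, :].mean(axis=1)

    def classify_head(self, enc_summary: Tensor) -> Tensor:
        """Class probabilities on the simplex from summary features."""
        if not hasattr(self, "cls_head"):
            raise RuntimeError("model built without a classification head")
        return softmax(self.cls_head(enc_summary), axis=-1)

    def regress_head(self, enc_summary: Tensor) -> Tensor:
        return self.reg_head(enc_summary)

    def classify(self, patches: np.ndarray) -> np.ndarray:
        return self.classify_head(self.features(patches)).data

    def theta_penalty(self):
        return self.encoder.theta_penalty()

    # -- persistence ----------------------------------------------------------
    def ssl_state(self) -> dict[str, np.ndarray]:
        """Embedder + encoder parameters (what the momentum copy tracks)."""
        return {k: v for k, v in self.state().items()
                if k.startswith(("embedder.", "encoder."))}

    def load_ssl_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        for k, v in state.items():
            params[k].data = np.array(v, dtype=np.float64)


def lr_depth_map(model: AFTAModel) -> dict[str, int]:
    """Depth-from-top per parameter for layer-wise learning-rate decay.

    Output-side modules (heads, predictor, reconstructor) sit at depth 0;
    encoder blocks deepen toward the input; the embedder is deepest.
    """
    n = model.cfg.n_blocks
    depths: dict[str, int] = {}
    for name in model.parameters():
        if name.startswith("encoder.blocks."):
            idx = int(name.split(".")[2])
            depths[name] = n - idx
        elif name.startswith("encoder.final_ln"):
            depths[name] = 1
        elif name.startswith("embedder."):
            depths[name] = n + 1
        else:
            depths[name] = 0
    return depths
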