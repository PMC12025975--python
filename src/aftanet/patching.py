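"""Spatiotemporal patching, dual-ratio masking, and token embedding.

An epoch X of shape (C, T) is cut into a grid of C x (T/d) patches of d
samples each.  The self-supervised pretext task occludes a fixed fraction
of time columns and channel rows; a patch is masked when its row OR its
column is selected (the union rule), so heavy channel masking combined with
50% time masking leaves only a small visible context.  Counts are exact:
round-half-up of ratio * n per axis.

Tokens are affine embeddings of patch content plus learnable channel and
time-position embeddings; masked positions carry only the positional part
plus a shared mask token (no signal term).  Learnable summary tokens are
appended to carry sequence-global context.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import EpochTensor

__all__ = ["PatchGrid", "MaskSpec", "TokenSequence", "round_half_up",
           "partition_patches", "reassemble", "sample_mask", "embed_tokens"]


def round_half_up(x: float) -> int:
    """Round with ties going up: round_half_up(2.5) == 3."""
    return int(math.floor(x + 0.5))


@dataclass
class PatchGrid:
    """Patches of one epoch, shape (C, n_time_patches, d)."""

    patches: np.ndarray
    d: int

    @property
    def n_channels(self) -> int:
        return self.patches.shape[0]

    @property
    def n_time(self) -> int:
        return self.patches.shape[1]


@dataclass
class MaskSpec:
    """Masked/unmasked patch index sets over a (C, n_time) grid."""

    n_channels: int
    n_time: int
    masked_channels: np.ndarray
    masked_time: np.ndarray

    def __post_init__(self):
        self.masked_channels = np.asarray(sorted(self.masked_channels),
                                          dtype=np.int64)
        self.masked_time = np.asarray(sorted(self.masked_time), dtype=np.int64)
        grid = np.zeros((self.n_channels, self.n_time), dtype=bool)
        grid[self.masked_channels, :] = True
        grid[:, self.masked_time] = True
        self._mask_grid = grid

    @property
    def mask_grid(self) -> np.ndarray:
        """Boolean (C, n_time) array, True where masked."""
        return self._mask_grid

    @property
    def masked_pairs(self) -> np.ndarray:
        """(|M|, 2) array of (channel, time) indices of masked patches."""
        return np.argwhere(self._mask_grid)

    @property
    def unmasked_pairs(self) -> np.ndarray:
        return np.argwhere(~self._mask_grid)

    @property
    def n_masked(self) -> int:
        return int(self._mask_grid.sum())


@dataclass
class TokenSequence:
    """Embedded tokens with per-token roles and mask flags.

    roles[i] is ("patch", c, t) or ("summary", k); mask_flags marks masked
    patch tokens (summary tokens are never masked).
    """

    tokens: np.ndarray
    roles: list[tuple]
    mask_flags: np.ndarray

    @property
    def n_tokens(self) -> int:
        return self.tokens.shape[0]


def partition_patches(ep: EpochTensor | np.ndarray, d: int) -> PatchGrid:
    """Cut an epoch into non-overlapping patches of d samples.

    Lossless: `reassemble` reproduces the input bitwise.
    """
    data = ep.data if isinstance(ep, EpochTensor) else np.atleast_2d(ep)
    C, T = data.shape
    if d < 1 or T % d != 0:
        raise ValueError(f"patch length d={d} does not divide T={T}")
    return PatchGrid(patches=data.reshape(C, T // d, d).copy(), d=d)


def reassemble(grid: PatchGrid) -> np.ndarray:
    """Concatenate patches along time; exact inverse of partition_patches."""
    C, n_t, d = grid.patches.shape
    return grid.patches.reshape(C, n_t * d)


def sample_mask(n_time_patches: int, n_channels: int, time_ratio: float,
                channel_ratio: float, seed: int | np.random.Generator = 0,
                rule: str = "union") -> MaskSpec:
    """Sample the dual-ratio mask.

    Exactly round_half_up(time_ratio * n_time_patches) time columns and
    round_half_up(channel_ratio * n_channels) channel rows are drawn
    uniformly without replacement.  Under the default union rule a patch is
    masked when its row or column is selected; "intersection" masks only
    patches selected on both axes.
    """
    for name, r in (("time_ratio", time_ratio), ("channel_ratio", channel_ratio)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {r}")
    if rule not in ("union", "intersection"):
        raise ValueError(f"unknown mask rule {rule!r}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_t = round_half_up(time_ratio * n_time_patches)
    n_c = round_half_up(channel_ratio * n_channels)
    masked_time = rng.choice(n_time_patches, size=n_t, replace=False)
    masked_channels = rng.choice(n_channels, size=n_c, replace=False)
    spec = MaskSpec(n_channels=n_channels, n_time=n_time_patches,
                    masked_channels=masked_channels, masked_time=masked_time)
    if rule == "intersection":
        grid = np.zeros((n_channels, n_time_patches), dtype=bool)
        rows = np.isin(np.arange(n_channels), spec.masked_channels)
        cols = np.isin(np.arange(n_time_patches), spec.masked_time)
        grid[np.ix_(rows, cols)] = True
        spec._mask_grid = grid
    return spec


@dataclass
class EmbedParams:
    """Plain-array embedding parameters (the reference semantics).

    w_p : (d, d_model) linear map; b_p : (d_model,) bias;
    zeta : (C, d_model) channel embeddings; pi : (n_time, d_model) temporal
    positional embeddings; summary : (n_summary, d_model); mask_token :
    (d_model,) shared learnable token standing in for occluded signal.
    """

    w_p: np.ndarray
    b_p: np.ndarray
    zeta: np.ndarray
    pi: np.ndarray
    summary: np.ndarray
    mask_token: np.ndarray


def embed_tokens(grid: PatchGrid, mask: MaskSpec | None,
                 params: EmbedParams) -> TokenSequence:
    """Embed all patches plus summary tokens.

    Unmasked token (i, j) = w_p^T p_ij + b_p + zeta_i + pi_j.  Masked
    positions carry zeta_i + pi_j + mask_token and are independent of the
    patch values.  Summary tokens are appended as-is (no positional terms).
    """
    C, n_t, d = grid.patches.shape
    d_model = params.w_p.shape[1]
    if params.w_p.shape[0] != d:
        raise ValueError(
            f"w_p expects patches of length {params.w_p.shape[0]}, got {d}")
    if params.zeta.shape[0] < C or params.pi.shape[0] < n_t:
        raise ValueError("zeta/pi smaller than the patch grid")
    signal = grid.patches.reshape(C * n_t, d) @ params.w_p + params.b_p
    pos = (params.zeta[:C, None, :] + params.pi[None, :n_t, :]
           ).reshape(C * n_t, d_model)
    flags = (mask.mask_grid.reshape(-1) if mask is not None
             else np.zeros(C * n_t, dtype=bool))
    tokens = np.where(flags[:, None], pos + params.mask_token, signal + pos)
    tokens = np.concatenate([tokens, params.summary], axis=0)
    roles = [("patch", i, j) for i in range(C) for j in range(n_t)]
    roles += [("summary", k) for k in range(params.summary.shape[0])]
    mask_flags = np.concatenate(
        [flags, np.zeros(params.summary.shape[0], dtype=bool)])
    return TokenSequence(tokens=tokens, roles=roles, mask_flags=mask_flags)
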