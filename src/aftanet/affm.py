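"""Adaptive frequency filtering: learnable spectral gains with energy masking.

The module implements the adaptive frequency filtering stage of the
frequency-time attention block.  A real sequence is taken to the frequency
domain, per-bin energies are compared (after median normalization) against a
learnable threshold ``theta`` to form an adaptive mask, learnable global and
local gain vectors ``sigma(W)`` rescale the surviving bins, and the filtered
signal is brought back to the time domain and blended with the input through
a learnable gate ``alpha``:

    x_tilde = alpha * x + (1 - alpha) * IFFT(FFT(x) * mask * G)

Two surfaces are provided.  The plain-array functions (`forward_fft`,
`adaptive_mask`, `filter_gains`, `apply_filter`, `inverse_and_fuse`,
`affm_forward`) operate on numpy arrays and define the reference semantics.
`AFFMLayer` is the trainable version used inside the encoder; it expresses
the same pipeline through the autodiff engine (the DFT as explicit
cosine/sine matrices, so gradients flow through ordinary matmuls) and is
tested for agreement with the functional path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .nn import Module, Parameter, Tensor, sigmoid

logger = logging.getLogger(__name__)

__all__ = ["FilterBank", "SpectrumTensor", "forward_fft", "filter_gains",
           "adaptive_mask", "apply_filter", "inverse_and_fuse",
           "affm_forward", "AFFMLayer"]


@dataclass
class FilterBank:
    """Learnable filter state for one sequence length.

    Gains are ``sigma(W)`` so they always lie in (0, 1); the combined gain is
    the elementwise product of the global and local gains.
    """

    w_global: np.ndarray          # per-bin logits, global scope
    w_local: np.ndarray           # per-bin logits, fine-grained scope
    theta: float = 0.5            # energy threshold (on median-normalized power)
    alpha: float = 0.5            # fusion gate in [0, 1]
    lam: float = 1e-4             # regularization weight on theta**2
    epsilon: float = 1e-12        # stabilizer for the median normalization

    def __post_init__(self):
        self.w_global = np.asarray(self.w_global, dtype=np.float64)
        self.w_local = np.asarray(self.w_local, dtype=np.float64)
        if self.w_global.shape != self.w_local.shape:
            raise ValueError("global and local weights must share a shape")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class SpectrumTensor:
    """One-sided spectrum of a real sequence plus derived quantities."""

    F: np.ndarray                      # complex bins, shape (..., n_bins)
    n: int                             # original sequence length
    P: np.ndarray = field(init=False)  # power per bin

    def __post_init__(self):
        self.P = np.abs(self.F) ** 2


def forward_fft(x: np.ndarray, axis: int = -1) -> SpectrumTensor:
    """Real-input FFT along `axis`; bins cover non-negative frequencies."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input to forward_fft must be finite")
    F = np.fft.rfft(x, axis=axis)
    F = np.moveaxis(F, axis, -1)
    return SpectrumTensor(F=F, n=x.shape[axis])


def filter_gains(bank: FilterBank) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sigmoid gains and their product; all lie strictly inside (0, 1)."""
    if not (np.all(np.isfinite(bank.w_global)) and np.all(np.isfinite(bank.w_local))):
        raise ValueError("filter weights must be finite")
    g_global = expit(bank.w_global)
    g_local = expit(bank.w_local)
    return g_global, g_local, g_global * g_local


def adaptive_mask(spec: SpectrumTensor, theta: float, epsilon: float = 1e-12,
                  temperature: float | None = None) -> np.ndarray:
    """Energy-thresholded frequency mask.

    Power is normalized by the median over bins (plus `epsilon`); a bin
    survives when its normalized energy exceeds `theta`.  With a
    `temperature`, the comparison is relaxed to a sigmoid (the trainable
    form); otherwise the mask is hard {0, 1}.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    P = spec.P
    if P.shape[-1] == 0:
        raise ValueError("empty spectrum")
    med = np.median(P, axis=-1, keepdims=True)
    norm = P / (med + epsilon)
    if temperature is None:
        return (norm > theta).astype(np.float64)
    return expit((norm - theta) / temperature)


def apply_filter(spec: SpectrumTensor, mask: np.ndarray,
                 gains: np.ndarray) -> np.ndarray:
    """Filtered spectrum F_hat = F * mask * G, elementwise per bin."""
    mask = np.asarray(mask, dtype=np.float64)
    gains = np.asarray(gains, dtype=np.float64)
    if np.broadcast_shapes(spec.F.shape, mask.shape, gains.shape) != spec.F.shape:
        raise ValueError(
            f"shape mismatch: F {spec.F.shape}, mask {mask.shape}, G {gains.shape}")
    return spec.F * mask * gains


def inverse_and_fuse(F_hat: np.ndarray, x: np.ndarray,
                     alpha: float, axis: int = -1) -> np.ndarray:
    """Inverse FFT of the filtered spectrum blended with the original signal."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.fft.irfft(np.moveaxis(F_hat, -1, axis), n=x.shape[axis], axis=axis)
    return alpha * x + (1.0 - alpha) * x_hat


def affm_forward(H: np.ndarray, bank: FilterBank, mode: str = "eval",
                 temperature: float = 0.1, axis: int = -2) -> np.ndarray:
    """Full filtering pipeline on a plain array.

    Applied along `axis` (the token-sequence axis of an (n_tokens, d_model)
    array) independently per trailing feature dimension.  `mode` selects the
    hard mask ("eval") or its sigmoid relaxation ("soft").
    """
    H = np.asarray(H, dtype=np.float64)
    n = H.shape[axis]
    if n == 1:
        logger.warning("affm_forward: sequence length 1, spectrum degenerate; "
                       "passing input through unchanged")
        return H.copy()
    work = np.moveaxis(H, axis, -1)
    spec = forward_fft(work, axis=-1)
    temp = None if mode == "eval" else temperature
    mask = adaptive_mask(spec, bank.theta, bank.epsilon, temperature=temp)
    _, _, gains = filter_gains(bank)
    if gains.shape[-1] != spec.F.shape[-1]:
        raise ValueError("filter bank sized for a different sequence length")
    F_hat = apply_filter(spec, mask, gains)
    out = inverse_and_fuse(F_hat, work, bank.alpha, axis=-1)
    return np.moveaxis(out, -1, axis)


# -- trainable layer ---------------------------------------------------------

def _dft_matrices(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Real/imag forward DFT matrices and their one-sided inverses."""
    n_bins = n // 2 + 1
    k = np.arange(n_bins)[:, None]
    m = np.arange(n)[None, :]
    ang = 2.0 * np.pi * k * m / n
    cr = np.cos(ang)
    ci = -np.sin(ang)
    w = np.full(n_bins, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    dr = (w[None, :] * np.cos(ang.T)) / n          # (n, n_bins)
    di = (-w[None, :] * np.sin(ang.T)) / n
    return cr, ci, dr, di


def _interp_matrix(n_bins: int, n_ref: int) -> np.ndarray:
    """Linear interpolation from n_ref reference bins to n_bins bins."""
    if n_bins == n_ref:
        return np.eye(n_ref)
    pos = np.linspace(0.0, n_ref - 1.0, n_bins)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_ref - 1)
    frac = pos - lo
    M = np.zeros((n_bins, n_ref))
    M[np.arange(n_bins), lo] += 1.0 - frac
    M[np.arange(n_bins), hi] += frac
    return M


class AFFMLayer(Module):
    """Trainable adaptive frequency filter acting on a token sequence.

    Operates along the second-to-last axis (tokens) independently per
    embedding dimension.  Parameters:

    * per-bin global gain logits, shared across embedding dims;
    * per-bin local gain logits, active only above `local_cutoff_fraction`
      of the spectrum (ones below it);
    * scalar threshold `theta` on median-normalized bin energy;
    * scalar fusion gate `alpha`, kept in (0, 1) by a sigmoid
      reparameterization, initialized at `alpha_init`.

    `forward` also returns a per-token gate: the time-domain energy profile
    of the filtered signal, normalized to mean one, which downstream
    attention uses to rescale value vectors.
    """

    def __init__(self, n_ref_bins: int, local_cutoff_fraction: float = 0.5,
                 mask_temperature: float = 0.1, lambda_theta: float = 1e-4,
                 epsilon: float = 1e-12, alpha_init: float = 0.5,
                 hard_mask_eval: bool = True, theta_init: float = 0.5):
        if n_ref_bins < 1:
            raise ValueError("need at least one reference bin")
        if not 0.0 < alpha_init < 1.0:
            raise ValueError("alpha_init must lie strictly inside (0, 1)")
        self.n_ref_bins = n_ref_bins
        self.local_cutoff_fraction = local_cutoff_fraction
        self.mask_temperature = mask_temperature
        self.lambda_theta = lambda_theta
        self.epsilon = epsilon
        self.hard_mask_eval = hard_mask_eval
        self.w_global = Parameter(np.zeros(n_ref_bins))
        self.w_local = Parameter(np.zeros(n_ref_bins))
        self.theta = Parameter(np.array(theta_init))
        self.alpha_raw = Parameter(np.array(np.log(alpha_init / (1.0 - alpha_init))))
        self._cache: dict[int, tuple] = {}

    # effective (interpolated, scoped) gain vector for a sequence length
    def gains_for(self, n: int) -> tuple[Tensor, Tensor, Tensor]:
        n_bins = n // 2 + 1
        interp = Tensor(_interp_matrix(n_bins, self.n_ref_bins))
        g_global = sigmoid(interp @ self.w_global)
        scope = (np.arange(n_bins) >= self.local_cutoff_fraction * (n_bins - 1)
                 ).astype(np.float64)
        g_local = sigmoid(interp @ self.w_local) * scope + (1.0 - scope)
        return g_global, g_local, g_global * g_local

    def alpha(self) -> Tensor:
        return sigmoid(self.alpha_raw)

    def theta_penalty(self) -> Tensor:
        return self.theta * self.theta * self.lambda_theta

    def _mats(self, n: int):
        if n not in self._cache:
            self._cache[n] = tuple(Tensor(m) for m in _dft_matrices(n))
        return self._cache[n]

    def forward(self, H: Tensor, training: bool = True) -> tuple[Tensor, Tensor]:
        """Return (fused sequence, per-token gate), shapes preserved."""
        n = H.shape[-2]
        if n == 1:
            logger.warning("AFFMLayer: sequence length 1, spectrum degenerate; "
                           "pass-through")
            ones = Tensor(np.ones(H.shape[:-1]))
            return H, ones
        cr, ci, dr, di = self._mats(n)
        fr = cr @ H                       # (..., n_bins, d)
        fi = ci @ H
        power = fr * fr + fi * fi
        med = np.median(power.data, axis=-2, keepdims=True)  # detached
        norm = power * (1.0 / (med + self.epsilon))
        if training or not self.hard_mask_eval:
            mask = sigmoid((norm - self.theta) * (1.0 / self.mask_temperature))
        else:
            mask = Tensor((norm.data > self.theta.data).astype(np.float64))
        _, _, g = self.gains_for(n)
        g_col = g.reshape(-1, 1)
        fhr = fr * mask * g_col
        fhi = fi * mask * g_col
        x_hat = dr @ fhr + di @ fhi
        alpha = self.alpha()
        fused = alpha * H + (1.0 - alpha) * x_hat
        energy = (x_hat * x_hat).mean(axis=-1)          # (..., n)
        gate = energy / (energy.mean(axis=-1, keepdims=True) + 1e-12)
        return fused, gate

    __call__ = forward
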