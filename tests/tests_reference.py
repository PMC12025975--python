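"""Independent numpy reference implementations used as oracles in tests."""

import numpy as np
from scipy.special import erf


def _ln(v, g, b, eps=1e-5):
    mu = v.mean(-1, keepdims=True)
    var = ((v - mu) ** 2).mean(-1, keepdims=True)
    return (v - mu) / np.sqrt(var + eps) * g + b


def _gelu(v):
    return 0.5 * v * (1 + erf(v / np.sqrt(2)))


def _mha(v, blk):
    h, dk = blk.attn.n_heads, blk.attn.d_k
    q = v @ blk.attn.w_q.weight.data + blk.attn.w_q.bias.data
    k = v @ blk.attn.w_k.weight.data + blk.attn.w_k.bias.data
    vv = v @ blk.attn.w_v.weight.data + blk.attn.w_v.bias.data
    outs = []
    for i in range(h):
        sl = slice(i * dk, (i + 1) * dk)
        s = q[:, sl] @ k[:, sl].T / np.sqrt(dk)
        a = np.exp(s - s.max(-1, keepdims=True))
        a /= a.sum(-1, keepdims=True)
        outs.append(a @ vv[:, sl])
    return np.concatenate(outs, -1) @ blk.attn.w_o.weight.data \
        + blk.attn.w_o.bias.data


def plain_pre_norm_transformer(x: np.ndarray, enc) -> np.ndarray:
    """Forward pass of a standard pre-norm Transformer using the weights of
    `enc` (an Encoder), written independently of the autodiff engine."""
    ref = x.copy()
    for blk in enc.blocks:
        ref = ref + _mha(_ln(ref, blk.ln1.gamma.data, blk.ln1.beta.data), blk)
        h = _ln(ref, blk.ln2.gamma.data, blk.ln2.beta.data)
        h = _gelu(h @ blk.mlp.fc1.weight.data + blk.mlp.fc1.bias.data)
        ref = ref + h @ blk.mlp.fc2.weight.data + blk.mlp.fc2.bias.data
    if enc.final_ln is not None:
        ref = _ln(ref, enc.final_ln.gamma.data, enc.final_ln.beta.data)
    return ref
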