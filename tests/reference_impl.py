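"""Brute-force, loop-based reference implementation of the network forward
pass. Written independently of the package's vectorized/autodiff path: plain
Python loops over positions, heads and channels, mirroring the written
definitions of each stage. Used only as a test oracle.
"""

from __future__ import annotations

import math

import numpy as np


def ref_conv1d(x: np.ndarray, w: np.ndarray, b: np.ndarray,
               stride: int = 1) -> np.ndarray:
    """x [C, L], w [D, C, k], b [D] -> [D, L_out]; same-style padding."""
    C, L = x.shape
    D, _, k = w.shape
    half = k // 2
    xp = np.zeros((C, L + 2 * half))
    xp[:, half:half + L] = x
    L_out = (L + 2 * half - k) // stride + 1
    out = np.zeros((D, L_out))
    for d in range(D):
        for t in range(L_out):
            acc = 0.0
            for c in range(C):
                for i in range(k):
                    acc += w[d, c, i] * xp[c, t * stride + i]
            out[d, t] = acc + b[d]
    return out


def ref_positional_encoding(L: int, D: int) -> np.ndarray:
    pe = np.zeros((L, D))
    for pos in range(L):
        for kk in range(D // 2):
            angle = pos / (10000.0 ** (2.0 * kk / D))
            pe[pos, 2 * kk] = math.sin(angle)
            pe[pos, 2 * kk + 1] = math.cos(angle)
    return pe


def ref_softmax_row(v: np.ndarray) -> np.ndarray:
    e = np.exp(v - v.max())
    return e / e.sum()


def ref_multi_head_attention(O: np.ndarray, W_Q: np.ndarray, W_K: np.ndarray,
                             W_V: np.ndarray, n_heads: int) -> np.ndarray:
    """O [L, D]; per-head slices of the packed projection matrices."""
    L, D = O.shape
    dq = W_Q.shape[1] // n_heads
    dv = W_V.shape[1] // n_heads
    heads = []
    for h in range(n_heads):
        Q = O @ W_Q[:, h * dq:(h + 1) * dq]
        K = O @ W_K[:, h * dq:(h + 1) * dq]
        V = O @ W_V[:, h * dv:(h + 1) * dv]
        out_h = np.zeros((L, dv))
        for i in range(L):
            scores = np.array([Q[i] @ K[j] / math.sqrt(dq) for j in range(L)])
            attn = ref_softmax_row(scores)
            out_h[i] = sum(attn[j] * V[j] for j in range(L))
        heads.append(out_h)
    return np.concatenate(heads, axis=1)


def ref_layernorm(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                  eps: float = 1e-5) -> np.ndarray:
    """Normalize each row of x over its last axis."""
    out = np.zeros_like(x)
    flat = x.reshape(-1, x.shape[-1])
    oflat = out.reshape(-1, x.shape[-1])
    for r in range(flat.shape[0]):
        mu = flat[r].mean()
        var = ((flat[r] - mu) ** 2).mean()
        oflat[r] = (flat[r] - mu) / math.sqrt(var + eps) * gamma + beta
    return out


def ref_ffn(x: np.ndarray, w1, b1, w2, b2) -> np.ndarray:
    h = np.maximum(x @ w1 + b1, 0.0)
    return h @ w2 + b2


def ref_transformer_block(O, p, standard: bool = False) -> np.ndarray:
    """p: dict of the block's parameter arrays."""
    a = ref_multi_head_attention(O, p["W_Q"], p["W_K"], p["W_V"], p["n_heads"])
    if standard:
        h = ref_layernorm(O + a, p["gamma_attn"], p["beta_attn"])
        return ref_layernorm(
            h + ref_ffn(h, p["w1"], p["b1"], p["w2"], p["b2"]),
            p["gamma"], p["beta"])
    return ref_layernorm(
        a + ref_ffn(a, p["w1"], p["b1"], p["w2"], p["b2"]),
        p["gamma"], p["beta"])


def ref_conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x [C, H, W], w [D, C, k, k] -> [D, H, W] same padding."""
    C, H, W = x.shape
    D, _, k, _ = w.shape
    pad = k // 2
    xp = np.zeros((C, H + 2 * pad, W + 2 * pad))
    xp[:, pad:pad + H, pad:pad + W] = x
    out = np.zeros((D, H, W))
    for d in range(D):
        for r in range(H):
            for cc in range(W):
                acc = 0.0
                for c in range(C):
                    for i in range(k):
                        for j in range(k):
                            acc += w[d, c, i, j] * xp[c, r + i, cc + j]
                out[d, r, cc] = acc + b[d]
    return out


def ref_depthwise_conv2d(x: np.ndarray, w: np.ndarray,
                         b: np.ndarray) -> np.ndarray:
    """x [C, H, W], w [C, k, k] -> [C, H, W] same padding."""
    C, H, W = x.shape
    k = w.shape[-1]
    pad = k // 2
    xp = np.zeros((C, H + 2 * pad, W + 2 * pad))
    xp[:, pad:pad + H, pad:pad + W] = x
    out = np.zeros((C, H, W))
    for c in range(C):
        for r in range(H):
            for cc in range(W):
                acc = 0.0
                for i in range(k):
                    for j in range(k):
                        acc += w[c, i, j] * xp[c, r + i, cc + j]
                out[c, r, cc] = acc + b[c]
    return out


def ref_gelu(x: np.ndarray) -> np.ndarray:
    from scipy.special import erf
    return x * 0.5 * (1.0 + erf(x / math.sqrt(2.0)))


def ref_maxpool2d(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    C, H, W = x.shape
    Ho, Wo = H // kh, W // kw
    out = np.zeros((C, Ho, Wo))
    for c in range(C):
        for r in range(Ho):
            for cc in range(Wo):
                out[c, r, cc] = x[c, r * kh:(r + 1) * kh,
                                  cc * kw:(cc + 1) * kw].max()
    return out


def ref_batchnorm_stats(xs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/var over a list of [C, H, W] maps (the joint batch)."""
    stacked = np.stack(xs)  # [N, C, H, W]
    mu = stacked.mean(axis=(0, 2, 3))
    var = stacked.var(axis=(0, 2, 3))
    return mu, var


def ref_trunk_batch(zs: list[np.ndarray], params: dict,
                    pool: tuple[int, int]) -> list[np.ndarray]:
    """Fusion trunk on a joint batch of [L, D] sequences (training-mode BN)."""
    maps = [ref_conv2d(z[None, :, :], params["conv1_w"], params["conv1_b"])
            for z in zs]
    mu, var = ref_batchnorm_stats(maps)
    outs = []
    for m in maps:
        h = (m - mu[:, None, None]) / np.sqrt(var[:, None, None] + 1e-5)
        h = h * params["bn_gamma"][:, None, None] + params["bn_beta"][:, None, None]
        h = np.maximum(h, 0.0)
        h = ref_maxpool2d(h, *pool)
        for blk in params["blocks"]:
            h = ref_depthwise_conv2d(h, blk["w"], blk["b"])
            # layer norm over channels at each spatial position
            hn = np.zeros_like(h)
            for r in range(h.shape[1]):
                for cc in range(h.shape[2]):
                    v = h[:, r, cc]
                    mu_v = v.mean()
                    var_v = ((v - mu_v) ** 2).mean()
                    hn[:, r, cc] = ((v - mu_v) / math.sqrt(var_v + 1e-5)
                                    * blk["gamma"] + blk["beta"])
            h = ref_gelu(hn)
        outs.append(h.reshape(-1))
    return outs


def extract_block_params(block) -> dict:
    """Pull one TransformerBlock's arrays into the reference layout."""
    p = {
        "W_Q": block.attn.W_Q.data, "W_K": block.attn.W_K.data,
        "W_V": block.attn.W_V.data, "n_heads": block.attn.n_heads,
        "w1": block.ffn.fc1.weight.data, "b1": block.ffn.fc1.bias.data,
        "w2": block.ffn.fc2.weight.data, "b2": block.ffn.fc2.bias.data,
        "gamma": block.norm.gamma.data, "beta": block.norm.beta.data,
    }
    if block.standard:
        p["gamma_attn"] = block.norm_attn.gamma.data
        p["beta_attn"] = block.norm_attn.beta.data
    return p


def extract_trunk_params(trunk) -> dict:
    return {
        "conv1_w": trunk.conv1.weight.data, "conv1_b": trunk.conv1.bias.data,
        "bn_gamma": trunk.bn.gamma.data, "bn_beta": trunk.bn.beta.data,
        "blocks": [{"w": c.weight.data, "b": c.bias.data,
                    "gamma": n.gamma.data, "beta": n.beta.data}
                   for c, n in zip(trunk.blocks, trunk.norms)],
    }


def ref_full_forward(model, eeg: np.ndarray, emg: np.ndarray) -> np.ndarray:
    """Workload logits for a batch, via the loop reference (training-mode BN
    over the joint two-modality batch, matching the network's joint trunk
    pass)."""
    B = eeg.shape[0]
    cfg = model.cfg
    pe = ref_positional_encoding(model.seq_len, cfg.D)
    seqs = []
    for mod, batch, proj, blocks in (
            ("eeg", eeg, model.eeg_proj, getattr(model, "eeg_blocks", None)),
            ("emg", emg, model.emg_proj, getattr(model, "emg_blocks", None))):
        kernel = cfg.k_eeg if mod == "eeg" else cfg.k_emg
        for n in range(B):
            h = ref_conv1d(batch[n], proj.weight.data, proj.bias.data,
                           cfg.proj_stride).T           # [L, D]
            if model.uses_transformer:
                h = h + pe
                for blk in blocks:
                    h = ref_transformer_block(h, extract_block_params(blk),
                                              blk.standard)
            seqs.append(h)
    pool = (2, 2) if cfg.pool_mode == "2d" else (2, 1)
    fused = ref_trunk_batch(seqs, extract_trunk_params(model.trunk), pool)
    logits = np.zeros((B, cfg.n_classes))
    head = model.workload_head
    for n in range(B):
        f = np.concatenate([fused[n], fused[B + n]])
        h1 = np.maximum(f @ head.fc1.weight.data + head.fc1.bias.data, 0.0)
        logits[n] = h1 @ head.fc2.weight.data + head.fc2.bias.data
    return logits
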