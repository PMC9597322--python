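"""Network building blocks: linear, attention, transformer encoder.

The encoder is a small 3D vision transformer: the VOI is cut into
non-overlapping cubic patches, each patch flattened and linearly
projected to the embedding dimension, learned positional embeddings
added, then a stack of pre-norm attention/MLP blocks.  Layer norms use
learnable affine parameters.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "SelfAttention", "MLP",
           "TransformerBlock", "PatchEncoder3D", "patchify"]


class Module:
    """Minimal parameter container with recursive discovery."""

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict does not match parameter count")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.copy()


def _param(rng, *shape, scale=0.02, dtype=np.float32) -> Tensor:
    return Tensor(rng.normal(0.0, scale, size=shape).astype(dtype),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        # fan-in scaled init keeps activations O(1) at depth
        self.w = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d_in),
                                   size=(d_in, d_out)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=np.float32):
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm() * self.gamma + self.beta


class SelfAttention(Module):
    """Multi-head scaled dot-product self-attention."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 dtype=np.float32):
        if dim % heads:
            raise ValueError("embedding dim must divide by head count")
        self.heads = heads
        self.dk = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng, dtype)
        self.proj = Linear(dim, dim, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        h, dk = self.heads, self.dk
        from .autodiff import gather_rows
        qkv = self.qkv(x)  # (B, T, 3D)
        qkv = qkv.reshape(B, T, 3, h, dk).transpose(2, 0, 3, 1, 4)  # (3,B,h,T,dk)
        qkv = qkv.reshape(3, B * h * T * dk)
        q = gather_rows(qkv, np.array([0])).reshape(B, h, T, dk)
        k = gather_rows(qkv, np.array([1])).reshape(B, h, T, dk)
        v = gather_rows(qkv, np.array([2])).reshape(B, h, T, dk)
        att = (q @ k.transpose(0, 1, 3, 2)) * float(1.0 / np.sqrt(dk))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.proj(out)


class MLP(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.fc1 = Linear(dim, hidden, rng, dtype)
        self.fc2 = Linear(hidden, dim, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class TransformerBlock(Module):
    """Pre-norm residual block: x + Att(LN(x)); x + MLP(LN(x))."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float,
                 rng: np.random.Generator, dtype=np.float32):
        self.ln1 = LayerNorm(dim, dtype)
        self.att = SelfAttention(dim, heads, rng, dtype)
        self.ln2 = LayerNorm(dim, dtype)
        self.mlp = MLP(dim, int(dim * mlp_ratio), rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.att(self.ln1(x))
        return x + self.mlp(self.ln2(x))


def patchify(vol: np.ndarray, patch: int) -> np.ndarray:
    """Cut a (B, S, S, S) volume batch into flattened cubic patches.

    Returns (B, n_patches, patch**3) with patches ordered z-major.
    """
    if vol.ndim == 3:
        vol = vol[None]
    B, Z, Y, X = vol.shape
    if Z % patch or Y % patch or X % patch:
        raise ValueError("volume size must be a multiple of the patch size")
    nz, ny, nx = Z // patch, Y // patch, X // patch
    v = vol.reshape(B, nz, patch, ny, patch, nx, patch)
    v = v.transpose(0, 1, 3, 5, 2, 4, 6)
    return v.reshape(B, nz * ny * nx, patch ** 3)


def central_patch_index(voi_size: int, patch: int, extent: float = 0.5) -> np.ndarray:
    """Indices of patches whose centres fall in the central cube.

    ``extent`` is the fractional side length of the central cube; the
    default 0.5 keeps the middle half of the field of view, which is
    where the nodule sits in a centred VOI.
    """
    n = voi_size // patch
    centers = (np.arange(n) + 0.5) * patch
    lo = voi_size * (0.5 - extent / 2.0)
    hi = voi_size * (0.5 + extent / 2.0)
    keep = (centers >= lo) & (centers <= hi)
    idx = np.nonzero(keep)[0]
    if idx.size == 0:  # degenerate: fall back to the middle patch
        idx = np.array([n // 2])
    grid = np.stack(np.meshgrid(idx, idx, idx, indexing="ij"), -1).reshape(-1, 3)
    return grid[:, 0] * n * n + grid[:, 1] * n + grid[:, 2]


class PatchEncoder3D(Module):
    """ViT-style encoder over flattened 3D patches (no class token).

    The global embedding is the mean over all patch tokens of the
    final layer; the local embedding is the mean over the tokens whose
    patch centres lie in the central cube.  Keeping both summaries as
    token means makes the two Siamese branches exactly exchangeable.
    """

    def __init__(self, voi_size: int, patch: int, dim: int, depth: int,
                 heads: int, rng: np.random.Generator, mlp_ratio: float = 2.0,
                 dtype=np.float32):
        self.voi_size = voi_size
        self.patch = patch
        n_tok = (voi_size // patch) ** 3
        self.embed = Linear(patch ** 3, dim, rng, dtype)
        self.pos = _param(rng, n_tok, dim, dtype=dtype)
        self.blocks = [TransformerBlock(dim, heads, mlp_ratio, rng, dtype)
                       for _ in range(depth)]
        self.ln_f = LayerNorm(dim, dtype)
        self.local_idx = central_patch_index(voi_size, patch)

    def __call__(self, patches: Tensor) -> Tensor:
        """Encode pre-patchified input (B, n_tok, patch^3) -> tokens."""
        x = self.embed(patches) + self.pos
        for blk in self.blocks:
            x = blk(x)
        return self.ln_f(x)

    def global_embedding(self, tokens: Tensor) -> Tensor:
        return tokens.mean(axis=1)

    def local_embedding(self, tokens: Tensor) -> Tensor:
        B, T, D = tokens.shape
        from .autodiff import gather_rows
        flat = tokens.transpose(1, 0, 2)  # (T, B, D)
        sel = gather_rows(flat, self.local_idx)  # (k, B, D)
        return sel.mean(axis=0)
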