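"""Detection-transformer decoder with deformable cross-attention and
uncertainty-minimal query selection.

The encoder's three fused pyramid levels are flattened into a memory
sequence.  A linear+norm projection scores every token; the top
``num_queries`` tokens seed the object queries, with initial boxes
predicted relative to level-dependent grid anchors.  Each decoder layer
runs softmax self-attention among queries, multi-scale deformable
cross-attention into the memory (bilinear sampling at learned offsets
around each query's reference box), and an FFN; boxes are refined
iteratively in inverse-sigmoid space.  Every layer carries its own
classification and box heads so auxiliary losses can supervise each
refinement step.  Detection is end-to-end: no non-maximum suppression.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .backbone import FeatureMap
from .encoder import MultiheadAttention
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = ["MLP", "MSDeformableAttention", "DecoderLayer", "RTDETRDecoder"]


def inverse_sigmoid(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    x = np.clip(x, eps, 1 - eps)
    return np.log(x / (1 - x))


class MLP(nn.Module):
    def __init__(self, cin: int, hidden: int, cout: int, num_layers: int):
        super().__init__()
        dims = [cin] + [hidden] * (num_layers - 1) + [cout]
        self.layers = nn.ModuleList(
            nn.Linear(a, b) for a, b in zip(dims[:-1], dims[1:])
        )

    def forward(self, x: Tensor) -> Tensor:
        n = len(self.layers)
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < n - 1:
                x = x.relu()
        return x


class MSDeformableAttention(nn.Module):
    def __init__(self, embed_dim: int = 256, num_heads: int = 8,
                 num_levels: int = 3, num_points: int = 4):
        super().__init__()
        if embed_dim % num_heads:
            raise ValueError("embed_dim must divide by num_heads")
        self.embed_dim = embed_dim
        self.num_heads = num_heads
        self.num_levels = num_levels
        self.num_points = num_points
        self.head_dim = embed_dim // num_heads
        n = num_heads * num_levels * num_points
        self.sampling_offsets = nn.Linear(embed_dim, n * 2)
        self.attention_weights = nn.Linear(embed_dim, n)
        self.value_proj = nn.Linear(embed_dim, embed_dim)
        self.output_proj = nn.Linear(embed_dim, embed_dim)
        self._init_offsets()

    def _init_offsets(self):
        # spread initial sampling points on a ring per head, growing with
        # point index — the conventional deformable-attention init
        h, L, P = self.num_heads, self.num_levels, self.num_points
        theta = np.arange(h, dtype=np.float32) * (2 * np.pi / h)
        grid = np.stack([np.cos(theta), np.sin(theta)], axis=-1)  # (h,2)
        grid /= np.abs(grid).max(axis=-1, keepdims=True)
        bias = np.tile(grid[:, None, None, :], (1, L, P, 1))
        bias *= (np.arange(P, dtype=np.float32) + 1).reshape(1, 1, P, 1)
        self.sampling_offsets.weight.data[:] = 0.0
        self.sampling_offsets.bias.data[:] = bias.reshape(-1)

    def forward(
        self,
        query: Tensor,
        ref_boxes: np.ndarray,
        memory: Tensor,
        level_shapes: list[tuple[int, int]],
    ) -> Tensor:
        """``query``: (B, Nq, C); ``ref_boxes``: (B, Nq, 4) normalized
        cxcywh (no gradient); ``memory``: (B, N, C) flattened levels."""
        B, Nq, C = query.shape
        h, L, P, dh = self.num_heads, self.num_levels, self.num_points, self.head_dim
        value = self.value_proj(memory)  # (B,N,C)
        offsets = self.sampling_offsets(query).reshape(B, Nq, h, L, P, 2)
        weights = self.attention_weights(query).reshape(B, Nq, h, L * P)
        weights = F.softmax(weights, axis=-1).reshape(B, Nq, h, L, P)

        centers = ref_boxes[:, :, None, None, None, :2]  # (B,Nq,1,1,1,2)
        wh = ref_boxes[:, :, None, None, None, 2:]
        scale = Tensor((wh / (2.0 * P)).astype(np.float32))
        locs = offsets * scale + Tensor(centers.astype(np.float32))  # normalized

        # split the flattened value back into levels / heads
        sizes = [hw[0] * hw[1] for hw in level_shapes]
        offsets_n = np.cumsum([0] + sizes)
        out_heads = []
        for l, (H, W) in enumerate(level_shapes):
            v_l = value[:, offsets_n[l] : offsets_n[l + 1]]  # (B, HW, C)
            v_l = (
                v_l.reshape(B, H, W, h, dh)
                .transpose(0, 3, 4, 1, 2)
                .reshape(B * h, dh, H, W)
            )
            loc_l = locs[:, :, :, l].transpose(0, 2, 1, 3, 4)  # (B,h,Nq,P,2)
            loc_l = loc_l.reshape(B * h, Nq * P, 2)
            pix = loc_l * Tensor(np.array([W, H], dtype=np.float32)) - 0.5
            sampled = F.bilinear_sample(v_l, pix)  # (B*h, dh, Nq*P)
            sampled = sampled.reshape(B, h, dh, Nq, P)
            w_l = weights[:, :, :, l].transpose(0, 2, 1, 3)  # (B,h,Nq,P)
            out_heads.append((sampled * w_l.reshape(B, h, 1, Nq, P)).sum(axis=-1))
        out = out_heads[0]
        for o in out_heads[1:]:
            out = out + o  # (B,h,dh,Nq)
        out = out.transpose(0, 3, 1, 2).reshape(B, Nq, C)
        return self.output_proj(out)


class DecoderLayer(nn.Module):
    def __init__(self, embed_dim: int = 256, num_heads: int = 8,
                 ffn_dim: int = 1024, num_levels: int = 3, num_points: int = 4,
                 dropout: float = 0.0):
        super().__init__()
        self.self_attn = MultiheadAttention(embed_dim, num_heads)
        self.norm1 = nn.LayerNorm(embed_dim)
        self.cross_attn = MSDeformableAttention(embed_dim, num_heads, num_levels,
                                                num_points)
        self.norm2 = nn.LayerNorm(embed_dim)
        self.linear1 = nn.Linear(embed_dim, ffn_dim)
        self.linear2 = nn.Linear(ffn_dim, embed_dim)
        self.norm3 = nn.LayerNorm(embed_dim)
        self.drop = nn.Dropout(dropout)

    def forward(self, tgt: Tensor, query_pos: Tensor, ref_boxes: np.ndarray,
                memory: Tensor, level_shapes) -> Tensor:
        q = tgt + query_pos
        tgt = self.norm1(tgt + self.drop(self.self_attn(q, q, tgt)))
        c = self.cross_attn(tgt + query_pos, ref_boxes, memory, level_shapes)
        tgt = self.norm2(tgt + self.drop(c))
        f = self.linear2(self.drop(self.linear1(tgt).relu()))
        return self.norm3(tgt + self.drop(f))


class RTDETRDecoder(nn.Module):
    """Query selection + iterative box refinement decoder.

    Classification heads emit ``num_classes + 1`` logits (the last is the
    background class used by the set-prediction loss).
    """

    def __init__(
        self,
        num_classes: int = 5,
        embed_dim: int = 256,
        num_queries: int = 300,
        num_layers: int = 3,
        num_heads: int = 8,
        ffn_dim: int = 1024,
        num_points: int = 4,
        anchor_base_size: float = 0.05,
    ):
        super().__init__()
        self.num_classes = num_classes
        self.embed_dim = embed_dim
        self.num_queries = num_queries
        self.num_layers = num_layers
        self.anchor_base_size = anchor_base_size
        self.enc_output = nn.Linear(embed_dim, embed_dim)
        self.enc_norm = nn.LayerNorm(embed_dim)
        self.enc_score_head = nn.Linear(embed_dim, num_classes + 1)
        self.enc_bbox_head = MLP(embed_dim, embed_dim, 4, 3)
        self.query_pos_head = MLP(4, 2 * embed_dim, embed_dim, 2)
        self.layers = nn.ModuleList(
            DecoderLayer(embed_dim, num_heads, ffn_dim, num_levels=3,
                         num_points=num_points)
            for _ in range(num_layers)
        )
        self.score_heads = nn.ModuleList(
            nn.Linear(embed_dim, num_classes + 1) for _ in range(num_layers)
        )
        self.bbox_heads = nn.ModuleList(
            MLP(embed_dim, embed_dim, 4, 3) for _ in range(num_layers)
        )

    def _anchors(self, level_shapes) -> np.ndarray:
        """Grid anchors in inverse-sigmoid space, (N, 4)."""
        anchors = []
        for lvl, (H, W) in enumerate(level_shapes):
            gy, gx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
            cx = (gx.reshape(-1) + 0.5) / W
            cy = (gy.reshape(-1) + 0.5) / H
            wh = np.full_like(cx, self.anchor_base_size * (2.0**lvl))
            anchors.append(np.stack([cx, cy, wh, wh], axis=-1))
        a = np.concatenate(anchors, axis=0).astype(np.float32)
        return inverse_sigmoid(a)

    def forward(self, levels: list[FeatureMap]) -> dict:
        B = levels[0].data.shape[0]
        C = self.embed_dim
        level_shapes = [(f.data.shape[2], f.data.shape[3]) for f in levels]
        memory = concat(
            [f.data.reshape(B, C, -1).transpose(0, 2, 1) for f in levels], axis=1
        )
        mem_proj = self.enc_norm(self.enc_output(memory))
        enc_logits = self.enc_score_head(mem_proj)  # (B,N,K+1)
        anchors = self._anchors(level_shapes)  # (N,4)
        enc_deltas = self.enc_bbox_head(mem_proj)
        enc_boxes_unact = enc_deltas + Tensor(anchors[None])
        enc_boxes = enc_boxes_unact.sigmoid()

        # uncertainty-minimal selection: rank tokens by best foreground logit
        fg = enc_logits.data[:, :, : self.num_classes].max(axis=-1)
        k = min(self.num_queries, fg.shape[1])
        topk = np.argsort(-fg, axis=1)[:, :k]  # (B,k)

        bi = np.arange(B)[:, None]
        tgt = mem_proj[bi, topk].detach()
        ref_unact = enc_boxes_unact[bi, topk]  # grads flow to encoder heads
        ref = 1.0 / (1.0 + np.exp(-ref_unact.data))

        sel_logits = enc_logits[bi, topk]
        sel_boxes = enc_boxes[bi, topk]

        out_logits, out_boxes = [], []
        for layer, score_head, bbox_head in zip(
            self.layers, self.score_heads, self.bbox_heads
        ):
            query_pos = self.query_pos_head(Tensor(ref.astype(np.float32)))
            tgt = layer(tgt, query_pos, ref, memory, level_shapes)
            deltas = bbox_head(tgt)
            boxes_unact = deltas + Tensor(inverse_sigmoid(ref))
            boxes = boxes_unact.sigmoid()
            out_logits.append(score_head(tgt))
            out_boxes.append(boxes)
            ref = boxes.data  # detached refinement for the next layer

        return {
            "logits": out_logits,  # per decoder layer, (B,k,K+1)
            "boxes": out_boxes,  # per decoder layer, (B,k,4) normalized cxcywh
            "enc_logits": sel_logits,
            "enc_boxes": sel_boxes,
            "level_shapes": level_shapes,
        }
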