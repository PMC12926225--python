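"""Dimension-independent graph networks, in NumPy with explicit backprop.

Two architectures post-process difference images defined on mesh graphs:

* ``GraphUNet`` — an encoder/decoder over a 3-level cluster hierarchy.
  Each level applies three graph convolutions with the fixed normalized
  aggregation N = D^{-1/2}(A+I)D^{-1/2}; pooling takes per-channel maxima
  over geometric node clusters (~1/8 of nodes kept), unpooling clones each
  cluster's feature back to its members, and skip connections concatenate
  encoder features before decoding.  Channels double per level
  (32, 64, 128, 256), giving ~327k trainable parameters.

* ``GResNet`` — a residual baseline: 10 blocks of 3 graph convolutions
  with identity skips, wrapped in a global residual so the all-zero
  network is the identity map.

All trainable tensors are weight matrices and biases whose shapes depend
only on channel counts, never on a graph's node count: a network trained
on 2D mesh graphs runs unchanged on 3D mesh graphs.

Signals are batches ``H`` of shape (B, N, C).  Inputs are scaled by their
maximum absolute value before the network and the output rescaled by the
same factor, so the learned mapping transfers across amplitude ranges
(e.g. from 2D training images to 3D inference).
"""

from __future__ import annotations

import numpy as np

from .graphs import ClusterHierarchy, GraphStructure


def _sp_apply(norm, H):
    """Apply sparse normalizer along the node axis of (B, N, C)."""
    B, N, C = H.shape
    Ht = np.ascontiguousarray(H.transpose(1, 0, 2)).reshape(N, B * C)
    Y = norm @ Ht
    return Y.reshape(N, B, C).transpose(1, 0, 2)


def _pool_max(assign, H, n_coarse):
    Ht = H.transpose(1, 0, 2)  # (N, B, C)
    out = np.full((n_coarse,) + Ht.shape[1:], -np.inf)
    np.maximum.at(out, assign, Ht)
    return out.transpose(1, 0, 2)


def _unpool_clone(assign, Hc):
    return Hc[:, assign, :]


def gcn_propagate(graph, H, W, bias=None, activation=True):
    """One graph convolution: activation(N H W + b) with the fixed
    normalized aggregation N = D^{-1/2}(A+I)D^{-1/2}.

    ``H`` may be (N, C) or batched (B, N, C).
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    single = H.ndim == 2
    Hb = H[None] if single else H
    if Hb.shape[2] != W.shape[0]:
        raise ValueError("channel dimensions are inconsistent")
    Y = _sp_apply(graph.normalizer, Hb) @ W
    if bias is not None:
        Y = Y + bias
    if activation:
        Y = np.maximum(Y, 0.0)
    return Y[0] if single else Y


def glorot(rng, fin, fout):
    s = np.sqrt(6.0 / (fin + fout))
    return rng.uniform(-s, s, size=(fin, fout))


class _GCNBase:
    """Shared machinery: parameter store, conv op, tape-based backprop."""

    def __init__(self):
        self.weights = []  # list of [W, b] pairs

    # -- parameters -------------------------------------------------------
    def _add_conv(self, rng, fin, fout):
        self.weights.append([glorot(rng, fin, fout), np.zeros(fout)])
        return len(self.weights) - 1

    @property
    def n_parameters(self) -> int:
        return sum(W.size + b.size for W, b in self.weights)

    def get_flat(self) -> np.ndarray:
        return np.concatenate(
            [np.concatenate([W.ravel(), b]) for W, b in self.weights]
        )

    def set_flat(self, vec: np.ndarray):
        off = 0
        for pair in self.weights:
            for i, t in enumerate(pair):
                pair[i] = vec[off : off + t.size].reshape(t.shape)
                off += t.size
        assert off == vec.size

    def zero_grads(self):
        return [[np.zeros_like(W), np.zeros_like(b)] for W, b in self.weights]

    # -- ops --------------------------------------------------------------
    def _conv(self, idx, graph, H, relu, tape, grads):
        W, b = self.weights[idx]
        Z = _sp_apply(graph.normalizer, H)
        Y = Z @ W + b
        if relu:
            Y = np.maximum(Y, 0.0)
        if tape is not None:
            mask = (Y > 0.0) if relu else None

            def back(dY):
                if mask is not None:
                    dY = dY * mask
                grads[idx][0] += np.einsum("bnc,bnk->ck", Z, dY)
                grads[idx][1] += dY.sum(axis=(0, 1))
                return _sp_apply(graph.normalizer, dY @ W.T)

            tape.append(back)
        return Y

    def _pool(self, assign, n_coarse, H, tape):
        Y = _pool_max(assign, H, n_coarse)
        if tape is not None:
            Ht = H.transpose(1, 0, 2)
            winner = Ht == Y.transpose(1, 0, 2)[assign]

            def back(dY):
                dHt = dY.transpose(1, 0, 2)[assign] * winner
                return dHt.transpose(1, 0, 2)

            tape.append(back)
        return Y

    def _unpool(self, assign, H, tape):
        Y = _unpool_clone(assign, H)
        if tape is not None:
            K = H.shape[1]

            def back(dY):
                dt = np.zeros((K,) + (dY.shape[0], dY.shape[2]))
                np.add.at(dt, assign, dY.transpose(1, 0, 2))
                return dt.transpose(1, 0, 2)

            tape.append(back)
        return Y


class GraphUNet(_GCNBase):
    """Graph U-net; see module docstring for the architecture."""

    def __init__(
        self,
        channels=(32, 64, 128, 256),
        convs_per_level: int = 3,
        seed: int = 0,
    ):
        super().__init__()
        channels = tuple(channels)
        if len(channels) < 1:
            raise ValueError("need at least the bottom channel count")
        self.channels = channels
        self.convs_per_level = convs_per_level
        self.levels = len(channels) - 1
        rng = np.random.default_rng(seed)

        self._enc, self._dec = [], []
        prev = 1
        for l in range(self.levels):
            ids = []
            for c in range(convs_per_level):
                ids.append(self._add_conv(rng, prev, channels[l]))
                prev = channels[l]
            self._enc.append(ids)
        self._bottom = []
        for c in range(convs_per_level):
            self._bottom.append(self._add_conv(rng, prev, channels[-1]))
            prev = channels[-1]
        for l in reversed(range(self.levels)):
            ids = []
            fin = prev + channels[l]  # skip concatenation
            for c in range(convs_per_level):
                ids.append(self._add_conv(rng, fin, channels[l]))
                fin = channels[l]
            prev = channels[l]
            self._dec.append(ids)
        self._out = self._add_conv(rng, prev, 1)

    def forward(
        self,
        graph: GraphStructure,
        hierarchy: ClusterHierarchy,
        X: np.ndarray,
        train: bool = False,
    ):
        """Map (B, N, 1) signals to (B, N, 1) on the same graph.

        With ``train=True`` also returns a backward closure mapping the
        output gradient to parameter gradients.
        """
        if self.levels > 0:
            if hierarchy is None or hierarchy.levels < self.levels:
                raise ValueError("hierarchy does not cover the network depth")
            if len(hierarchy.assignments[0]) != graph.n_nodes:
                raise ValueError("hierarchy was built for a different graph")
        graphs = [graph] + (hierarchy.graphs if hierarchy else [])
        tape = [] if train else None
        grads = self.zero_grads() if train else None

        h = X
        skips = []
        for l in range(self.levels):
            for idx in self._enc[l]:
                h = self._conv(idx, graphs[l], h, True, tape, grads)
            skips.append(h)
            h = self._pool(
                hierarchy.assignments[l], graphs[l + 1].n_nodes, h, tape
            )
        for idx in self._bottom:
            h = self._conv(idx, graphs[self.levels], h, True, tape, grads)
        skip_grads = []
        for i, l in enumerate(reversed(range(self.levels))):
            h = self._unpool(hierarchy.assignments[l], h, tape)
            csplit = h.shape[2]
            h = np.concatenate([h, skips[l]], axis=2)
            if tape is not None:
                store = {}
                skip_grads.append(store)

                def back(dY, csplit=csplit, store=store):
                    store["g"] = dY[:, :, csplit:]
                    return dY[:, :, :csplit]

                tape.append(back)
            for idx in self._dec[i]:
                h = self._conv(idx, graphs[l], h, True, tape, grads)
        out = self._conv(self._out, graphs[0], h, False, tape, grads)

        if not train:
            return out

        def backward(dOut):
            g = dOut
            gi = len(tape) - 1
            # output conv
            g = tape[gi](g)
            gi -= 1
            # decoder levels: deepest level is decoder index 0 and appears
            # first in the tape, so walk decoder indices in reverse
            for i in reversed(range(self.levels)):
                for _ in self._dec[i]:
                    g = tape[gi](g)
                    gi -= 1
                g = tape[gi](g)  # concat split; stores skip grad
                gi -= 1
                g = tape[gi](g)  # unpool
                gi -= 1
            for _ in self._bottom:
                g = tape[gi](g)
                gi -= 1
            # encoder levels in reverse; stored skip grads are indexed by
            # decoder loop i where i=0 is the deepest level (l = levels-1)
            for l in reversed(range(self.levels)):
                g = tape[gi](g)  # pool
                gi -= 1
                g = g + skip_grads[self.levels - 1 - l]["g"]
                for _ in self._enc[l]:
                    g = tape[gi](g)
                    gi -= 1
            assert gi == -1
            return grads

        return out, backward


class GResNet(_GCNBase):
    """Residual graph network baseline (10 blocks x 3 convolutions)."""

    def __init__(self, channels: int = 32, blocks: int = 10,
                 convs_per_block: int = 3, seed: int = 0):
        super().__init__()
        self.channels = channels
        self.blocks = blocks
        self.convs_per_block = convs_per_block
        rng = np.random.default_rng(seed)
        self._in = self._add_conv(rng, 1, channels)
        self._blocks = []
        for b in range(blocks):
            self._blocks.append(
                [self._add_conv(rng, channels, channels)
                 for _ in range(convs_per_block)]
            )
        self._out = self._add_conv(rng, channels, 1)

    def forward(self, graph, hierarchy, X, train=False):
        """Global-residual forward: out = X + proj(blocks(lift(X)))."""
        tape = [] if train else None
        grads = self.zero_grads() if train else None
        h = self._conv(self._in, graph, X, True, tape, grads)
        block_masks = []
        for ids in self._blocks:
            r = h
            f = h
            for j, idx in enumerate(ids):
                last = j == len(ids) - 1
                f = self._conv(idx, graph, f, not last, tape, grads)
            h = np.maximum(f + r, 0.0)
            if train:
                block_masks.append(h > 0.0)
        out = X + self._conv(self._out, graph, h, False, tape, grads)
        if not train:
            return out

        def backward(dOut):
            gi = len(tape) - 1
            g = tape[gi](dOut)  # output conv
            gi -= 1
            for b in reversed(range(self.blocks)):
                g = g * block_masks[b]
                gres = g
                for _ in self._blocks[b]:
                    g = tape[gi](g)
                    gi -= 1
                g = g + gres
            g = tape[gi](g)
            gi -= 1
            assert gi == -1
            return grads

        return out, backward


def normalized_apply(net, graph, hierarchy, x: np.ndarray) -> np.ndarray:
    """Apply a network to a single nodal image with max-|.| normalization."""
    x = np.asarray(x, dtype=float)
    s = np.max(np.abs(x))
    if s == 0:
        s = 1.0
    X = (x / s)[None, :, None]
    out = net.forward(graph, hierarchy, X)
    return s * out[0, :, 0]


class Adam:
    """Adam optimizer over a network's (W, b) list."""

    def __init__(self, net, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = net.zero_grads()
        self.v = net.zero_grads()

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for pair, gm, gv, gg in zip(self.net.weights, self.m, self.v, grads):
            for i in range(2):
                gm[i] = self.b1 * gm[i] + (1 - self.b1) * gg[i]
                gv[i] = self.b2 * gv[i] + (1 - self.b2) * gg[i] ** 2
                pair[i] -= (
                    self.lr * (gm[i] / b1t) / (np.sqrt(gv[i] / b2t) + self.eps)
                )
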