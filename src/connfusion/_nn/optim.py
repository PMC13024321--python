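"""Pytree utilities and an Adam optimiser with module-level freezing.

Parameter trees are nested dicts/lists of numpy arrays keyed by module name
at the top level (e.g. ``{"tst1": ..., "head1": ...}``).  Freezing a module
means its subtree is never updated; gradients for it are simply discarded,
which is numerically identical to excluding it from the optimiser.
"""

from __future__ import annotations

import copy
import hashlib
from typing import Iterable

import numpy as np
from autograd.misc import flatten

__all__ = ["tree_copy", "tree_hash", "tree_add_scaled", "Adam"]


def tree_copy(tree):
    return copy.deepcopy(tree)


def tree_hash(tree) -> str:
    """Deterministic content hash of every array in the tree (order-stable)."""
    flat, _ = flatten(tree)
    return hashlib.sha256(np.ascontiguousarray(flat).tobytes()).hexdigest()


def tree_add_scaled(tree, delta, scale):
    flat, unflatten = flatten(tree)
    dflat, _ = flatten(delta)
    return unflatten(flat + scale * dflat)


class Adam:
    """Adam with decoupled-style L2 weight decay over named parameter subtrees.

    ``frozen`` names top-level keys whose parameters must remain bit-identical;
    their update is skipped entirely.
    """

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0, frozen: Iterable[str] = ()):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.frozen = set(frozen)
        self.t = 0
        self._m = {}
        self._v = {}
        for name in params:
            flat, _ = flatten(params[name])
            self._m[name] = np.zeros_like(flat)
            self._v[name] = np.zeros_like(flat)

    def step(self, params, grads):
        """Return a new parameter dict; frozen subtrees are passed through."""
        self.t += 1
        out = {}
        for name, sub in params.items():
            if name in self.frozen or name not in grads:
                out[name] = sub
                continue
            flat, unflatten = flatten(sub)
            gflat, _ = flatten(grads[name])
            if self.weight_decay:
                gflat = gflat + self.weight_decay * flat
            m = self._m[name] = self.b1 * self._m[name] + (1 - self.b1) * gflat
            v = self._v[name] = self.b2 * self._v[name] + (1 - self.b2) * gflat ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            out[name] = unflatten(flat - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out
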