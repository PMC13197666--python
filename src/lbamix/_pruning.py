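"""Felsenstein pruning on flattened tree arrays, batched over mixture
components and rate classes.

Internal engine shared by the ML and MCMC modules.  Likelihoods are computed
per site *pattern*; callers scatter back to site order with the inverse index
from :func:`compress_patterns`.  Per-(class, pattern) rescaling keeps the peel
in linear space with an accumulated log correction, so underflow cannot
produce silent NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .trees_io import Alignment, Tree
from .substitution_models import SpectralDecomposition

__all__ = [
    "TreeArrays",
    "compress_patterns",
    "component_site_loglik",
    "mixture_site_loglik",
]


@dataclass
class TreeArrays:
    """Postorder-flattened topology with branch lengths, bound to a taxon order."""

    children: list[list[int]]  # per node (postorder indexing), root last
    leaf_row: np.ndarray  # taxon row per node, -1 for internal
    lengths: np.ndarray  # branch above each node (root entry unused)
    node_names: list[str | None]

    @classmethod
    def from_tree(cls, tree: Tree, taxa: list[str]) -> "TreeArrays":
        order = list(tree.postorder())
        index = {id(n): i for i, n in enumerate(order)}
        row = {name: i for i, name in enumerate(taxa)}
        missing = set(tree.leaf_names) - set(taxa)
        if missing:
            raise KeyError(f"tree leaves absent from alignment: {sorted(missing)}")
        children = [[index[id(c)] for c in n.children] for n in order]
        leaf_row = np.array(
            [row[n.name] if n.is_leaf else -1 for n in order], dtype=np.int64
        )
        lengths = np.array([n.length for n in order], dtype=float)
        return cls(children, leaf_row, lengths, [n.name for n in order])

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def edge_indices(self) -> np.ndarray:
        """Indices of non-root nodes (each owns the branch above it)."""
        return np.arange(self.n_nodes - 1)

    def with_lengths(self, lengths: np.ndarray) -> "TreeArrays":
        full = np.append(np.asarray(lengths, float), 0.0)
        if full.shape != self.lengths.shape:
            raise ValueError("length vector does not match edge count")
        return TreeArrays(self.children, self.leaf_row, full, self.node_names)


def compress_patterns(aln: Alignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns: (patterns (n_taxa, P), inverse (n_sites,), counts)."""
    patterns, inverse, counts = np.unique(
        aln.codes.T, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, inverse.ravel(), counts


def _class_peel(
    tarr: TreeArrays, patterns: np.ndarray, trans: np.ndarray, pis: np.ndarray
) -> np.ndarray:
    """Log-likelihood per (class, pattern) for one flattened class batch.

    ``trans``: (n_nodes, M, 20, 20) transition matrices per branch and class;
    ``pis``: (M, 20) root frequencies per class.
    """
    M = trans.shape[1]
    P = patterns.shape[1]
    aug = np.concatenate([trans, np.ones_like(trans[..., :1])], axis=-1)
    partial: list[np.ndarray | None] = [None] * tarr.n_nodes
    logscale = np.zeros((M, P))
    for idx in range(tarr.n_nodes):
        kids = tarr.children[idx]
        if not kids:
            continue
        acc = np.ones((M, P, 20))
        for c in kids:
            if tarr.leaf_row[c] >= 0:
                codes = patterns[tarr.leaf_row[c]]
                msg = aug[c][:, :, codes].transpose(0, 2, 1)  # (M, P, 20)
            else:
                child_partial = partial[c]
                partial[c] = None
                msg = child_partial @ trans[c].transpose(0, 2, 1)
            acc *= msg
        mx = acc.max(axis=2)
        safe = np.where(mx > 0, mx, 1.0)
        acc /= safe[:, :, None]
        logscale += np.log(safe)
        partial[idx] = acc
    root_partial = partial[tarr.root]
    if root_partial is None:  # degenerate single-leaf tree: L(site) = pi[state]
        codes = patterns[tarr.leaf_row[tarr.root]]
        pi_aug = np.concatenate([pis, np.ones((M, 1))], axis=1)
        return np.log(np.maximum(pi_aug[:, codes], 1e-300))
    lik = np.einsum("mpi,mi->mp", root_partial, pis)
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def mixture_site_loglik(
    tarr: TreeArrays,
    patterns: np.ndarray,
    spectrals: list[SpectralDecomposition],
    rates: np.ndarray,
    rate_probs: np.ndarray,
) -> np.ndarray:
    """Per-component pattern log-likelihoods, shape (K, P), marginalized over
    the rate classes.  All K*G classes are peeled in one batched pass."""
    K, G = len(spectrals), len(rates)
    P = patterns.shape[1]
    ts = np.multiply.outer(tarr.lengths, rates)  # (n_nodes, G)
    trans = np.empty((tarr.n_nodes, K * G, 20, 20))
    pis = np.empty((K * G, 20))
    for k, sp in enumerate(spectrals):
        trans[:, k * G : (k + 1) * G] = sp.transition(ts)
        pis[k * G : (k + 1) * G] = sp.pi
    logl = _class_peel(tarr, patterns, trans, pis).reshape(K, G, P)
    return logsumexp(logl + np.log(rate_probs)[None, :, None], axis=1)


def component_site_loglik(
    tarr: TreeArrays,
    patterns: np.ndarray,
    spectral: SpectralDecomposition,
    rates: np.ndarray,
    rate_probs: np.ndarray,
) -> np.ndarray:
    """Per-pattern log-likelihood under a single profile component."""
    return mixture_site_loglik(tarr, patterns, [spectral], rates, rate_probs)[0]


def mixture_loglik_and_grad(
    tarr: TreeArrays,
    patterns: np.ndarray,
    counts: np.ndarray,
    spectrals: list[SpectralDecomposition],
    Qs: list[np.ndarray],
    rates: np.ndarray,
    rate_probs: np.ndarray,
    weights: np.ndarray,
    chunk: int = 8,
) -> tuple[float, np.ndarray]:
    """Total log-likelihood and its gradient w.r.t. every branch length.

    Standard two-pass (down/up) algorithm: dP(t r)/dt = r Q P(t r), so each
    edge's derivative is an up-partial x (r Q P) x down-partial contraction.
    Components are processed in chunks to bound memory; per-(class, pattern)
    scale factors are carried in log space and cancelled against the global
    per-pattern likelihood.
    """
    K, G = len(spectrals), len(rates)
    P = patterns.shape[1]
    n_nodes = tarr.n_nodes
    comp_ll = mixture_site_loglik(tarr, patterns, spectrals, rates, rate_probs)
    logw = np.log(np.maximum(weights, 1e-300))
    logl_p = logsumexp(logw[:, None] + comp_ll, axis=0)  # (P,)
    lnl = float(logl_p @ counts)

    grad = np.zeros(n_nodes - 1)
    log_rate_probs = np.log(rate_probs)
    for c0 in range(0, K, chunk):
        comp_idx = range(c0, min(c0 + chunk, K))
        Mc = len(comp_idx) * G
        ts = np.multiply.outer(tarr.lengths, rates)
        trans = np.empty((n_nodes, Mc, 20, 20))
        pis = np.empty((Mc, 20))
        rQ = np.empty((Mc, 20, 20))
        logW = np.empty(Mc)
        for j, k in enumerate(comp_idx):
            trans[:, j * G : (j + 1) * G] = spectrals[k].transition(ts)
            pis[j * G : (j + 1) * G] = spectrals[k].pi
            rQ[j * G : (j + 1) * G] = rates[:, None, None] * Qs[k][None]
            logW[j * G : (j + 1) * G] = logw[k] + log_rate_probs

        # -- down pass: messages through each edge, scaled partials ----------
        aug = np.concatenate([trans, np.ones_like(trans[..., :1])], axis=-1)
        msg: list[np.ndarray | None] = [None] * n_nodes
        msg_ls: list[np.ndarray | float] = [0.0] * n_nodes
        down: list[np.ndarray | None] = [None] * n_nodes
        down_ls: list[np.ndarray | float] = [0.0] * n_nodes
        for idx in range(n_nodes):
            kids = tarr.children[idx]
            if not kids:
                if idx != tarr.root:
                    codes = patterns[tarr.leaf_row[idx]]
                    msg[idx] = aug[idx][:, :, codes].transpose(0, 2, 1)
                continue
            acc = np.ones((Mc, P, 20))
            ls = np.zeros((Mc, P))
            for c in kids:
                acc = acc * msg[c]
                ls = ls + msg_ls[c]
            mx = acc.max(axis=2)
            safe = np.where(mx > 0, mx, 1.0)
            acc /= safe[:, :, None]
            ls = ls + np.log(safe)
            down[idx], down_ls[idx] = acc, ls
            if idx != tarr.root:
                msg[idx] = acc @ trans[idx].transpose(0, 2, 1)
                msg_ls[idx] = ls

        # -- up pass (preorder): edge contractions ---------------------------
        up: list[np.ndarray | None] = [None] * n_nodes
        up_ls: list[np.ndarray | float] = [0.0] * n_nodes
        up[tarr.root] = np.broadcast_to(pis[:, None, :], (Mc, P, 20))
        up_ls[tarr.root] = np.zeros((Mc, P))
        for idx in range(n_nodes - 1, -1, -1):
            kids = tarr.children[idx]
            if not kids:
                continue
            for v in kids:
                sib = np.asarray(up[idx]).copy()
                ls = np.asarray(up_ls[idx]).copy()
                for s in kids:
                    if s != v:
                        sib *= msg[s]
                        ls += msg_ls[s]
                rQP = rQ @ trans[v]  # (Mc, 20, 20) batched
                if tarr.leaf_row[v] >= 0:
                    codes = patterns[tarr.leaf_row[v]]
                    rQP_aug = np.concatenate(
                        [rQP, np.zeros_like(rQP[..., :1])], axis=-1
                    )
                    B = np.einsum(
                        "mpi,mip->mp", sib, rQP_aug[:, :, codes]
                    )
                    tot_ls = ls
                else:
                    Bmat = sib @ rQP  # (Mc, P, 20)
                    B = np.einsum("mpj,mpj->mp", Bmat, down[v])
                    tot_ls = ls + down_ls[v]
                    # recurse: up partial at v
                    uv = sib @ trans[v]
                    mx = uv.max(axis=2)
                    safe = np.where(mx > 0, mx, 1.0)
                    uv /= safe[:, :, None]
                    up[v] = uv
                    up_ls[v] = ls + np.log(safe)
                scale = np.exp(tot_ls + logW[:, None] - logl_p[None, :])
                grad[v] += (B * scale).sum(axis=0) @ counts
    return lnl, grad
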