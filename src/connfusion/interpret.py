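"""Gradient-based importance of connections and ROIs for the case logit.

For the connectivity stream, the importance of edge (i, j) is the absolute
gradient of the case-class logit with respect to that edge's Pearson value,
averaged over the analysed samples:

    I_conn[i, j] = E_x | d f_case(x) / d PCC_ij(x) |

The edge scores live on the package's fixed upper-triangle ordering and are
scattered back into a symmetric R x R matrix with zero diagonal.  The
connectivity vector is treated as the independent variable: the dependence
of PCC on the underlying time series is deliberately not chained through.

For the temporal stream, gradients are aggregated over time *before* the
absolute value (signed temporal mean — cancellation is meaningful), then
averaged over samples:

    I_roi[k] = E_x | (1/T) sum_t d f_case(x) / d X[t, k] |

``abs_first=True`` selects the alternative reading (absolute value before
the temporal mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, List, Sequence, Tuple

import numpy as onp
from autograd import grad

from .io import n_rois_for_length, upper_indices

__all__ = ["ImportanceReport", "connection_importance", "roi_importance",
           "top_connections", "model_gradient_fns", "importance_report"]


@dataclass
class ImportanceReport:
    conn: onp.ndarray            # (R, R), symmetric, zero diagonal
    roi: onp.ndarray             # (R,)
    top_connections: list        # [((i, j), score), ...] descending
    n_samples_averaged: int


def connection_importance(f_case: Callable, pcc_vectors: Sequence,
                          R: int = None) -> onp.ndarray:
    """Mean absolute gradient of ``f_case`` (scalar logit of a flattened
    connectivity vector) at each edge, as a symmetric R x R matrix."""
    pcc_vectors = [onp.asarray(v, dtype=float) for v in pcc_vectors]
    if not pcc_vectors:
        raise ValueError("empty sample list")
    if R is None:
        R = n_rois_for_length(pcc_vectors[0].size)
    g = grad(f_case)
    acc = onp.zeros(pcc_vectors[0].size)
    for v in pcc_vectors:
        acc += onp.abs(onp.asarray(g(v)))
    edge_scores = acc / len(pcc_vectors)
    conn = onp.zeros((R, R))
    iu = upper_indices(R)
    conn[iu] = edge_scores
    conn[(iu[1], iu[0])] = edge_scores
    return conn


def roi_importance(f_case: Callable, series_samples: Sequence,
                   abs_first: bool = False) -> onp.ndarray:
    """Per-ROI importance from gradients of ``f_case`` (scalar logit of a
    T x R series) aggregated over time then averaged over samples."""
    series_samples = [onp.asarray(s, dtype=float) for s in series_samples]
    if not series_samples:
        raise ValueError("empty sample list")
    g = grad(f_case)
    R = series_samples[0].shape[1]
    acc = onp.zeros(R)
    for s in series_samples:
        gs = onp.asarray(g(s))                      # (T, R)
        if abs_first:
            acc += onp.mean(onp.abs(gs), axis=0)
        else:
            acc += onp.abs(onp.mean(gs, axis=0))
    return acc / len(series_samples)


def top_connections(conn: onp.ndarray, k: int) -> List[Tuple[Tuple[int, int], float]]:
    """The k largest strict-upper-triangle entries, descending; ties broken
    by (i, j) lexicographic order.  k larger than the edge count is clipped
    with a warning."""
    conn = onp.asarray(conn)
    R = conn.shape[0]
    iu = upper_indices(R)
    edges = list(zip(zip(iu[0].tolist(), iu[1].tolist()), conn[iu].tolist()))
    if k > len(edges):
        warnings.warn(f"k={k} exceeds edge count {len(edges)}; clipping")
        k = len(edges)
    edges.sort(key=lambda e: (-e[1], e[0]))
    return edges[:max(0, k)]


def model_gradient_fns(tree, t_cfg, c_cfg, f_cfg, streams="both",
                       use_heads=True):
    """Build per-sample case-logit closures for a fitted parameter tree.

    Returns ``(f_conn_factory, f_series_factory)``: each factory takes the
    sample's *other* input fixed (the series for the connectivity gradient
    and vice versa) and returns a scalar function of the stream of interest.
    """
    from .train import model_forward

    def f_conn_factory(series_fixed):
        def f(p_vec):
            logits = model_forward(tree, series_fixed[None], p_vec[None],
                                   t_cfg, c_cfg, f_cfg, streams, use_heads)
            return logits[0, 1]
        return f

    def f_series_factory(pcc_fixed):
        def f(series):
            logits = model_forward(tree, series[None], pcc_fixed[None],
                                   t_cfg, c_cfg, f_cfg, streams, use_heads)
            return logits[0, 1]
        return f

    return f_conn_factory, f_series_factory


def importance_report(tree, t_cfg, c_cfg, f_cfg, X, P, k_top: int = 20,
                      streams: str = "both", use_heads: bool = True,
                      abs_first: bool = False) -> ImportanceReport:
    """Full gradient-importance analysis of a fitted model over samples."""
    f_conn_factory, f_series_factory = model_gradient_fns(
        tree, t_cfg, c_cfg, f_cfg, streams, use_heads)
    R = X.shape[2]
    iu = upper_indices(R)
    acc_edges = onp.zeros(P.shape[1])
    acc_roi = onp.zeros(R)
    for s, p in zip(X, P):
        g_edge = onp.asarray(grad(f_conn_factory(s))(onp.asarray(p, dtype=float)))
        acc_edges += onp.abs(g_edge)
        g_series = onp.asarray(grad(f_series_factory(p))(onp.asarray(s, dtype=float)))
        if abs_first:
            acc_roi += onp.mean(onp.abs(g_series), axis=0)
        else:
            acc_roi += onp.abs(onp.mean(g_series, axis=0))
    n = X.shape[0]
    conn = onp.zeros((R, R))
    conn[iu] = acc_edges / n
    conn[(iu[1], iu[0])] = acc_edges / n
    roi = acc_roi / n
    return ImportanceReport(conn, roi, top_connections(conn, k_top), n)
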