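"""Synthetic multi-site ROI time-series datasets with implanted group effects.

The generator emulates the statistical skeleton of a two-group resting-state
cohort: each subject's ROI signals are a stationary AR(1) process whose
instantaneous covariance is a correlation matrix equal to the identity except
on a designated *edge set*, where controls (label 0) get ``base_r`` and cases
(label 1) get ``base_r + delta_r``.  Because the AR(1) recursion

    x_t = a * x_{t-1} + sqrt(1 - a^2) * e_t,   e_t ~ N(0, C)

preserves the stationary covariance ``C`` exactly, the implanted group
difference in Pearson correlation survives temporal smoothing, so both the
temporal stream and the connectivity stream carry signal.  Classes are
balanced (counts differ by at most 1) and subjects are dealt to pseudo-sites
round-robin; optional per-site mean/scale perturbations create the
distribution shift exercised by leave-one-site-out evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .io import (DatasetManifest, SubjectRecord, ValidationError,
                 save_manifest, write_series)

__all__ = ["SimConfig", "build_group_correlation", "simulate_dataset",
           "split_dataset", "stratified_split_indices",
           "nearest_positive_definite"]


@dataclass
class SimConfig:
    """Study-design knobs for the simulator.

    Defaults mirror a scaled-down multi-site cohort: 100 time points per
    subject (the real cohort's scan length after preprocessing), 20 ROIs,
    3 pseudo-sites, baseline correlation 0.1 on the affected edges and a
    case-minus-control difference of 0.5 — a strong, clearly learnable
    effect.  ``ar_coeff`` 0.85 matches the lag-1 autocorrelation of
    0.01–0.1 Hz band-passed BOLD sampled at ~2 s, so masked time points are
    genuinely predictable from their temporal context.
    """

    n_subjects: int = 200
    R: int = 20
    T: int = 100
    n_sites: int = 3
    edge_set: Optional[List[Tuple[int, int]]] = None
    delta_r: float = 0.5
    base_r: float = 0.1
    ar_coeff: float = 0.85
    seed: int = 0
    site_mean_sd: float = 0.0
    site_scale_sd: float = 0.0

    def __post_init__(self):
        if self.edge_set is None:
            # default: a contiguous block among the first ~R/4 ROIs
            k = max(2, self.R // 4)
            self.edge_set = [(i, j) for i in range(k) for j in range(i + 1, k)]
        for (i, j) in self.edge_set:
            if not (0 <= i < j < self.R):
                raise ValidationError(f"edge ({i},{j}) invalid for R={self.R}")
        if not (0 <= self.base_r < 1):
            raise ValidationError("base_r must be in [0, 1)")
        if not (0 < self.delta_r <= 1) and self.delta_r != 0:
            raise ValidationError("delta_r must be in (0, 1] or 0")
        if self.base_r + self.delta_r >= 1:
            raise ValidationError("base_r + delta_r must be < 1")
        if not (0 <= self.ar_coeff < 1):
            raise ValidationError("ar_coeff must be in [0, 1)")
        if self.n_subjects <= 0 or self.n_sites <= 0 or self.T < 3 or self.R < 2:
            raise ValidationError("invalid size parameters")


def nearest_positive_definite(C: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to the PD cone and restore unit diagonal."""
    w, V = np.linalg.eigh((C + C.T) / 2)
    w = np.clip(w, eig_floor, None)
    C2 = (V * w) @ V.T
    d = np.sqrt(np.diag(C2))
    C2 = C2 / np.outer(d, d)
    return (C2 + C2.T) / 2


def build_group_correlation(cfg: SimConfig, group: int) -> np.ndarray:
    """Target correlation matrix for one diagnostic group (0 or 1)."""
    r = cfg.base_r + (cfg.delta_r if group == 1 else 0.0)
    C = np.eye(cfg.R)
    for (i, j) in cfg.edge_set:
        C[i, j] = C[j, i] = r
    w = np.linalg.eigvalsh(C)
    if w.min() <= 1e-10:
        repaired = nearest_positive_definite(C)
        shift = max(abs(repaired[i, j] - C[i, j]) for (i, j) in cfg.edge_set)
        if shift > 0.05:
            raise ValidationError(
                f"correlation target infeasible: PD repair moved an edge by {shift:.3f} > 0.05")
        warnings.warn("correlation matrix repaired by nearest-PD projection "
                      f"(max edge shift {shift:.4f})")
        C = repaired
    return C


def _simulate_series(rng: np.random.Generator, C: np.ndarray, T: int,
                     a: float) -> np.ndarray:
    """Stationary AR(1) draw with instantaneous covariance exactly C."""
    L = np.linalg.cholesky(C)
    R = C.shape[0]
    innov = rng.standard_normal((T, R)) @ L.T
    x = np.empty((T, R))
    x[0] = innov[0]
    s = np.sqrt(1.0 - a * a)
    for t in range(1, T):
        x[t] = a * x[t - 1] + s * innov[t]
    return x


def simulate_dataset(cfg: SimConfig, out_dir=None):
    """Generate a labelled multi-site cohort.

    Returns ``(manifest, records)``.  When ``out_dir`` is given, per-subject
    series are written as TSV files plus a ``manifest.tsv`` in that directory
    (paths in the manifest are relative to it); otherwise the manifest's
    paths are in-memory placeholders.
    """
    rng = np.random.default_rng(cfg.seed)
    C = {g: build_group_correlation(cfg, g) for g in (0, 1)}

    site_names = [f"site{k:02d}" for k in range(cfg.n_sites)]
    site_mean = {s: (rng.normal(0, cfg.site_mean_sd) if cfg.site_mean_sd > 0 else 0.0)
                 for s in site_names}
    site_scale = {s: (float(np.exp(rng.normal(0, cfg.site_scale_sd)))
                      if cfg.site_scale_sd > 0 else 1.0)
                  for s in site_names}

    records, rows = [], []
    for n in range(cfg.n_subjects):
        label = n % 2                      # exact balance (+-1)
        site = site_names[(n // 2) % cfg.n_sites]   # round-robin within class
        series = _simulate_series(rng, C[label], cfg.T, cfg.ar_coeff)
        series = series * site_scale[site] + site_mean[site]
        sid = f"sub{n:04d}"
        rel_path = f"{sid}.tsv"
        records.append(SubjectRecord(sid, label, site, series))
        rows.append({"subject_id": sid, "label": label, "site": site, "path": rel_path})

    manifest = DatasetManifest(rows, atlas_R=cfg.R)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, row in zip(records, rows):
            write_series(rec.series, out_dir / row["path"])
        save_manifest(manifest, out_dir / "manifest.tsv")
    return manifest, records


def stratified_split_indices(y, fractions=(0.7, 0.1, 0.2), seed: int = 0):
    """Index sets for a stratified split with exact per-class counts.

    Per class, counts are allocated by largest remainder so the realised
    fractions are as close to the request as integer arithmetic allows;
    partitions are disjoint, exhaustive, and deterministic given ``seed``.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("fractions must be positive and sum to 1")
    n_parts = len(fractions)
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    parts = [[] for _ in range(n_parts)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < n_parts:
            raise ValidationError(
                f"class {cls} has {idx.size} subjects < {n_parts} partitions")
        rng.shuffle(idx)
        raw = np.array(fractions) * idx.size
        counts = np.floor(raw).astype(int)
        rem = raw - counts
        for k in np.argsort(-rem)[: idx.size - counts.sum()]:
            counts[k] += 1
        # guarantee every partition sees this class
        while counts.min() == 0:
            counts[np.argmin(counts)] += 1
            counts[np.argmax(counts)] -= 1
        start = 0
        for k, c in enumerate(counts):
            parts[k].extend(idx[start:start + c].tolist())
            start += c
    return tuple(sorted(p) for p in parts)


def split_dataset(manifest: DatasetManifest, fractions=(0.7, 0.1, 0.2),
                  seed: int = 0):
    """Stratified train/validation/test manifests (see
    :func:`stratified_split_indices` for the allocation rule)."""
    parts = stratified_split_indices(manifest.labels, fractions, seed)
    return tuple(manifest.subset(p) for p in parts)
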