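"""Marker filtering: MAF floor, singleton removal, distance thinning, LD pruning,
and optional fixed-size random subsampling (e.g. emulating a reduced-representation
marker panel)."""
from __future__ import annotations

import logging

import numpy as np

from .rng import child_rng
from .types import MISSING, FilterSpec, GenotypeMatrix

log = logging.getLogger("hierpop")


def _pearson_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared dosage correlation; 0 when either vector is constant."""
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm @ xm) * (ym @ ym))
    if denom == 0:
        return 0.0
    return float((xm @ ym) / denom) ** 2


def thin_by_distance(pos: np.ndarray, chrom: np.ndarray, thin_bp: int) -> np.ndarray:
    """Greedy left-to-right thinning: keep a SNP iff it is at least `thin_bp`
    past the previously kept SNP on the same chromosome. Returns kept indices."""
    keep = []
    last_pos = None
    last_chrom = None
    for i in range(pos.size):
        if chrom[i] != last_chrom or last_pos is None or pos[i] - last_pos >= thin_bp:
            keep.append(i)
            last_pos = pos[i]
            last_chrom = chrom[i]
    return np.asarray(keep, dtype=np.int64)


def ld_prune(dosages: np.ndarray, chrom: np.ndarray, r2_max: float, window: int, step: int) -> np.ndarray:
    """Sliding-window LD pruning: within each window of `window` SNPs (advanced by
    `step`), drop the later SNP of every pair with dosage r^2 >= `r2_max`.
    Passes repeat until no SNP is removed, so the operation is idempotent.
    Returns kept indices (into the input columns)."""
    x = dosages.astype(np.float64)
    miss = dosages == MISSING
    if miss.any():
        col_mean = np.where(miss, np.nan, x).astype(float)
        means = np.nanmean(col_mean, axis=0)
        x[miss] = np.take(means, np.where(miss)[1])
    alive = np.ones(x.shape[1], dtype=bool)
    changed = True
    while changed:
        changed = False
        idx = np.where(alive)[0]
        start = 0
        while start < idx.size:
            win = idx[start : start + window]
            win = win[chrom[win] == chrom[win[0]]]
            for a_i in range(len(win)):
                i = win[a_i]
                if not alive[i]:
                    continue
                for b_i in range(a_i + 1, len(win)):
                    j = win[b_i]
                    if not alive[j]:
                        continue
                    if _pearson_r2(x[:, i], x[:, j]) >= r2_max:
                        alive[j] = False
                        changed = True
            start += step
    return np.where(alive)[0]


def filter_markers(gm: GenotypeMatrix, spec: FilterSpec) -> GenotypeMatrix:
    """Apply a :class:`FilterSpec` in its fixed order and return the surviving SNPs."""
    n0 = gm.n_snps
    idx = np.arange(n0)

    if spec.min_maf > 0:
        maf = gm.minor_allele_frequencies()
        idx = idx[maf[idx] >= spec.min_maf]

    if spec.drop_singletons:
        sub = gm.dosages[:, idx]
        called = sub != MISSING
        alt_count = np.where(called, sub, 0).sum(axis=0)
        n_called = 2 * called.sum(axis=0)
        minor = np.minimum(alt_count, n_called - alt_count)
        idx = idx[minor > 1]

    if spec.thin_bp > 0:
        kept = thin_by_distance(gm.variants.pos[idx], gm.variants.chrom[idx], spec.thin_bp)
        idx = idx[kept]

    if spec.ld_r2 is not None:
        kept = ld_prune(
            gm.dosages[:, idx], gm.variants.chrom[idx], spec.ld_r2, spec.ld_window, spec.ld_step
        )
        idx = idx[kept]

    if spec.subsample is not None:
        if spec.subsample > idx.size:
            raise ValueError(
                f"requested subsample of {spec.subsample} exceeds {idx.size} surviving SNPs"
            )
        rng = child_rng(spec.seed, "filter_markers.subsample")
        pick = rng.choice(idx.size, size=spec.subsample, replace=False)
        idx = idx[np.sort(pick)]

    log.info("filter_markers: %d -> %d SNPs", n0, idx.size)
    return gm.take_snps(idx)
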