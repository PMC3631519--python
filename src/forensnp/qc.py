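"""Sample quality control and marker filtering.

The QC gate mirrors forensic chip practice: a sample *fails* when strictly
more than 10 % of its genotype calls are missing (call rate < 90 %).
Marker filtering keeps markers with minor allele frequency above a floor,
missingness below a cap, and — optionally — prunes one of every pair of
markers in high linkage disequilibrium using a greedy sliding window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix

logger = logging.getLogger("forensnp.qc")

#: A sample fails QC when its missing fraction strictly exceeds this.
QC_MAX_MISSING = 0.10


@dataclass
class QCReport:
    """Per-sample missingness and pass/fail flags."""

    table: pd.DataFrame  # index sample_id; columns missing_frac, n_markers, passed
    max_missing: float = QC_MAX_MISSING

    @property
    def passed(self) -> pd.Series:
        return self.table["passed"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def qc_call_rate(g: GenotypeMatrix, max_missing: float = QC_MAX_MISSING) -> QCReport:
    """Compute per-sample missing fractions over all panel markers.

    A sample passes iff its missing fraction is <= ``max_missing``; strictly
    more missingness than the gate fails the sample.
    """
    if g.n_markers == 0:
        raise ValueError("QC undefined on an empty marker panel")
    miss = np.isnan(g.dosage).mean(axis=1)
    table = pd.DataFrame(
        {
            "missing_frac": miss,
            "n_markers": g.n_markers,
            "passed": miss <= max_missing,
        },
        index=pd.Index(g.sample_ids, name="sample_id"),
    )
    return QCReport(table=table, max_missing=max_missing)


def _minor_allele_freq(freq: np.ndarray) -> np.ndarray:
    return np.minimum(freq, 1.0 - freq)


def _ld_prune_mask(
    dosage: np.ndarray, r2_max: float, window: int, step: int
) -> np.ndarray:
    """Greedy windowed LD pruning; returns a keep-mask over markers.

    Within each window the pairwise squared Pearson correlation of dosages
    (mean-imputed for missing calls) is computed and, scanning pairs in
    marker order, the later marker of any pair with r² > ``r2_max`` is
    dropped.  Windows advance by ``step`` so pruning decisions propagate.
    """
    n_markers = dosage.shape[1]
    keep = np.ones(n_markers, dtype=bool)
    col_mean = np.nanmean(dosage, axis=0)
    filled = np.where(np.isnan(dosage), col_mean[None, :], dosage)
    for start in range(0, max(n_markers - 1, 1), step):
        idx = np.flatnonzero(keep[start : start + window]) + start
        if len(idx) < 2:
            continue
        block = filled[:, idx]
        sd = block.std(axis=0)
        sd[sd == 0] = np.nan  # zero-variance: r2 undefined, never pruned here
        z = (block - block.mean(axis=0)) / sd
        r2 = np.abs(np.nan_to_num(z.T @ z / block.shape[0])) ** 2
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if keep[idx[b]] and r2[a, b] > r2_max:
                    keep[idx[b]] = False
        if start + window >= n_markers:
            break
    return keep


def filter_markers(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    max_marker_missing: float = 0.05,
    classes: Iterable[str] | None = None,
    ld_r2_max: float | None = None,
    ld_window: int = 50,
    ld_step: int = 5,
) -> GenotypeMatrix:
    """Keep markers passing MAF, missingness, class and (optional) LD gates.

    MAF is computed on the analysis cohort itself from non-missing calls;
    the MAF gate is strict (MAF must exceed ``maf_min``) and the missingness
    gate is strict (missing fraction must be below ``max_marker_missing``),
    matching the conventional "greater than 1 %, less than 5 %" phrasing.
    """
    keep = np.ones(g.n_markers, dtype=bool)
    if classes is not None:
        keep &= g.panel.class_mask(classes)
    miss = np.isnan(g.dosage).mean(axis=0)
    keep &= miss < max_marker_missing
    with np.errstate(invalid="ignore"):
        freq = g.allele_freq()
        maf = _minor_allele_freq(freq)
        keep &= np.nan_to_num(maf, nan=-1.0) > maf_min
    if ld_r2_max is not None and keep.any():
        sub_idx = np.flatnonzero(keep)
        prune_keep = _ld_prune_mask(
            g.dosage[:, sub_idx], ld_r2_max, ld_window, ld_step
        )
        keep[sub_idx[~prune_keep]] = False
    if not keep.any():
        raise ValueError(
            "no markers survive filtering; relax maf_min/max_marker_missing "
            "or the LD threshold"
        )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_markers dropped %d of %d markers", n_dropped, g.n_markers)
    return g.subset_markers(keep)
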