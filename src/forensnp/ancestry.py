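"""Biparental continental ancestry inference.

Two complementary routes, both against a labelled reference panel:

* **PCA + nearest centroid** — the reference cohort is decomposed into its
  top principal components (markers centred by twice the allele frequency
  and scaled by ``sqrt(2p(1-p))``); a query sample is projected into that
  space and assigned to the population whose centroid is nearest.
* **Supervised admixture** — with per-population allele frequencies
  ``f_kj`` held fixed, the admixture vector ``q`` maximising the binomial
  log-likelihood ``sum_j g_j log(pi_j) + (2-g_j) log(1-pi_j)`` with
  ``pi_j = sum_k q_k f_kj`` is found by EM on the simplex.  A sample is
  assigned to a single group when its largest component strictly exceeds
  0.70, and to "multiple groups" otherwise.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import GenotypeMatrix

logger = logging.getLogger("forensnp.ancestry")

#: Label used when no single ancestry component dominates.
MULTIPLE_GROUPS = "multiple groups"

#: A single group is assigned only when its proportion strictly exceeds this.
SINGLE_GROUP_THRESHOLD = 0.70

#: Allele frequencies are clamped into this range to keep likelihoods finite.
FREQ_FLOOR, FREQ_CEIL = 0.001, 0.999


@dataclass
class ReferencePanel:
    """Fitted reference space: allele frequencies + PCA + centroids."""

    labels: list[str]                # K population labels
    marker_ids: np.ndarray           # M marker ids (order defines columns)
    freqs: np.ndarray                # K x M population allele frequencies
    center: np.ndarray               # M, = 2 * reference mean frequency
    scale: np.ndarray                # M, = sqrt(2 p (1-p))
    loadings: np.ndarray             # M x n_pc, orthonormal columns
    centroids: np.ndarray            # K x n_pc mean reference coordinates

    def __post_init__(self) -> None:
        K, M = len(self.labels), len(self.marker_ids)
        if self.freqs.shape != (K, M):
            raise ValueError("freqs shape inconsistent with labels/markers")
        if K < 2:
            raise ValueError("a reference panel needs at least two populations")
        if np.any(self.freqs < FREQ_FLOOR) or np.any(self.freqs > FREQ_CEIL):
            raise ValueError("panel frequencies must be clamped to [0.001, 0.999]")

    @property
    def n_pc(self) -> int:
        return self.loadings.shape[1]

    # -- serialisation: TSV bundle + JSON manifest -----------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.freqs.T, index=self.marker_ids, columns=self.labels
        ).rename_axis("marker_id").to_csv(d / "frequencies.tsv", sep="\t")
        pc_cols = [f"PC{i+1}" for i in range(self.n_pc)]
        pd.DataFrame(
            np.column_stack([self.center, self.scale, self.loadings]),
            index=self.marker_ids,
            columns=["center", "scale", *pc_cols],
        ).rename_axis("marker_id").to_csv(d / "loadings.tsv", sep="\t")
        pd.DataFrame(self.centroids, index=self.labels, columns=pc_cols).rename_axis(
            "population"
        ).to_csv(d / "centroids.tsv", sep="\t")
        (d / "manifest.json").write_text(
            json.dumps(
                {
                    "format": "forensnp-reference-panel",
                    "version": 1,
                    "populations": self.labels,
                    "n_markers": int(len(self.marker_ids)),
                    "n_pc": int(self.n_pc),
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ReferencePanel":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        freqs = pd.read_csv(d / "frequencies.tsv", sep="\t", index_col="marker_id")
        load = pd.read_csv(d / "loadings.tsv", sep="\t", index_col="marker_id")
        cent = pd.read_csv(d / "centroids.tsv", sep="\t", index_col="population")
        labels = list(manifest["populations"])
        pc_cols = [f"PC{i+1}" for i in range(manifest["n_pc"])]
        return cls(
            labels=labels,
            marker_ids=freqs.index.to_numpy(),
            freqs=freqs[labels].to_numpy().T,
            center=load["center"].to_numpy(),
            scale=load["scale"].to_numpy(),
            loadings=load[pc_cols].to_numpy(),
            centroids=cent.loc[labels, pc_cols].to_numpy(),
        )


@dataclass
class AncestryResult:
    """Joint categorical and quantitative ancestry for one sample."""

    sample_id: str
    labels: list[str]
    pc_coords: np.ndarray | None = None
    nearest_group: str | None = None
    distance: float | None = None
    q: np.ndarray | None = None
    assignment: str | None = None
    loglik: float | None = None
    converged: bool = True
    qc_failed: bool = False

    def q_dict(self) -> dict[str, float]:
        if self.q is None:
            return {}
        return {lab: float(v) for lab, v in zip(self.labels, self.q)}


# ---------------------------------------------------------------------------
# reference fitting
# ---------------------------------------------------------------------------

def _select_ancestry_markers(g: GenotypeMatrix) -> np.ndarray:
    """Markers used for ancestry: the tagged low-LD subset if present,
    otherwise all autosomal markers."""
    mask = g.panel.tag_mask("ancestry_subset")
    if not mask.any():
        mask = g.panel.class_mask(["autosomal"])
    return mask


def fit_reference(
    ref: GenotypeMatrix,
    labels: Sequence[str] | None = None,
    n_pc: int = 3,
) -> ReferencePanel:
    """Fit the reference space from labelled reference genotypes.

    ``labels`` gives the population of each reference sample; if omitted it
    is read from the ``population`` metadata column.  Zero-variance markers
    are dropped (their count logged).  Per-population frequencies are
    estimated within the labelled groups and clamped to [0.001, 0.999].
    """
    if labels is None:
        if "population" not in ref.metadata.columns:
            raise ValueError("labels not given and no 'population' metadata column")
        labels = list(ref.metadata["population"])
    labels = list(labels)
    if len(labels) != ref.n_samples:
        raise ValueError("one population label per reference sample required")
    pops = sorted(set(labels))
    if len(pops) < 2:
        raise ValueError("at least two reference populations required")
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError(
            f"populations with <2 samples: {sorted(counts[counts < 2].index)}"
        )

    mask = _select_ancestry_markers(ref)
    dose = ref.dosage[:, mask]
    marker_ids = ref.panel.marker_ids[mask]

    with np.errstate(invalid="ignore"):
        pbar = np.nanmean(dose, axis=0) / 2.0
    variable = np.isfinite(pbar) & (pbar > 0) & (pbar < 1)
    n_dropped = int((~variable).sum())
    if n_dropped:
        logger.info("fit_reference dropped %d zero-variance markers", n_dropped)
    dose, marker_ids, pbar = dose[:, variable], marker_ids[variable], pbar[variable]
    if dose.shape[1] == 0:
        raise ValueError("no variable markers available for the reference fit")

    center = 2.0 * pbar
    scale = np.sqrt(2.0 * pbar * (1.0 - pbar))
    z = (dose - center) / scale
    z = np.where(np.isnan(z), 0.0, z)  # mean imputation of missing calls
    # economical SVD; right singular vectors are the marker loadings
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[:n_pc].T
    scores = z @ loadings

    lab_arr = np.asarray(labels)
    centroids = np.vstack([scores[lab_arr == p].mean(axis=0) for p in pops])
    freqs = np.vstack(
        [
            np.clip(
                np.nanmean(dose[lab_arr == p], axis=0) / 2.0,
                FREQ_FLOOR,
                FREQ_CEIL,
            )
            for p in pops
        ]
    )
    return ReferencePanel(
        labels=pops,
        marker_ids=marker_ids,
        freqs=freqs,
        center=center,
        scale=scale,
        loadings=loadings,
        centroids=centroids,
    )


# ---------------------------------------------------------------------------
# projection and categorical assignment
# ---------------------------------------------------------------------------

def _aligned_dosage(g: GenotypeMatrix, sample_id: str, panel: ReferencePanel) -> np.ndarray:
    """Sample dosages reordered to the panel's marker order (NaN where absent)."""
    idx = g.panel.indexer()
    row = g.sample_dosage(sample_id)
    out = np.full(len(panel.marker_ids), np.nan)
    for j, m in enumerate(panel.marker_ids):
        i = idx.get(m)
        if i is not None:
            out[j] = row[i]
    return out


def project_and_assign(
    g: GenotypeMatrix,
    sample_id: str,
    panel: ReferencePanel,
    min_overlap_frac: float = 0.5,
) -> tuple[np.ndarray, str, float]:
    """Project one sample into the reference PC space; nearest centroid wins.

    Missing markers are dropped and the projection solved by least squares
    on the remaining loading rows, which renormalises the scaling; with no
    missingness this equals the plain orthonormal projection.  Ties between
    centroids break by label order with a logged warning.
    """
    x = _aligned_dosage(g, sample_id, panel)
    obs = np.isfinite(x)
    if obs.mean() < min_overlap_frac:
        raise ValueError(
            f"sample {sample_id}: only {obs.sum()} of {len(x)} panel markers "
            f"called; need >= {min_overlap_frac:.0%}"
        )
    z = (x[obs] - panel.center[obs]) / panel.scale[obs]
    v = panel.loadings[obs]
    coords, *_ = np.linalg.lstsq(v, z, rcond=None)
    dists = np.linalg.norm(panel.centroids - coords, axis=1)
    best = float(dists.min())
    hits = np.flatnonzero(np.isclose(dists, best, rtol=0.0, atol=1e-12))
    if len(hits) > 1:
        logger.warning(
            "sample %s equidistant from %d centroids; tie broken by label order",
            sample_id,
            len(hits),
        )
    k = int(hits[0])
    return coords, panel.labels[k], float(dists[k])


# ---------------------------------------------------------------------------
# supervised admixture EM
# ---------------------------------------------------------------------------

def admixture_loglik(q: np.ndarray, g: np.ndarray, freqs: np.ndarray) -> float:
    """Binomial log-likelihood of dosages ``g`` under mixture ``q``."""
    pi = q @ freqs
    return float(np.sum(g * np.log(pi) + (2.0 - g) * np.log1p(-pi)))


def estimate_admixture(
    g: GenotypeMatrix | np.ndarray,
    panel: ReferencePanel,
    sample_id: str | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    return_trace: bool = False,
):
    """Supervised admixture proportions by EM.

    Each of the sample's ``2M`` allele draws is attributed to population
    ``k`` with posterior responsibility proportional to ``q_k f_kj`` (for an
    alternate allele) or ``q_k (1-f_kj)`` (reference allele); the M-step
    sets ``q`` to the mean responsibility.  The likelihood is monotone
    non-decreasing; convergence is declared when it improves by < ``tol``.

    Returns ``(q, loglik, converged)`` — plus the per-iteration likelihood
    trace when ``return_trace`` is set.
    """
    if isinstance(g, GenotypeMatrix):
        if sample_id is None:
            raise ValueError("sample_id required with a GenotypeMatrix input")
        x = _aligned_dosage(g, sample_id, panel)
    else:
        x = np.asarray(g, dtype=float)
        if x.shape[0] != len(panel.marker_ids):
            raise ValueError("dosage vector length does not match the panel")
    obs = np.isfinite(x)
    x = x[obs]
    if x.size == 0:
        raise ValueError("no autosomal calls available for admixture estimation")
    f = panel.freqs[:, obs]  # K x M
    K, M = f.shape

    q = np.full(K, 1.0 / K)
    ll = admixture_loglik(q, x, f)
    trace = [ll]
    converged = False
    for _ in range(max_iter):
        pi = q @ f  # mixture alt-allele frequency per marker
        # responsibilities for alt and ref allele draws
        a = (q[:, None] * f) / pi          # K x M
        b = (q[:, None] * (1.0 - f)) / (1.0 - pi)
        q_new = (a @ x + b @ (2.0 - x)) / (2.0 * M)
        q_new /= q_new.sum()
        ll_new = admixture_loglik(q_new, x, f)
        q = q_new
        trace.append(ll_new)
        if ll_new - ll < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    if not converged:
        logger.warning("admixture EM did not converge in %d iterations", max_iter)
    if return_trace:
        return q, ll, converged, trace
    return q, ll, converged


def assign_quantitative(
    q: np.ndarray, labels: Sequence[str], threshold: float = SINGLE_GROUP_THRESHOLD
) -> str:
    """Single-group label when max(q) strictly exceeds the threshold."""
    q = np.asarray(q, dtype=float)
    if abs(q.sum() - 1.0) > 1e-6 or np.any(q < -1e-9):
        raise ValueError("q must lie on the probability simplex")
    k = int(np.argmax(q))
    return labels[k] if q[k] > threshold else MULTIPLE_GROUPS


def analyse_sample(
    g: GenotypeMatrix,
    sample_id: str,
    panel: ReferencePanel,
    threshold: float = SINGLE_GROUP_THRESHOLD,
) -> AncestryResult:
    """Full per-sample ancestry: PCA assignment + admixture + 0.70 rule."""
    coords, nearest, dist = project_and_assign(g, sample_id, panel)
    q, ll, converged = estimate_admixture(g, panel, sample_id=sample_id)
    return AncestryResult(
        sample_id=sample_id,
        labels=list(panel.labels),
        pc_coords=coords,
        nearest_group=nearest,
        distance=dist,
        q=q,
        assignment=assign_quantitative(q, panel.labels, threshold),
        loglik=ll,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def group_summary(
    q_matrix: np.ndarray,
    component_labels: Sequence[str],
    cohorts: Sequence[str],
) -> pd.DataFrame:
    """Box-plot style five-number summaries of ancestry components per cohort.

    Whiskers follow the Tukey convention: the most extreme observation
    within 1.5 IQR of the nearer quartile.
    """
    q_matrix = np.asarray(q_matrix, dtype=float)
    cohorts = np.asarray(cohorts)
    if q_matrix.shape[0] != len(cohorts):
        raise ValueError("one cohort label per q vector required")
    rows = []
    for cohort in sorted(set(cohorts.tolist())):
        sub = q_matrix[cohorts == cohort]
        for k, lab in enumerate(component_labels):
            v = np.sort(sub[:, k])
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            lo = v[v >= q1 - 1.5 * iqr].min()
            hi = v[v <= q3 + 1.5 * iqr].max()
            rows.append((cohort, lab, len(v), lo, q1, med, q3, hi))
    return pd.DataFrame(
        rows,
        columns=[
            "cohort",
            "component",
            "n",
            "whisker_low",
            "q1",
            "median",
            "q3",
            "whisker_high",
        ],
    )


def results_to_tsv(results: Sequence[AncestryResult], path: str | Path) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict[str, object] = {"sample_id": r.sample_id}
        if r.pc_coords is not None:
            for i, c in enumerate(r.pc_coords):
                row[f"PC{i+1}"] = c
        row["nearest_group"] = r.nearest_group
        row["distance"] = r.distance
        for lab, v in r.q_dict().items():
            row[f"q_{lab}"] = v
        row["assignment"] = r.assignment
        row["converged"] = r.converged
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
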