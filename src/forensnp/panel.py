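"""Marker panel and genotype matrix containers.

The genotype model mirrors a forensic SNP microarray: a panel of biallelic
markers annotated with a chromosome class (autosomal, X-specific,
XY-pseudoautosomal, Y, mitochondrial) and, per sample, an alternate-allele
dosage.  Diploid classes use dosages {0, 1, 2}; haploid classes (Y, mt) use
{0, 1}.  Missing calls are ``NaN`` throughout, so every downstream statistic
masks rather than imputes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Recognised chromosome classes.
CHROM_CLASSES = ("autosomal", "X_specific", "XY_pseudoautosomal", "Y", "mt")

#: Classes whose genotypes are haploid states (dosage in {0, 1}).
HAPLOID_CLASSES = frozenset({"Y", "mt"})

#: Panel tag vocabulary (free-form tags are allowed; these are the ones the
#: pipeline itself consumes).
KNOWN_TAGS = frozenset({"ancestry_subset", "eye_snp", "hair_snp", "kinship_set"})


@dataclass(frozen=True)
class MarkerPanel:
    """Immutable description of the marker set of a chip or simulation.

    Parameters
    ----------
    table
        One row per marker with columns ``marker_id`` (unique str),
        ``chrom_class`` (one of :data:`CHROM_CLASSES`), ``position``
        (1-based int), ``ref``, ``alt`` (single-character alleles) and
        ``tags`` (a frozenset of strings, possibly empty).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker_id", "chrom_class", "position", "ref", "alt", "tags"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"panel table missing columns: {sorted(missing)}")
        ids = self.table["marker_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate marker ids: {dups[:5]}")
        bad = set(self.table["chrom_class"]) - set(CHROM_CLASSES)
        if bad:
            raise ValueError(f"unknown chromosome classes: {sorted(bad)}")
        object.__setattr__(self, "table", self.table.reset_index(drop=True))

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        marker_ids: Sequence[str],
        chrom_class: Sequence[str],
        position: Sequence[int] | None = None,
        ref: Sequence[str] | None = None,
        alt: Sequence[str] | None = None,
        tags: Sequence[Iterable[str]] | None = None,
    ) -> "MarkerPanel":
        n = len(marker_ids)
        table = pd.DataFrame(
            {
                "marker_id": list(marker_ids),
                "chrom_class": list(chrom_class),
                "position": list(position) if position is not None else np.arange(1, n + 1),
                "ref": list(ref) if ref is not None else ["A"] * n,
                "alt": list(alt) if alt is not None else ["G"] * n,
                "tags": [frozenset(t) for t in tags] if tags is not None else [frozenset()] * n,
            }
        )
        return cls(table)

    # -- accessors ------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chrom_class(self) -> np.ndarray:
        return self.table["chrom_class"].to_numpy()

    def class_mask(self, classes: Iterable[str]) -> np.ndarray:
        """Boolean mask of markers whose class is in ``classes``."""
        wanted = set(classes)
        bad = wanted - set(CHROM_CLASSES)
        if bad:
            raise ValueError(f"unknown chromosome classes: {sorted(bad)}")
        return np.isin(self.chrom_class, list(wanted))

    @property
    def haploid_mask(self) -> np.ndarray:
        return np.isin(self.chrom_class, list(HAPLOID_CLASSES))

    def tag_mask(self, tag: str) -> np.ndarray:
        return np.array([tag in t for t in self.table["tags"]], dtype=bool)

    def indexer(self) -> dict[str, int]:
        """marker_id -> column index."""
        return {m: i for i, m in enumerate(self.marker_ids)}

    def subset(self, mask: np.ndarray) -> "MarkerPanel":
        return MarkerPanel(self.table.loc[np.asarray(mask)].reset_index(drop=True))

    def equals(self, other: "MarkerPanel") -> bool:
        a, b = self.table, other.table
        if len(a) != len(b):
            return False
        cols = ["marker_id", "chrom_class", "position", "ref", "alt"]
        return bool(
            a[cols].reset_index(drop=True).equals(b[cols].reset_index(drop=True))
            and all(x == y for x, y in zip(a["tags"], b["tags"]))
        )


@dataclass
class GenotypeMatrix:
    """Samples × markers dosage matrix with a missingness mask.

    ``dosage`` is a float array of shape (n_samples, n_markers); missing
    calls are ``NaN``.  Haploid markers (Y, mt) must never carry dosage 2.
    ``metadata`` is indexed by sample id and may carry the optional
    site-reported columns ``reported_sex``, ``reported_ancestry``,
    ``reported_eye`` and ``reported_hair``.
    """

    sample_ids: list[str]
    panel: MarkerPanel
    dosage: np.ndarray
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), self.panel.n_markers):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {self.panel.n_markers} markers"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        with np.errstate(invalid="ignore"):
            vals = self.dosage[~np.isnan(self.dosage)]
            if vals.size and (np.any(vals < 0) or np.any(vals > 2) or np.any(vals % 1 != 0)):
                raise ValueError("dosages must be integers in {0,1,2} or NaN")
            hap = self.panel.haploid_mask
            if hap.any():
                hd = self.dosage[:, hap]
                if np.any(hd[~np.isnan(hd)] > 1):
                    raise ValueError("haploid markers (Y/mt) must not carry dosage 2")
        if self.metadata is None or len(self.metadata) == 0:
            self.metadata = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        else:
            self.metadata = self.metadata.reindex(self.sample_ids)
            self.metadata.index.name = "sample_id"

    # -- accessors ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.panel.n_markers

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id}") from None

    def sample_dosage(self, sample_id: str) -> np.ndarray:
        return self.dosage[self.sample_index(sample_id)]

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_markers, dtype=bool)
            idx[mask] = True
            mask = idx
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            panel=self.panel.subset(mask),
            dosage=self.dosage[:, mask].copy(),
            metadata=self.metadata.copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            panel=self.panel,
            dosage=self.dosage[idx].copy(),
            metadata=self.metadata.iloc[idx].copy(),
        )

    def allele_freq(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele frequency per marker from non-missing calls.

        Haploid markers divide by the number of calls, diploid by twice that.
        Markers with no calls return ``NaN``.
        """
        d = self.dosage if mask is None else self.dosage[:, mask]
        hap = self.panel.haploid_mask if mask is None else self.panel.haploid_mask[mask]
        n_called = np.sum(~np.isnan(d), axis=0).astype(float)
        ploidy = np.where(hap, 1.0, 2.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.nansum(d, axis=0) / (ploidy * n_called)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return bool(
            self.sample_ids == other.sample_ids
            and self.panel.equals(other.panel)
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )
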