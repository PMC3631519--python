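"""Reading and writing genotype matrices.

Two dialects are supported:

* ``tsv`` — the package's internal tabular dialect: one row per marker with
  the panel annotation columns (``marker_id``, ``chrom_class``, ``position``,
  ``ref``, ``alt``, ``tags``) followed by one dosage column per sample;
  missing calls are ``.``.  Tags are comma-joined in a single cell.
* ``vcf`` — standard VCF with GT genotypes.  The chromosome class is derived
  from the contig name (1–22 autosomal, X X-specific, Y, MT mitochondrial,
  XY pseudoautosomal); panel tags ride in the INFO field as ``TAGS=``.

Haploid classes (Y, mt) are tolerated in diploid coding on input: a
homozygous diploid call is coerced to the haploid state with a logged
warning, a heterozygous call on a haploid marker is set missing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import CHROM_CLASSES, GenotypeMatrix, MarkerPanel

logger = logging.getLogger("forensnp.io")

_PANEL_COLS = ["marker_id", "chrom_class", "position", "ref", "alt", "tags"]

_CONTIG_FOR_CLASS = {
    "autosomal": "1",
    "X_specific": "X",
    "XY_pseudoautosomal": "XY",
    "Y": "Y",
    "mt": "MT",
}


def _class_for_contig(contig: str) -> str:
    c = contig.removeprefix("chr")
    if c in {str(i) for i in range(1, 23)}:
        return "autosomal"
    if c == "X":
        return "X_specific"
    if c == "XY":
        return "XY_pseudoautosomal"
    if c == "Y":
        return "Y"
    if c in {"MT", "M"}:
        return "mt"
    raise ValueError(f"cannot derive chromosome class from contig {contig!r}")


def _normalise_haploid(dosage: np.ndarray, hap_mask: np.ndarray) -> np.ndarray:
    """Coerce diploid-coded calls on haploid markers; warn once per file."""
    if not hap_mask.any():
        return dosage
    hd = dosage[:, hap_mask]
    n_twos = int(np.nansum(hd == 2))
    if n_twos:
        logger.warning(
            "%d haploid-marker calls coded as diploid dosage 2; coerced to 1", n_twos
        )
        hd[hd == 2] = 1
        dosage[:, hap_mask] = hd
    return dosage


# ---------------------------------------------------------------------------
# internal TSV dialect
# ---------------------------------------------------------------------------

def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    t = g.panel.table.copy()
    t["tags"] = [",".join(sorted(s)) for s in t["tags"]]
    dos = g.dosage.T  # markers x samples
    cols = {
        s: ["." if np.isnan(v) else str(int(v)) for v in dos[:, i]]
        for i, s in enumerate(g.sample_ids)
    }
    t = pd.concat([t, pd.DataFrame(cols)], axis=1)
    t.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    t = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in _PANEL_COLS if c not in t.columns and c != "tags"]
    if missing_cols:
        raise ValueError(f"TSV dialect requires columns {missing_cols}")
    if "tags" not in t.columns:
        t["tags"] = ""
    sample_ids = [c for c in t.columns if c not in _PANEL_COLS]
    panel = MarkerPanel.from_arrays(
        marker_ids=t["marker_id"],
        chrom_class=t["chrom_class"],
        position=t["position"].astype(int),
        ref=t["ref"],
        alt=t["alt"],
        tags=[frozenset(x.split(",")) - {""} for x in t["tags"].fillna("")],
    )
    raw = t[sample_ids].to_numpy(dtype=object).T  # samples x markers
    dosage = np.where(raw == ".", np.nan, raw)
    try:
        dosage = dosage.astype(float)
    except ValueError as e:
        raise ValueError(f"non-numeric dosage in {path}: {e}") from None
    bad = dosage[~np.isnan(dosage)]
    if bad.size and (np.any(bad < 0) or np.any(bad > 2)):
        j = int(np.argwhere(np.nan_to_num(dosage, nan=1) > 2)[0][1])
        raise ValueError(
            f"dosage out of range at marker {panel.marker_ids[j]!r} in {path}"
        )
    dosage = _normalise_haploid(dosage, panel.haploid_mask)
    return GenotypeMatrix(sample_ids=sample_ids, panel=panel, dosage=dosage)


# ---------------------------------------------------------------------------
# VCF dialect
# ---------------------------------------------------------------------------

def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF (uncompressed)."""
    lines = ["##fileformat=VCFv4.2"]
    for cls in CHROM_CLASSES:
        lines.append(f"##contig=<ID={_CONTIG_FOR_CLASS[cls]}>")
    lines.append('##INFO=<ID=TAGS,Number=.,Type=String,Description="Panel tags">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.sample_ids)
    )
    hap = g.panel.haploid_mask
    tab = g.panel.table
    for j in range(g.n_markers):
        row = tab.iloc[j]
        tags = sorted(row["tags"])
        info = f"TAGS={','.join(tags)}" if tags else "."
        gts = []
        for d in g.dosage[:, j]:
            if np.isnan(d):
                gts.append("." if hap[j] else "./.")
            elif hap[j]:
                gts.append(str(int(d)))
            else:
                gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
        lines.append(
            "\t".join(
                [
                    _CONTIG_FOR_CLASS[row["chrom_class"]],
                    str(int(row["position"])),
                    row["marker_id"],
                    row["ref"],
                    row["alt"],
                    ".",
                    ".",
                    info,
                    "GT",
                ]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _dosage_from_alleles(alleles: list[int], haploid: bool, marker_id: str) -> float:
    """Dosage from GT allele indices (-1 = missing); coerce haploid coding."""
    called = [a for a in alleles if a >= 0]
    if not called:
        return np.nan
    if any(a not in (0, 1) for a in called):
        raise ValueError(f"dosage out of range (multiallelic GT) at {marker_id}")
    d = float(sum(called))
    if haploid and len(called) == 2:
        if called[0] != called[1]:
            logger.warning(
                "heterozygous diploid call on haploid marker %s set missing", marker_id
            )
            return np.nan
        logger.warning(
            "haploid marker %s coded diploid; coerced to haploid dosage", marker_id
        )
        return d / 2
    return d


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    sample_ids = list(vcf.samples)
    ids, classes, positions, refs, alts, tags, rows = [], [], [], [], [], [], []
    for v in vcf:
        cls = _class_for_contig(v.CHROM)
        hap = cls in ("Y", "mt")
        mid = v.ID or f"{v.CHROM}:{v.POS}"
        ids.append(mid)
        classes.append(cls)
        positions.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0] if v.ALT else "N")
        raw_tags = v.INFO.get("TAGS")
        tags.append(frozenset(raw_tags.split(",")) if raw_tags else frozenset())
        # cyvcf2 genotype entries are [a0, (a1,) phased]; drop the phase flag
        rows.append(
            [_dosage_from_alleles(list(g[:-1]), hap, mid) for g in v.genotypes]
        )
    panel = MarkerPanel.from_arrays(ids, classes, positions, refs, alts, tags)
    dosage = np.array(rows, dtype=float).T if rows else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids=sample_ids, panel=panel, dosage=dosage)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, dialect: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix; dialect inferred from the suffix if omitted."""
    dialect = dialect or ("vcf" if str(path).endswith(".vcf") else "tsv")
    if dialect == "vcf":
        return read_genotypes_vcf(path)
    if dialect == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(g: GenotypeMatrix, path: str | Path, dialect: str | None = None) -> None:
    dialect = dialect or ("vcf" if str(path).endswith(".vcf") else "tsv")
    if dialect == "vcf":
        write_genotypes_vcf(g, path)
    elif dialect == "tsv":
        write_genotypes_tsv(g, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
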