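"""Two-pronged genetic sex inference.

Males carry one X chromosome, so their X-specific markers — those without a
Y homologue, excluding the pseudoautosomal region — are effectively haploid
and read out as homozygous calls: observed X heterozygosity near zero.
Females are diploid X, with heterozygosity set by panel allele frequencies
(well above the male level for a genome-wide panel).  The rule is:

* normalised X heterozygosity < 0.2 implies male-derived DNA,
* normalised X heterozygosity > 0.8 implies female-derived DNA,
* intermediate values are inconclusive.

"Normalised" means the observed heterozygous fraction divided by the
heterozygosity a diploid genome would show at the same markers under
Hardy-Weinberg (see :func:`x_heterozygosity`); the raw fraction cannot
exceed 0.5 in expectation at biallelic SNPs, so the 0.8 female threshold
only makes sense on this scale.

The second prong is Y-chromosome evidence (a called Y haplogroup, or simply
a usable Y call rate).  A full call needs both prongs to agree; a call from
one prong alone carries a single-evidence caveat.  Calls are compared
against site-reported sex and conflicts flagged, never overwritten.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lineage import HaplogroupCall
from .panel import GenotypeMatrix

logger = logging.getLogger("forensnp.sex")

MALE_XHET_MAX = 0.2
FEMALE_XHET_MIN = 0.8
MIN_X_MARKERS = 100

#: Y-evidence states.
Y_HAPLOGROUP = "haplogroup_called"
Y_PRESENT = "y_present"
Y_ABSENT = "absent"


@dataclass
class SexCall:
    """A sex inference with its evidence trail."""

    sample_id: str
    x_heterozygosity: float  # NaN when too few informative X markers
    n_x_markers_used: int
    y_evidence: str  # one of Y_HAPLOGROUP / Y_PRESENT / Y_ABSENT
    call: str  # "male" / "female" / "inconclusive"
    single_evidence: bool = False
    conflict_with_report: bool = False
    reported_sex: str | None = None


def x_heterozygosity(
    g: GenotypeMatrix,
    sample_id: str,
    min_markers: int = MIN_X_MARKERS,
    x_freqs: np.ndarray | None = None,
) -> tuple[float, int]:
    """Normalised X heterozygosity of one sample, in [0, 1].

    The observed heterozygous fraction over non-missing X-specific calls is
    divided by the heterozygosity expected of a diploid (female) genome at
    the same markers under Hardy–Weinberg, ``mean(2 p (1-p))``, then clamped
    to [0, 1].  A female scores near 1, a male (haploid X read out as
    homozygous calls) near 0; the raw fraction alone could never reach the
    0.8 female threshold because ``2pq`` tops out at 0.5 per marker.

    ``x_freqs`` supplies the X allele frequencies (aligned to the panel's
    X-specific markers); by default they are estimated from the cohort
    itself.  Pseudoautosomal markers are excluded (diploid in males too).
    Returns ``(NaN, n)`` when fewer than ``min_markers`` informative calls
    are available — the inconclusive-by-data signal.
    """
    mask = g.panel.class_mask(["X_specific"])
    if not mask.any():
        return float("nan"), 0
    x = g.sample_dosage(sample_id)[mask]
    called = np.isfinite(x)
    n = int(called.sum())
    if n < min_markers:
        return float("nan"), n
    if x_freqs is None:
        x_freqs = g.allele_freq(mask)
    else:
        x_freqs = np.asarray(x_freqs, dtype=float)
        if x_freqs.shape[0] != mask.sum():
            raise ValueError("x_freqs must align with the panel's X-specific markers")
    p = x_freqs[called]
    ok = np.isfinite(p)
    expected = float(np.mean(2.0 * p[ok] * (1.0 - p[ok]))) if ok.any() else 0.0
    observed = float(np.mean(x[called] == 1))
    if expected <= 1e-12:
        return (0.0 if observed == 0.0 else float("nan")), n
    return float(np.clip(observed / expected, 0.0, 1.0)), n


def y_call_evidence(
    g: GenotypeMatrix,
    sample_id: str,
    haplogroup: HaplogroupCall | None = None,
    call_rate_min: float = 0.5,
) -> str:
    """Operationalise the Y prong: haplogroup > raw call rate > absent."""
    if haplogroup is not None:
        return Y_HAPLOGROUP
    mask = g.panel.class_mask(["Y"])
    if not mask.any():
        return Y_ABSENT
    y = g.sample_dosage(sample_id)[mask]
    call_rate = float(np.isfinite(y).mean())
    return Y_PRESENT if call_rate >= call_rate_min else Y_ABSENT


def infer_sex(
    xhet: float,
    y_evidence: str,
    sample_id: str = "",
    n_x_markers: int = 0,
    reported_sex: str | None = None,
    male_max: float = MALE_XHET_MAX,
    female_min: float = FEMALE_XHET_MIN,
) -> SexCall:
    """Combine the X-heterozygosity and Y-evidence prongs into a sex call.

    * ``male`` when X heterozygosity < ``male_max`` **and** Y evidence is
      present (both prongs).
    * ``female`` when X heterozygosity > ``female_min`` **and** Y evidence
      is absent (both prongs).
    * one prong alone (low X het without Y data; Y evidence with
      intermediate or unavailable X het) yields the corresponding call with
      a single-evidence caveat.
    * contradictory prongs (high X het *with* Y evidence — e.g. a mixture)
      and the closed intermediate zone [male_max, female_min] are
      inconclusive.
    """
    y_present = y_evidence in (Y_HAPLOGROUP, Y_PRESENT)
    x_male = np.isfinite(xhet) and xhet < male_max
    x_female = np.isfinite(xhet) and xhet > female_min

    if x_male and y_present:
        call, single = "male", False
    elif x_female and not y_present:
        call, single = "female", False
    elif x_male and not y_present:
        call, single = "male", True  # X prong only
    elif y_present and not np.isfinite(xhet):
        call, single = "male", True  # Y prong only
    elif y_present and not x_female:
        call, single = "male", True  # Y prong; X intermediate
    else:
        call, single = "inconclusive", False

    conflict = (
        reported_sex in ("male", "female")
        and call in ("male", "female")
        and call != reported_sex
    )
    if conflict:
        logger.warning(
            "sample %s: inferred %s conflicts with reported %s",
            sample_id,
            call,
            reported_sex,
        )
    return SexCall(
        sample_id=sample_id,
        x_heterozygosity=float(xhet),
        n_x_markers_used=n_x_markers,
        y_evidence=y_evidence,
        call=call,
        single_evidence=single,
        conflict_with_report=bool(conflict),
        reported_sex=reported_sex,
    )


def infer_sex_cohort(
    g: GenotypeMatrix,
    haplogroups: Mapping[str, HaplogroupCall | None] | None = None,
    min_markers: int = MIN_X_MARKERS,
) -> list[SexCall]:
    """Run both prongs for every sample; reported sex read from metadata."""
    haplogroups = haplogroups or {}
    reported = (
        g.metadata["reported_sex"]
        if "reported_sex" in g.metadata.columns
        else pd.Series(index=g.metadata.index, dtype=object)
    )
    calls = []
    for s in g.sample_ids:
        xhet, n = x_heterozygosity(g, s, min_markers=min_markers)
        yev = y_call_evidence(g, s, haplogroup=haplogroups.get(s))
        rep = reported.get(s)
        rep = rep if isinstance(rep, str) else None
        calls.append(
            infer_sex(xhet, yev, sample_id=s, n_x_markers=n, reported_sex=rep)
        )
    return calls


def sex_report(calls: Sequence[SexCall], path: str | Path | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "x_heterozygosity": c.x_heterozygosity,
                "n_x_markers": c.n_x_markers_used,
                "y_evidence": c.y_evidence,
                "call": c.call,
                "single_evidence": c.single_evidence,
                "reported_sex": c.reported_sex,
                "conflict_with_report": c.conflict_with_report,
            }
            for c in calls
        ]
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
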