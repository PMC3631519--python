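"""Categorical eye- and hair-colour prediction from predictor SNPs.

Both traits use multinomial logistic (softmax) models over effect-allele
dosages: eye colour from the 6 established predictor SNPs with three
categories (blue / intermediate / brown), hair colour from an 18-SNP panel
(the full 22-variant panel minus four MC1R variants that a genome-wide chip
cannot assay) with four categories (black-dark-brown / brown-light-brown /
blonde-dark-blonde / red).

The published model coefficients are not redistributed here: models load
from a coefficient file, and the package ships **synthetic defaults fitted
on a planted-parameter simulated cohort** (see ``data/*_model_synthetic``).
They reproduce the published models' *structure*, not their numbers — swap
in a real coefficient file for casework-like behaviour.

Calling rules: a prediction requires the full complement of predictor SNPs
non-missing; eye colour is called only when the top probability strictly
exceeds 0.7 (otherwise "undetermined"); hair colour follows a configurable
prediction guide, by default the top category with exact ties broken toward
the lighter shade.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluate import ConfusionTable, confusion_stats
from .panel import GenotypeMatrix

logger = logging.getLogger("forensnp.phenotype")

EYE_CATEGORIES = ("blue", "intermediate", "brown")
HAIR_CATEGORIES = (
    "black_dark_brown",
    "brown_light_brown",
    "blonde_dark_blonde",
    "red",
)

#: The 6 canonical eye-colour predictor SNPs.
EYE_SNPS = (
    "rs12913832",
    "rs1800407",
    "rs12896399",
    "rs16891982",
    "rs1393350",
    "rs12203592",
)

#: The 18 hair-colour predictor SNPs assayable on a genome-wide chip (the
#: four MC1R variants N29insA, Y152OCH, rs1805007 and rs1805009 are not).
HAIR_SNPS = (
    "rs11547464",
    "rs885479",
    "rs1805008",
    "rs1805005",
    "rs1805006",
    "rs2228479",
    "rs1110400",
    "rs28777",
    "rs16891982",
    "rs12821256",
    "rs4959270",
    "rs12203592",
    "rs1042602",
    "rs1800407",
    "rs2402130",
    "rs12913832",
    "rs2378249",
    "rs683",
)

#: Lighter-shade ordering used by the default hair guide's tie-break
#: (index = lighter).  Red sits between brown and blonde by convention.
HAIR_LIGHTNESS = (
    "black_dark_brown",
    "brown_light_brown",
    "red",
    "blonde_dark_blonde",
)

EYE_P_THRESHOLD = 0.7

UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class PhenotypeModel:
    """Multinomial logistic model over effect-allele dosages.

    ``beta`` has shape (n_categories - 1, n_predictors + 1): one row per
    non-reference category (the first listed category is the reference),
    column 0 the intercept.
    """

    trait: str  # "eye" or "hair"
    snp_ids: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    categories: tuple[str, ...]
    beta: np.ndarray

    def __post_init__(self) -> None:
        expected = {"eye": 6, "hair": 18}.get(self.trait)
        if expected is not None and len(self.snp_ids) != expected:
            raise ValueError(
                f"{self.trait} model requires {expected} predictor SNPs, "
                f"got {len(self.snp_ids)}"
            )
        if len(self.effect_alleles) != len(self.snp_ids):
            raise ValueError("one effect allele per predictor SNP required")
        want = (len(self.categories) - 1, len(self.snp_ids) + 1)
        if self.beta.shape != want:
            raise ValueError(f"beta shape {self.beta.shape} != expected {want}")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")

    @property
    def reference_category(self) -> str:
        return self.categories[0]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax category probabilities for one dosage vector."""
        x = np.asarray(x, dtype=float)
        if x.shape[0] != len(self.snp_ids) or not np.all(np.isfinite(x)):
            raise ValueError("complete predictor dosage vector required")
        eta = np.concatenate([[0.0], self.beta @ np.concatenate([[1.0], x])])
        eta -= eta.max()  # overflow guard; softmax is shift-invariant
        w = np.exp(eta)
        return w / w.sum()

    # -- serialisation: coefficient TSV + JSON manifest -------------------
    def save(self, tsv_path: str | Path, manifest_path: str | Path) -> None:
        rows = []
        allele_of = dict(zip(self.snp_ids, self.effect_alleles))
        for c, cat in enumerate(self.categories[1:]):
            rows.append((self.trait, cat, "(intercept)", "", self.beta[c, 0]))
            for j, snp in enumerate(self.snp_ids):
                rows.append((self.trait, cat, snp, allele_of[snp], self.beta[c, j + 1]))
        pd.DataFrame(
            rows, columns=["trait", "category", "term", "effect_allele", "beta"]
        ).to_csv(tsv_path, sep="\t", index=False)
        Path(manifest_path).write_text(
            json.dumps(
                {
                    "format": "forensnp-phenotype-model",
                    "version": 1,
                    "trait": self.trait,
                    "categories": list(self.categories),
                    "reference_category": self.reference_category,
                    "snp_ids": list(self.snp_ids),
                    "effect_alleles": list(self.effect_alleles),
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, tsv_path: str | Path, manifest_path: str | Path) -> "PhenotypeModel":
        manifest = json.loads(Path(manifest_path).read_text())
        coef = pd.read_csv(tsv_path, sep="\t")
        categories = tuple(manifest["categories"])
        snp_ids = tuple(manifest["snp_ids"])
        beta = np.zeros((len(categories) - 1, len(snp_ids) + 1))
        term_col = {"(intercept)": 0, **{s: j + 1 for j, s in enumerate(snp_ids)}}
        for _, row in coef.iterrows():
            c = categories.index(row["category"]) - 1
            beta[c, term_col[row["term"]]] = row["beta"]
        return cls(
            trait=manifest["trait"],
            snp_ids=snp_ids,
            effect_alleles=tuple(manifest["effect_alleles"]),
            categories=categories,
            beta=beta,
        )


@dataclass
class PhenotypePrediction:
    """Per-category probabilities plus the guided category call."""

    sample_id: str
    trait: str
    probabilities: dict[str, float] | None
    call: str | None  # category, UNDETERMINED, or None when incomplete
    complete: bool


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def fit_multinomial(
    x: np.ndarray,
    labels: Sequence[str],
    snp_ids: Sequence[str],
    effect_alleles: Sequence[str],
    categories: Sequence[str],
    trait: str = "eye",
    l2: float = 1e-4,
) -> PhenotypeModel:
    """Fit a penalised multinomial logistic model (deterministic, convex).

    ``x`` is an (n, P) effect-allele dosage matrix with complete rows;
    ``l2`` is the ridge weight on the total penalised log-likelihood
    (intercepts unpenalised).  Every listed category must appear at least
    three times in ``labels``.
    """
    from sklearn.linear_model import LogisticRegression

    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != len(labels):
        raise ValueError("x must be (n_samples, n_predictors) matching labels")
    if not np.all(np.isfinite(x)):
        raise ValueError("complete predictor profiles required for fitting")
    counts = pd.Series(labels).value_counts()
    missing = [c for c in categories if c not in counts.index]
    if missing:
        raise ValueError(f"categories absent from training labels: {missing}")
    thin = [c for c in categories if counts[c] < 3]
    if thin:
        raise ValueError(f"categories with <3 training samples: {thin}")

    clf = LogisticRegression(C=1.0 / l2, solver="lbfgs", max_iter=10_000, tol=1e-10)
    clf.fit(x, labels)
    order = {c: i for i, c in enumerate(clf.classes_)}
    idx = [order[c] for c in categories]
    intercepts = clf.intercept_[idx]
    coefs = clf.coef_[idx]
    # reference-category parametrisation: subtract the reference row
    beta = np.column_stack(
        [intercepts[1:] - intercepts[0], coefs[1:] - coefs[0]]
    )
    return PhenotypeModel(
        trait=trait,
        snp_ids=tuple(snp_ids),
        effect_alleles=tuple(effect_alleles),
        categories=tuple(categories),
        beta=beta,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _predictor_dosages(
    g: GenotypeMatrix, sample_id: str, model: PhenotypeModel
) -> np.ndarray | None:
    """Effect-allele dosages at the model's SNPs; None unless complete."""
    idx = g.panel.indexer()
    row = g.sample_dosage(sample_id)
    out = np.empty(len(model.snp_ids))
    for j, snp in enumerate(model.snp_ids):
        i = idx.get(snp)
        if i is None or not np.isfinite(row[i]):
            return None
        out[j] = row[i]
    return out


def predict_eye(
    g: GenotypeMatrix,
    sample_id: str,
    model: PhenotypeModel,
    p_threshold: float = EYE_P_THRESHOLD,
) -> PhenotypePrediction:
    """Eye-colour prediction; called only when max p strictly exceeds 0.7."""
    x = _predictor_dosages(g, sample_id, model)
    if x is None:
        return PhenotypePrediction(sample_id, "eye", None, None, complete=False)
    p = model.predict_proba(x)
    best = int(np.argmax(p))
    call = model.categories[best] if p[best] > p_threshold else UNDETERMINED
    return PhenotypePrediction(
        sample_id,
        "eye",
        dict(zip(model.categories, map(float, p))),
        call,
        complete=True,
    )


@dataclass(frozen=True)
class PredictionGuide:
    """Configurable rule table turning hair probabilities into a call.

    ``min_p`` maps a category to the minimum probability it needs to be
    callable (default 0: plain argmax); ``tie_break`` orders categories for
    exact probability ties ("lighter" = later in :data:`HAIR_LIGHTNESS`
    wins).  Serialisable to JSON so a published guide can be encoded.
    """

    min_p: Mapping[str, float] = field(default_factory=dict)
    tie_break: tuple[str, ...] = HAIR_LIGHTNESS

    def apply(self, probabilities: Mapping[str, float]) -> str:
        best_p = max(probabilities.values())
        tied = [c for c, p in probabilities.items() if p == best_p]
        if len(tied) > 1:
            tied.sort(key=lambda c: self.tie_break.index(c))
            winner = tied[-1]  # lighter shade wins
            logger.warning(
                "hair guide: exact tie among %s resolved to lighter shade %s",
                tied,
                winner,
            )
        else:
            winner = tied[0]
        if best_p < self.min_p.get(winner, 0.0):
            return UNDETERMINED
        return winner

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"min_p": dict(self.min_p), "tie_break": list(self.tie_break)},
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "PredictionGuide":
        d = json.loads(Path(path).read_text())
        return cls(min_p=d.get("min_p", {}), tie_break=tuple(d["tie_break"]))


def predict_hair(
    g: GenotypeMatrix,
    sample_id: str,
    model: PhenotypeModel,
    guide: PredictionGuide | None = None,
) -> PhenotypePrediction:
    """Hair-colour prediction via the (configurable) prediction guide."""
    guide = guide or PredictionGuide()
    x = _predictor_dosages(g, sample_id, model)
    if x is None:
        return PhenotypePrediction(sample_id, "hair", None, None, complete=False)
    p = model.predict_proba(x)
    probs = dict(zip(model.categories, map(float, p)))
    return PhenotypePrediction(sample_id, "hair", probs, guide.apply(probs), complete=True)


# ---------------------------------------------------------------------------
# evaluation against site reports
# ---------------------------------------------------------------------------

#: Site-reported eye labels collapsed into the three model categories.
EYE_REPORT_COLLAPSE = {
    "blue": "blue",
    "blue-gray": "blue",
    "gray": "blue",
    "heterochromia": "intermediate",
    "blue-green": "intermediate",
    "green": "intermediate",
    "green-hazel": "intermediate",
    "gray-green": "intermediate",
    "yellow": "intermediate",
    "intermediate": "intermediate",
    "hazel": "brown",
    "brown": "brown",
}


def evaluate_phenotypes(
    predictions: Sequence[PhenotypePrediction],
    reported: Sequence[str],
    collapse_map: Mapping[str, str],
    correct_map: Mapping[str, Sequence[str]] | None = None,
    exclude_columns: Sequence[str] | None = None,
    rows: Sequence[str] | None = None,
    columns: Sequence[str] | None = None,
) -> tuple[ConfusionTable, pd.DataFrame]:
    """Predicted-vs-reported confusion table plus per-row accuracies.

    Samples without a category call (incomplete profiles, undetermined) are
    excluded, as in published evaluations.  ``collapse_map`` must cover
    every reported label; an unmapped label raises, listing the offenders.
    ``correct_map`` defaults to the identity (row correct iff the collapsed
    report equals the predicted category).
    """
    if len(predictions) != len(reported):
        raise ValueError("one reported label per prediction required")
    unmapped = sorted({r for r in reported if r not in collapse_map})
    if unmapped:
        raise ValueError(f"reported labels missing from collapse_map: {unmapped}")
    pred_calls, obs = [], []
    for p, r in zip(predictions, reported):
        if p.call is None or p.call == UNDETERMINED:
            continue
        pred_calls.append(p.call)
        obs.append(collapse_map[r])
    table = ConfusionTable.from_labels(pred_calls, obs, rows=rows, columns=columns)
    if correct_map is None:
        correct_map = {row: [row] for row in table.table.index}
    stats = confusion_stats(table, correct_map, exclude_columns=exclude_columns)
    return table, stats


# ---------------------------------------------------------------------------
# synthetic cohorts and shipped default models
# ---------------------------------------------------------------------------

def simulate_phenotype_cohort(
    model: PhenotypeModel,
    n: int,
    seed: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Draw genotypes at the model's SNPs (HWE) and labels from the model.

    Returns (dosage matrix, labels, per-SNP allele frequencies).  Used for
    planted-parameter recovery tests and to build the shipped synthetic
    default models.
    """
    rng = np.random.default_rng(seed)
    P = len(model.snp_ids)
    freqs = rng.uniform(*maf_range, P)
    x = rng.binomial(2, freqs, size=(n, P)).astype(float)
    labels = []
    for i in range(n):
        p = model.predict_proba(x[i])
        labels.append(model.categories[rng.choice(len(p), p=p)])
    return x, labels, freqs


def planted_model(trait: str, seed: int = 7) -> PhenotypeModel:
    """A deterministic ground-truth model used by the simulator and tests.

    The architecture mirrors the real traits: each non-reference category is
    driven by one major-effect predictor (as a single HERC2 variant
    dominates blue/brown eye colour and MC1R variants dominate red hair)
    with per-allele log-odds 3, plus moderate random modifier effects.
    Intercepts centre each linear predictor at the cohort-mean dosage so no
    category dominates a priori.
    """
    rng = np.random.default_rng(seed)
    if trait == "eye":
        snps, cats = EYE_SNPS, EYE_CATEGORIES
    elif trait == "hair":
        snps, cats = HAIR_SNPS, HAIR_CATEGORIES
    else:
        raise ValueError("trait must be 'eye' or 'hair'")
    beta = rng.normal(0.0, 0.8, size=(len(cats) - 1, len(snps) + 1))
    for c in range(len(cats) - 1):
        beta[c, 1 + (c % len(snps))] = 3.0  # the category's major locus
    beta[:, 0] = -beta[:, 1:] @ np.full(len(snps), 0.6)
    return PhenotypeModel(
        trait=trait,
        snp_ids=snps,
        effect_alleles=tuple("A" for _ in snps),
        categories=cats,
        beta=beta,
    )


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def default_eye_model() -> PhenotypeModel:
    """The shipped synthetic eye model (fitted on a planted cohort)."""
    return PhenotypeModel.load(
        _data_path("eye_model_synthetic.tsv"), _data_path("eye_model_synthetic.json")
    )


def default_hair_model() -> PhenotypeModel:
    """The shipped synthetic hair model (fitted on a planted cohort)."""
    return PhenotypeModel.load(
        _data_path("hair_model_synthetic.tsv"), _data_path("hair_model_synthetic.json")
    )


def predictions_to_tsv(
    predictions: Sequence[PhenotypePrediction], path: str | Path | None = None
) -> pd.DataFrame:
    rows = []
    for p in predictions:
        row: dict[str, object] = {
            "sample_id": p.sample_id,
            "trait": p.trait,
            "call": p.call if p.call is not None else "no_call",
            "complete": p.complete,
        }
        if p.probabilities:
            for cat, prob in p.probabilities.items():
                row[f"p_{cat}"] = prob
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
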