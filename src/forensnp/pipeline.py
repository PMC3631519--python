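"""All-in-one orchestration: QC -> lineage -> sex -> ancestry -> phenotype -> kinship.

``run_all`` executes every inference stage over one genotype matrix and
writes per-stage TSVs plus a consolidated JSON/TSV report.  Stage failures
isolate the affected sample (logged, recorded in the report) and never abort
the cohort.  Samples failing the QC gate still get an ancestry attempt —
ancestry tends to survive low call rates because it pools thousands of
markers — but carry a ``qc_failed`` flag.

Configuration is one declarative YAML file (see :func:`validate_config`);
command-line flags override file values.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import io as fio
from . import kinship as kin
from . import lineage as lin
from . import phenotype as phe
from . import qc as fqc
from . import sex as fsex

logger = logging.getLogger("forensnp.pipeline")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Validated configuration of a full run."""

    input: str | None = None
    input_dialect: str | None = None
    reference_genotypes: str | None = None
    reference_labels: str | None = None
    eye_model: str | None = None
    eye_manifest: str | None = None
    hair_model: str | None = None
    hair_manifest: str | None = None
    hair_guide: str | None = None
    y_tree_newick: str | None = None
    y_tree_table: str | None = None
    mt_tree_newick: str | None = None
    mt_tree_table: str | None = None
    qc_max_missing: float = 0.10
    sex_male_max: float = 0.2
    sex_female_min: float = 0.8
    min_x_markers: int = 100
    ancestry_threshold: float = 0.70
    eye_p_threshold: float = 0.7
    kinship_min_overlap: int = 1000
    kinship_bins: dict[str, float] = field(
        default_factory=lambda: dict(kin.DEFAULT_DEGREE_BINS)
    )
    seed: int = 0
    outdir: str = "forensnp_out"

    _THRESHOLDS = (
        "qc_max_missing",
        "sex_male_max",
        "sex_female_min",
        "ancestry_threshold",
        "eye_p_threshold",
    )
    _PATH_KEYS = (
        "input",
        "reference_genotypes",
        "reference_labels",
        "eye_model",
        "eye_manifest",
        "hair_model",
        "hair_manifest",
        "hair_guide",
        "y_tree_newick",
        "y_tree_table",
        "mt_tree_newick",
        "mt_tree_table",
    )


def validate_config(
    path: str | Path | None = None,
    overrides: dict[str, Any] | None = None,
) -> tuple[RunConfig | None, list[str], list[str]]:
    """Parse + validate a YAML config; return (config, errors, warnings).

    All problems are reported at once, not first-failure.  Unknown keys are
    warnings (forward compatibility), not errors.  On any error the config
    slot is ``None``.
    """
    import yaml

    raw: dict[str, Any] = {}
    errors: list[str] = []
    warnings: list[str] = []
    if path is not None:
        try:
            loaded = yaml.safe_load(Path(path).read_text())
        except FileNotFoundError:
            return None, [f"config file not found: {path}"], []
        except yaml.YAMLError as e:
            return None, [f"config does not parse as YAML: {e}"], []
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            return None, ["config must be a YAML mapping"], []
        raw = loaded
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    for k in unknown:
        warnings.append(f"unknown config key ignored: {k!r}")
    kwargs = {k: v for k, v in raw.items() if k in known}

    try:
        config = RunConfig(**kwargs)
    except (TypeError, ValueError) as e:
        return None, [f"config field error: {e}"], warnings

    if config.input is None:
        errors.append("mandatory key missing: 'input' (genotype matrix path)")
    for key in RunConfig._THRESHOLDS:
        v = getattr(config, key)
        if not isinstance(v, (int, float)) or not (0.0 <= float(v) <= 1.0):
            errors.append(f"{key} must be a number in [0, 1]; got {v!r}")
    if config.sex_male_max >= config.sex_female_min:
        errors.append("sex_male_max must be below sex_female_min")
    if not isinstance(config.seed, int):
        errors.append(f"seed must be an integer; got {config.seed!r}")
    if config.kinship_min_overlap < 1:
        errors.append("kinship_min_overlap must be >= 1")
    for key in RunConfig._PATH_KEYS:
        v = getattr(config, key)
        if v is not None and not Path(v).exists():
            errors.append(f"{key} path does not exist: {v}")
    paired = [
        ("eye_model", "eye_manifest"),
        ("hair_model", "hair_manifest"),
        ("y_tree_newick", "y_tree_table"),
        ("mt_tree_newick", "mt_tree_table"),
    ]
    for a, b in paired:
        if (getattr(config, a) is None) != (getattr(config, b) is None):
            errors.append(f"{a} and {b} must be given together")
    if errors:
        return None, errors, warnings
    return config, [], warnings


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _load_trees(config: RunConfig) -> tuple[lin.HaplogroupTree, lin.HaplogroupTree]:
    if config.y_tree_newick:
        y_tree = lin.HaplogroupTree.from_files(config.y_tree_newick, config.y_tree_table)
    else:
        y_tree = lin.fixture_tree("Y")
    if config.mt_tree_newick:
        mt_tree = lin.HaplogroupTree.from_files(
            config.mt_tree_newick, config.mt_tree_table
        )
    else:
        mt_tree = lin.fixture_tree("mt")
    return y_tree, mt_tree


def _load_models(config: RunConfig) -> tuple[phe.PhenotypeModel, phe.PhenotypeModel, phe.PredictionGuide]:
    if config.eye_model:
        eye = phe.PhenotypeModel.load(config.eye_model, config.eye_manifest)
    else:
        eye = phe.default_eye_model()
    if config.hair_model:
        hair = phe.PhenotypeModel.load(config.hair_model, config.hair_manifest)
    else:
        hair = phe.default_hair_model()
    guide = (
        phe.PredictionGuide.load(config.hair_guide)
        if config.hair_guide
        else phe.PredictionGuide()
    )
    return eye, hair, guide


def _haplogroup_states(g, mask) -> dict[str, dict[str, float]]:
    ids = g.panel.marker_ids[mask]
    out = {}
    for s in g.sample_ids:
        row = g.sample_dosage(s)[mask]
        out[s] = dict(zip(ids, row))
    return out


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns the consolidated report dict.

    Writes per-stage TSVs, ``report.json`` and ``report.tsv`` under
    ``config.outdir``, plus a run log.  Deterministic given config + seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("forensnp")
    root.addHandler(log_handler)
    try:
        return _run_all_inner(config, outdir)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run_all_inner(config: RunConfig, outdir: Path) -> dict[str, Any]:
    g = fio.read_genotypes(config.input, dialect=config.input_dialect)
    logger.info("loaded %d samples x %d markers", g.n_samples, g.n_markers)
    samples: dict[str, dict[str, Any]] = {
        s: {"errors": []} for s in g.sample_ids
    }

    # ---- QC ----------------------------------------------------------
    qc_report = fqc.qc_call_rate(g, max_missing=config.qc_max_missing)
    qc_report.to_tsv(outdir / "qc.tsv")
    for s in g.sample_ids:
        samples[s]["missing_frac"] = float(qc_report.table.loc[s, "missing_frac"])
        samples[s]["qc_pass"] = bool(qc_report.table.loc[s, "passed"])

    # ---- lineage -----------------------------------------------------
    y_tree, mt_tree = _load_trees(config)
    y_calls: dict[str, lin.HaplogroupCall | None] = {}
    mt_calls: dict[str, lin.HaplogroupCall | None] = {}
    y_states = _haplogroup_states(g, g.panel.class_mask(["Y"]))
    mt_states = _haplogroup_states(g, g.panel.class_mask(["mt"]))
    for s in g.sample_ids:
        try:
            y_calls[s] = lin.call_haplogroup(y_states[s], y_tree)
            mt_calls[s] = lin.call_haplogroup(mt_states[s], mt_tree)
        except Exception as e:  # noqa: BLE001 - isolate the sample
            logger.error("lineage failed for %s: %s", s, e)
            samples[s]["errors"].append(f"lineage: {e}")
            y_calls[s] = mt_calls[s] = None
        samples[s]["y_haplogroup"] = y_calls[s].node if y_calls[s] else None
        samples[s]["y_geography"] = y_calls[s].geography if y_calls[s] else None
        samples[s]["mt_haplogroup"] = mt_calls[s].node if mt_calls[s] else None
        samples[s]["mt_geography"] = mt_calls[s].geography if mt_calls[s] else None
    lin.calls_to_tsv(y_calls, outdir / "lineage_y.tsv")
    lin.calls_to_tsv(mt_calls, outdir / "lineage_mt.tsv")

    # ---- sex ---------------------------------------------------------
    sex_calls = fsex.infer_sex_cohort(g, haplogroups=y_calls, min_markers=config.min_x_markers)
    fsex.sex_report(sex_calls, outdir / "sex.tsv")
    for c in sex_calls:
        samples[c.sample_id]["sex_call"] = c.call
        samples[c.sample_id]["x_heterozygosity"] = (
            None if not np.isfinite(c.x_heterozygosity) else c.x_heterozygosity
        )
        samples[c.sample_id]["sex_conflict"] = c.conflict_with_report

    # ---- ancestry ----------------------------------------------------
    ancestry_results: list[anc.AncestryResult] = []
    if config.reference_genotypes:
        ref = fio.read_genotypes(config.reference_genotypes)
        labels = None
        if config.reference_labels:
            lab_table = pd.read_csv(
                config.reference_labels, sep="\t", index_col="sample_id"
            )
            labels = [lab_table.loc[s, "population"] for s in ref.sample_ids]
        panel = anc.fit_reference(ref, labels=labels)
        for s in g.sample_ids:
            try:
                r = anc.analyse_sample(g, s, panel, threshold=config.ancestry_threshold)
                r.qc_failed = not samples[s]["qc_pass"]
                ancestry_results.append(r)
                samples[s]["ancestry_assignment"] = r.assignment
                samples[s]["nearest_group"] = r.nearest_group
                samples[s]["q"] = r.q_dict()
            except Exception as e:  # noqa: BLE001
                logger.error("ancestry failed for %s: %s", s, e)
                samples[s]["errors"].append(f"ancestry: {e}")
                samples[s]["ancestry_assignment"] = None
        anc.results_to_tsv(ancestry_results, outdir / "ancestry.tsv")
        # consistency of uniparental vs biparental origins
        by_id = {r.sample_id: r for r in ancestry_results}
        for s in g.sample_ids:
            r = by_id.get(s)
            if r is None or (y_calls.get(s) is None and mt_calls.get(s) is None):
                samples[s]["lineage_consistency"] = None
                continue
            rep = lin.lineage_consistency(y_calls.get(s), mt_calls.get(s), r)
            samples[s]["lineage_consistency"] = rep.summary
            samples[s]["lineage_flags"] = rep.flags
    else:
        logger.warning("no reference panel configured; ancestry stage skipped")

    # ---- phenotype ---------------------------------------------------
    eye_model, hair_model, guide = _load_models(config)
    eye_preds, hair_preds = [], []
    for s in g.sample_ids:
        try:
            e = phe.predict_eye(g, s, eye_model, p_threshold=config.eye_p_threshold)
            h = phe.predict_hair(g, s, hair_model, guide=guide)
        except Exception as exc:  # noqa: BLE001
            logger.error("phenotype failed for %s: %s", s, exc)
            samples[s]["errors"].append(f"phenotype: {exc}")
            e = phe.PhenotypePrediction(s, "eye", None, None, complete=False)
            h = phe.PhenotypePrediction(s, "hair", None, None, complete=False)
        eye_preds.append(e)
        hair_preds.append(h)
        samples[s]["eye_call"] = e.call if e.call else "no_call"
        samples[s]["hair_call"] = h.call if h.call else "no_call"
    phe.predictions_to_tsv(eye_preds, outdir / "phenotype_eye.tsv")
    phe.predictions_to_tsv(hair_preds, outdir / "phenotype_hair.tsv")

    # ---- kinship -----------------------------------------------------
    pair_rows: list[dict[str, Any]] = []
    if g.n_samples >= 2:
        try:
            results = kin.kinship_all_pairs(
                g, min_overlap=config.kinship_min_overlap, bins=config.kinship_bins
            )
            kin.kinship_to_tsv(results, outdir / "kinship.tsv")
            pair_rows = [
                {
                    "sample_a": r.sample_a,
                    "sample_b": r.sample_b,
                    "pi_hat": r.pi_hat,
                    "mean_ibs": r.mean_ibs,
                    "degree": r.degree,
                }
                for r in results
            ]
        except Exception as e:  # noqa: BLE001
            logger.error("kinship stage failed: %s", e)

    # ---- consolidated report -----------------------------------------
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "n_samples": g.n_samples,
        "n_markers": g.n_markers,
        "samples": samples,
        "pairs": pair_rows,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    report_table(report).to_csv(outdir / "report.tsv", sep="\t", index=False)
    return report


def report_table(report: dict[str, Any]) -> pd.DataFrame:
    """Flatten the per-sample section of a report into one row per sample."""
    rows = []
    for sid in sorted(report["samples"]):
        info = report["samples"][sid]
        row = {"sample_id": sid}
        for key in (
            "missing_frac",
            "qc_pass",
            "sex_call",
            "sex_conflict",
            "ancestry_assignment",
            "nearest_group",
            "y_haplogroup",
            "y_geography",
            "mt_haplogroup",
            "mt_geography",
            "lineage_consistency",
            "eye_call",
            "hair_call",
        ):
            v = info.get(key)
            row[key] = v if v is not None else ""
        q = info.get("q") or {}
        for lab in sorted(q):
            row[f"q_{lab}"] = q[lab]
        row["errors"] = "; ".join(info.get("errors", []))
        rows.append(row)
    return pd.DataFrame(rows)
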