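"""Synthetic genotype simulator.

Generates everything the inference stack consumes, with known ground truth:

* **Reference panels** of K drifted populations under the Balding–Nichols
  model: for marker j an ancestral frequency ``p_j`` is drawn uniformly,
  and population k's frequency ``f_kj ~ Beta(p_j (1-F_k)/F_k,
  (1-p_j)(1-F_k)/F_k)`` — ``F_k`` plays the role of a per-population
  FST-like drift parameter.  Markers are independent (no LD), matching a
  pipeline that works on an LD-pruned subset.
* **Individuals** with an arbitrary admixture vector ``q``: autosomal
  dosage ``~ Binomial(2, sum_k q_k f_kj)``; X-specific markers diploid in
  females, haploid in males but rendered as homozygous diploid calls (the
  way a chip reports them); Y markers present only in males; Y and mtDNA
  states follow one root-to-node path of a haplogroup tree.
* **Relative pairs** of degree 1–4 by gene-dropping founder haplotypes
  through the minimal pedigree realising the degree, with the realised IBD
  sharing recorded.
* **Quality loss**: independent missingness plus symmetric genotype-flip
  errors, emulating degraded or dilute DNA input.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ancestry as _ancestry
from .lineage import FIXTURE_POP_HAPLOGROUPS, HaplogroupTree, fixture_tree
from .panel import GenotypeMatrix, MarkerPanel

#: Population labels used for the default five-population reference,
#: standing in for the continental groups of public reference panels.
DEFAULT_POPULATIONS = ("AFR", "EUR", "EAS", "SAS", "AMR")

#: Frequencies are clamped away from fixation so likelihoods stay finite.
FREQ_FLOOR, FREQ_CEIL = 0.001, 0.999

DEGREE_RELATIONSHIPS = {
    1: "parent_offspring",
    2: "half_sib",
    3: "first_cousin",
    4: "first_cousin_once_removed",
}

#: Expected genome-wide IBD proportion (pi) per degree.
DEGREE_EXPECTED_PI = {1: 0.5, 2: 0.25, 3: 0.125, 4: 0.0625}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic reference panel.

    Defaults emulate five continental populations with drift values spanning
    within- to between-continent differentiation.
    """

    n_populations: int = 5
    n_autosomal: int = 10_000
    n_x: int = 500
    n_y: int | None = None   # None -> the Y fixture tree's marker count
    n_mt: int | None = None  # None -> the mt fixture tree's marker count
    drift: tuple[float, ...] | None = None  # per-population F in (0,1)
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 2:
            raise ValueError("need at least two populations")
        for name in ("n_autosomal", "n_x"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_y", "n_mt"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        drift = self.drift
        if drift is None:
            drift = tuple(np.linspace(0.02, 0.15, self.n_populations))
            object.__setattr__(self, "drift", drift)
        else:
            drift = tuple(float(f) for f in drift)
            object.__setattr__(self, "drift", drift)
        if len(drift) != self.n_populations:
            raise ValueError("one drift value per population required")
        if any(not (0.0 < f < 1.0) for f in drift):
            raise ValueError("drift F must lie strictly inside (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.05 <= lo < hi <= 0.95):
            raise ValueError("ancestral_freq_range must lie within (0.05, 0.95)")

    @property
    def population_labels(self) -> tuple[str, ...]:
        if self.n_populations == len(DEFAULT_POPULATIONS):
            return DEFAULT_POPULATIONS
        return tuple(f"POP{i+1}" for i in range(self.n_populations))


@dataclass
class TrueState:
    """Ground truth attached to every simulated record."""

    sample_id: str
    true_q: np.ndarray
    labels: tuple[str, ...]
    sex: str  # "male" / "female"
    y_haplogroup: str | None = None
    mt_haplogroup: str | None = None
    pedigree_degree: int | None = None  # 0 self, 1-4, None unrelated/singleton
    realised_pi: float | None = None

    def __post_init__(self) -> None:
        self.true_q = np.asarray(self.true_q, dtype=float)
        if abs(self.true_q.sum() - 1.0) > 1e-9:
            raise ValueError("true_q must sum to 1 within 1e-9")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.sex == "female" and self.y_haplogroup is not None:
            raise ValueError("females carry no Y lineage")


@dataclass
class SimulatedReference:
    """A simulated reference panel plus its generating truth.

    ``reference`` is the fitted :class:`~forensnp.ancestry.ReferencePanel`
    whose allele frequencies are the simulator's exact population
    frequencies (the PCA space is fitted from the simulated reference
    genotypes); ``genotypes`` carries the labelled reference cohort.
    """

    config: SimConfig
    reference: _ancestry.ReferencePanel
    genotypes: GenotypeMatrix
    marker_panel: MarkerPanel
    freq_auto: np.ndarray  # K x n_autosomal true frequencies
    freq_x: np.ndarray     # K x n_x true frequencies
    y_tree: HaplogroupTree
    mt_tree: HaplogroupTree
    truth: list[TrueState] = field(default_factory=list)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.config.population_labels


# ---------------------------------------------------------------------------
# marker panel construction
# ---------------------------------------------------------------------------

def _build_marker_panel(
    config: SimConfig, y_tree: HaplogroupTree, mt_tree: HaplogroupTree
) -> MarkerPanel:
    y_tree_markers = y_tree.marker_ids
    mt_tree_markers = mt_tree.marker_ids
    n_y = config.n_y if config.n_y is not None else len(y_tree_markers)
    n_mt = config.n_mt if config.n_mt is not None else len(mt_tree_markers)

    ids: list[str] = []
    classes: list[str] = []
    tags: list[frozenset[str]] = []
    for j in range(config.n_autosomal):
        ids.append(f"auto{j+1}")
        classes.append("autosomal")
        tags.append(frozenset({"ancestry_subset", "kinship_set"}))
    for j in range(config.n_x):
        ids.append(f"x{j+1}")
        classes.append("X_specific")
        tags.append(frozenset())
    for j in range(n_y):
        ids.append(y_tree_markers[j] if j < len(y_tree_markers) else f"ypriv{j+1}")
        classes.append("Y")
        tags.append(frozenset())
    for j in range(n_mt):
        ids.append(mt_tree_markers[j] if j < len(mt_tree_markers) else f"mtpriv{j+1}")
        classes.append("mt")
        tags.append(frozenset())
    return MarkerPanel.from_arrays(ids, classes)


def _balding_nichols_freqs(
    rng: np.random.Generator,
    n_markers: int,
    drift: Sequence[float],
    freq_range: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral frequencies and K x M drifted population frequencies."""
    lo, hi = freq_range
    p_anc = rng.uniform(lo, hi, n_markers)
    rows = []
    for F in drift:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        rows.append(np.clip(rng.beta(a, b), FREQ_FLOOR, FREQ_CEIL))
    return p_anc, np.vstack(rows) if rows else np.empty((0, n_markers))


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def simulate_reference_panel(
    config: SimConfig, n_per_pop: int = 50
) -> SimulatedReference:
    """Simulate a labelled K-population reference cohort and fit its panel.

    Returns a :class:`SimulatedReference` bundling the fitted
    :class:`~forensnp.ancestry.ReferencePanel` (with the simulator's exact
    population frequencies substituted for the sample estimates) and the
    reference :class:`~forensnp.panel.GenotypeMatrix` with population labels
    in its metadata.
    """
    if n_per_pop < 2:
        raise ValueError("n_per_pop must be >= 2 (PCA/frequencies undefined)")
    rng = np.random.default_rng(config.seed)
    y_tree = fixture_tree("Y")
    mt_tree = fixture_tree("mt")
    panel = _build_marker_panel(config, y_tree, mt_tree)
    labels = config.population_labels

    _, freq_auto = _balding_nichols_freqs(
        rng, config.n_autosomal, config.drift, config.ancestral_freq_range
    )
    _, freq_x = _balding_nichols_freqs(
        rng, config.n_x, config.drift, config.ancestral_freq_range
    )

    sample_ids: list[str] = []
    pop_of: list[str] = []
    truth: list[TrueState] = []
    rows: list[np.ndarray] = []
    for k, pop in enumerate(labels):
        for i in range(n_per_pop):
            sid = f"{pop}_{i+1:03d}"
            sex = "male" if i % 2 == 0 else "female"
            q = np.zeros(len(labels))
            q[k] = 1.0
            row, state = _simulate_dosage_row(
                rng,
                panel,
                freq_auto,
                freq_x,
                y_tree,
                mt_tree,
                q=q,
                labels=labels,
                sex=sex,
                sample_id=sid,
                pop_for_lineage=pop,
            )
            rows.append(row)
            truth.append(state)
            sample_ids.append(sid)
            pop_of.append(pop)

    metadata = pd.DataFrame(
        {
            "population": pop_of,
            "reported_sex": [t.sex for t in truth],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    genotypes = GenotypeMatrix(
        sample_ids=sample_ids, panel=panel, dosage=np.vstack(rows), metadata=metadata
    )
    fitted = _ancestry.fit_reference(genotypes, labels=pop_of, n_pc=3)
    # substitute the exact generating frequencies for the sample estimates,
    # matching the fitted panel's (sorted) population order and its marker
    # subset (autosomal markers occupy the first panel columns)
    id_to_col = {m: j for j, m in enumerate(panel.marker_ids)}
    cols = np.array([id_to_col[m] for m in fitted.marker_ids])
    row_order = np.array([list(labels).index(p) for p in fitted.labels])
    fitted = replace(fitted, freqs=freq_auto[np.ix_(row_order, cols)])
    return SimulatedReference(
        config=config,
        reference=fitted,
        genotypes=genotypes,
        marker_panel=panel,
        freq_auto=freq_auto,
        freq_x=freq_x,
        y_tree=y_tree,
        mt_tree=mt_tree,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# individuals
# ---------------------------------------------------------------------------

def _lineage_states(
    tree: HaplogroupTree, node: str, marker_ids: Sequence[str]
) -> np.ndarray:
    on_path = set(tree.path_variants(node))
    tree_markers = set(tree.marker_ids)
    out = np.zeros(len(marker_ids))
    for j, m in enumerate(marker_ids):
        if m in on_path:
            out[j] = 1.0
        elif m not in tree_markers:
            out[j] = 0.0  # private non-tree marker: ancestral
    return out


def _simulate_dosage_row(
    rng: np.random.Generator,
    panel: MarkerPanel,
    freq_auto: np.ndarray,
    freq_x: np.ndarray,
    y_tree: HaplogroupTree,
    mt_tree: HaplogroupTree,
    q: np.ndarray,
    labels: Sequence[str],
    sex: str,
    sample_id: str,
    pop_for_lineage: str | None = None,
    y_haplogroup: str | None = None,
    mt_haplogroup: str | None = None,
) -> tuple[np.ndarray, TrueState]:
    auto_mask = panel.class_mask(["autosomal"])
    x_mask = panel.class_mask(["X_specific"])
    y_mask = panel.class_mask(["Y"])
    mt_mask = panel.class_mask(["mt"])

    row = np.full(panel.n_markers, np.nan)
    mix_auto = q @ freq_auto
    row[auto_mask] = rng.binomial(2, mix_auto).astype(float)
    mix_x = q @ freq_x
    if sex == "female":
        row[x_mask] = rng.binomial(2, mix_x).astype(float)
    else:
        # haploid X rendered as homozygous diploid calls
        row[x_mask] = 2.0 * rng.binomial(1, mix_x).astype(float)

    if pop_for_lineage is None:
        pop_for_lineage = labels[int(np.argmax(q))]

    mt_node = mt_haplogroup or _draw_haplogroup(rng, "mt", pop_for_lineage)
    mt_ids = panel.marker_ids[mt_mask]
    row[mt_mask] = _lineage_states(mt_tree, mt_node, mt_ids)

    y_node = None
    if sex == "male":
        y_node = y_haplogroup or _draw_haplogroup(rng, "Y", pop_for_lineage)
        y_ids = panel.marker_ids[y_mask]
        row[y_mask] = _lineage_states(y_tree, y_node, y_ids)
    # females: Y markers stay missing (zero non-missing Y calls)

    state = TrueState(
        sample_id=sample_id,
        true_q=q,
        labels=tuple(labels),
        sex=sex,
        y_haplogroup=y_node,
        mt_haplogroup=mt_node,
    )
    return row, state


def _draw_haplogroup(rng: np.random.Generator, lineage: str, pop: str) -> str:
    choices = FIXTURE_POP_HAPLOGROUPS.get(pop)
    if choices is None:  # non-default labels: fall back to an African clade
        choices = FIXTURE_POP_HAPLOGROUPS["AFR"]
    return f"{lineage}-{choices[rng.integers(len(choices))]}"


def simulate_individual(
    sim_ref: SimulatedReference,
    q: Sequence[float],
    sex: str,
    seed: int,
    sample_id: str = "query",
    y_haplogroup: str | None = None,
    mt_haplogroup: str | None = None,
) -> tuple[GenotypeMatrix, TrueState]:
    """Simulate one individual with admixture vector ``q`` from the panel."""
    q = np.asarray(q, dtype=float)
    if q.shape[0] != len(sim_ref.labels):
        raise ValueError("q length must equal the number of panel populations")
    if abs(q.sum() - 1.0) > 1e-6 or np.any(q < -1e-9):
        raise ValueError("q must lie on the probability simplex (within 1e-6)")
    q = np.clip(q, 0.0, None)
    q = q / q.sum()
    rng = np.random.default_rng(seed)
    row, state = _simulate_dosage_row(
        rng,
        sim_ref.marker_panel,
        sim_ref.freq_auto,
        sim_ref.freq_x,
        sim_ref.y_tree,
        sim_ref.mt_tree,
        q=q,
        labels=sim_ref.labels,
        sex=sex,
        sample_id=sample_id,
        y_haplogroup=y_haplogroup,
        mt_haplogroup=mt_haplogroup,
    )
    g = GenotypeMatrix(
        sample_ids=[sample_id],
        panel=sim_ref.marker_panel,
        dosage=row[None, :],
        metadata=pd.DataFrame(
            {"reported_sex": [sex]}, index=pd.Index([sample_id], name="sample_id")
        ),
    )
    return g, state


def simulate_cohort(
    sim_ref: SimulatedReference,
    qs: Sequence[Sequence[float]],
    sexes: Sequence[str],
    seed: int,
    id_prefix: str = "S",
) -> tuple[GenotypeMatrix, list[TrueState]]:
    """Simulate several individuals into one genotype matrix."""
    if len(qs) != len(sexes):
        raise ValueError("one sex per q vector required")
    rows, truth, ids = [], [], []
    rng = np.random.default_rng(seed)
    for i, (q, sex) in enumerate(zip(qs, sexes)):
        sid = f"{id_prefix}{i+1:03d}"
        sub_seed = int(rng.integers(2**31 - 1))
        g, state = simulate_individual(sim_ref, q, sex, seed=sub_seed, sample_id=sid)
        rows.append(g.dosage[0])
        truth.append(state)
        ids.append(sid)
    metadata = pd.DataFrame(
        {"reported_sex": [t.sex for t in truth]},
        index=pd.Index(ids, name="sample_id"),
    )
    return (
        GenotypeMatrix(
            sample_ids=ids,
            panel=sim_ref.marker_panel,
            dosage=np.vstack(rows),
            metadata=metadata,
        ),
        truth,
    )


# ---------------------------------------------------------------------------
# relative pairs by gene-dropping
# ---------------------------------------------------------------------------

# Minimal pedigrees: individual -> (father, mother); founders absent.
_PEDIGREES: dict[str, tuple[dict[str, tuple[str, str]], tuple[str, str]]] = {
    "parent_offspring": ({"C": ("F1", "F2")}, ("F1", "C")),
    "full_sib": ({"S1": ("F1", "F2"), "S2": ("F1", "F2")}, ("S1", "S2")),
    "half_sib": ({"A": ("F1", "F2"), "B": ("F1", "F3")}, ("A", "B")),
    "avuncular": (
        {"S1": ("F1", "F2"), "S2": ("F1", "F2"), "N": ("S2", "F3")},
        ("S1", "N"),
    ),
    "grandparent": (
        {"C": ("F1", "F2"), "G": ("C", "F3")},
        ("F1", "G"),
    ),
    "first_cousin": (
        {
            "S1": ("F1", "F2"),
            "S2": ("F1", "F2"),
            "C1": ("S1", "F3"),
            "C2": ("S2", "F4"),
        },
        ("C1", "C2"),
    ),
    "great_avuncular": (
        {
            "S1": ("F1", "F2"),
            "S2": ("F1", "F2"),
            "C": ("S2", "F3"),
            "G": ("C", "F4"),
        },
        ("S1", "G"),
    ),
    "first_cousin_once_removed": (
        {
            "S1": ("F1", "F2"),
            "S2": ("F1", "F2"),
            "C1": ("S1", "F3"),
            "C2": ("S2", "F4"),
            "D": ("C2", "F5"),
        },
        ("C1", "D"),
    ),
}

RELATIONSHIP_DEGREE = {
    "parent_offspring": 1,
    "full_sib": 1,
    "half_sib": 2,
    "avuncular": 2,
    "grandparent": 2,
    "first_cousin": 3,
    "great_avuncular": 3,
    "first_cousin_once_removed": 4,
}


def _gene_drop(
    rng: np.random.Generator,
    pedigree: Mapping[str, tuple[str, str]],
    founder_freqs: np.ndarray,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Drop founder haplotypes through a pedigree, one meiosis per marker.

    Returns per individual a pair of arrays: founder-gamete labels (2 x M)
    and allele values (2 x M).  Markers segregate independently (no
    linkage), consistent with the simulator's no-LD design.
    """
    M = founder_freqs.shape[0]
    founders = sorted(
        {p for parents in pedigree.values() for p in parents} - set(pedigree)
    )
    genomes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    next_label = 0
    for f in founders:
        labels = np.vstack(
            [np.full(M, next_label, dtype=int), np.full(M, next_label + 1, dtype=int)]
        )
        next_label += 2
        values = rng.binomial(1, founder_freqs, size=(2, M)).astype(float)
        genomes[f] = (labels, values)

    resolved = set(founders)
    pending = dict(pedigree)
    while pending:
        progress = False
        for child, (pa, ma) in list(pending.items()):
            if pa in resolved and ma in resolved:
                lab_rows, val_rows = [], []
                for parent in (pa, ma):
                    plab, pval = genomes[parent]
                    pick = rng.integers(0, 2, M)
                    lab_rows.append(plab[pick, np.arange(M)])
                    val_rows.append(pval[pick, np.arange(M)])
                genomes[child] = (np.vstack(lab_rows), np.vstack(val_rows))
                resolved.add(child)
                del pending[child]
                progress = True
        if not progress:
            raise ValueError("pedigree contains a cycle or missing founder")
    return genomes


def _ibd_sharing(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]
) -> float:
    """Realised genome-share: mean over markers of (shared IBD alleles)/2."""
    la, lb = a[0], b[0]
    # maximum matching between the two label pairs at each marker
    direct = (la[0] == lb[0]).astype(int) + (la[1] == lb[1]).astype(int)
    crossed = (la[0] == lb[1]).astype(int) + (la[1] == lb[0]).astype(int)
    ibd = np.maximum(direct, crossed)
    return float(ibd.mean() / 2.0)


def simulate_pedigree(
    sim_ref: SimulatedReference,
    population: str,
    relationship: str,
    seed: int,
    members: Sequence[str] | None = None,
    id_prefix: str = "P",
) -> tuple[GenotypeMatrix, list[TrueState], dict[tuple[str, str], float]]:
    """Gene-drop one pedigree and return genotypes for the chosen members.

    ``relationship`` names a minimal pedigree (see :data:`RELATIONSHIP_DEGREE`)
    or ``"unrelated"`` (two independent draws).  ``members`` defaults to the
    pedigree's canonical pair; any pedigree individual (founders included)
    may be requested.  Returns the genotype matrix, per-member truth, and
    the realised IBD genome-share for every member pair.

    Founders come from a single population; only the autosomal sharing is
    pedigree-faithful — sex, X, Y and mt content are drawn independently per
    member (the pair statistics downstream use autosomes only).
    """
    labels = list(sim_ref.labels)
    if population not in labels:
        raise ValueError(f"unknown population {population!r}")
    k = labels.index(population)
    rng = np.random.default_rng(seed)
    f = sim_ref.freq_auto[k]

    if relationship == "unrelated":
        members = list(members) if members is not None else ["U1", "U2"]
        # independent draws; each member gets unique "founder" labels so the
        # realised IBD bookkeeping stays well defined
        genomes = {}
        for i, m in enumerate(members):
            labels_arr = np.vstack(
                [
                    np.full(f.shape[0], 2 * i, dtype=int),
                    np.full(f.shape[0], 2 * i + 1, dtype=int),
                ]
            )
            values = rng.binomial(1, f, size=(2, f.shape[0])).astype(float)
            genomes[m] = (labels_arr, values)
        degree_out = None
    else:
        if relationship not in _PEDIGREES:
            raise ValueError(f"unknown relationship {relationship!r}")
        pedigree, pair = _PEDIGREES[relationship]
        if members is None:
            members = list(pair)
        genomes = _gene_drop(rng, pedigree, f)
        unknown = [m for m in members if m not in genomes]
        if unknown:
            raise ValueError(f"members not in the {relationship!r} pedigree: {unknown}")
        degree_out = RELATIONSHIP_DEGREE[relationship]

    realised = {
        (a, b): _ibd_sharing(genomes[a], genomes[b])
        for i, a in enumerate(members)
        for b in list(members)[i + 1 :]
    }

    panel = sim_ref.marker_panel
    auto_mask = panel.class_mask(["autosomal"])
    rows, truth, ids = [], [], []
    q = np.zeros(len(labels))
    q[k] = 1.0
    for member in members:
        sid = f"{id_prefix}_{member}"
        sex = "male" if rng.integers(2) == 0 else "female"
        row, state = _simulate_dosage_row(
            rng,
            panel,
            sim_ref.freq_auto,
            sim_ref.freq_x,
            sim_ref.y_tree,
            sim_ref.mt_tree,
            q=q,
            labels=labels,
            sex=sex,
            sample_id=sid,
            pop_for_lineage=population,
        )
        row[auto_mask] = genomes[member][1].sum(axis=0)  # pedigree autosomes
        state.pedigree_degree = degree_out
        rows.append(row)
        truth.append(state)
        ids.append(sid)

    g = GenotypeMatrix(
        sample_ids=ids,
        panel=panel,
        dosage=np.vstack(rows),
        metadata=pd.DataFrame(
            {"reported_sex": [t.sex for t in truth]},
            index=pd.Index(ids, name="sample_id"),
        ),
    )
    return g, truth, realised


def simulate_relative_pair(
    sim_ref: SimulatedReference,
    population: str,
    degree: int | str,
    seed: int,
    relationship: str | None = None,
    id_prefix: str = "P",
) -> tuple[GenotypeMatrix, TrueState, TrueState]:
    """Simulate a relative pair of the given degree (or 'unrelated').

    Degree 1 defaults to parent–offspring, 2 to half-sibs, 3 to first
    cousins, 4 to first cousins once removed; alternatives (full sibs,
    avuncular, grandparent, great-avuncular) are selectable via
    ``relationship``.
    """
    if degree == "unrelated" or degree is None:
        relationship = "unrelated"
    else:
        degree = int(degree)
        if degree not in DEGREE_RELATIONSHIPS:
            raise ValueError("degree must be 1..4 or 'unrelated'")
        relationship = relationship or DEGREE_RELATIONSHIPS[degree]
        if RELATIONSHIP_DEGREE.get(relationship) != degree:
            raise ValueError(
                f"relationship {relationship!r} does not realise degree {degree}"
            )
    g, truth, realised = simulate_pedigree(
        sim_ref, population, relationship, seed, id_prefix=id_prefix
    )
    pi = next(iter(realised.values()))
    for t in truth:
        t.realised_pi = pi
    return g, truth[0], truth[1]


#: Composition of the simulated relatedness study: 81 samples whose 3,240
#: unordered pairs contain 27 first-degree (25 parent-offspring duos plus a
#: father/mother/child trio), 10 second-degree (4 avuncular, 5 grandparent,
#: 1 half-sib), 3 third-degree (2 first-cousin, 1 great-avuncular) and one
#: fourth-degree pair; the remaining 3,199 pairs are unrelated.
RELATEDNESS_STUDY_CLUSTERS: tuple[tuple[str, tuple[str, ...]], ...] = (
    *((f"po{i+1}", ("parent_offspring", "F1", "C")) for i in range(25)),
    ("trio", ("parent_offspring", "F1", "F2", "C")),
    *((f"av{i+1}", ("avuncular", "S1", "N")) for i in range(4)),
    *((f"gp{i+1}", ("grandparent", "F1", "G")) for i in range(5)),
    ("hs1", ("half_sib", "A", "B")),
    *((f"fc{i+1}", ("first_cousin", "C1", "C2")) for i in range(2)),
    ("ga1", ("great_avuncular", "S1", "G")),
    ("fcor1", ("first_cousin_once_removed", "C1", "D")),
)


def simulate_relatedness_study(
    sim_ref: SimulatedReference,
    population: str,
    seed: int,
) -> tuple[GenotypeMatrix, dict[tuple[str, str], str]]:
    """Simulate the 81-sample relatedness study cohort.

    Returns the combined genotype matrix and the expected degree class
    ("first" ... "fourth" / "unrelated") for every unordered sample pair,
    keyed by sorted id pairs.
    """
    rng = np.random.default_rng(seed)
    blocks: list[GenotypeMatrix] = []
    expected: dict[tuple[str, str], str] = {}
    degree_name = {1: "first", 2: "second", 3: "third", 4: "fourth"}
    all_ids: list[str] = []
    for prefix, (relationship, *members) in RELATEDNESS_STUDY_CLUSTERS:
        sub_seed = int(rng.integers(2**31 - 1))
        g, _, realised = simulate_pedigree(
            sim_ref, population, relationship, sub_seed, members=members, id_prefix=prefix
        )
        id_of = dict(zip(members, g.sample_ids))
        for (a, b) in realised:
            sa, sb = sorted((id_of[a], id_of[b]))
            if relationship == "parent_offspring" and {a, b} == {"F1", "F2"}:
                expected[(sa, sb)] = "unrelated"  # the trio's founder couple
            else:
                pedigree, _ = _PEDIGREES[relationship]
                deg = _pedigree_pair_degree(pedigree, a, b)
                expected[(sa, sb)] = degree_name.get(deg, "unrelated")
        blocks.append(g)
        all_ids.extend(g.sample_ids)
    dosage = np.vstack([b.dosage for b in blocks])
    metadata = pd.concat([b.metadata for b in blocks])
    cohort = GenotypeMatrix(
        sample_ids=all_ids,
        panel=sim_ref.marker_panel,
        dosage=dosage,
        metadata=metadata,
    )
    for i, a in enumerate(all_ids):
        for b in all_ids[i + 1 :]:
            key = tuple(sorted((a, b)))
            expected.setdefault(key, "unrelated")
    return cohort, expected


def _pedigree_pair_degree(
    pedigree: Mapping[str, tuple[str, str]], a: str, b: str
) -> int | None:
    """Degree of relationship between two pedigree members via kinship
    coefficients computed by recursion (founders unrelated, non-inbred)."""

    def kinship(x: str, y: str) -> float:
        if x == y:
            return 0.5
        # order so that a non-founder is decomposed first
        for first, second in ((x, y), (y, x)):
            if first in pedigree:
                pa, ma = pedigree[first]
                if second not in _descendants(pedigree, first):
                    return 0.5 * (kinship(pa, second) + kinship(ma, second))
        return 0.0

    pi = 2.0 * kinship(a, b)  # expected genome share for non-inbred pairs
    if pi <= 0.0:
        return None
    degree = round(float(np.log2(1.0 / pi)))
    return int(degree)


def _descendants(pedigree: Mapping[str, tuple[str, str]], node: str) -> set[str]:
    out: set[str] = set()
    frontier = {node}
    while frontier:
        nxt = {c for c, parents in pedigree.items() if set(parents) & frontier}
        nxt -= out
        out |= nxt
        frontier = nxt
    return out


# ---------------------------------------------------------------------------
# quality loss
# ---------------------------------------------------------------------------

def apply_quality_loss(
    g: GenotypeMatrix, missing_rate: float, error_rate: float, seed: int
) -> GenotypeMatrix:
    """Degrade a genotype matrix: random missingness then symmetric flips.

    Each call is independently set missing with probability ``missing_rate``;
    each surviving call is flipped to a uniformly chosen *other* valid
    genotype (diploid {0,1,2}, haploid {0,1}) with probability
    ``error_rate``.  ``missing_rate=0, error_rate=0`` returns an identical
    copy.
    """
    for name, rate in (("missing_rate", missing_rate), ("error_rate", error_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    dosage = g.dosage.copy()
    if missing_rate == 0.0 and error_rate == 0.0:
        return GenotypeMatrix(
            sample_ids=list(g.sample_ids),
            panel=g.panel,
            dosage=dosage,
            metadata=g.metadata.copy(),
        )
    rng = np.random.default_rng(seed)
    called = np.isfinite(dosage)
    if missing_rate > 0.0:
        drop = called & (rng.random(dosage.shape) < missing_rate)
        dosage[drop] = np.nan
        called &= ~drop
    if error_rate > 0.0:
        flip = called & (rng.random(dosage.shape) < error_rate)
        hap = g.panel.haploid_mask[None, :] & np.ones(dosage.shape, dtype=bool)
        # haploid flip: 0 <-> 1
        sel = flip & hap
        dosage[sel] = 1.0 - dosage[sel]
        # diploid flip: to one of the two other categories, uniformly
        sel = flip & ~hap
        shift = rng.integers(1, 3, size=int(sel.sum()))
        dosage[sel] = (dosage[sel] + shift) % 3
    return GenotypeMatrix(
        sample_ids=list(g.sample_ids),
        panel=g.panel,
        dosage=dosage,
        metadata=g.metadata.copy(),
    )


# ---------------------------------------------------------------------------
# truth sidecar
# ---------------------------------------------------------------------------

def truth_to_tsv(truth: Sequence[TrueState], path: str | Path) -> pd.DataFrame:
    rows = []
    for t in truth:
        row: dict[str, object] = {
            "sample_id": t.sample_id,
            "sex": t.sex,
            "y_haplogroup": t.y_haplogroup or "",
            "mt_haplogroup": t.mt_haplogroup or "",
            "pedigree_degree": "" if t.pedigree_degree is None else t.pedigree_degree,
            "realised_pi": "" if t.realised_pi is None else t.realised_pi,
        }
        for lab, v in zip(t.labels, t.true_q):
            row[f"q_{lab}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
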