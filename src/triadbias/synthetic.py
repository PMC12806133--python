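"""Synthetic triad-expression and cell-matrix generators with known truth.

The bulk generator emulates the structure of a multi-stage allohexaploid
expression experiment: each triad carries a latent bias category per stage,
categories evolve along a Markov chain with a high stay probability, and
the observed (A, B, D) fractions scatter around the category centroid with
tunable tightness.  The cell generator builds a toy UMI matrix in which a
requested number of cells each violate exactly one quality-control rule.

Randomness comes from :class:`numpy.random.Generator` (PCG64) seeded from
``config.seed``, so outputs are bit-reproducible across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse

from .bias import CATEGORIES, DEFAULT_CENTROIDS, NOT_EXPRESSED, centroid_array
from .io import CellMatrix, ExpressionMatrix, TriadEntry, TriadSet
from .sc_qc import QCThresholds

#: Default per-category starting proportions: balanced largest, suppressed
#: intermediate, dominant smallest, mirroring the rank structure seen in
#: developmental bulk data of hexaploid wheat.
DEFAULT_PROPORTIONS: Mapping[str, float] = {
    "balanced": 0.40,
    "A.dominant": 0.09,
    "B.dominant": 0.09,
    "D.dominant": 0.09,
    "A.suppressed": 0.12,
    "B.suppressed": 0.12,
    "D.suppressed": 0.09,
}

#: The eight spike developmental stages used as default group labels.
DEFAULT_STAGES: tuple[str, ...] = ("VE", "EL", "IM", "DR", "GP", "FM", "PP", "AM")


def stay_transition_matrix(stay: float = 0.80) -> np.ndarray:
    """7×7 row-stochastic matrix: stay with probability ``stay``, otherwise
    move uniformly to one of the six other categories."""
    if not 0.0 <= stay <= 1.0:
        raise ValueError("stay probability must lie in [0, 1]")
    k = len(CATEGORIES)
    t = np.full((k, k), (1.0 - stay) / (k - 1))
    np.fill_diagonal(t, stay)
    return t


@dataclass
class SimulationConfig:
    """Parameters of the bulk triad simulation.

    ``concentration`` controls the tightness of simulated fractions around
    the category centroid (Dirichlet precision: larger = tighter);
    ``noise_free`` bypasses all sampling noise and emits centroids exactly.
    Triad total TPM is log-normal with the given log-scale mean and sd;
    ``not_expressed_fraction`` of triads are silenced (all-zero) in one
    randomly chosen group each.
    """

    n_triads: int = 20_400
    groups: Sequence[str] = DEFAULT_STAGES
    initial_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    transition_matrix: np.ndarray = field(default_factory=stay_transition_matrix)
    concentration: float = 200.0
    total_expression_log_mean: float = math.log(20.0)
    total_expression_log_sd: float = 1.0
    not_expressed_fraction: float = 0.05
    replicates_per_group: int = 3
    replicate_log_sd: float = 0.1
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_triads < 1:
            raise ValueError("n_triads must be ≥ 1")
        if len(self.groups) < 1 or len(set(self.groups)) != len(self.groups):
            raise ValueError("groups must be non-empty and unique")
        missing = [c for c in CATEGORIES if c not in self.initial_proportions]
        if missing:
            raise ValueError(f"initial_proportions missing categories {missing}")
        total = sum(self.initial_proportions[c] for c in CATEGORIES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"initial_proportions sum {total} != 1")
        t = np.asarray(self.transition_matrix, dtype=float)
        if t.shape != (7, 7):
            raise ValueError("transition_matrix must be 7×7")
        if np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9) or np.any(t < 0):
            raise ValueError("transition_matrix rows must be non-negative and sum to 1")
        self.transition_matrix = t
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")
        if not 0.0 <= self.not_expressed_fraction <= 1.0:
            raise ValueError("not_expressed_fraction must lie in [0, 1]")
        if self.replicates_per_group < 1:
            raise ValueError("replicates_per_group must be ≥ 1")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated data set.

    ``categories``: DataFrame (triad_id × group) of true bias categories,
    with ``not_expressed`` for silenced triad/group cells.
    ``fractions``: long DataFrame with columns triad_id, group, frac_A,
    frac_B, frac_D (expressed triads only).
    ``transition_counts``: for stage series, realized category-transition
    counts per consecutive group pair, keyed ``(from_group, to_group)``.
    """

    categories: pd.DataFrame
    fractions: pd.DataFrame
    transition_counts: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)

    def category_counts(self, group: str) -> dict[str, int]:
        vc = self.categories[group].value_counts()
        return {c: int(vc.get(c, 0)) for c in CATEGORIES + (NOT_EXPRESSED,)}


_ALPHA_FLOOR = 1e-3  # floor for zero centroid components before use as Dirichlet shape


def _sample_fractions(
    cat_idx: np.ndarray, concentration: float, rng: np.random.Generator, noise_free: bool
) -> np.ndarray:
    """Draw simplex fractions around each row's category centroid."""
    _, cent = centroid_array(DEFAULT_CENTROIDS)
    centers = cent[cat_idx]
    if noise_free:
        return centers.copy()
    alpha = np.maximum(centers, _ALPHA_FLOOR)
    alpha /= alpha.sum(axis=1, keepdims=True)
    alpha *= concentration
    gam = rng.gamma(shape=alpha)
    return gam / gam.sum(axis=1, keepdims=True)


def _markov_step(
    state: np.ndarray, transition: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    cum = np.cumsum(transition, axis=1)
    u = rng.random(state.shape[0])
    nxt = (u[:, None] >= cum[state]).sum(axis=1)
    return np.minimum(nxt, len(CATEGORIES) - 1)


def _simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, TriadSet, SyntheticTruth]:
    rng = np.random.default_rng(config.seed)
    n = config.n_triads
    groups = list(config.groups)
    k = len(CATEGORIES)

    triad_ids = [f"t{i + 1:06d}" for i in range(n)]
    entries = [
        TriadEntry(tid, f"{tid}_A", f"{tid}_B", f"{tid}_D") for tid in triad_ids
    ]
    triads = TriadSet(entries)

    # latent category chain
    p0 = np.array([config.initial_proportions[c] for c in CATEGORIES])
    state = rng.choice(k, size=n, p=p0 / p0.sum())
    states = [state]
    for _ in groups[1:]:
        state = _markov_step(states[-1], config.transition_matrix, rng)
        states.append(state)
    state_mat = np.stack(states, axis=1)  # (n, n_groups)

    # silenced triad/group cells
    silenced = np.zeros((n, len(groups)), dtype=bool)
    n_silent = int(round(config.not_expressed_fraction * n))
    if n_silent:
        which = rng.choice(n, size=n_silent, replace=False)
        grp = rng.integers(0, len(groups), size=n_silent)
        silenced[which, grp] = True

    gene_ids = [g for e in entries for g in (e.gene_A, e.gene_B, e.gene_D)]
    sample_ids = [f"{g}_r{j + 1}" for g in groups for j in range(config.replicates_per_group)]
    values = np.zeros((3 * n, len(sample_ids)))

    truth_cat = pd.DataFrame(index=pd.Index(triad_ids, name="triad_id"), columns=groups, dtype=object)
    frac_rows = []
    for gi, group in enumerate(groups):
        fracs = _sample_fractions(state_mat[:, gi], config.concentration, rng, config.noise_free)
        if config.noise_free:
            totals = np.full(n, math.exp(config.total_expression_log_mean))
        else:
            totals = rng.lognormal(
                config.total_expression_log_mean, config.total_expression_log_sd, size=n
            )
        expr = fracs * totals[:, None]  # (n, 3) stage-level TPM
        expr[silenced[:, gi]] = 0.0
        cats = np.array(CATEGORIES, dtype=object)[state_mat[:, gi]]
        cats[silenced[:, gi]] = NOT_EXPRESSED
        truth_cat[group] = cats
        for i in np.flatnonzero(~silenced[:, gi]):
            frac_rows.append((triad_ids[i], group, *fracs[i]))
        for j in range(config.replicates_per_group):
            col = gi * config.replicates_per_group + j
            if config.noise_free:
                rep = expr
            else:
                noise = rng.lognormal(0.0, config.replicate_log_sd, size=expr.shape)
                rep = expr * noise
            values[:, col] = rep.reshape(-1)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        sample_meta=pd.DataFrame(
            {
                "group": [s.rsplit("_r", 1)[0] for s in sample_ids],
                "replicate": [s.rsplit("_r", 1)[1] for s in sample_ids],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )
    fractions = pd.DataFrame(
        frac_rows, columns=["triad_id", "group", "frac_A", "frac_B", "frac_D"]
    )
    truth = SyntheticTruth(categories=truth_cat, fractions=fractions)

    # realized transition counts between consecutive groups
    labels = list(CATEGORIES) + [NOT_EXPRESSED]
    for gi in range(len(groups) - 1):
        a, b = groups[gi], groups[gi + 1]
        tab = pd.DataFrame(0, index=labels, columns=labels)
        pair_counts = truth_cat.groupby([a, b]).size()
        for (fr, to), cnt in pair_counts.items():
            tab.at[fr, to] = int(cnt)
        truth.transition_counts[(a, b)] = tab
    return matrix, triads, truth


def generate_triad_profiles(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, TriadSet, SyntheticTruth]:
    """Simulate triad expression for one or more groups with known truth.

    For the first group each triad's category is drawn from
    ``initial_proportions``; later groups follow the Markov
    ``transition_matrix``.  Fractions are Dirichlet around the category
    centroid, triad totals log-normal, replicates carry multiplicative
    log-normal noise.  Deterministic for a fixed seed.
    """
    return _simulate(config)


def generate_stage_series(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, TriadSet, SyntheticTruth]:
    """Simulate a multi-stage series; requires ≥2 groups.

    Identical to :func:`generate_triad_profiles` but enforces a series and
    guarantees realized transition counts in the truth object.
    """
    if len(config.groups) < 2:
        raise ValueError("a stage series needs at least 2 groups")
    return _simulate(config)


QC_RULES = ("low_umi", "high_umi", "low_genes", "high_genes", "high_mito", "high_chloro")


def generate_cell_matrix(
    n_cells: int,
    n_genes: int,
    qc_violations: Mapping[str, int] | None = None,
    seed: int = 0,
    thresholds: QCThresholds | None = None,
) -> CellMatrix:
    """Build a toy UMI matrix with a known number of single-rule QC violators.

    Every requested violator breaks exactly one rule; all other cells pass
    every rule.  Violator barcodes carry the rule name as a suffix
    (``cell0007-low_umi``), passing cells the suffix ``-pass``, so the
    construction doubles as its own ground truth.  Gene 0 is flagged
    mitochondrial and gene 1 chloroplast; the rest are nuclear.
    """
    thr = thresholds or QCThresholds()
    qc_violations = dict(qc_violations or {})
    for rule in qc_violations:
        if rule not in QC_RULES:
            raise ValueError(f"unknown QC rule {rule!r}")
    n_violators = sum(qc_violations.values())
    if n_violators > n_cells:
        raise ValueError("requested violators exceed n_cells")

    n_nuclear = n_genes - 2
    pass_genes = thr.genes_min + 10  # detected genes of a passing cell
    if n_nuclear < pass_genes:
        raise ValueError(
            f"n_genes={n_genes} too small to construct a passing cell "
            f"({pass_genes} nuclear genes needed)"
        )
    if qc_violations.get("high_genes", 0) and n_nuclear < thr.genes_max + 1:
        raise ValueError(
            f"n_genes={n_genes} too small for a high_genes violator "
            f"({thr.genes_max + 1} nuclear genes needed)"
        )

    rng = np.random.default_rng(seed)
    roles = [rule for rule in QC_RULES for _ in range(qc_violations.get(rule, 0))]
    roles += ["pass"] * (n_cells - n_violators)
    rng.shuffle(roles)

    per_gene = max(2, (thr.umi_min * 4) // pass_genes)  # passing cell: ~4× min UMI

    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []

    def add_cell(i: int, gene_idx: np.ndarray, counts: np.ndarray) -> None:
        rows.extend([i] * len(gene_idx))
        cols.extend(gene_idx.tolist())
        data.extend(counts.tolist())

    nuclear_ids = np.arange(2, n_genes)
    for i, role in enumerate(roles):
        if role == "pass":
            g = rng.choice(nuclear_ids, size=pass_genes, replace=False)
            add_cell(i, g, np.full(pass_genes, per_gene))
        elif role == "low_umi":
            # genes in range but total UMI below the floor
            k = thr.genes_min
            g = rng.choice(nuclear_ids, size=k, replace=False)
            c = np.ones(k, dtype=int)
            budget = thr.umi_min - 1 - k
            c[: min(budget, k)] += 1 if budget > 0 else 0
            if budget > k:
                c[0] += budget - k
            add_cell(i, g, c)
        elif role == "high_umi":
            k = pass_genes
            g = rng.choice(nuclear_ids, size=k, replace=False)
            total = thr.umi_max + k  # strictly exceeds the ceiling
            c = np.full(k, total // k)
            c[0] += total - int(c.sum())
            add_cell(i, g, c)
        elif role == "low_genes":
            k = thr.genes_min - 1
            g = rng.choice(nuclear_ids, size=k, replace=False)
            per = max(2, math.ceil(thr.umi_min / k) + 1)
            add_cell(i, g, np.full(k, per))
        elif role == "high_genes":
            k = thr.genes_max + 1
            g = rng.choice(nuclear_ids, size=k, replace=False)
            add_cell(i, g, np.ones(k, dtype=int))
        elif role == "high_mito":
            g = rng.choice(nuclear_ids, size=pass_genes, replace=False)
            c = np.full(pass_genes, per_gene)
            nuc_total = int(c.sum())
            # mito count pushing the fraction to ~2× the allowed maximum
            mito = math.ceil(2 * thr.mito_max_fraction * nuc_total / (1 - 2 * thr.mito_max_fraction))
            add_cell(i, np.concatenate(([0], g)), np.concatenate(([mito], c)))
        elif role == "high_chloro":
            g = rng.choice(nuclear_ids, size=pass_genes, replace=False)
            c = np.full(pass_genes, per_gene)
            nuc_total = int(c.sum())
            chl = math.ceil(2 * thr.chloro_max_fraction * nuc_total / (1 - 2 * thr.chloro_max_fraction))
            add_cell(i, np.concatenate(([1], g)), np.concatenate(([chl], c)))

    counts = scipy.sparse.csr_matrix(
        (data, (rows, cols)), shape=(n_cells, n_genes), dtype=np.int64
    )
    barcodes = [f"cell{i:04d}-{role}" for i, role in enumerate(roles)]
    genes = [f"gene{j:05d}" for j in range(n_genes)]
    flags = {g: "nuclear" for g in genes}
    flags[genes[0]] = "mitochondrial"
    flags[genes[1]] = "chloroplast"
    return CellMatrix(counts, barcodes, genes, flags)
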