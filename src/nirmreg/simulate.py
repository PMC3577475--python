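"""Synthetic-data generators for end-to-end testing of the pipeline.

Two generators are provided, mirroring the two ways the model is exercised:

* **Block regression data** — a coefficient matrix with known column
  (property) clusters and, nested within each, known row (site) clusters;
  each block shares a coefficient drawn from N(1, 0.25) and observations
  are y* = phi x* + N(0, 0.001).  This probes the co-clustering machinery
  directly, with no sequence layer.
* **Codon sequences** — tip sequences evolved down a phylogeny under a
  GY94-style Markov substitution process with uniform codon equilibrium
  frequencies, where designated site regions bias nonsynonymous rates
  toward conserving or radicalizing a chosen property.  The full pipeline
  (ancestral reconstruction fallback, distance computation, model fit) can
  then be run with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .distances import DistanceDataset, build_dataset, fitch_ancestral_fallback
from .genetics import CodonNeighborhood, PropertyTable, build_codon_neighborhood

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# simulation study 1: block-structured regression data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockScenario:
    """Known co-clustering structure for a coefficient matrix.

    ``column_clusters`` partitions the J property indices; ``row_clusters``
    gives, per column cluster, a partition of the I site indices.  One
    coefficient per (row-cluster, column-cluster) block; Gaussian
    observation noise with variance ``noise_var``.
    """

    column_clusters: tuple[tuple[int, ...], ...]
    row_clusters: tuple[tuple[tuple[int, ...], ...], ...]
    true_phi: tuple[tuple[float, ...], ...]
    noise_var: float = 0.001

    def __post_init__(self) -> None:
        if self.noise_var <= 0:
            raise ValueError("noise_var must be > 0")
        cols = sorted(j for cc in self.column_clusters for j in cc)
        if cols != list(range(len(cols))):
            raise ValueError("column_clusters must partition 0..J-1")
        if len(self.row_clusters) != len(self.column_clusters):
            raise ValueError("one row partition per column cluster required")
        I = len({i for rc in self.row_clusters[0] for i in rc})
        for rcs, phis in zip(self.row_clusters, self.true_phi):
            rows = sorted(i for rc in rcs for i in rc)
            if rows != list(range(I)):
                raise ValueError("row_clusters must partition 0..I-1")
            if len(phis) != len(rcs):
                raise ValueError("one phi per row cluster required")

    @property
    def I(self) -> int:
        return len({i for rc in self.row_clusters[0] for i in rc})

    @property
    def J(self) -> int:
        return sum(len(cc) for cc in self.column_clusters)

    def beta_matrix(self) -> np.ndarray:
        """The true I x J coefficient matrix."""
        beta = np.empty((self.I, self.J))
        for c, cols in enumerate(self.column_clusters):
            for rc, rows in enumerate(self.row_clusters[c]):
                for j in cols:
                    beta[list(rows), j] = self.true_phi[c][rc]
        return beta

    def column_labels(self) -> np.ndarray:
        lab = np.empty(self.J, dtype=int)
        for c, cols in enumerate(self.column_clusters):
            lab[list(cols)] = c
        return lab


def sim1_hyperpriors():
    """Hyperpriors matched to the block-simulation generating process.

    The atom variance prior InvGamma(100, 10) has mean 1/(10*99) ~ 0.001,
    the generating noise variance, and V0 = 0.004 puts the slab coefficient
    variance theta2/V0 at a prior mean of 0.25, the generating coefficient
    variance.  Centering the variance priors on the truth is part of the
    block-simulation study design.
    """
    from .sampler import Hyperpriors

    return Hyperpriors(a_sigma_star=100.0, b_sigma_star=10.0, V0=0.004)


def default_block_scenario(rng: np.random.Generator) -> BlockScenario:
    """Four column clusters over J=16 properties with nested row partitions
    of I=40 sites (3+2+2+1 = 8 blocks); coefficients drawn from N(1, 0.25),
    noise variance 0.001."""
    I, J = 40, 16
    col_sizes = (5, 5, 3, 3)
    row_counts = (3, 2, 2, 1)
    cols = np.arange(J)
    column_clusters = []
    start = 0
    for s in col_sizes:
        column_clusters.append(tuple(cols[start : start + s]))
        start += s
    row_clusters = []
    true_phi = []
    for n_rc in row_counts:
        bounds = np.linspace(0, I, n_rc + 1).astype(int)
        rcs = tuple(
            tuple(range(bounds[r], bounds[r + 1])) for r in range(n_rc)
        )
        row_clusters.append(rcs)
        true_phi.append(tuple(rng.normal(1.0, np.sqrt(0.25), size=n_rc)))
    return BlockScenario(
        tuple(column_clusters), tuple(row_clusters), tuple(true_phi)
    )


def simulate_block_data(
    scenario: BlockScenario,
    rng: np.random.Generator,
    x_star: np.ndarray | None = None,
    x_range: tuple[float, float] = (0.2, 0.9),
) -> tuple[DistanceDataset, dict]:
    """Generate y* = phi_block x* + N(0, noise_var) with known structure.

    When no expected-distance matrix is supplied, x* is drawn uniformly on
    ``x_range``.  ``n_obs`` is constant 1 (no sequence layer).  Returns the
    dataset and a truth dict with the block labels and coefficient matrix.
    """
    I, J = scenario.I, scenario.J
    if x_star is None:
        x_star = rng.uniform(*x_range, size=(I, J))
    else:
        x_star = np.asarray(x_star, dtype=float)
        if x_star.shape != (I, J):
            raise ValueError("x_star shape must match the scenario")
        if (x_star <= 0).any() or (x_star > 1).any():
            raise ValueError("x_star entries must lie in (0, 1]")
    beta = scenario.beta_matrix()
    y_star = beta * x_star + rng.normal(0.0, np.sqrt(scenario.noise_var), (I, J))
    dataset = DistanceDataset(
        sites=tuple(range(1, I + 1)),
        properties=tuple(f"prop{j + 1}" for j in range(J)),
        y_star=y_star,
        x_star=x_star,
        n_obs=np.ones(I, dtype=int),
        zero_mask=(y_star == 0.0),
        bounded=False,
    )
    truth = {
        "beta": beta,
        "column_labels": scenario.column_labels(),
        "row_clusters": scenario.row_clusters,
        "n_column_clusters": len(scenario.column_clusters),
    }
    return dataset, truth


# ---------------------------------------------------------------------------
# simulation study 2: codon sequences under biased substitution regimes
# ---------------------------------------------------------------------------

Regime = Literal["neutral", "conserve", "radicalize"]


@dataclass(frozen=True)
class SeqSimScenario:
    """Codon-sequence simulation with property-biased site regions.

    ``region_map`` holds ``(first_site, last_site, regime, property)``
    entries (1-based, inclusive; property is None for neutral regions);
    regions must be disjoint and cover 1..n_codons.  ``bias_strength``
    exponentially tilts nonsynonymous rates by the standardized property
    distance: conserve multiplies by exp(-bias * d/max_d), radicalize by
    exp(+bias * d/max_d).  The genealogy is a balanced tree over
    ``n_sequences`` tips with uniform ``branch_length``.
    """

    n_sequences: int = 20
    n_codons: int = 90
    region_map: tuple[tuple[int, int, Regime, str | None], ...] = (
        (1, 30, "neutral", None),
        (31, 60, "conserve", "M_v"),
        (61, 90, "radicalize", "h"),
    )
    bias_strength: float = 3.0
    kappa: float = 2.0
    branch_length: float = 0.1

    def __post_init__(self) -> None:
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        covered = []
        for first, last, regime, prop in self.region_map:
            if regime not in ("neutral", "conserve", "radicalize"):
                raise ValueError(f"unknown regime {regime!r}")
            if regime != "neutral" and prop is None:
                raise ValueError("biased regimes need a property")
            covered.extend(range(first, last + 1))
        if sorted(covered) != list(range(1, self.n_codons + 1)):
            raise ValueError("regions must disjointly cover 1..n_codons")

    def regime_of_site(self, site: int) -> tuple[Regime, str | None]:
        for first, last, regime, prop in self.region_map:
            if first <= site <= last:
                return regime, prop
        raise KeyError(site)


def _is_transition(a: str, b: str) -> bool:
    return (a, b) in TRANSITIONS


def baseline_rate_matrix(
    nbhd: CodonNeighborhood, kappa: float = 2.0
) -> np.ndarray:
    """GY94-style 61x61 rate matrix: single-nucleotide neighbors only,
    transition/transversion ratio kappa, uniform codon frequencies; scaled
    to one expected substitution per unit time."""
    sense = nbhd.sense_codons
    index = {c: i for i, c in enumerate(sense)}
    n = len(sense)
    Q = np.zeros((n, n))
    for codon in sense:
        i = index[codon]
        for nb, pos in nbhd.neighbors[codon]:
            rate = kappa if _is_transition(codon[pos], nb[pos]) else 1.0
            Q[i, index[nb]] = rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.mean(np.diag(Q))
    return Q / mean_rate


def tilt_rate_matrix(
    Q: np.ndarray,
    nbhd: CodonNeighborhood,
    table: PropertyTable,
    prop: str,
    bias_strength: float,
    direction: Literal["conserve", "radicalize"],
) -> np.ndarray:
    """Multiply nonsynonymous rates by exp(-+ bias * d/max_d) and
    renormalize each row to its baseline total leaving rate."""
    sense = nbhd.sense_codons
    index = {c: i for i, c in enumerate(sense)}
    sign = -1.0 if direction == "conserve" else 1.0
    maxd = table.max_distance[prop]
    out = Q.copy()
    np.fill_diagonal(out, 0.0)
    for codon in sense:
        i = index[codon]
        aa = nbhd.code[codon]
        for nb, _pos in nbhd.neighbors[codon]:
            aa_nb = nbhd.code[nb]
            if aa_nb == aa:
                continue
            d = table.distance(prop, aa, aa_nb) / maxd if maxd > 0 else 0.0
            out[i, index[nb]] *= np.exp(sign * bias_strength * d)
        base_total = -Q[i, i]
        new_total = out[i].sum()
        if new_total > 0:
            out[i] *= base_total / new_total
    np.fill_diagonal(out, -out.sum(axis=1))
    return out


def balanced_tree(
    n_tips: int, branch_length: float
) -> tuple[dendropy.Tree, list[str]]:
    """Balanced (as even as possible) rooted binary tree with labeled
    internal nodes and uniform branch lengths."""
    counter = {"n": 0}

    def build(tips: list[str]) -> str:
        if len(tips) == 1:
            return f"{tips[0]}:{branch_length}"
        half = len(tips) // 2
        counter["n"] += 1
        label = f"N{counter['n']}"
        left = build(tips[:half])
        right = build(tips[half:])
        return f"({left},{right}){label}:{branch_length}"

    tip_names = [f"T{i + 1}" for i in range(n_tips)]
    newick = build(tip_names)
    # strip the root's branch length; keep its label
    newick = newick.rsplit(":", 1)[0] + ";"
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    return tree, tip_names


def simulate_codon_sequences(
    scenario: SeqSimScenario,
    table: PropertyTable,
    rng: np.random.Generator,
    nbhd: CodonNeighborhood | None = None,
) -> tuple[dendropy.Tree, dict[str, tuple[str, ...]]]:
    """Evolve codon sequences down a balanced tree under the per-region
    substitution regimes; returns the generating tree and tip sequences.

    The root sequence is drawn uniformly over the 61 sense codons.
    Deterministic given the generator state.
    """
    nbhd = nbhd or build_codon_neighborhood()
    sense = nbhd.sense_codons
    Q0 = baseline_rate_matrix(nbhd, scenario.kappa)
    matrices: dict[tuple[Regime, str | None], np.ndarray] = {}
    for _first, _last, regime, prop in scenario.region_map:
        key = (regime, prop)
        if key in matrices:
            continue
        if regime == "neutral" or scenario.bias_strength == 0.0:
            Q = Q0
        else:
            Q = tilt_rate_matrix(Q0, nbhd, table, prop, scenario.bias_strength,
                                 regime)
        matrices[key] = expm(Q * scenario.branch_length)

    site_P = [
        matrices[scenario.regime_of_site(s)]
        for s in range(1, scenario.n_codons + 1)
    ]
    tree, _tips = balanced_tree(scenario.n_sequences, scenario.branch_length)

    def label_of(node: dendropy.Node) -> str:
        return node.taxon.label if node.taxon is not None else node.label

    sequences: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states = rng.integers(0, len(sense), size=scenario.n_codons)
        else:
            parent = sequences[label_of(node.parent_node)]
            states = np.array([
                rng.choice(len(sense), p=site_P[s][parent[s]])
                for s in range(scenario.n_codons)
            ])
        sequences[label_of(node)] = states

    tip_seqs = {
        label_of(leaf): tuple(sense[s] for s in sequences[label_of(leaf)])
        for leaf in tree.leaf_node_iter()
    }
    return tree, tip_seqs


def end_to_end_sim2(
    scenario: SeqSimScenario,
    properties: Sequence[str],
    table: PropertyTable,
    rng: np.random.Generator,
    nbhd: CodonNeighborhood | None = None,
) -> DistanceDataset:
    """Simulate sequences, reconstruct ancestral states with the parsimony
    fallback, and build the distance dataset for the requested properties.

    The reference workflow uses a model-based ancestral reconstruction at
    this step; the parsimony fallback keeps the pipeline self-contained.
    """
    nbhd = nbhd or build_codon_neighborhood()
    sub_table = table.select(list(properties))
    tree, tips = simulate_codon_sequences(scenario, table, rng, nbhd)
    node_seqs = fitch_ancestral_fallback(tree, tips)
    return build_dataset(tree, node_seqs, sub_table, nbhd)
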