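"""Observed and expected per-site amino-acid property distances.

Given a codon alignment that includes reconstructed ancestral sequences at
the internal nodes of a rooted phylogeny, each retained codon site ``i`` and
property ``j`` yields two quantities:

* the *observed* mean distance ``y_{i,j}`` — the mean absolute property-score
  difference over all nonsynonymous substitutions at the site, where a
  substitution is a parent–child node pair whose codons encode different
  amino acids;
* the *expected* mean distance ``x_{i,j}`` — the neutral expectation under
  single-nucleotide mutation,

  ``x_{i,j} = sum_k F_k^i sum_l D_{k,l}^{i,j} / sum_k F_k^i N_k``,

  with ``F_k^i`` the tip-sequence frequency of codon ``k`` at site ``i``,
  ``D_{k,l}`` the absolute score difference to the l-th nonsynonymous
  single-step neighbor of ``k``, and ``N_k`` the neighbor count.

Both are standardized by the property's maximum pairwise score distance, so
all model inputs live in [0, 1].  Sites with alignment gaps anywhere, no
nonsynonymous change on the tree, or no possible nonsynonymous single-step
mutation are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .genetics import CodonNeighborhood, PropertyTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteCodonProfile:
    """Relative codon frequencies among the tip sequences at one site."""

    site_index: int  # 1-based codon position
    codon_freq: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.codon_freq.values())
        if self.codon_freq and not np.isclose(total, 1.0):
            raise ValueError(f"codon frequencies sum to {total}, expected 1")
        if any(f < 0 for f in self.codon_freq.values()):
            raise ValueError("negative codon frequency")


@dataclass(frozen=True)
class SubstitutionEvent:
    """A codon change on one branch at one site."""

    branch: tuple[str, str]  # (parent label, child label)
    site_index: int
    from_codon: str
    to_codon: str
    is_nonsynonymous: bool


@dataclass
class DistanceDataset:
    """Standardized distance matrices feeding the regression model.

    ``y_star`` and ``x_star`` are I x J (sites x properties); ``n_obs`` holds
    the per-site observed nonsynonymous change counts ``n_i^O`` (>= 1 for
    every retained site).  ``zero_mask`` flags exact zeros of ``y_star``
    (substitutions that left the property score unchanged).
    """

    sites: tuple[int, ...]
    properties: tuple[str, ...]
    y_star: np.ndarray
    x_star: np.ndarray
    n_obs: np.ndarray
    zero_mask: np.ndarray
    y: np.ndarray | None = None
    x: np.ndarray | None = None
    #: sequence-derived datasets must satisfy the [0,1] bound; purely
    #: simulated regression data (unbounded Gaussian noise) need not.
    bounded: bool = True

    def __post_init__(self) -> None:
        self.y_star = np.asarray(self.y_star, dtype=float)
        self.x_star = np.asarray(self.x_star, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        self.zero_mask = np.asarray(self.zero_mask, dtype=bool)
        I, J = self.y_star.shape
        if len(self.sites) != I or len(self.properties) != J:
            raise ValueError("shape mismatch between labels and matrices")
        if self.x_star.shape != (I, J) or self.n_obs.shape != (I,):
            raise ValueError("shape mismatch in DistanceDataset")
        if I == 0:
            raise ValueError("empty dataset: no retained sites")
        if (self.n_obs < 1).any():
            raise ValueError("every retained site must have n_obs >= 1")
        if self.bounded and (
            (self.y_star < 0).any()
            or (self.y_star > 1 + 1e-12).any()
            or (self.x_star < 0).any()
            or (self.x_star > 1 + 1e-12).any()
        ):
            raise ValueError("standardized distances must lie in [0, 1]")
        if not np.array_equal(self.zero_mask, self.y_star == 0.0):
            raise ValueError("zero_mask inconsistent with y_star")

    @property
    def n_sites(self) -> int:
        return self.y_star.shape[0]

    @property
    def n_properties(self) -> int:
        return self.y_star.shape[1]


# ---------------------------------------------------------------------------
# expected distances
# ---------------------------------------------------------------------------

def expected_distance(
    profile: SiteCodonProfile,
    prop: str,
    table: PropertyTable,
    nbhd: CodonNeighborhood,
) -> float:
    """Frequency-weighted mean property distance over nonsynonymous
    single-step neighbors; unstandardized.

    Returns NaN when no nonsynonymous single-nucleotide mutation is possible
    at the site (``sum_k F_k N_k = 0``); callers drop such sites.
    """
    if prop not in table.properties:
        raise KeyError(f"unknown property {prop!r}")
    num = 0.0
    den = 0.0
    for codon, freq in profile.codon_freq.items():
        if freq == 0.0:
            continue
        aa = nbhd.code[codon]
        d_sum = sum(
            table.distance(prop, aa, nbhd.code[nb])
            for nb in nbhd.nonsyn_neighbors(codon)
        )
        num += freq * d_sum
        den += freq * nbhd.nonsyn_count[codon]
    if den == 0.0:
        return float("nan")
    return num / den


def site_profile(
    tip_sequences: Mapping[str, Sequence[str]], site_index: int
) -> SiteCodonProfile:
    """Codon frequencies at a (1-based) site from the extant sequences only."""
    counts: dict[str, int] = {}
    for seq in tip_sequences.values():
        codon = seq[site_index - 1]
        counts[codon] = counts.get(codon, 0) + 1
    n = sum(counts.values())
    return SiteCodonProfile(site_index, {c: k / n for c, k in counts.items()})


# ---------------------------------------------------------------------------
# observed distances
# ---------------------------------------------------------------------------

def _edges(tree: dendropy.Tree) -> list[tuple[str, str]]:
    """(parent label, child label) pairs for all branches of a rooted tree."""
    pairs = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        pairs.append((_label(node.parent_node), _label(node)))
    return pairs


def _label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    raise ValueError("tree contains an unlabeled node; ancestral sequences "
                     "cannot be matched")


def substitution_events(
    tree: dendropy.Tree,
    node_sequences: Mapping[str, Sequence[str]],
    site_index: int,
    nbhd: CodonNeighborhood,
) -> list[SubstitutionEvent]:
    """All codon changes at a site over all parent-child branches."""
    events = []
    for parent, child in _edges(tree):
        cp = node_sequences[parent][site_index - 1]
        cc = node_sequences[child][site_index - 1]
        if cp == cc:
            continue
        nonsyn = nbhd.code[cp] != nbhd.code[cc]
        events.append(SubstitutionEvent((parent, child), site_index, cp, cc, nonsyn))
    return events


def observed_distance(
    tree: dendropy.Tree,
    node_sequences: Mapping[str, Sequence[str]],
    site_index: int,
    prop: str,
    table: PropertyTable,
    nbhd: CodonNeighborhood,
) -> tuple[float, int]:
    """Mean |score difference| over nonsynonymous substitution events at a
    site, with the event count ``n_i^O``.

    Returns ``(nan, 0)`` when the site shows no nonsynonymous change.
    """
    dists = []
    for ev in substitution_events(tree, node_sequences, site_index, nbhd):
        if not ev.is_nonsynonymous:
            continue
        aa_from = nbhd.code[ev.from_codon]
        aa_to = nbhd.code[ev.to_codon]
        dists.append(table.distance(prop, aa_from, aa_to))
    if not dists:
        return float("nan"), 0
    return float(np.mean(dists)), len(dists)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _as_codons(seq: str | Sequence[str]) -> tuple[str, ...]:
    if isinstance(seq, str):
        if len(seq) % 3 != 0:
            raise ValueError(f"sequence length {len(seq)} is not a codon multiple")
        return tuple(seq[i : i + 3].upper() for i in range(0, len(seq), 3))
    return tuple(str(c).upper() for c in seq)


def build_dataset(
    tree: dendropy.Tree,
    node_sequences: Mapping[str, str | Sequence[str]],
    table: PropertyTable,
    nbhd: CodonNeighborhood,
) -> DistanceDataset:
    """Full observed/expected distance matrices for every retained site.

    Site filtering, in order: (1) sites where any sequence carries a
    non-sense codon (alignment gap, ambiguity or stop) are removed from all
    sequences; (2) sites with no nonsynonymous change on the tree are
    dropped; (3) sites where no nonsynonymous single-step mutation is
    possible are dropped with a warning.  Distances are standardized by the
    per-property maximum pairwise score distance.
    """
    seqs = {name: _as_codons(s) for name, s in node_sequences.items()}
    labels = {_label(n) for n in tree.preorder_node_iter()}
    missing = labels - set(seqs)
    if missing:
        raise ValueError(f"nodes without sequences: {sorted(missing)}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"sequences of unequal codon length: {sorted(lengths)}")
    n_codons = lengths.pop()
    tip_labels = {_label(leaf) for leaf in tree.leaf_node_iter()}
    tips = {name: seqs[name] for name in tip_labels}

    sense = set(nbhd.sense_codons)
    clean_sites = [
        i + 1
        for i in range(n_codons)
        if all(seq[i] in sense for seq in seqs.values())
    ]
    n_gapped = n_codons - len(clean_sites)
    if n_gapped:
        logger.info("removed %d site(s) with gaps or non-sense codons", n_gapped)

    sites: list[int] = []
    y_rows: list[list[float]] = []
    x_rows: list[list[float]] = []
    n_obs: list[int] = []
    for site in clean_sites:
        profile = site_profile(tips, site)
        x_row = [expected_distance(profile, p, table, nbhd) for p in table.properties]
        if any(np.isnan(v) for v in x_row):
            logger.warning(
                "site %d dropped: no nonsynonymous single-step mutation possible",
                site,
            )
            continue
        aa_pairs = [
            (nbhd.code[ev.from_codon], nbhd.code[ev.to_codon])
            for ev in substitution_events(tree, seqs, site, nbhd)
            if ev.is_nonsynonymous
        ]
        count = len(aa_pairs)
        if count == 0:
            continue
        y_row = [
            float(np.mean([table.distance(p, a, b) for a, b in aa_pairs]))
            for p in table.properties
        ]
        sites.append(site)
        y_rows.append(y_row)
        x_rows.append(x_row)
        n_obs.append(count)

    if not sites:
        raise ValueError("no sites retained: every site lacks a nonsynonymous change")

    y = np.array(y_rows)
    x = np.array(x_rows)
    maxd = np.array([table.max_distance[p] for p in table.properties])
    with np.errstate(invalid="ignore", divide="ignore"):
        y_star = np.where(maxd > 0, y / maxd, 0.0)
        x_star = np.where(maxd > 0, x / maxd, 0.0)
    return DistanceDataset(
        sites=tuple(sites),
        properties=table.properties,
        y_star=y_star,
        x_star=x_star,
        n_obs=np.array(n_obs),
        zero_mask=(y_star == 0.0),
        y=y,
        x=x,
    )


# ---------------------------------------------------------------------------
# parsimony fallback for ancestral sequences
# ---------------------------------------------------------------------------

def fitch_ancestral_fallback(
    tree: dendropy.Tree,
    tip_sequences: Mapping[str, str | Sequence[str]],
) -> dict[str, tuple[str, ...]]:
    """Codon-level Fitch parsimony assignment of ancestral sequences.

    A deterministic test/bootstrap substitute for model-based ancestral
    reconstruction (e.g. PAML's codon models): ties are broken by
    lexicographic codon order, and polytomies are handled by the standard
    intersection-else-union generalization.  Not equivalent to a
    likelihood-based reconstruction.
    """
    tips = {name: _as_codons(s) for name, s in tip_sequences.items()}
    lengths = {len(s) for s in tips.values()}
    if len(lengths) != 1:
        raise ValueError("tip sequences must be aligned (equal codon length)")
    n_codons = lengths.pop()

    nodes = list(tree.postorder_node_iter())
    has_polytomy = any(len(n.child_nodes()) > 2 for n in nodes if n.child_nodes())
    if has_polytomy:
        logger.info("tree has polytomies; Fitch uses intersection-else-union")

    result: dict[str, list[str]] = {_label(n): [] for n in nodes}
    for site in range(n_codons):
        state_sets: dict[int, frozenset[str]] = {}
        for node in nodes:  # postorder: children first
            if node.is_leaf():
                state_sets[id(node)] = frozenset({tips[_label(node)][site]})
            else:
                child_sets = [state_sets[id(c)] for c in node.child_nodes()]
                inter = frozenset.intersection(*child_sets)
                state_sets[id(node)] = inter if inter else frozenset().union(*child_sets)
        # top-down pass, deterministic tie-break by lexicographic order
        assignment: dict[int, str] = {}
        for node in tree.preorder_node_iter():
            options = state_sets[id(node)]
            if node.parent_node is None:
                choice = min(options)
            else:
                parent_state = assignment[id(node.parent_node)]
                choice = parent_state if parent_state in options else min(options)
            assignment[id(node)] = choice
            result[_label(node)].append(choice)
    return {name: tuple(codons) for name, codons in result.items()}


def parsimony_score(
    tree: dendropy.Tree, node_sequences: Mapping[str, Sequence[str]]
) -> int:
    """Number of branches with a codon change, summed over sites."""
    seqs = {k: _as_codons(v) for k, v in node_sequences.items()}
    n_codons = len(next(iter(seqs.values())))
    score = 0
    for parent, child in _edges(tree):
        for i in range(n_codons):
            if seqs[parent][i] != seqs[child][i]:
                score += 1
    return score
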