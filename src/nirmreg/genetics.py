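"""Amino-acid property tables and single-nucleotide codon neighborhoods.

Physicochemical amino-acid properties (hydropathy, volume, polarity, ...)
are each a map from the 20 standard amino acids to a real score.  The
package ships a default table (``data/properties.tsv``) of accession-backed
AAindex properties; users may supply their own TSV with the same schema.

The codon layer enumerates, for every sense codon of a genetic code, the
alternative codons reachable by a single nucleotide substitution.  Changes
to stop codons are ignored; the count of neighbors encoding a *different*
amino acid, ``N_k``, is the per-codon number of possible nonsynonymous
single-step mutations and drives the expected-distance computation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")

#: All 64 codons in lexicographic order.
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)
)


def standard_genetic_code(table_id: int = 1) -> dict[str, str]:
    """Return a codon -> amino acid (or ``'*'`` for stop) map.

    Parameters
    ----------
    table_id:
        NCBI translation-table identifier (1 = standard nuclear code).
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    code = {c.upper(): aa for c, aa in table.forward_table.items()}
    for stop in table.stop_codons:
        code[stop.upper()] = "*"
    missing = set(ALL_CODONS) - set(code)
    if missing:  # pragma: no cover - NCBI tables are complete
        raise ValueError(f"genetic code table {table_id} missing codons: {missing}")
    return code


@dataclass(frozen=True)
class PropertyTable:
    """Scores for an ordered set of amino-acid properties.

    Attributes
    ----------
    properties:
        Ordered property identifiers (unique).
    accessions:
        Optional AAindex accession per property ('' when unknown).
    scores:
        ``scores[prop][aa]`` -> real score, 20 amino acids per property.
    max_distance:
        Per property, the maximum absolute score difference over all 190
        unordered amino-acid pairs — the standardization denominator.
    """

    properties: tuple[str, ...]
    accessions: Mapping[str, str]
    scores: Mapping[str, Mapping[str, float]]
    max_distance: Mapping[str, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.properties)) != len(self.properties):
            raise ValueError("duplicate property identifiers")
        for prop in self.properties:
            aas = set(self.scores[prop])
            if aas != set(AMINO_ACIDS):
                raise ValueError(
                    f"property {prop!r}: expected scores for the 20 standard "
                    f"amino acids, got {sorted(aas)}"
                )
        if self.max_distance is None:
            object.__setattr__(
                self,
                "max_distance",
                {p: _max_pairwise(self.scores[p]) for p in self.properties},
            )

    def distance(self, prop: str, aa1: str, aa2: str) -> float:
        """Absolute score difference between two amino acids."""
        s = self.scores[prop]
        return abs(s[aa1] - s[aa2])

    def select(self, selection: Sequence[str]) -> "PropertyTable":
        """Restrict to ``selection``, in the requested order."""
        unknown = [p for p in selection if p not in self.properties]
        if unknown:
            raise KeyError(f"unknown properties: {unknown}")
        return PropertyTable(
            properties=tuple(selection),
            accessions={p: self.accessions[p] for p in selection},
            scores={p: dict(self.scores[p]) for p in selection},
            max_distance={p: self.max_distance[p] for p in selection},
        )


def _max_pairwise(scores: Mapping[str, float]) -> float:
    vals = sorted(scores[a] for a in AMINO_ACIDS)
    return float(vals[-1] - vals[0])


def load_property_table(
    path: str | Path | None = None,
    selection: Sequence[str] | None = None,
) -> PropertyTable:
    """Load a property table from TSV (default: the shipped AAindex subset).

    The TSV must have columns ``property``, ``accession`` (may be empty) and
    one column per one-letter amino-acid code.  Rows with missing amino-acid
    columns, duplicate identifiers or non-numeric scores are rejected with
    the offending row named.
    """
    if path is None:
        with resources.as_file(
            resources.files("nirmreg").joinpath("data/properties.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    if "property" not in df.columns:
        raise ValueError("property table must have a 'property' column")
    missing_cols = [aa for aa in AMINO_ACIDS if aa not in df.columns]
    if missing_cols:
        raise ValueError(f"property table missing amino-acid columns: {missing_cols}")

    props: list[str] = []
    accessions: dict[str, str] = {}
    scores: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        prop = str(row["property"]).strip()
        if prop in scores:
            raise ValueError(f"duplicate property identifier {prop!r}")
        row_scores: dict[str, float] = {}
        for aa in AMINO_ACIDS:
            raw = row[aa]
            try:
                row_scores[aa] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"property {prop!r}: non-numeric score {raw!r} for {aa}"
                ) from None
        props.append(prop)
        acc = row.get("accession", "")
        accessions[prop] = "" if pd.isna(acc) else str(acc).strip()
        scores[prop] = row_scores

    table = PropertyTable(tuple(props), accessions, scores)
    if selection is not None:
        table = table.select(selection)
    return table


@dataclass(frozen=True)
class CodonNeighborhood:
    """Single-nucleotide mutation structure of the sense codons.

    ``neighbors[k]`` lists ``(codon, position)`` pairs reachable from sense
    codon ``k`` by one nucleotide substitution, stop codons excluded (each
    codon has exactly 9 single-nucleotide variants before stop removal).
    ``nonsyn_count[k]`` is ``N_k``, the number of those neighbors encoding a
    different amino acid.
    """

    code: Mapping[str, str]
    sense_codons: tuple[str, ...]
    neighbors: Mapping[str, tuple[tuple[str, int], ...]]
    nonsyn_count: Mapping[str, int]

    def nonsyn_neighbors(self, codon: str) -> tuple[str, ...]:
        """Neighbor codons of ``codon`` encoding a different amino acid."""
        aa = self.code[codon]
        return tuple(c for c, _ in self.neighbors[codon] if self.code[c] != aa)


def build_codon_neighborhood(
    genetic_code: Mapping[str, str] | None = None,
) -> CodonNeighborhood:
    """Enumerate single-nucleotide codon neighborhoods for a genetic code.

    Parameters
    ----------
    genetic_code:
        Map of all 64 codons to amino acids (``'*'`` for stop).  Defaults to
        the standard nuclear code.
    """
    code = dict(standard_genetic_code() if genetic_code is None else genetic_code)
    if set(code) != set(ALL_CODONS):
        raise ValueError("genetic code must cover all 64 codons")
    sense = tuple(c for c in ALL_CODONS if code[c] != "*")
    neighbors: dict[str, tuple[tuple[str, int], ...]] = {}
    nonsyn: dict[str, int] = {}
    for codon in sense:
        nbrs: list[tuple[str, int]] = []
        n_k = 0
        for pos in range(3):
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if code[alt] == "*":
                    continue
                nbrs.append((alt, pos))
                if code[alt] != code[codon]:
                    n_k += 1
        neighbors[codon] = tuple(nbrs)
        nonsyn[codon] = n_k
    return CodonNeighborhood(code, sense, neighbors, nonsyn)


def translate_codon(codon: str, code: Mapping[str, str]) -> str:
    """Translate a codon; raises on non-sense codons (gaps, ambiguity, stop)."""
    aa = code.get(codon.upper())
    if aa is None or aa == "*":
        raise ValueError(f"not a sense codon: {codon!r}")
    return aa
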