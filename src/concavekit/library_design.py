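"""Degenerate-codon combinatorial library design and design-metric filtering.

A degenerate codon is a triplet of IUPAC nucleotide codes (e.g. NNK, RAC)
that encodes a set of amino acids; combinatorial affinity-maturation
libraries place one such codon at each varied position.  Codon selection is
a brute-force search over all 15^3 = 3375 degenerate triplets, ranked by
(fewest off-target amino acids, smallest DNA degeneracy, lexicographic
triplet) among those covering the desired amino-acid set.

Library DNA diversity (the product of per-position codon degeneracies) is
checked against a transformation capacity of ~1e7, the practical limit of a
yeast electroporation; protein diversity is reported alongside.

``apply_design_filters`` applies the interface-design metric thresholds
(ddG <= -40, contact molecular surface >= 400, pAE <= 10, optionally mean
plDDT >= 80) to an externally produced metrics table.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "IUPAC_NUCLEOTIDES",
    "STOP",
    "DegenerateCodon",
    "LibrarySpec",
    "FilterRule",
    "FilterSpec",
    "FilterReport",
    "LibraryDesignError",
    "CoverageError",
    "expand_degenerate_codon",
    "design_degenerate_codon",
    "build_library",
    "apply_design_filters",
    "library_to_tsv",
]

IUPAC_NUCLEOTIDES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
STOP = "*"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
_CODON_TO_AA.update({codon: STOP for codon in _TABLE.stop_codons})

CANONICAL_AAS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class LibraryDesignError(Exception):
    """Invalid input to library design."""


class CoverageError(LibraryDesignError):
    """No degenerate codon covers the desired set under the constraints."""


@dataclass(frozen=True)
class DegenerateCodon:
    triplet: str
    dna_degeneracy: int
    encoded_aas: Mapping[str, int]  # amino acid (or ``*``) -> codon multiplicity

    @property
    def distinct_aas(self) -> frozenset[str]:
        return frozenset(a for a in self.encoded_aas if a != STOP)

    @property
    def encodes_stop(self) -> bool:
        return STOP in self.encoded_aas


@dataclass
class LibrarySpec:
    positions: list[tuple[int, str, frozenset[str], DegenerateCodon]]
    dna_diversity: int
    protein_diversity: int
    capacity: int
    fits_capacity: bool


@dataclass(frozen=True)
class FilterRule:
    column: str
    op: str  # "le" or "ge"
    bound: float

    def passes(self, value: float) -> bool:
        return value <= self.bound if self.op == "le" else value >= self.bound


@dataclass
class FilterSpec:
    """Interface-design admission thresholds, in application order."""

    rules: list[FilterRule] = field(
        default_factory=lambda: [
            FilterRule("ddg", "le", -40.0),
            FilterRule("contact_molecular_surface", "ge", 400.0),
            FilterRule("pae", "le", 10.0),
        ]
    )

    @classmethod
    def with_plddt(cls, plddt_min: float = 80.0) -> "FilterSpec":
        spec = cls()
        spec.rules.append(FilterRule("plddt", "ge", plddt_min))
        return spec


@dataclass
class FilterReport:
    survivors: pd.DataFrame
    attrition: dict[str, int]      # rows failing each rule, in application order
    missing: dict[str, int]        # rows with missing values per rule
    boundary: dict[str, int]       # rows sitting exactly on a rule's bound


@lru_cache(maxsize=4096)
def expand_degenerate_codon(triplet: str) -> DegenerateCodon:
    """Enumerate a degenerate triplet against the standard genetic code."""
    triplet = triplet.upper()
    if len(triplet) != 3:
        raise LibraryDesignError(f"codon must have 3 symbols, got {triplet!r}")
    sets = []
    for ch in triplet:
        if ch not in IUPAC_NUCLEOTIDES:
            raise LibraryDesignError(f"invalid IUPAC nucleotide symbol {ch!r} in {triplet!r}")
        sets.append(IUPAC_NUCLEOTIDES[ch])
    encoded: Counter[str] = Counter()
    for bases in itertools.product(*sets):
        encoded[_CODON_TO_AA["".join(bases)]] += 1
    degeneracy = len(sets[0]) * len(sets[1]) * len(sets[2])
    return DegenerateCodon(
        triplet=triplet, dna_degeneracy=degeneracy, encoded_aas=dict(encoded)
    )


def design_degenerate_codon(
    desired: Sequence[str] | frozenset[str], forbid_stop: bool = True
) -> list[DegenerateCodon]:
    """Ranked covering codons for a desired amino-acid set.

    All 3375 degenerate triplets are enumerated; those whose encoded set
    contains every desired amino acid (and no stop, if forbidden) are ranked
    by fewest off-target distinct amino acids, then smallest DNA degeneracy,
    then lexicographic triplet.
    """
    desired_set = frozenset(a.upper() for a in desired)
    if not desired_set:
        raise LibraryDesignError("desired amino-acid set is empty")
    bad = desired_set - CANONICAL_AAS
    if bad:
        raise LibraryDesignError(f"non-canonical amino acid(s): {sorted(bad)}")

    symbols = sorted(IUPAC_NUCLEOTIDES)
    covering: list[DegenerateCodon] = []
    best_with_stop: DegenerateCodon | None = None
    for combo in itertools.product(symbols, repeat=3):
        codon = expand_degenerate_codon("".join(combo))
        if not desired_set <= codon.distinct_aas:
            continue
        if forbid_stop and codon.encodes_stop:
            key = (len(codon.distinct_aas - desired_set), codon.dna_degeneracy, codon.triplet)
            if best_with_stop is None or key < (
                len(best_with_stop.distinct_aas - desired_set),
                best_with_stop.dna_degeneracy,
                best_with_stop.triplet,
            ):
                best_with_stop = codon
            continue
        covering.append(codon)
    if not covering:
        hint = (
            f"; best stop-permitting alternative: {best_with_stop.triplet}"
            if best_with_stop is not None
            else ""
        )
        raise CoverageError(
            f"no degenerate codon covers {sorted(desired_set)} without a stop{hint}"
        )
    covering.sort(
        key=lambda c: (len(c.distinct_aas - desired_set), c.dna_degeneracy, c.triplet)
    )
    return covering


def build_library(
    parent_sequence: str,
    desired_sets: Mapping[int, Sequence[str] | frozenset[str]],
    capacity: int = 10_000_000,
    forbid_stop: bool = True,
    require_parent: bool = True,
) -> LibrarySpec:
    """Choose the top-ranked codon per varied position and account diversity.

    Positions are 1-based along the parent.  By default each desired set must
    retain the parent residue (combinatorial libraries keep the parent
    identity available at every varied position); relax with
    ``require_parent=False``.  A capacity violation is flagged, not fatal.
    """
    positions: list[tuple[int, str, frozenset[str], DegenerateCodon]] = []
    errors = []
    dna_div = 1
    prot_div = 1
    for pos in sorted(desired_sets):
        if not 1 <= pos <= len(parent_sequence):
            raise LibraryDesignError(
                f"position {pos} outside parent (length {len(parent_sequence)})"
            )
        parent_aa = parent_sequence[pos - 1]
        desired = frozenset(a.upper() for a in desired_sets[pos])
        if require_parent and parent_aa not in desired:
            raise LibraryDesignError(
                f"position {pos}: desired set {sorted(desired)} omits parent {parent_aa} "
                "(pass require_parent=False to allow)"
            )
        try:
            codon = design_degenerate_codon(desired, forbid_stop=forbid_stop)[0]
        except CoverageError as exc:
            errors.append(f"position {pos}: {exc}")
            continue
        positions.append((pos, parent_aa, desired, codon))
        dna_div *= codon.dna_degeneracy
        prot_div *= len(codon.distinct_aas)
    if errors:
        raise CoverageError("; ".join(errors))
    return LibrarySpec(
        positions=positions,
        dna_diversity=dna_div,
        protein_diversity=prot_div,
        capacity=capacity,
        fits_capacity=dna_div <= capacity,
    )


def apply_design_filters(metrics: pd.DataFrame, spec: FilterSpec | None = None) -> FilterReport:
    """Keep rows passing every rule; report attrition per rule in order.

    Missing values fail their rule and are counted separately; rows sitting
    exactly on a bound pass (inclusive thresholds) but are flagged.
    """
    spec = spec or FilterSpec()
    for rule in spec.rules:
        if rule.column not in metrics.columns:
            raise KeyError(
                f"metrics table lacks column {rule.column!r}; has {list(metrics.columns)}"
            )
    alive = pd.Series(True, index=metrics.index)
    attrition: dict[str, int] = {}
    missing: dict[str, int] = {}
    boundary: dict[str, int] = {}
    for rule in spec.rules:
        col = metrics[rule.column]
        isna = col.isna()
        ok = col.apply(lambda v: (not pd.isna(v)) and rule.passes(float(v)))
        missing[rule.column] = int((alive & isna).sum())
        attrition[rule.column] = int((alive & ~ok).sum())
        boundary[rule.column] = int((alive & (col == rule.bound)).sum())
        alive &= ok
    return FilterReport(
        survivors=metrics[alive].copy(),
        attrition=attrition,
        missing=missing,
        boundary=boundary,
    )


def library_to_tsv(spec: LibrarySpec, path) -> None:
    from pathlib import Path

    rows = ["position\tparent_aa\tdesired\tcodon\tdna_degeneracy\tencoded\textras"]
    for pos, parent_aa, desired, codon in spec.positions:
        extras = sorted(codon.distinct_aas - desired)
        rows.append(
            f"{pos}\t{parent_aa}\t{''.join(sorted(desired))}\t{codon.triplet}"
            f"\t{codon.dna_degeneracy}\t{''.join(sorted(codon.distinct_aas))}"
            f"\t{''.join(extras) or '-'}"
        )
    rows.append(
        f"# dna_diversity={spec.dna_diversity} protein_diversity={spec.protein_diversity} "
        f"capacity={spec.capacity} fits_capacity={spec.fits_capacity}"
    )
    Path(path).write_text("\n".join(rows) + "\n")
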