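"""Site-saturation mutagenesis analysis.

Deep-sequencing count tables (position x amino acid, for a selected and a
reference pool) are turned into log2 enrichment matrices and per-position
Shannon-entropy conservation profiles.  Low entropy marks conserved
positions (typically core and interfacial residues of a binder), high
entropy marks tolerant surface positions.

Conventions: enrichment is log2 of whole-pool-normalized frequencies with a
pseudocount of 1 (standard deep-mutational-scanning practice; both exposed
as parameters); entropy is computed from selected-pool frequencies.
Read-level processing (merging, alignment, barcode extraction) is out of
scope — counts are the input boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "MAX_ENTROPY_BITS",
    "SsmCounts",
    "EnrichmentMatrix",
    "EntropyProfile",
    "SsmError",
    "UndefinedEntropyError",
    "log_enrichment",
    "position_entropy",
    "conservation_classes",
    "simulate_ssm_counts",
    "read_counts_tsv",
    "write_matrix_tsv",
    "write_entropy_tsv",
    "entropy_to_bfactor_pdb",
    "plot_enrichment_heatmap",
]

# canonical amino acids in fixed alphabetical order
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
MAX_ENTROPY_BITS = math.log2(20)


class SsmError(Exception):
    """Invalid SSM count input."""


class UndefinedEntropyError(SsmError):
    """A position has zero total counts and zero pseudocount."""


@dataclass
class SsmCounts:
    """Selected/reference count matrices aligned to a parent sequence.

    Matrices are (length x 20) non-negative integers with columns in
    :data:`AA_ALPHABET` order; positions are 1-based along the parent.
    """

    parent_sequence: str
    counts_selected: np.ndarray
    counts_reference: np.ndarray

    def __post_init__(self) -> None:
        sel = np.asarray(self.counts_selected)
        ref = np.asarray(self.counts_reference)
        shape = (len(self.parent_sequence), len(AA_ALPHABET))
        if sel.shape != shape or ref.shape != shape:
            raise SsmError(
                f"count matrices must have shape {shape}; got {sel.shape} / {ref.shape}"
            )
        if (sel < 0).any() or (ref < 0).any():
            raise SsmError("counts must be non-negative")
        self.counts_selected = sel.astype(float)
        self.counts_reference = ref.astype(float)

    def swapped(self) -> "SsmCounts":
        return SsmCounts(self.parent_sequence, self.counts_reference, self.counts_selected)


@dataclass
class EnrichmentMatrix:
    values: np.ndarray  # (length, 20) log2 enrichments
    pseudocount: float
    parent_sequence: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.RangeIndex(1, len(self.parent_sequence) + 1, name="position"),
            columns=list(AA_ALPHABET),
        )


@dataclass
class EntropyProfile:
    entropy_bits: np.ndarray  # per position, in [0, log2 20]
    source: str = "selected-frequency"


def log_enrichment(counts: SsmCounts, pseudocount: float = 1.0) -> EnrichmentMatrix:
    """log2( f_sel / f_ref ) with whole-pool frequency normalization.

    f = (count + pseudocount) / sum over the whole matrix of the same; a
    positive pseudocount keeps every entry finite.
    """
    if pseudocount < 0:
        raise SsmError("pseudocount must be >= 0")
    sel = counts.counts_selected + pseudocount
    ref = counts.counts_reference + pseudocount
    if counts.counts_reference.sum() <= 0 and pseudocount == 0:
        raise SsmError("reference pool is empty and pseudocount is 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.log2((sel / sel.sum()) / (ref / ref.sum()))
    return EnrichmentMatrix(values=values, pseudocount=pseudocount, parent_sequence=counts.parent_sequence)


def position_entropy(
    counts: SsmCounts,
    pool: Literal["selected", "reference"] = "selected",
    pseudocount: float = 0.0,
) -> EntropyProfile:
    """Per-position Shannon entropy (bits) of amino-acid frequencies."""
    mat = counts.counts_selected if pool == "selected" else counts.counts_reference
    mat = mat + pseudocount
    totals = mat.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise UndefinedEntropyError(
            f"position {zero[0] + 1}: zero total counts with pseudocount {pseudocount}"
        )
    q = mat / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * np.log2(q), 0.0)
    return EntropyProfile(entropy_bits=-terms.sum(axis=1), source=f"{pool}-frequency")


def conservation_classes(
    profile: EntropyProfile, quantiles: tuple[float, float] = (0.25, 0.75)
) -> list[str]:
    """Per-position class by entropy quantile within the profile.

    Strictly below the low quantile -> ``conserved``; strictly above the high
    quantile -> ``variable``; otherwise ``intermediate`` (a constant profile
    therefore collapses to all-intermediate).
    """
    h = np.asarray(profile.entropy_bits, dtype=float)
    if h.size == 0:
        raise SsmError("empty entropy profile")
    lo, hi = np.quantile(h, quantiles[0]), np.quantile(h, quantiles[1])
    return [
        "conserved" if x < lo else ("variable" if x > hi else "intermediate")
        for x in h
    ]


def simulate_ssm_counts(
    parent_sequence: str,
    conserved_positions: Sequence[int],
    depth_per_position: int = 10_000,
    conserved_penalty: float = 0.05,
    fitness_sigma: float = 0.3,
    seed: int = 0,
) -> tuple[SsmCounts, np.ndarray]:
    """Synthetic FACS-sorting experiment for an SSM library.

    The reference pool draws a multinomial of ``depth_per_position`` reads at
    each position over a mildly uneven variant distribution.  Each variant
    carries a log-normal fitness; at conserved positions every substitution
    is penalized by ``conserved_penalty`` while the parent residue keeps
    fitness 1.  The selected pool is a multinomial over fitness-reweighted
    reference frequencies.  Returns the counts plus the ground-truth fitness
    matrix so recovery can be checked against it.
    """
    rng = np.random.default_rng(seed)
    L, A = len(parent_sequence), len(AA_ALPHABET)
    aa_index = {a: i for i, a in enumerate(AA_ALPHABET)}
    conserved = set(int(p) for p in conserved_positions)

    fitness = np.exp(rng.normal(0.0, fitness_sigma, size=(L, A)))
    for p in range(L):
        parent_aa = parent_sequence[p]
        if parent_aa not in aa_index:
            raise SsmError(f"parent residue {parent_aa!r} at position {p + 1} is not canonical")
        if (p + 1) in conserved:
            fitness[p, :] = conserved_penalty * np.exp(
                rng.normal(0.0, 0.1 * fitness_sigma, size=A)
            )
        fitness[p, aa_index[parent_aa]] = 1.0

    ref_prob = rng.dirichlet(np.full(A, 20.0), size=L)
    counts_ref = np.stack(
        [rng.multinomial(depth_per_position, ref_prob[p]) for p in range(L)]
    )
    sel_prob = ref_prob * fitness
    sel_prob /= sel_prob.sum(axis=1, keepdims=True)
    counts_sel = np.stack(
        [rng.multinomial(depth_per_position, sel_prob[p]) for p in range(L)]
    )
    return SsmCounts(parent_sequence, counts_sel, counts_ref), fitness


def read_counts_tsv(path: str | Path, parent_sequence: str | None = None) -> SsmCounts:
    """Read counts from TSV: long form (position, aa, pool, count) or matrix
    form (rows ``selected``/``reference`` x position, columns amino acids)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower() for c in df.columns}
    if {"position", "aa", "pool", "count"} <= cols:
        df.columns = [c.lower() for c in df.columns]
        L = int(df["position"].max())
        if parent_sequence is None:
            if "parent_aa" in cols:
                parent = ["X"] * L
                for _, row in df.iterrows():
                    parent[int(row["position"]) - 1] = str(row["parent_aa"])
                parent_sequence = "".join(parent)
            else:
                raise SsmError("long-form TSV without parent_aa needs parent_sequence")
        mats = {
            "selected": np.zeros((L, len(AA_ALPHABET))),
            "reference": np.zeros((L, len(AA_ALPHABET))),
        }
        aa_index = {a: i for i, a in enumerate(AA_ALPHABET)}
        for _, row in df.iterrows():
            pool = str(row["pool"]).lower()
            if pool not in mats:
                raise SsmError(f"unknown pool {pool!r} (expected selected/reference)")
            mats[pool][int(row["position"]) - 1, aa_index[str(row["aa"])]] = row["count"]
        return SsmCounts(parent_sequence, mats["selected"], mats["reference"])
    if {"pool", "position"} <= cols and set(AA_ALPHABET) <= set(df.columns):
        df.columns = [c if c in AA_ALPHABET else c.lower() for c in df.columns]
        sel = df[df["pool"].str.lower() == "selected"].sort_values("position")
        ref = df[df["pool"].str.lower() == "reference"].sort_values("position")
        if parent_sequence is None:
            raise SsmError("matrix-form TSV needs parent_sequence")
        return SsmCounts(
            parent_sequence,
            sel[list(AA_ALPHABET)].to_numpy(),
            ref[list(AA_ALPHABET)].to_numpy(),
        )
    raise SsmError(
        "unrecognized counts TSV: need (position, aa, pool, count) long form or "
        "(pool, position, A..Y) matrix form"
    )


def write_matrix_tsv(matrix: EnrichmentMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.4f")


def write_entropy_tsv(
    profile: EntropyProfile, path: str | Path, parent_sequence: str | None = None
) -> None:
    rows = ["position\tparent_aa\tentropy_bits"]
    for i, h in enumerate(profile.entropy_bits, start=1):
        aa = parent_sequence[i - 1] if parent_sequence else "X"
        rows.append(f"{i}\t{aa}\t{h:.4f}")
    Path(path).write_text("\n".join(rows) + "\n")


def entropy_to_bfactor_pdb(model, profile: EntropyProfile, path: str | Path) -> None:
    """Write the model as PDB with per-residue entropy in the B-factor
    column, for structure coloring.  Positions index the chain's residues in
    order (1-based); residues beyond the profile get B = 0."""
    from .structure_io import StructureModel  # local import to avoid cycles

    assert isinstance(model, StructureModel)
    order: dict[tuple[str, int], int] = {}
    for cid in model.chains:
        for k, (chain, num, _) in enumerate(model.residues(cid), start=1):
            order[(chain, num)] = k
    lines = []
    for i, a in enumerate(model.atoms, start=1):
        pos = order[(a.chain_id, a.residue_number)]
        b = profile.entropy_bits[pos - 1] if pos <= len(profile.entropy_bits) else 0.0
        x, y, z = a.coords
        name = f" {a.name:<3s}" if len(a.element) == 1 and len(a.name) <= 3 else f"{a.name:<4s}"
        lines.append(
            f"ATOM  {i:5d} {name} {a.residue_name:<3s} {a.chain_id[:1]}"
            f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
            f"          {a.element:>2s}"
        )
    lines += ["TER", "END"]
    Path(path).write_text("\n".join(lines) + "\n")


def plot_enrichment_heatmap(matrix: EnrichmentMatrix, path: str | Path) -> None:
    """Red/blue heatmap of log enrichments (enriched red, depleted blue)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = matrix.to_frame()
    vmax = max(1.0, np.abs(frame.to_numpy()).max())
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.25 * len(frame)), 5.0), constrained_layout=True
    )
    im = ax.imshow(
        frame.to_numpy().T, cmap="bwr", vmin=-vmax, vmax=vmax, aspect="auto"
    )
    ax.set_yticks(range(len(AA_ALPHABET)), list(AA_ALPHABET))
    ax.set_xlabel("position")
    ax.set_ylabel("amino acid")
    fig.colorbar(im, ax=ax, label="log2 enrichment")
    fig.savefig(path, dpi=150)
    plt.close(fig)
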