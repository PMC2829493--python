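"""Corpus-level descriptive statistics over predicted che operons.

Covers the questions a comparative survey asks of an operon catalogue:
which compressed operon types are most frequent, which species possess a
complete operon (all of cheA, B, R, W, Y) or a small set of operons that is
jointly complete, how often che genes occur in multiple copies, and which
ordered gene pairs are adjacent within operons.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import CORE_TYPES
from .operon_model import Operon

__all__ = [
    "AdjacencyMatrix",
    "SpeciesCompleteness",
    "compress_operon",
    "operon_type_frequencies",
    "classify_completeness",
    "classify_corpus_completeness",
    "adjacency_matrix",
    "relative_from_counts",
    "multiplicity_summary",
]

CORE_SET = frozenset(CORE_TYPES)


def compress_operon(operon: Operon) -> tuple[frozenset, Counter]:
    """Support set and per-type copy counts of an operon's core che genes."""
    composition = operon.composition
    return frozenset(composition), composition


def _by_species(operons: Iterable[Operon]) -> dict[str, list[Operon]]:
    grouped: dict[str, list[Operon]] = {}
    for op in operons:
        grouped.setdefault(op.species_id, []).append(op)
    return grouped


def operon_type_frequencies(operons: Sequence[Operon]) -> pd.DataFrame:
    """Rank compressed operon types by operon count and by species count.

    Returns a frame with one row per observed compressed type (key in fixed
    A,B,R,W,Y order, e.g. ``'ABWY'``), carrying the number of operons of
    that type, its relative frequency among all operons, the number of
    species possessing at least one such operon, and the relative frequency
    among species. Operons with no core gene are keyed ``''`` and excluded.
    """
    if not operons:
        raise ValueError("empty corpus")
    keys = [op.compressed_key for op in operons if op.compressed_key]
    op_counts = Counter(keys)
    species_sets: dict[str, set[str]] = {}
    for op in operons:
        if op.compressed_key:
            species_sets.setdefault(op.compressed_key, set()).add(op.species_id)
    n_ops = len(keys)
    n_species = len({op.species_id for op in operons})
    rows = [
        {
            "operon_type": key,
            "n_operons": count,
            "frac_operons": count / n_ops,
            "n_species": len(species_sets[key]),
            "frac_species": len(species_sets[key]) / n_species,
        }
        for key, count in op_counts.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["n_operons", "operon_type"], ascending=[False, True]
    )
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class SpeciesCompleteness:
    """Whether a species has a complete operon or a complementary set."""

    species_id: str
    has_complete_operon: bool
    has_complementary_operons: bool
    witness: tuple[str, ...]


def classify_completeness(
    species_operons: Sequence[Operon], pair_limit: int = 2
) -> SpeciesCompleteness:
    """Classify one species' operon catalogue.

    Complete: some single operon carries all five core types. Otherwise
    complementary: some combination of at most ``pair_limit`` operons has a
    jointly complete compressed union. The flag is monotone in
    ``pair_limit``. The witness records the operon id(s) involved.
    """
    if not species_operons:
        raise ValueError("species has no operons")
    species_id = species_operons[0].species_id
    for op in species_operons:
        if op.compressed >= CORE_SET:
            return SpeciesCompleteness(species_id, True, False, (op.operon_id,))
    # Deduplicate by compressed set before the union search: combining two
    # operons of the same type never helps.
    seen: dict[frozenset, Operon] = {}
    for op in species_operons:
        seen.setdefault(op.compressed, op)
    candidates = list(seen.values())
    for size in range(2, pair_limit + 1):
        for combo in combinations(candidates, size):
            union = frozenset().union(*(op.compressed for op in combo))
            if union >= CORE_SET:
                return SpeciesCompleteness(
                    species_id, False, True, tuple(op.operon_id for op in combo)
                )
    return SpeciesCompleteness(species_id, False, False, ())


def classify_corpus_completeness(
    operons: Iterable[Operon], pair_limit: int = 2
) -> pd.DataFrame:
    """Per-species completeness table plus corpus summary columns."""
    rows = []
    for species_id, ops in sorted(_by_species(operons).items()):
        c = classify_completeness(ops, pair_limit=pair_limit)
        rows.append(
            {
                "species_id": species_id,
                "complete": c.has_complete_operon,
                "complementary": c.has_complementary_operons,
                "witness": ";".join(c.witness),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Ordered adjacent gene-pair counts over the core alphabet.

    ``counts[first, second]`` is the number of times a ``first`` gene is
    immediately followed by a ``second`` gene in transcription order within
    one operon. ``relative`` row-normalises the counts; all-zero rows stay
    zero.
    """

    counts: pd.DataFrame
    relative: pd.DataFrame


def relative_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    row_sums = counts.sum(axis=1)
    rel = counts.div(row_sums.where(row_sums > 0, other=1), axis=0)
    return rel.astype(float)


def adjacency_matrix(operons: Iterable[Operon]) -> AdjacencyMatrix:
    """Count ordered adjacent core-gene pairs across a corpus.

    Pairs follow transcription direction: genomic order on the + strand,
    reversed on the - strand. Non-core genes are transparent (the core genes
    flanking them still count as consecutive).
    """
    counts = pd.DataFrame(
        0, index=list(CORE_TYPES), columns=list(CORE_TYPES), dtype=int
    )
    for op in operons:
        core = [g.che_type for g in op.transcription_order if g.is_core]
        for first, second in zip(core, core[1:]):
            counts.loc[first, second] += 1
    return AdjacencyMatrix(counts=counts, relative=relative_from_counts(counts))


def multiplicity_summary(operons: Sequence[Operon]) -> dict[str, pd.DataFrame | float]:
    """Copy-number distributions of core genes within operons and species.

    Returns ``by_operon`` (rows = copy number, columns = gene type, values =
    number of operons carrying that many copies), ``by_species`` (the same
    over species totals), and ``frac_single_copy``, the fraction of operons
    free of multiple copies of any core gene.
    """
    if not operons:
        raise ValueError("empty corpus")
    op_hist: dict[str, Counter] = {t: Counter() for t in CORE_TYPES}
    species_totals: dict[str, Counter] = {}
    clean = 0
    for op in operons:
        comp = op.composition
        if all(c <= 1 for c in comp.values()):
            clean += 1
        for t, c in comp.items():
            op_hist[t][c] += 1
        totals = species_totals.setdefault(op.species_id, Counter())
        totals.update(comp)
    sp_hist: dict[str, Counter] = {t: Counter() for t in CORE_TYPES}
    for totals in species_totals.values():
        for t, c in totals.items():
            sp_hist[t][c] += 1

    def to_frame(hists: dict[str, Counter]) -> pd.DataFrame:
        max_copy = max((max(h) for h in hists.values() if h), default=1)
        frame = pd.DataFrame(
            0, index=range(1, max_copy + 1), columns=list(CORE_TYPES), dtype=int
        )
        for t, h in hists.items():
            for copies, n in h.items():
                frame.loc[copies, t] = n
        frame.index.name = "copies"
        return frame

    return {
        "by_operon": to_frame(op_hist),
        "by_species": to_frame(sp_hist),
        "frac_single_copy": clean / len(operons),
    }
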