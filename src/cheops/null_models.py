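"""Shuffled-operon null models and homogeneity testing.

The null hypothesis is that the allocation of che genes to operons carries
no information: within each species the gene-type tokens are permuted
uniformly at random and refilled into the fixed operon-size slots, so the
number and size of operons and the per-species gene-type multiset are all
preserved while the assignment of genes to operons is randomised. Operon
geometry (coordinates, strands, replicons) is a fixed scaffold.

Replicate machinery re-runs the downstream analyses (pathway prediction,
PI occurrence counting, completeness classification) on many shuffled
corpora and reports per-statistic means and standard errors; observed
values are then compared against the mean +/- 2*SE band or with a
chi-square test of homogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .operon_model import Operon
from .operon_stats import classify_completeness
from .pathway_inference import (
    PI_TYPES,
    build_cooccurrence,
    count_pi_occurrences,
    predict_corpus,
)

__all__ = [
    "shuffle_species",
    "shuffle_corpus",
    "ReplicateResult",
    "replicate_statistics",
    "chi_square_homogeneity",
]


def shuffle_species(
    species_operons: list[Operon], rng: np.random.Generator
) -> list[Operon]:
    """Randomise gene-to-operon allocation within one species.

    Gene-type tokens (with multiplicity) are permuted uniformly and written
    back into the existing gene slots; every slot keeps its coordinates,
    strand and identifier.
    """
    if not species_operons:
        raise ValueError("species has no operons")
    tokens = [g.che_type for op in species_operons for g in op.genes]
    perm = rng.permutation(len(tokens))
    shuffled_tokens = [tokens[i] for i in perm]
    out: list[Operon] = []
    pos = 0
    for op in species_operons:
        genes = tuple(
            replace(g, che_type=shuffled_tokens[pos + i])
            for i, g in enumerate(op.genes)
        )
        pos += len(op.genes)
        out.append(replace(op, genes=genes))
    return out


def shuffle_corpus(operons: list[Operon], rng: np.random.Generator) -> list[Operon]:
    """Shuffle every species independently (never across species)."""
    per_species: dict[str, list[Operon]] = {}
    order: list[str] = []
    for op in operons:
        if op.species_id not in per_species:
            order.append(op.species_id)
        per_species.setdefault(op.species_id, []).append(op)
    out: list[Operon] = []
    for sp in order:
        out.extend(shuffle_species(per_species[sp], rng))
    return out


@dataclass(frozen=True)
class ReplicateResult:
    """Shuffled-replicate statistics for one corpus and model.

    ``pi_relative``/``pi_counts`` hold one row per replicate over the eight
    (PI type, scope) cells; ``summary`` carries per-cell mean, standard
    error (sd / sqrt(n_reps)) and the mean +/- 2*SE band, plus the two
    completeness fractions.
    """

    model: str
    n_reps: int
    pi_counts: pd.DataFrame
    pi_relative: pd.DataFrame
    complete_frac: np.ndarray
    complementary_frac: np.ndarray
    summary: pd.DataFrame


def _completeness_fractions(operons: list[Operon], pair_limit: int) -> tuple[float, float]:
    per_species: dict[str, list[Operon]] = {}
    for op in operons:
        per_species.setdefault(op.species_id, []).append(op)
    results = [
        classify_completeness(ops, pair_limit=pair_limit)
        for ops in per_species.values()
    ]
    n = len(results)
    complete = sum(r.has_complete_operon for r in results) / n
    incomplete = [r for r in results if not r.has_complete_operon]
    complementary = (
        sum(r.has_complementary_operons for r in incomplete) / len(incomplete)
        if incomplete
        else 0.0
    )
    return complete, complementary


def replicate_statistics(
    operons: list[Operon],
    model: str,
    n_reps: int = 100,
    base_seed: int = 0,
    pair_limit: int = 2,
) -> ReplicateResult:
    """Re-run the pathway analysis on ``n_reps`` shuffled corpora.

    Each replicate shuffles every species, rebuilds the co-occurrence table
    from the shuffled corpus, predicts pathways under ``model`` and records
    PI occurrence counts and completeness fractions. Replicate r uses the
    independent stream seeded by (base_seed, r), so results are reproducible
    from ``base_seed`` alone.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates for a standard error")
    cells = pd.MultiIndex.from_product(
        [PI_TYPES, ("within", "across")], names=["pi_type", "scope"]
    )
    counts = np.zeros((n_reps, len(cells)))
    rel = np.zeros((n_reps, len(cells)))
    complete = np.zeros(n_reps)
    complementary = np.zeros(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng([base_seed, r])
        shuffled = shuffle_corpus(operons, rng)
        cooc = build_cooccurrence(shuffled)
        preds = predict_corpus(shuffled, model, cooc)
        table = count_pi_occurrences(preds).reindex(cells)
        counts[r] = table["occurrence"].to_numpy()
        rel[r] = table["relative"].to_numpy()
        complete[r], complementary[r] = _completeness_fractions(shuffled, pair_limit)

    def band(values: np.ndarray) -> dict[str, np.ndarray | float]:
        mean = values.mean(axis=0)
        se = values.std(axis=0, ddof=1) / np.sqrt(n_reps)
        return {"mean": mean, "se": se, "lo": mean - 2 * se, "hi": mean + 2 * se}

    rel_stats = band(rel)
    summary = pd.DataFrame(rel_stats, index=cells)
    return ReplicateResult(
        model=model,
        n_reps=n_reps,
        pi_counts=pd.DataFrame(counts, columns=cells),
        pi_relative=pd.DataFrame(rel, columns=cells),
        complete_frac=complete,
        complementary_frac=complementary,
        summary=summary,
    )


def chi_square_homogeneity(table_a, table_b) -> tuple[float, int, float]:
    """Two-sample chi-square test of homogeneity over matched categories.

    ``table_a`` and ``table_b`` are count vectors over the same categories.
    Categories whose combined count is zero are dropped with a warning (they
    carry no information and would break the expected-count denominator).
    No continuity correction is applied. Returns (statistic, df, p-value).
    """
    a = np.asarray(table_a, dtype=float)
    b = np.asarray(table_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("tables must be 1-D count vectors of equal length")
    keep = (a + b) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-margin categories",
            stacklevel=2,
        )
        a, b = a[keep], b[keep]
    if a.size == 0 or a.sum() + b.sum() == 0:
        raise ValueError("all-zero table")
    if a.size == 1:
        # a single category cannot show heterogeneity
        return 0.0, 0, 1.0
    stat, p, df, _ = stats.chi2_contingency(np.vstack([a, b]), correction=False)
    return float(stat), int(df), float(p)
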