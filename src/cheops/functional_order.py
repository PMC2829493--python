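"""Gene functional-order (Zaslaver) scores for operon corpora.

A candidate gene order (permutation of the pathway alphabet) is laid over
each operon's gene content; the score counts functional steps skipped
between consecutive present genes. Only presence or absence of a gene type
matters — within-operon gene order and copy number are ignored. Corpus
scores sum over all operons of all species, so lower totals mark
permutations that better fit the observed arrangement of genes into
operons. A circular variant takes, per operon, the minimum linear score
over all rotations of a cyclic order, so steps closing around the cycle
are not counted as skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

from .genome_io import CORE_TYPES
from .operon_model import Operon

__all__ = [
    "PermutationScore",
    "linear_score",
    "circular_score",
    "corpus_score",
    "rank_permutations",
    "canonical_rotation",
]


@dataclass(frozen=True)
class PermutationScore:
    permutation: tuple[str, ...]
    mode: str
    score: int

    def __post_init__(self):
        if self.mode not in ("linear", "circular"):
            raise ValueError("mode must be 'linear' or 'circular'")


def _present_set(operon_types: Iterable[str], permutation: Sequence[str]) -> set[str]:
    alphabet = set(permutation)
    present = set(operon_types)
    unknown = present - alphabet
    if unknown:
        raise ValueError(
            f"genes {sorted(unknown)} absent from permutation alphabet"
        )
    return present


def linear_score(operon_types: Iterable[str], permutation: Sequence[str]) -> int:
    """Skipped steps of an operon's gene set under a linear gene order.

    Present genes are ordered by their permutation rank; each consecutive
    present pair contributes (rank difference - 1). Genes missing before the
    first or after the last present gene do not count, so an operon holding
    a contiguous run of the permutation scores 0.
    """
    present = _present_set(operon_types, permutation)
    ranks = sorted(i for i, g in enumerate(permutation) if g in present)
    return sum(b - a - 1 for a, b in zip(ranks, ranks[1:]))


def _rotations(permutation: Sequence[str]) -> list[tuple[str, ...]]:
    p = tuple(permutation)
    return [p[i:] + p[:i] for i in range(len(p))]


def circular_score(operon_types: Iterable[str], cyclic_permutation: Sequence[str]) -> int:
    """Minimum linear score over all rotations of a cyclic gene order."""
    present = _present_set(operon_types, cyclic_permutation)
    return min(linear_score(present, rot) for rot in _rotations(cyclic_permutation))


def corpus_score(
    operons: Iterable[Operon | Iterable[str]],
    permutation: Sequence[str],
    mode: str = "linear",
) -> int:
    """Summed per-operon score over a corpus; lower fits the corpus better.

    Accepts Operon objects (scored on their compressed core gene sets) or
    bare iterables of gene types.
    """
    if mode == "linear":
        scorer = linear_score
    elif mode == "circular":
        scorer = circular_score
    else:
        raise ValueError("mode must be 'linear' or 'circular'")
    total = 0
    for op in operons:
        types = op.compressed if isinstance(op, Operon) else set(op)
        total += scorer(types, permutation)
    return total


def canonical_rotation(permutation: Sequence[str]) -> tuple[str, ...]:
    """Canonical representative of a cyclic order: smallest gene first.

    Reflections are kept distinct — a cycle and its mirror image are
    different circular gene orders.
    """
    p = tuple(permutation)
    pivot = min(range(len(p)), key=lambda i: p[i])
    return p[pivot:] + p[:pivot]


def rank_permutations(
    operons: Sequence[Operon | Iterable[str]],
    mode: str = "linear",
    alphabet: Sequence[str] = CORE_TYPES,
) -> list[PermutationScore]:
    """Score every permutation of ``alphabet`` and sort ascending by score.

    Linear mode ranks all |alphabet|! orders (ties broken lexicographically);
    circular mode deduplicates rotations, leaving (|alphabet|-1)! cyclic
    classes. For the five core che genes that is 120 linear orders and 24
    cyclic ones.
    """
    if mode == "linear":
        perms = [tuple(p) for p in permutations(alphabet)]
    elif mode == "circular":
        perms = sorted(
            {canonical_rotation(p) for p in permutations(alphabet)}
        )
    else:
        raise ValueError("mode must be 'linear' or 'circular'")
    scored = [
        PermutationScore(p, mode, corpus_score(operons, p, mode)) for p in perms
    ]
    scored.sort(key=lambda s: (s.score, s.permutation))
    return scored
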