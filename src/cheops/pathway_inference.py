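"""Reconstruction of putative chemotaxis pathways from operon catalogues.

CheB, CheR, CheW and CheY are all functionally linked to the kinase CheA;
each such linkage is a putative interaction (PI) of type A~B, A~R, A~W or
A~Y, registered at operon granularity and classified as within-operon or
across-operon. Pathways are assembled under four models:

* ``ABRWY`` — the base model: all four PI types are treated alike.
* ``ABRW+Y`` — CheY is kept out of the assembly steps; afterwards every
  CheY is connected to every CheA.
* ``ABRWY+Y`` — the base assembly plus a final every-Y-to-every-A pass.
* ``ABRWY+Y'`` — the base assembly; only CheYs still unconnected to any
  CheA afterwards are then connected to every CheA.

Assembly is parsimonious. A species with a single CheA connects that CheA
to every other Che protein. Otherwise each CheA-encoding operon first gains
within-operon PIs; incomplete pathways are completed across operons,
preferring an exactly complementary partner, then several jointly
complementary partners, then any non-CheA partner, finally another
CheA-encoding operon. Partner choice is guided by how often the two
compressed operon types co-occur in species across the whole corpus, and
partners without existing cross-operon edges are preferred so pathways stay
distinct. Left-over operons carrying non-Y core genes are finally attached
to the CheA operon with the highest co-occurrence. Single-gene CheY operons
are deliberately left unattached by that last step: their wiring is exactly
what the Y-variant models differ on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .operon_model import Operon

__all__ = [
    "MODELS",
    "PI",
    "PI_TYPES",
    "PathwayPrediction",
    "CooccurrenceTable",
    "build_cooccurrence",
    "predict_pathways",
    "predict_corpus",
    "count_pi_occurrences",
]

MODELS = ("ABRWY", "ABRW+Y", "ABRWY+Y", "ABRWY+Y'")
PI_TYPES = ("A~B", "A~R", "A~W", "A~Y")
_REQUIRED = frozenset("ABRWY")


@dataclass(frozen=True)
class PI:
    """One putative interaction between CheA and another Che protein.

    ``source_operon`` is always the CheA-encoding side; scope is ``within``
    iff source and target coincide.
    """

    pi_type: str
    scope: str
    source_operon: str
    target_operon: str

    def __post_init__(self):
        if self.pi_type not in PI_TYPES:
            raise ValueError(f"unknown PI type {self.pi_type!r}")
        within = self.source_operon == self.target_operon
        if self.scope != ("within" if within else "across"):
            raise ValueError("scope inconsistent with operon endpoints")


@dataclass(frozen=True)
class PathwayPrediction:
    species_id: str
    model: str
    pis: frozenset[PI]


@dataclass(frozen=True)
class CooccurrenceTable:
    """Species counts of compressed operon-type pairs.

    ``pair_counts[(X, Y)]`` is the number of species containing at least one
    operon of type X and one of type Y; the diagonal counts species with at
    least two operons of the type. Lookup is symmetric.
    """

    pair_counts: Mapping[tuple[str, str], int]

    def count(self, type_a: str, type_b: str) -> int:
        key = tuple(sorted((type_a, type_b)))
        return self.pair_counts.get(key, 0)


def build_cooccurrence(operons: Iterable[Operon]) -> CooccurrenceTable:
    """Count, per compressed-type pair, the species containing both."""
    per_species: dict[str, list[str]] = {}
    for op in operons:
        per_species.setdefault(op.species_id, []).append(op.compressed_key)
    counts: dict[tuple[str, str], int] = {}
    for keys in per_species.values():
        distinct = sorted(set(keys))
        pairs = {(a, b) for i, a in enumerate(distinct) for b in distinct[i + 1 :]}
        pairs |= {(k, k) for k in distinct if keys.count(k) >= 2}
        for pair in pairs:
            counts[pair] = counts.get(pair, 0) + 1
    return CooccurrenceTable(counts)


def _ordered(ops: Sequence[Operon]) -> list[Operon]:
    return sorted(
        ops, key=lambda op: (op.replicon_id, min(g.start for g in op.genes), op.operon_id)
    )


class _Assembly:
    """Mutable PI set plus the bookkeeping the assembly steps need."""

    def __init__(self, cooc: CooccurrenceTable):
        self.cooc = cooc
        self.pis: set[PI] = set()
        self.linked: set[str] = set()  # operon ids touching any across edge

    def add(self, pi_type: str, source: Operon, target: Operon) -> None:
        scope = "within" if source.operon_id == target.operon_id else "across"
        self.pis.add(
            PI(pi_type, scope, source.operon_id, target.operon_id)
        )
        if scope == "across":
            self.linked.add(source.operon_id)
            self.linked.add(target.operon_id)

    def candidate_key(self, source: Operon, candidate: Operon):
        """Ranking: edge-less first, then high co-occurrence, then type, id."""
        return (
            candidate.operon_id in self.linked,
            -self.cooc.count(source.compressed_key, candidate.compressed_key),
            candidate.compressed_key,
            candidate.operon_id,
        )

    def covered(self, op: Operon, scope_types: frozenset) -> frozenset:
        """Types reachable from a CheA operon: own genes + assigned edges."""
        got = set(op.compressed)
        for pi in self.pis:
            if pi.source_operon == op.operon_id:
                got.add(pi.pi_type[-1])
        return frozenset(got) & (scope_types | {"A"})


def predict_pathways(
    species_operons: Sequence[Operon],
    model: str,
    cooccurrence: CooccurrenceTable,
) -> PathwayPrediction:
    """Assemble one species' putative chemotaxis pathways under one model."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    if not species_operons:
        raise ValueError("species has no operons")
    species_id = species_operons[0].species_id
    present = frozenset().union(*(op.compressed for op in species_operons))
    for t in sorted(_REQUIRED - present):
        raise ValueError(f"species {species_id} lacks required che type {t}")

    ops = _ordered(species_operons)
    a_ops = [op for op in ops if "A" in op.compressed]
    scope_types = frozenset("BRW") if model == "ABRW+Y" else frozenset("BRWY")
    required = scope_types | {"A"}
    asm = _Assembly(cooccurrence)

    n_chea = sum(op.composition["A"] for op in ops)
    if n_chea == 1:
        # Single kinase: it serves every Che protein in the species.
        src = a_ops[0]
        for op in ops:
            for t in sorted(scope_types & op.compressed):
                asm.add(f"A~{t}", src, op)
    else:
        _assemble_multi_chea(asm, ops, a_ops, scope_types, required)

    _apply_y_variant(asm, model, ops, a_ops)
    return PathwayPrediction(species_id, model, frozenset(asm.pis))


def _assemble_multi_chea(asm, ops, a_ops, scope_types, required):
    # Step 1: within-operon PIs for every CheA-encoding operon.
    for src in a_ops:
        for t in sorted(scope_types & src.compressed):
            asm.add(f"A~{t}", src, src)

    # Step 2: complete each incomplete CheA pathway across operons, walking
    # down the preference tiers until the deficit is covered.
    for src in a_ops:
        deficit = required - asm.covered(src, scope_types)
        if not deficit:
            continue

        def pick(candidates):
            return min(candidates, key=lambda op: asm.candidate_key(src, op))

        others = [op for op in ops if op.operon_id != src.operon_id]
        # (a) one exactly complementary operon
        exact = [op for op in others if (op.compressed & required) == deficit]
        if exact:
            partner = pick(exact)
            for t in sorted(deficit):
                asm.add(f"A~{t}", src, partner)
            continue
        # (b) several jointly complementary operons (no surplus genes)
        while deficit:
            pure = [
                op
                for op in others
                if op.compressed
                and (op.compressed & required) <= deficit
                and (op.compressed & deficit)
            ]
            if not pure:
                break
            partner = pick(pure)
            for t in sorted(partner.compressed & deficit):
                asm.add(f"A~{t}", src, partner)
            deficit = required - asm.covered(src, scope_types)
        # (c) any non-CheA partner operon, surplus allowed
        while deficit:
            useful = [
                op
                for op in others
                if "A" not in op.compressed and (op.compressed & deficit)
            ]
            if not useful:
                break
            partner = pick(useful)
            for t in sorted(partner.compressed & deficit):
                asm.add(f"A~{t}", src, partner)
            deficit = required - asm.covered(src, scope_types)
        # (d) another CheA-encoding operon
        while deficit:
            useful = [
                op
                for op in others
                if "A" in op.compressed and (op.compressed & deficit)
            ]
            if not useful:
                raise ValueError(
                    f"cannot complete pathway of {src.operon_id}: "
                    f"missing {sorted(deficit)}"
                )
            partner = pick(useful)
            for t in sorted(partner.compressed & deficit):
                asm.add(f"A~{t}", src, partner)
            deficit = required - asm.covered(src, scope_types)

    # Step 3: attach left-over edge-less operons to the CheA operon they
    # co-occur with most. Operons whose core content is CheY only are left
    # for the Y-variant passes — their wiring is model-dependent.
    for op in ops:
        if op.operon_id in asm.linked or "A" in op.compressed:
            continue
        core_present = op.compressed & scope_types
        if not core_present or core_present == frozenset("Y"):
            continue
        host = min(
            a_ops,
            key=lambda a: (
                -asm.cooc.count(a.compressed_key, op.compressed_key),
                a.compressed_key,
                a.operon_id,
            ),
        )
        for t in sorted(core_present):
            asm.add(f"A~{t}", host, op)


def _apply_y_variant(asm: _Assembly, model: str, ops, a_ops) -> None:
    y_ops = [op for op in ops if "Y" in op.compressed]
    if model in ("ABRW+Y", "ABRWY+Y"):
        # every CheY is connected to every CheA
        for src in a_ops:
            for target in y_ops:
                asm.add("A~Y", src, target)
    elif model == "ABRWY+Y'":
        # only CheYs not yet connected to any CheA gain edges, to every CheA
        connected = {
            pi.target_operon for pi in asm.pis if pi.pi_type == "A~Y"
        } | {pi.source_operon for pi in asm.pis if pi.pi_type == "A~Y"}
        for target in y_ops:
            if target.operon_id in connected:
                continue
            for src in a_ops:
                asm.add("A~Y", src, target)


def predict_corpus(
    operons: Sequence[Operon],
    model: str,
    cooccurrence: CooccurrenceTable | None = None,
) -> list[PathwayPrediction]:
    """Predict pathways for every species of a corpus under one model."""
    if cooccurrence is None:
        cooccurrence = build_cooccurrence(operons)
    per_species: dict[str, list[Operon]] = {}
    for op in operons:
        per_species.setdefault(op.species_id, []).append(op)
    return [
        predict_pathways(per_species[sp], model, cooccurrence)
        for sp in sorted(per_species)
    ]


def count_pi_occurrences(
    predictions: Iterable[PathwayPrediction],
) -> pd.DataFrame:
    """Tabulate PI occurrences over a corpus of one-model predictions.

    An occurrence is one distinct (PI type, operon) registration for
    within-operon PIs and one distinct (PI type, operon pair) registration
    for across-operon PIs — "at least one PI of this type" between those
    endpoints. Relative occurrences divide by the grand total over all
    eight (type, scope) cells.
    """
    predictions = list(predictions)
    models = {p.model for p in predictions}
    if len(models) > 1:
        raise ValueError(f"mixed models in predictions: {sorted(models)}")
    index = pd.MultiIndex.from_product(
        [PI_TYPES, ("within", "across")], names=["pi_type", "scope"]
    )
    counts = pd.Series(0, index=index, dtype=int)
    for pred in predictions:
        # registrations are unordered operon(-pair)s per PI type
        seen = {
            (pi.pi_type, pi.scope, frozenset((pi.source_operon, pi.target_operon)))
            for pi in pred.pis
        }
        for pi_type, scope, _ in seen:
            counts.loc[(pi_type, scope)] += 1
    total = int(counts.sum())
    out = counts.to_frame("occurrence")
    out["relative"] = counts / total if total else 0.0
    out["rank"] = out["relative"].rank(ascending=False, method="min").astype(int)
    return out
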