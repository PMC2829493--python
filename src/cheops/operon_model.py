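"""Assigning che genes to putative operons.

Operon structure is rarely annotated, so co-transcribed units are predicted
from gene proximity. Candidate operons are maximal same-strand runs of che
genes; within a run, genes are partitioned into contiguous clusters of their
centre positions. The number of clusters k is chosen by minimising a
corrected Akaike information criterion

    AICc(k) = 2 ln(W_k) + 2nk / (n - k + 1),

where W_k is the pooled within-cluster sum of squares of gene centres and n
the number of genes in the run. Two hard biological constraints bracket the
search: adjacent genes closer than ``merge_distance`` (default 3,500 bp, the
largest intra-operon gap in the E. coli che operon) always share an operon,
and genes further apart than ``split_distance`` (default 100,000 bp, below
the closest inter-operon spacing observed in R. sphaeroides) never do. A
valid partition must also keep every within-operon gap smaller than every
between-operon gap on the same run.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations, groupby
from typing import Callable, Iterable, Sequence

import numpy as np

from .genome_io import CORE_TYPES, GeneRecord

__all__ = [
    "ClusterConfig",
    "ClusteringFit",
    "Operon",
    "candidate_segments",
    "pooled_within_ss",
    "aicc_score",
    "best_partition_for_k",
    "cluster_operons",
    "cluster_corpus",
    "group_by_species",
    "write_operon_table",
    "read_operon_table",
    "write_operon_bed",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class ClusterConfig:
    """Tunable parameters of the operon clustering.

    ``distance_mode`` selects how adjacent-gene distance is measured for the
    merge/split constraints: ``gap`` is the intergenic gap (next start minus
    previous end, the default), ``centre`` the centre-to-centre distance.
    The AICc always uses the natural logarithm.
    """

    merge_distance: float = 3_500.0
    split_distance: float = 100_000.0
    distance_mode: str = "gap"

    def __post_init__(self):
        if not 0 < self.merge_distance < self.split_distance:
            raise ValueError("need 0 < merge_distance < split_distance")
        if self.distance_mode not in ("gap", "centre"):
            raise ValueError("distance_mode must be 'gap' or 'centre'")


@dataclass(frozen=True)
class ClusteringFit:
    """A candidate contiguous partition with its fit statistics."""

    k: int
    assignment: tuple[int, ...]
    w_k: float
    aicc: float


@dataclass(frozen=True)
class Operon:
    """An ordered run of same-strand genes assigned to one cluster."""

    operon_id: str
    species_id: str
    replicon_id: str
    strand: str
    genes: tuple[GeneRecord, ...]

    def __post_init__(self):
        if not self.genes:
            raise ValueError("operon must contain at least one gene")
        if any(g.strand != self.strand for g in self.genes):
            raise ValueError(f"operon {self.operon_id}: mixed strands")
        if any(g.replicon_id != self.replicon_id for g in self.genes):
            raise ValueError(f"operon {self.operon_id}: mixed replicons")

    @property
    def composition(self) -> Counter:
        """Multiset of core che types carried by the operon."""
        return Counter(g.che_type for g in self.genes if g.che_type in CORE_TYPES)

    @property
    def compressed(self) -> frozenset:
        """Distinct core types: copy number is ignored."""
        return frozenset(self.composition)

    @property
    def compressed_key(self) -> str:
        """Compressed set rendered in fixed A,B,R,W,Y order (e.g. 'ABWY')."""
        return "".join(t for t in CORE_TYPES if t in self.compressed)

    @property
    def transcription_order(self) -> tuple[GeneRecord, ...]:
        """Genes in the order they are transcribed (reversed on - strand)."""
        return self.genes if self.strand == "+" else tuple(reversed(self.genes))


def candidate_segments(genes: Sequence[GeneRecord]) -> list[list[GeneRecord]]:
    """Split genes (sorted by start, one replicon) into maximal same-strand runs.

    A strand flip always starts a new run; only che genes on the opposite
    strand break runs, so callers should pass che genes only.
    """
    return [list(run) for _, run in groupby(genes, key=lambda g: g.strand)]


def pooled_within_ss(
    centres: Sequence[float], blocks: Sequence[Sequence[int]]
) -> float:
    """Pooled within-cluster sum of squares W_k of gene centre positions."""
    x = np.asarray(centres, dtype=float)
    total = 0.0
    for block in blocks:
        if len(block) == 0:
            raise ValueError("empty block in partition")
        xs = x[list(block)]
        total += float(np.sum((xs - xs.mean()) ** 2))
    return total


def aicc_score(w_k: float, n: int, k: int) -> float:
    """Corrected AIC of a k-cluster assignment of n gene centres.

    W_k = 0 (e.g. an all-singleton partition) maps to -inf, which compares
    smaller than every finite score.
    """
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if w_k < 0:
        raise ValueError("W_k must be non-negative")
    penalty = 2.0 * n * k / (n - k + 1)
    if w_k == 0.0:
        return NEG_INF
    return 2.0 * math.log(w_k) + penalty


def _block_ss(x: np.ndarray, i: int, j: int) -> float:
    """Within-SS of x[i:j], computed directly; singletons are exactly zero."""
    if j - i == 1:
        return 0.0
    block = x[i:j]
    return float(np.sum((block - block.mean()) ** 2))


def _enumerate_partitions(
    n: int,
    k: int,
    allowed: Sequence[int],
    forced: frozenset[int],
):
    """Yield split-boundary tuples (boundary b splits genes b-1|b).

    Every partition contains all ``forced`` boundaries and chooses the
    remaining k-1-len(forced) boundaries among ``allowed``.
    """
    free = [b for b in allowed if b not in forced]
    need = k - 1 - len(forced)
    if need < 0 or need > len(free):
        return
    for chosen in combinations(free, need):
        yield tuple(sorted(set(chosen) | forced))


def _splits_to_blocks(n: int, splits: Sequence[int]) -> list[range]:
    edges = [0, *splits, n]
    return [range(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def best_partition_for_k(
    centres: Sequence[float],
    k: int,
    atomic_blocks: Sequence[Sequence[int]] | None = None,
    forbidden_joins: Iterable[int] | None = None,
    gaps: Sequence[float] | None = None,
    feasible: Callable[[tuple[int, ...]], bool] | None = None,
) -> ClusteringFit:
    """Best contiguous partition of ``centres`` into ``k`` blocks.

    ``atomic_blocks`` are contiguous index groups that may never be split
    (forced merges); ``forbidden_joins`` are boundary indices b at which a
    split is mandatory (gene b-1 and gene b never co-cluster). ``gaps``
    (length n-1, adjacent-gene distances) drive the tie-break: among
    W_k-minimal partitions the one whose largest within-block gap is
    smallest wins, then the lexicographically earliest split points.
    ``feasible`` optionally rejects split tuples before scoring.

    The search enumerates admissible split placements exactly; che segments
    are short (tens of genes), so exhaustion is cheap.
    """
    x = np.asarray(centres, dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("no centres to partition")
    gaps_arr = (
        np.diff(x) if gaps is None else np.asarray(gaps, dtype=float)
    )
    if len(gaps_arr) != max(n - 1, 0):
        raise ValueError("gaps must have length n-1")

    # Boundaries interior to an atomic block are disallowed.
    disallowed: set[int] = set()
    if atomic_blocks is not None:
        cover = sorted(i for blk in atomic_blocks for i in blk)
        if cover != list(range(n)):
            raise ValueError("atomic_blocks must partition the index range")
        for blk in atomic_blocks:
            blk = sorted(blk)
            disallowed.update(range(blk[0] + 1, blk[-1] + 1))
    forced = frozenset(forbidden_joins or ())
    if forced & disallowed:
        raise ValueError("a forbidden join falls inside an atomic block")
    allowed = [b for b in range(1, n) if b not in disallowed]

    best: tuple[float, float, tuple[int, ...]] | None = None
    for splits in _enumerate_partitions(n, k, allowed, forced):
        if feasible is not None and not feasible(splits):
            continue
        edges = [0, *splits, n]
        w = sum(_block_ss(x, edges[i], edges[i + 1]) for i in range(k))
        max_gap = 0.0
        for i in range(k):
            lo, hi = edges[i], edges[i + 1]
            if hi - lo > 1:
                max_gap = max(max_gap, float(np.max(gaps_arr[lo : hi - 1])))
        key = (w, max_gap, splits)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError(f"no feasible partition into k={k} blocks")
    w, _, splits = best
    assignment = tuple(
        bi for bi, blk in enumerate(_splits_to_blocks(n, splits)) for _ in blk
    )
    return ClusteringFit(k=k, assignment=assignment, w_k=w, aicc=aicc_score(w, n, k))


def _adjacent_distances(genes: Sequence[GeneRecord], mode: str) -> np.ndarray:
    if len(genes) < 2:
        return np.empty(0)
    if mode == "centre":
        return np.diff([g.centre for g in genes])
    return np.array(
        [genes[i + 1].start - genes[i].end for i in range(len(genes) - 1)],
        dtype=float,
    )


def _segment_fit(genes: Sequence[GeneRecord], config: ClusterConfig) -> ClusteringFit:
    """AICc-optimal admissible partition of one same-strand run."""
    n = len(genes)
    centres = [g.centre for g in genes]
    if n == 1:
        return ClusteringFit(1, (0,), 0.0, NEG_INF)
    dist = _adjacent_distances(genes, config.distance_mode)

    # Hard constraints: fuse near genes into atomic blocks, force splits at
    # gaps beyond the split distance.
    atomic: list[list[int]] = [[0]]
    for i in range(1, n):
        if dist[i - 1] <= config.merge_distance:
            atomic[-1].append(i)
        else:
            atomic.append([i])
    forced = {
        b for b in range(1, n) if dist[b - 1] > config.split_distance
    }
    k_min = len(forced) + 1
    k_max = len(atomic)

    def separation_ok(splits: tuple[int, ...]) -> bool:
        # every within-block distance < every between-block distance
        if not splits:
            return True
        min_between = min(dist[b - 1] for b in splits)
        within = [dist[i] for i in range(n - 1) if (i + 1) not in splits]
        return not within or max(within) < min_between

    best_fit: ClusteringFit | None = None
    for k in range(k_min, k_max + 1):
        try:
            fit = best_partition_for_k(
                centres,
                k,
                atomic_blocks=atomic,
                forbidden_joins=forced,
                gaps=dist,
                feasible=separation_ok,
            )
        except ValueError:
            continue  # no admissible partition at this k
        # ties in AICc resolve toward fewer operons (parsimony)
        if best_fit is None or fit.aicc < best_fit.aicc:
            best_fit = fit
    if best_fit is None:
        raise RuntimeError("no admissible partition found for segment")
    return best_fit


def cluster_operons(
    genes: Sequence[GeneRecord], config: ClusterConfig | None = None
) -> list[Operon]:
    """Cluster one species' che genes into putative operons.

    Clustering is performed per replicon (plasmid and chromosome genes are
    never co-clustered) and per same-strand run. Circular replicons are
    treated as linear in file coordinate order, so an origin-spanning operon
    would not be detected.
    """
    config = config or ClusterConfig()
    if not genes:
        return []
    species = {g.species_id for g in genes}
    if len(species) > 1:
        raise ValueError(f"cluster_operons expects one species, got {sorted(species)}")
    species_id = species.pop()

    operons: list[Operon] = []
    counter = 0
    by_replicon = groupby(
        sorted(genes, key=lambda g: (g.replicon_id, g.start, g.end)),
        key=lambda g: g.replicon_id,
    )
    for replicon_id, rep_genes in by_replicon:
        rep_genes = list(rep_genes)
        for segment in candidate_segments(rep_genes):
            fit = _segment_fit(segment, config)
            for _, members in groupby(
                range(len(segment)), key=lambda i: fit.assignment[i]
            ):
                counter += 1
                block = [segment[i] for i in members]
                operons.append(
                    Operon(
                        operon_id=f"{species_id}|{replicon_id}|op{counter:03d}",
                        species_id=species_id,
                        replicon_id=replicon_id,
                        strand=block[0].strand,
                        genes=tuple(block),
                    )
                )
    return operons


def group_by_species(genes: Iterable[GeneRecord]) -> dict[str, list[GeneRecord]]:
    out: dict[str, list[GeneRecord]] = {}
    for g in genes:
        out.setdefault(g.species_id, []).append(g)
    for records in out.values():
        records.sort(key=lambda g: (g.replicon_id, g.start, g.end))
    return out


def cluster_corpus(
    genes: Iterable[GeneRecord], config: ClusterConfig | None = None
) -> list[Operon]:
    """Cluster every species of a multi-species gene table."""
    grouped = group_by_species(genes)
    operons: list[Operon] = []
    for species_id in sorted(grouped):
        operons.extend(cluster_operons(grouped[species_id], config))
    return operons


OPERON_TSV_COLUMNS = (
    "species_id",
    "replicon_id",
    "operon_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "che_type",
)


def write_operon_table(operons: Iterable[Operon], path) -> None:
    """One gene per row, tagged with its operon id (lossless round-trip)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(OPERON_TSV_COLUMNS)
        for op in operons:
            for g in op.genes:
                writer.writerow(
                    [op.species_id, op.replicon_id, op.operon_id,
                     g.gene_id, g.start, g.end, g.strand, g.che_type]
                )


def read_operon_table(path) -> list[Operon]:
    import csv

    groups: dict[str, list[GeneRecord]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != OPERON_TSV_COLUMNS:
            raise ValueError(f"{path}: not an operon table")
        for row in reader:
            if not row:
                continue
            sp, rep, op_id, gid, start, end, strand, ctype = row
            if op_id not in groups:
                groups[op_id] = []
                order.append(op_id)
            groups[op_id].append(
                GeneRecord(gid, sp, rep, int(start), int(end), strand, ctype)
            )
    operons = []
    for op_id in order:
        block = sorted(groups[op_id], key=lambda g: g.start)
        operons.append(
            Operon(
                operon_id=op_id,
                species_id=block[0].species_id,
                replicon_id=block[0].replicon_id,
                strand=block[0].strand,
                genes=tuple(block),
            )
        )
    return operons


def write_operon_bed(operons: Iterable[Operon], path) -> None:
    """BED intervals (0-based half-open) for genome-browser inspection."""
    with open(path, "w") as fh:
        for op in operons:
            start = min(g.start for g in op.genes) - 1
            end = max(g.end for g in op.genes)
            fh.write(
                f"{op.replicon_id}\t{start}\t{end}\t{op.operon_id}"
                f"\t0\t{op.strand}\n"
            )
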