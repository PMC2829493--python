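"""Seeded synthetic che-gene catalogues with planted operon structure.

Real corpora of this kind are built from hundreds of complete genomes plus
homology searches, which is far beyond a test suite; the generator instead
emulates their statistical shape. Operon compositions are drawn from a
configurable frequency table whose default mirrors the strongly CheY-heavy
type distribution seen in large surveys, species carry a realistic number
of operons, genes get type-specific lengths, and intra-/inter-operon gaps
are drawn from ranges that respect the clustering thresholds (intra gaps
below the merge distance, inter gaps above the split distance). Every
planted assignment therefore satisfies the clusterability conditions, so
exact recovery by the operon model is a designed property of the corpus,
not luck. An adversarial configuration (wide intra gaps) deliberately
breaks that guarantee to exercise the information-criterion search itself.

Every species is resampled until it carries at least one gene of each of
the five core types, matching the conditioning of the analysed corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .genome_io import CORE_TYPES, GeneRecord, write_gene_table
from .operon_model import Operon

__all__ = [
    "DEFAULT_COMPOSITION_WEIGHTS",
    "DEFAULT_GENE_LENGTHS",
    "SyntheticSpec",
    "generate_species",
    "generate_corpus",
    "truth_operons",
    "write_truth_table",
    "read_truth_table",
    "write_corpus",
]

#: Default operon-composition weights, approximating the relative type
#: frequencies of large che-operon surveys (single-gene cheY operons near
#: half of all operons, cheW and complete ABRWY operons next, a long tail
#: of partial types). Strings are literal gene layouts in transcription
#: order; repeating a letter plants multiple copies.
DEFAULT_COMPOSITION_WEIGHTS: dict[str, float] = {
    "Y": 0.499,
    "W": 0.090,
    "ABRWY": 0.085,
    "R": 0.060,
    "ABWY": 0.044,
    "AWY": 0.021,
    "WY": 0.020,
    "BW": 0.019,
    "AY": 0.018,
    "ABRY": 0.018,
    "AW": 0.030,
    "B": 0.020,
    "RB": 0.020,
    "ABRW": 0.020,
    "BRWY": 0.020,
    "YY": 0.016,
}

#: Gene lengths in base pairs, about three times the residue counts of the
#: E. coli query proteins (CheA 654 aa, CheB 349, CheR 286, CheW 167,
#: CheY 129).
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "A": 1962,
    "B": 1047,
    "R": 858,
    "W": 501,
    "Y": 387,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic corpus.

    ``mean_operons_per_species`` sets the mean of a shifted Poisson
    (1 + Poisson(mean - 1)), defaulting to the ~6.9 operons per species of
    real surveys. Gap ranges are inclusive uniform bounds in base pairs;
    the defaults keep intra-operon gaps under the 3,500 bp merge threshold
    and inter-operon gaps above every split threshold a robustness sweep
    would try. Set ``adversarial=True`` to lift the separation validation
    and allow overlapping gap ranges.
    """

    n_species: int = 50
    composition_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_WEIGHTS)
    )
    mean_operons_per_species: float = 6.89
    gene_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS)
    )
    intra_gap: tuple[int, int] = (20, 3_000)
    inter_gap: tuple[int, int] = (250_000, 400_000)
    strand_flip_prob: float = 0.3
    replicon_length: int = 40_000_000
    seed: int = 0
    adversarial: bool = False

    def __post_init__(self):
        weights = np.array(list(self.composition_weights.values()), dtype=float)
        if weights.min() < 0 or not np.isclose(weights.sum(), 1.0):
            raise ValueError("composition weights must be non-negative and sum to 1")
        if not self.adversarial and self.intra_gap[1] >= self.inter_gap[0]:
            raise ValueError(
                "intra-operon gaps must stay below inter-operon gaps "
                "(set adversarial=True to override)"
            )
        if self.mean_operons_per_species < 1:
            raise ValueError("mean operons per species must be >= 1")


def _species_rng(spec: SyntheticSpec, species_index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, species_index])


def _draw_compositions(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    """Operon layouts for one species, conditioned on full core coverage."""
    keys = list(spec.composition_weights)
    probs = np.array([spec.composition_weights[k] for k in keys])
    for _ in range(10_000):
        n_ops = 1 + rng.poisson(spec.mean_operons_per_species - 1)
        chosen = [keys[i] for i in rng.choice(len(keys), size=n_ops, p=probs)]
        covered = set("".join(chosen))
        if covered >= set(CORE_TYPES):
            return chosen
    raise RuntimeError(
        "could not draw a species covering all core types; "
        "check composition_weights"
    )


def generate_species(
    spec: SyntheticSpec, species_index: int
) -> tuple[list[GeneRecord], dict[str, str]]:
    """Generate one species' gene table and its planted-operon truth.

    Returns the gene records (sorted by start) and a mapping from gene id
    to planted operon id. Layout is left to right: genes within an operon
    are separated by intra-operon gaps, operons by inter-operon gaps, and
    each operon carries one strand (flipped from its predecessor with
    ``strand_flip_prob``; minus-strand operons are laid out with their
    composition reversed so transcription order matches the layout string).
    """
    rng = _species_rng(spec, species_index)
    species_id = f"synth{species_index:04d}"
    replicon_id = f"{species_id}_chr"
    compositions = _draw_compositions(spec, rng)

    genes: list[GeneRecord] = []
    truth: dict[str, str] = {}
    pos = int(rng.integers(1, 10_000))
    strand = "+" if rng.random() < 0.5 else "-"
    gene_no = 0
    for op_index, layout in enumerate(compositions):
        if op_index > 0:
            pos += int(rng.integers(spec.inter_gap[0], spec.inter_gap[1] + 1))
            if rng.random() < spec.strand_flip_prob:
                strand = "+" if strand == "-" else "-"
        operon_id = f"{species_id}_true{op_index:03d}"
        placed = layout if strand == "+" else layout[::-1]
        for i, t in enumerate(placed):
            if i > 0:
                pos += int(rng.integers(spec.intra_gap[0], spec.intra_gap[1] + 1))
            length = spec.gene_lengths[t]
            start, end = pos, pos + length - 1
            if end > spec.replicon_length:
                raise ValueError(
                    f"species {species_id} overflows replicon_length="
                    f"{spec.replicon_length}; increase it"
                )
            gene_no += 1
            gid = f"{species_id}_g{gene_no:04d}"
            genes.append(
                GeneRecord(gid, species_id, replicon_id, start, end, strand, t)
            )
            truth[gid] = operon_id
            pos = end + 1
    genes.sort(key=lambda g: g.start)
    return genes, truth


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[list[GeneRecord], dict[str, str]]:
    """Concatenate ``generate_species`` over the whole corpus."""
    genes: list[GeneRecord] = []
    truth: dict[str, str] = {}
    for i in range(spec.n_species):
        g, t = generate_species(spec, i)
        genes.extend(g)
        truth.update(t)
    return genes, truth


def truth_operons(
    genes: list[GeneRecord], truth: Mapping[str, str]
) -> list[Operon]:
    """Materialise the planted assignment as Operon objects."""
    groups: dict[str, list[GeneRecord]] = {}
    for g in genes:
        groups.setdefault(truth[g.gene_id], []).append(g)
    operons = []
    for op_id in sorted(groups):
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


def write_truth_table(truth: Mapping[str, str], genes, path) -> None:
    by_gene = {g.gene_id: g for g in genes}
    with open(path, "w") as fh:
        fh.write("species_id\tgene_id\tplanted_operon_id\n")
        for gid, op_id in truth.items():
            fh.write(f"{by_gene[gid].species_id}\t{gid}\t{op_id}\n")


def read_truth_table(path) -> dict[str, str]:
    truth: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("species_id\tgene_id"):
            raise ValueError(f"{path}: not a truth table")
        for line in fh:
            if line.strip():
                _, gid, op_id = line.rstrip("\n").split("\t")
                truth[gid] = op_id
    return truth


def write_corpus(genes, truth, out_dir) -> tuple[Path, Path]:
    """Emit the simple-tsv gene table and the truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genes_path = out_dir / "genes.tsv"
    truth_path = out_dir / "truth.tsv"
    write_gene_table(genes, genes_path)
    write_truth_table(truth, genes, truth_path)
    return genes_path, truth_path
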