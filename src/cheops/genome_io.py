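"""Reading and writing che-gene catalogues and BLAST-hit tables.

Gene locations come either from NCBI ``.ptt`` protein tables (one file per
replicon; ``Location`` column formatted ``start..end``) or from the package's
own ``simple-tsv`` dialect, which carries species and replicon identifiers
per row and round-trips losslessly.

BLAST hits against the E. coli Che query proteins are screened with
domain-coverage criteria so that truncated but genuine homologues (for
example CheA variants retaining only the P4 or P5 domain) are kept while
spurious partial hits are discarded.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CHE_TYPES",
    "CORE_TYPES",
    "GeneRecord",
    "BlastHit",
    "CoverageRule",
    "FilterSpec",
    "DEFAULT_FILTERS",
    "read_gene_table",
    "write_gene_table",
    "filter_blast_hits",
]

#: Full alphabet of recognised che gene types. ``other`` marks genes that are
#: carried along but excluded from che-specific statistics.
CHE_TYPES = ("A", "B", "R", "W", "Y", "V", "Z", "other")

#: The five core chemotaxis genes every analysed species must encode.
CORE_TYPES = ("A", "B", "R", "W", "Y")

_GENE_TOKEN_RE = re.compile(r"che([ABRWYVZ])", re.IGNORECASE)


@dataclass(frozen=True)
class GeneRecord:
    """One che gene homologue located on a replicon.

    Coordinates are 1-based and inclusive, matching the ptt convention;
    gene centres may therefore be half-integral.
    """

    gene_id: str
    species_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    che_type: str

    def __post_init__(self):
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: need end >= start >= 1, "
                f"got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if self.che_type not in CHE_TYPES:
            raise ValueError(
                f"gene {self.gene_id}: unknown che type {self.che_type!r}"
            )

    @property
    def centre(self) -> float:
        """Arithmetic mean of start and end, the x_i of the clustering model."""
        return (self.start + self.end) / 2.0

    @property
    def is_core(self) -> bool:
        return self.che_type in CORE_TYPES


@dataclass(frozen=True)
class BlastHit:
    """One BLAST hit of a Che query protein against a subject proteome."""

    protein_query: str
    subject_id: str
    subject_species: str
    hit_length: int
    query_from: int
    query_to: int

    def __post_init__(self):
        if not (self.query_to > self.query_from >= 1):
            raise ValueError(
                f"hit {self.subject_id}: need query_to > query_from >= 1"
            )


# A bound pair (low, high): accepted iff low < value < high; None = unbounded.
Bound = tuple[int | None, int | None]


@dataclass(frozen=True)
class CoverageRule:
    """One domain-coverage row: open-interval bounds on query-from/query-to."""

    name: str
    from_bounds: Bound
    to_bounds: Bound

    def matches(self, query_from: int, query_to: int) -> bool:
        return _within(query_from, self.from_bounds) and _within(
            query_to, self.to_bounds
        )


def _within(value: int, bounds: Bound) -> bool:
    low, high = bounds
    if low is not None and not value > low:
        return False
    if high is not None and not value < high:
        return False
    return True


@dataclass(frozen=True)
class FilterSpec:
    """Screening criteria for hits of one Che query protein.

    A hit passes when its length does not exceed ``max_hit_length`` (if
    bounded) and it satisfies at least one coverage rule; rules are tried in
    order and the first match is reported. CheW, which has no informative
    coverage criteria, carries a single all-pass rule and is screened by
    length alone.
    """

    protein: str
    max_hit_length: int | None
    coverage_rules: tuple[CoverageRule, ...]

    def evaluate(self, hit: BlastHit) -> str | None:
        """Return the name of the first satisfied rule, or None if rejected."""
        if self.max_hit_length is not None and hit.hit_length > self.max_hit_length:
            return None
        for rule in self.coverage_rules:
            if rule.matches(hit.query_from, hit.query_to):
                return rule.name
        return None


def _rule(name: str, frm: Bound, to: Bound) -> CoverageRule:
    return CoverageRule(name, frm, to)


#: Default screening criteria for the seven Che query proteins. Bounds are
#: strict; alternative rows accept homologues covering only a subset of the
#: query's domains (e.g. P4-only or P5-only CheA variants).
DEFAULT_FILTERS: dict[str, FilterSpec] = {
    "CheA": FilterSpec(
        "CheA",
        None,
        (
            _rule("All", (None, 400), (610, None)),
            _rule("P4", (340, 400), (475, 535)),
            _rule("P5", (480, 540), (610, None)),
        ),
    ),
    "CheB": FilterSpec(
        "CheB",
        450,
        (
            _rule("All", (None, 30), (310, None)),
            _rule("1", (None, 30), (90, 160)),
            _rule("2", (130, 190), (310, None)),
        ),
    ),
    "CheR": FilterSpec(
        "CheR",
        415,
        (
            _rule("All", (None, 40), (250, None)),
            _rule("1", (None, 50), (50, 110)),
            _rule("2", (60, 210), (250, None)),
        ),
    ),
    "CheW": FilterSpec("CheW", 240, (_rule("All", (None, None), (None, None)),)),
    "CheY": FilterSpec("CheY", 176, (_rule("All", (None, 30), (100, None)),)),
    "CheV": FilterSpec(
        "CheV",
        400,
        (
            _rule("All", (None, 40), (250, None)),
            _rule("1", (None, 40), (120, 200)),
            _rule("2", (140, 210), (250, None)),
        ),
    ),
    "CheZ": FilterSpec("CheZ", 300, (_rule("All", (None, 30), (180, None)),)),
}


def filter_blast_hits(
    hits: Iterable[BlastHit],
    specs: Mapping[str, FilterSpec] = DEFAULT_FILTERS,
) -> list[tuple[BlastHit, str]]:
    """Screen BLAST hits, returning accepted hits with the matched rule name.

    Raises ``KeyError`` for hits whose query protein has no FilterSpec.
    Filtering is idempotent: re-filtering the accepted hits changes nothing.
    """
    accepted: list[tuple[BlastHit, str]] = []
    for hit in hits:
        if hit.protein_query not in specs:
            raise KeyError(
                f"no filter criteria for query protein {hit.protein_query!r}"
            )
        rule_name = specs[hit.protein_query].evaluate(hit)
        if rule_name is not None:
            accepted.append((hit, rule_name))
    return accepted


SIMPLE_TSV_COLUMNS = (
    "species_id",
    "replicon_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "che_type",
)


def _type_from_token(text: str) -> str:
    m = _GENE_TOKEN_RE.search(text or "")
    return m.group(1).upper() if m else "other"


def assign_che_type(
    gene_id: str,
    gene_name: str,
    product: str = "",
    type_map: Mapping[str, str] | None = None,
) -> str:
    """Resolve a che type: explicit mapping first, then gene/product tokens."""
    if type_map and gene_id in type_map:
        return type_map[gene_id]
    for text in (gene_name, product):
        t = _type_from_token(text)
        if t != "other":
            return t
    return "other"


def read_gene_table(
    path: str | Path,
    dialect: str = "simple-tsv",
    species_id: str | None = None,
    replicon_id: str | None = None,
    type_map: Mapping[str, str] | None = None,
) -> list[GeneRecord]:
    """Read a gene-location table, sorted by species, replicon and start.

    ``simple-tsv`` is the package dialect (header + one gene per row);
    ``ptt`` is the NCBI protein table, which carries no species or replicon
    identifiers, so these must be supplied by the caller (the replicon
    defaults to the file stem).
    """
    path = Path(path)
    if dialect == "simple-tsv":
        records = _read_simple_tsv(path)
    elif dialect == "ptt":
        records = _read_ptt(path, species_id, replicon_id, type_map)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_duplicates(records)
    records.sort(key=lambda g: (g.species_id, g.replicon_id, g.start, g.end))
    return records


def _check_duplicates(records: Sequence[GeneRecord]) -> None:
    seen: set[tuple[str, str]] = set()
    for g in records:
        key = (g.species_id, g.gene_id)
        if key in seen:
            raise ValueError(
                f"duplicate gene id {g.gene_id!r} within species {g.species_id!r}"
            )
        seen.add(key)


def _read_simple_tsv(path: Path) -> list[GeneRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != SIMPLE_TSV_COLUMNS:
            expected = "\t".join(SIMPLE_TSV_COLUMNS)
            raise ValueError(f"{path}: expected header {expected!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(SIMPLE_TSV_COLUMNS):
                raise ValueError(f"{path}: line {lineno}: expected 7 columns")
            sp, rep, gid, start, end, strand, ctype = row
            try:
                records.append(
                    GeneRecord(gid, sp, rep, int(start), int(end), strand, ctype)
                )
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records


_LOCATION_RE = re.compile(r"^(\d+)\.\.(\d+)$")


def _read_ptt(
    path: Path,
    species_id: str | None,
    replicon_id: str | None,
    type_map: Mapping[str, str] | None,
) -> list[GeneRecord]:
    species_id = species_id or path.stem
    replicon_id = replicon_id or path.stem
    with open(path) as fh:
        lines = fh.read().splitlines()
    # ptt layout: description line, "N proteins" line, column header, data.
    header_idx = None
    for i, line in enumerate(lines):
        if line.startswith("Location\t"):
            header_idx = i
            break
    if header_idx is None:
        raise ValueError(f"{path}: no ptt column header ('Location\\t...') found")
    columns = lines[header_idx].split("\t")
    col = {name: j for j, name in enumerate(columns)}
    for required in ("Location", "Strand", "PID"):
        if required not in col:
            raise ValueError(f"{path}: ptt header lacks column {required!r}")
    records = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        loc = fields[col["Location"]]
        m = _LOCATION_RE.match(loc.strip())
        if m is None:
            raise ValueError(
                f"{path}: line {lineno}: unparseable Location field {loc!r}"
            )
        start, end = int(m.group(1)), int(m.group(2))
        strand = fields[col["Strand"]].strip()
        gene_id = fields[col["PID"]].strip()
        gene_name = fields[col["Gene"]].strip() if "Gene" in col else ""
        product = fields[col["Product"]].strip() if "Product" in col else ""
        che_type = assign_che_type(gene_id, gene_name, product, type_map)
        try:
            records.append(
                GeneRecord(gene_id, species_id, replicon_id, start, end, strand, che_type)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write records to the simple-tsv dialect (lossless round-trip)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SIMPLE_TSV_COLUMNS)
        for g in records:
            writer.writerow(
                [g.species_id, g.replicon_id, g.gene_id, g.start, g.end, g.strand, g.che_type]
            )
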