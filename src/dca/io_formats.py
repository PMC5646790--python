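"""Readers and writers for the external text formats.

All downstream code operates on the clean in-memory types defined here:
an undirected :class:`networkx.Graph` for the interactome, an
:class:`ExpressionProfileSet` for the time-course matrix, a
:class:`ComplexSet` for predicted or reference complexes, and an
:class:`AnnotationMap` for gene -> functional-term tables.

Formats are deliberately simple delimited text: a two-column PPI edge
list (DIP-style pairs), a gene x T expression matrix with a header row,
one complex per line for references (CYC2008-style), and a five-column
prediction table (id, time_point, core, attachments, score) with
';'-joined member lists.  Comment lines start with ``#``; the delimiter
is auto-detected among tab, comma and whitespace unless given.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence, TextIO

import networkx as nx
import numpy as np

logger = logging.getLogger("dca")

PREDICTION_HEADER = "#id\ttime_point\tcore\tattachments\tscore"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionProfileSet:
    """Gene -> expression vector over ``n_timepoints`` time points.

    Vectors all share the same length; gene identifiers are unique after
    probe aggregation.
    """

    profiles: dict[str, np.ndarray]
    n_timepoints: int

    def __post_init__(self) -> None:
        for gene, vec in self.profiles.items():
            if len(vec) != self.n_timepoints:
                raise ValueError(
                    f"profile for {gene!r} has length {len(vec)}, "
                    f"expected {self.n_timepoints}"
                )

    def __len__(self) -> int:
        return len(self.profiles)

    def genes(self) -> set[str]:
        return set(self.profiles)


@dataclass(frozen=True)
class Complex:
    """A predicted or reference complex: disjoint core and attachment sets.

    ``time_point`` is the 1-based snapshot the complex was detected in
    (0 for reference complexes, where the notion does not apply).
    ``score`` is the summed node weight of its members for predictions.
    """

    id: str
    core: frozenset[str]
    attachments: frozenset[str] = frozenset()
    time_point: int = 0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.core & self.attachments:
            raise ValueError("core and attachments must be disjoint")

    @property
    def members(self) -> frozenset[str]:
        return self.core | self.attachments

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ComplexSet:
    """Ordered list of :class:`Complex` records plus a provenance label."""

    complexes: list[Complex]
    provenance: str = "predicted"  # "predicted" | "reference"

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def __getitem__(self, i):
        return self.complexes[i]

    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.complexes]


@dataclass
class AnnotationMap:
    """Functional term -> annotated gene set, with background size N."""

    terms: dict[str, set[str]]
    background_n: int

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
        union = set().union(*self.terms.values()) if self.terms else set()
        if self.background_n < len(union):
            raise ValueError(
                f"background N={self.background_n} smaller than the "
                f"{len(union)} distinct annotated genes"
            )


# ---------------------------------------------------------------------------
# low-level line handling
# ---------------------------------------------------------------------------

def _split(line: str, delimiter: str | None) -> list[str]:
    if delimiter is None:
        # auto-detect per line: tab beats comma beats any whitespace
        if "\t" in line:
            return [f.strip() for f in line.split("\t")]
        if "," in line:
            return [f.strip() for f in line.split(",")]
        return line.split()
    if delimiter.isspace() or delimiter == "":
        return line.split()
    return [f.strip() for f in line.split(delimiter)]


def _data_lines(stream: TextIO) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line) skipping blanks/comments."""
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


# ---------------------------------------------------------------------------
# PPI edge list
# ---------------------------------------------------------------------------

def read_ppi_edgelist(
    stream: TextIO,
    *,
    delimiter: str | None = None,
    case_fold: bool = True,
) -> nx.Graph:
    """Read a two-column interaction list into an undirected simple graph.

    Self-loops are dropped (with a logged count) and duplicate or
    reversed-duplicate edges are collapsed.  Identifiers are upper-cased
    by default because yeast ORF names appear in mixed case across the
    common sources.
    """
    graph = nx.Graph()
    n_self_loops = 0
    n_lines = 0
    for lineno, line in _data_lines(stream):
        fields = _split(line, delimiter)
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise FormatError(f"line {lineno}: expected two identifiers, got {line!r}")
        n_lines += 1
        a, b = fields[0], fields[1]
        if case_fold:
            a, b = a.upper(), b.upper()
        if a == b:
            n_self_loops += 1
            continue
        graph.add_edge(a, b)
    if n_lines == 0:
        raise FormatError("empty PPI edge list")
    if n_self_loops:
        logger.info("dropped %d self-loop(s) from PPI edge list", n_self_loops)
    return graph


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(
    stream: TextIO,
    *,
    delimiter: str | None = None,
    id_column: int = 0,
    probe_map: Mapping[str, str] | None = None,
    aggregate: str = "max",
    case_fold: bool = True,
) -> ExpressionProfileSet:
    """Read a probe/gene x T matrix with a header row naming the T columns.

    Probes mapping to the same gene (via ``probe_map`` or duplicate
    identifiers) are aggregated per time point, by maximum by default
    (conservative activity calling when probes disagree) or by mean.
    """
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    lines = _data_lines(stream)
    try:
        _, header = next(lines)
    except StopIteration:
        raise FormatError("empty expression matrix") from None
    n_cols = len(_split(header, delimiter))
    n_timepoints = n_cols - 1
    if n_timepoints < 1:
        raise FormatError("expression matrix header names no time-point columns")

    vectors: dict[str, list[np.ndarray]] = {}
    for lineno, line in lines:
        fields = _split(line, delimiter)
        if len(fields) != n_cols:
            raise FormatError(
                f"line {lineno}: ragged row ({len(fields)} fields, expected {n_cols})"
            )
        probe = fields[id_column]
        if case_fold:
            probe = probe.upper()
        gene = probe_map.get(probe, probe) if probe_map else probe
        if case_fold:
            gene = gene.upper()
        values = fields[:id_column] + fields[id_column + 1:]
        try:
            vec = np.array([float(v) for v in values], dtype=float)
        except ValueError:
            raise FormatError(f"line {lineno}: unparseable expression value") from None
        if not np.all(np.isfinite(vec)):
            raise FormatError(f"line {lineno}: non-finite expression value")
        vectors.setdefault(gene, []).append(vec)

    if not vectors:
        raise FormatError("expression matrix has no data rows")
    reduce: Callable = np.maximum.reduce if aggregate == "max" else (
        lambda vs: np.mean(vs, axis=0)
    )
    profiles = {gene: np.asarray(reduce(vs), dtype=float) for gene, vs in vectors.items()}
    return ExpressionProfileSet(profiles=profiles, n_timepoints=n_timepoints)


def filter_unexpressed(
    net: nx.Graph, profiles: ExpressionProfileSet
) -> nx.Graph:
    """Drop network proteins with no expression profile (logged count).

    Mirrors the usual preprocessing step of removing the small number of
    interactome proteins that were never measured on the array.
    """
    missing = set(net.nodes) - profiles.genes()
    if not missing:
        return net
    logger.info("dropped %d network protein(s) without expression", len(missing))
    kept = net.subgraph(set(net.nodes) - missing).copy()
    return kept


# ---------------------------------------------------------------------------
# complex sets
# ---------------------------------------------------------------------------

def read_complex_set(
    stream: TextIO,
    *,
    min_size: int = 2,
    case_fold: bool = True,
    provenance: str = "reference",
) -> ComplexSet:
    """Read complexes from either supported dialect.

    The reference dialect is one complex per line, members whitespace- or
    tab-separated.  The prediction dialect (as written by
    :func:`write_complex_set`) is five tab-separated columns
    ``id, time_point, core, attachments, score`` with ';'-joined members,
    announced by a header comment; it round-trips exactly.
    Lines with fewer than ``min_size`` members are skipped with a warning.
    """
    text = stream.read()
    is_prediction = any(
        line.startswith(PREDICTION_HEADER) for line in text.splitlines()
    )
    complexes: list[Complex] = []
    n_skipped = 0
    for lineno, line in _data_lines(_as_stream(text)):
        if is_prediction:
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(
                    f"line {lineno}: expected 5 prediction columns, got {len(fields)}"
                )
            cid, tp, core_s, att_s, score_s = fields
            core = frozenset(_fold(core_s.split(";"), case_fold)) if core_s else frozenset()
            atts = frozenset(_fold(att_s.split(";"), case_fold)) if att_s else frozenset()
            cx = Complex(
                id=cid,
                core=core,
                attachments=atts,
                time_point=int(tp),
                score=float(score_s),
            )
        else:
            members = _fold(line.split(), case_fold)
            cx = Complex(id=f"C{len(complexes) + 1}", core=frozenset(members))
        if len(cx) < min_size:
            n_skipped += 1
            logger.warning(
                "line %d: complex with %d member(s) < min_size=%d skipped",
                lineno, len(cx), min_size,
            )
            continue
        complexes.append(cx)
    if n_skipped:
        logger.info("skipped %d undersized complex line(s)", n_skipped)
    return ComplexSet(complexes=complexes, provenance=provenance)


def _fold(items: Sequence[str], case_fold: bool) -> list[str]:
    items = [i for i in items if i]
    return [i.upper() for i in items] if case_fold else list(items)


def _as_stream(text: str):
    import io

    return io.StringIO(text)


def write_complex_set(
    cset: ComplexSet,
    stream: TextIO,
    *,
    stamp: Mapping[str, object] | None = None,
) -> None:
    """Write the prediction dialect; ``stamp`` items become header comments."""
    if stamp:
        for key in sorted(stamp):
            stream.write(f"# {key} = {stamp[key]}\n")
    stream.write(PREDICTION_HEADER + "\n")
    for cx in cset:
        core = ";".join(sorted(cx.core))
        atts = ";".join(sorted(cx.attachments))
        stream.write(
            f"{cx.id}\t{cx.time_point}\t{core}\t{atts}\t{_fmt_score(cx.score)}\n"
        )


def _fmt_score(score: float) -> str:
    if math.isclose(score, round(score), abs_tol=1e-12):
        return f"{score:.1f}"
    return repr(score)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotation_table(
    stream: TextIO,
    *,
    delimiter: str | None = None,
    background_n: int | None = None,
    case_fold: bool = True,
) -> AnnotationMap:
    """Read a two-column gene, term table and invert it to term -> genes.

    ``background_n`` is the genome size N of the enrichment test; when
    absent it defaults to the number of distinct annotated genes.
    """
    terms: dict[str, set[str]] = {}
    genes_seen: set[str] = set()
    for lineno, line in _data_lines(stream):
        fields = _split(line, delimiter)
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise FormatError(f"line {lineno}: expected gene and term columns")
        gene, term = fields[0], fields[1]
        if case_fold:
            gene = gene.upper()
        terms.setdefault(term, set()).add(gene)
        genes_seen.add(gene)
    if not terms:
        raise FormatError("empty annotation table")
    n = background_n if background_n is not None else len(genes_seen)
    return AnnotationMap(terms=terms, background_n=n)


# ---------------------------------------------------------------------------
# expression writer (used by the simulator CLI)
# ---------------------------------------------------------------------------

def write_expression_matrix(profiles: ExpressionProfileSet, stream: TextIO) -> None:
    header = "gene\t" + "\t".join(f"t{i+1}" for i in range(profiles.n_timepoints))
    stream.write(header + "\n")
    for gene in sorted(profiles.profiles):
        vec = profiles.profiles[gene]
        stream.write(gene + "\t" + "\t".join(f"{v:.4f}" for v in vec) + "\n")


def write_ppi_edgelist(net: nx.Graph, stream: TextIO) -> None:
    for a, b in sorted(tuple(sorted(e)) for e in net.edges):
        stream.write(f"{a}\t{b}\n")
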