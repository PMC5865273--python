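"""Pipeline plumbing: read-mapper output ingestion, stage driver, TSV writers.

The pipeline mirrors the production workflow: candidate matches per read
(e.g. BLAST tabular filtered to top-E-value ties) are resolved to reference
leaves, each read is annotated at its indicator-optimal nodes, whole-sample
ambiguity is removed by set cover, and a relative abundance profile is
derived (optionally rolled up to a taxonomic rank).
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from fractions import Fraction
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .annotation import (
    ReadAnnotation,
    ReadCandidates,
    ambiguity_histogram,
    annotate_sample,
)
from .confusion import Indicator
from .setcover import (
    Cover,
    SetCoverInstance,
    abundance_profile,
    assign_reads,
    build_instance,
    greedy_cover,
    min_cardinality_cover,
    min_total_size_cover,
    rollup_profile,
)
from .taxonomy import TaxonomyError, TaxonomyTree

__all__ = [
    "MatchRecord",
    "BlastFormatError",
    "MappingError",
    "parse_blast_tabular",
    "to_read_candidates",
    "run_pipeline",
    "PipelineResult",
    "write_annotations_tsv",
    "write_cover_tsv",
    "write_profile_tsv",
]


class BlastFormatError(ValueError):
    """Malformed row in a BLAST tabular file (message carries the line number)."""


class MappingError(TaxonomyError):
    """Subject ids that cannot be resolved to reference leaves (strict mode)."""


@dataclass(frozen=True)
class MatchRecord:
    """One read-to-reference match; raw fields are preserved."""

    read_id: str
    subject_id: str
    e_value: Decimal
    bitscore: float | None = None
    fields: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.read_id or not self.subject_id:
            raise ValueError("read_id and subject_id must be non-empty")
        if self.e_value < 0:
            raise ValueError(f"negative E-value: {self.e_value}")


def parse_blast_tabular(source: str | Path | IO[str] | Iterable[str]) -> list[MatchRecord]:
    """Parse 12-column BLAST tabular output (outfmt 6) and keep, per read,
    exactly the hits whose E-value equals the read's minimum E-value.

    E-values are compared as decimals after normalization, so ``1e-30``,
    ``1E-30`` and ``1.0e-30`` tie.  Input order is preserved.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return parse_blast_tabular(fh)

    records: list[MatchRecord] = []
    for lineno, line in enumerate(source, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 12:
            raise BlastFormatError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(parts)}")
        try:
            e_value = Decimal(parts[10].strip())
        except InvalidOperation:
            raise BlastFormatError(
                f"line {lineno}: non-numeric E-value {parts[10]!r}") from None
        try:
            bitscore = float(parts[11])
        except ValueError:
            raise BlastFormatError(
                f"line {lineno}: non-numeric bit score {parts[11]!r}") from None
        records.append(MatchRecord(
            read_id=parts[0], subject_id=parts[1], e_value=e_value,
            bitscore=bitscore, fields=tuple(parts)))

    best: dict[str, Decimal] = {}
    for rec in records:
        cur = best.get(rec.read_id)
        if cur is None or rec.e_value < cur:
            best[rec.read_id] = rec.e_value
    return [rec for rec in records if rec.e_value == best[rec.read_id]]


def to_read_candidates(
    matches: Sequence[MatchRecord],
    tree: TaxonomyTree,
    mapping: Mapping[str, str] | None = None,
    strict: bool = False,
) -> tuple[list[ReadCandidates], list[str]]:
    """Resolve subject ids to reference leaves and collect candidate sets.

    ``mapping`` optionally translates subject ids to leaf labels first.
    Returns (candidates, unassigned read ids); reads with no resolvable
    subject are reported, never silently dropped.  In strict mode any
    unresolvable subject id raises :class:`MappingError` listing offenders.
    """
    leaf_labels = {tree.label(v): v for v in tree.leaves}
    per_read: dict[str, set[int]] = {}
    order: list[str] = []
    bad_subjects: set[str] = set()
    for rec in matches:
        if rec.read_id not in per_read:
            per_read[rec.read_id] = set()
            order.append(rec.read_id)
        label = mapping.get(rec.subject_id, rec.subject_id) if mapping else rec.subject_id
        leaf = leaf_labels.get(label)
        if leaf is None:
            bad_subjects.add(rec.subject_id)
        else:
            per_read[rec.read_id].add(leaf)
    if strict and bad_subjects:
        raise MappingError(
            "unresolvable subject ids: " + ", ".join(sorted(bad_subjects)))
    assigned = [ReadCandidates(read_id=r, m=frozenset(per_read[r]))
                for r in order if per_read[r]]
    unassigned = [r for r in order if not per_read[r]]
    return assigned, unassigned


_SOLVERS = {
    "min_total_size": min_total_size_cover,
    "min_cardinality": min_cardinality_cover,
    "greedy": greedy_cover,
}


@dataclass(frozen=True)
class PipelineResult:
    """Everything the pipeline computed, stage by stage."""

    annotations: list[ReadAnnotation]
    unassigned: list[str]
    instance: SetCoverInstance
    cover: Cover
    assignments: Mapping[str, Mapping[str, Fraction]]
    profile: Mapping[str, Fraction]
    rolled_profile: Mapping[str, Fraction] | None
    histogram_before: Mapping[int, int]
    histogram_after: Mapping[int, int]


def run_pipeline(
    tree: TaxonomyTree,
    reads: Sequence[ReadCandidates] | Sequence[MatchRecord],
    *,
    kind: Indicator = Indicator.RAND,
    solver: str = "min_total_size",
    rank: str | None = None,
    mapping: Mapping[str, str] | None = None,
    strict: bool = False,
    out_dir: str | Path | None = None,
    log: IO[str] | None = None,
) -> PipelineResult:
    """Annotate -> set cover -> abundance profile, deterministically.

    ``reads`` may be pre-built :class:`ReadCandidates` or raw
    :class:`MatchRecord` lists (then subject resolution runs first).
    ``solver`` is ``min_total_size`` (default; least overlap),
    ``min_cardinality``, or ``greedy``.  If ``out_dir`` is given, writes
    ``annotations.tsv``, ``cover.tsv`` and ``profile.tsv`` there.
    """
    if solver not in _SOLVERS:
        raise ValueError(f"solver must be one of {sorted(_SOLVERS)}, got {solver!r}")
    log = log if log is not None else sys.stderr

    def stage(msg: str) -> float:
        print(f"[taxocover] {msg}", file=log)
        return time.perf_counter()

    unassigned: list[str] = []
    if reads and isinstance(reads[0], MatchRecord):
        t0 = stage("resolving candidate matches")
        candidates, unassigned = to_read_candidates(
            list(reads), tree, mapping=mapping, strict=strict)
        stage(f"  {len(candidates)} reads assigned, {len(unassigned)} unassigned "
              f"({time.perf_counter() - t0:.3f}s)")
    else:
        candidates = list(reads)  # type: ignore[arg-type]
    if not candidates:
        raise TaxonomyError("no assignable reads in input")

    t0 = stage(f"annotating {len(candidates)} reads ({Indicator(kind).value})")
    annotations = annotate_sample(tree, candidates, kind)
    hist_before = ambiguity_histogram(annotations)
    stage(f"  ambiguity histogram {hist_before} ({time.perf_counter() - t0:.3f}s)")

    t0 = stage(f"solving set cover ({solver})")
    instance = build_instance(annotations, name_of_node=tree.display_name)
    cover = _SOLVERS[solver](instance)
    assignments = assign_reads(instance, cover)
    stage(f"  cover size {cover.size}, total size {cover.total_size}, "
          f"overlap {cover.overlap} ({time.perf_counter() - t0:.3f}s)")

    hist_after = {}
    for shares in assignments.values():
        k = len(shares)
        hist_after[k] = hist_after.get(k, 0) + 1
    hist_after = dict(sorted(hist_after.items()))

    profile = abundance_profile(assignments)
    rolled = rollup_profile(tree, profile, rank) if rank else None

    result = PipelineResult(
        annotations=annotations, unassigned=unassigned, instance=instance,
        cover=cover, assignments=assignments, profile=profile,
        rolled_profile=rolled, histogram_before=hist_before,
        histogram_after=hist_after)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_annotations_tsv(tree, annotations, out_dir / "annotations.tsv")
        write_cover_tsv(cover, out_dir / "cover.tsv")
        write_profile_tsv(rolled if rolled is not None else profile,
                          out_dir / "profile.tsv")
    return result


# -- writers -----------------------------------------------------------------


def write_annotations_tsv(tree: TaxonomyTree, annotations: Sequence[ReadAnnotation],
                          path: str | Path) -> None:
    """read_id, score, comma-separated node labels (one row per read)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("read_id\tscore\tnodes\n")
        for ann in annotations:
            nodes = ",".join(sorted(tree.display_name(v) for v in ann.argmax_nodes))
            fh.write(f"{ann.read_id}\t{float(ann.score):.12g}\t{nodes}\n")


def write_cover_tsv(cover: Cover, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tsize\ttotal_size\toverlap\n")
        for name in cover.chosen:
            fh.write(f"{name}\t{cover.size}\t{cover.total_size}\t{cover.overlap}\n")


def write_profile_tsv(profile: Mapping[str, Fraction], path: str | Path) -> None:
    """Percentages to 2 decimals plus an exact full-precision column."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node\tabundance_pct\tabundance_exact\n")
        for name, value in profile.items():
            fh.write(f"{name}\t{float(value):.2f}\t{value}\n")
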