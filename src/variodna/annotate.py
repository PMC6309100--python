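"""Per-variant annotation records and TSV/JSON serialization.

Each input variant yields one :class:`AnnotationRecord` holding its
labels grouped by branch (variation type, affected level, and the
branch-validated manual origin/function/property/structure terms),
processing flags, and optional ECO evidence codes.  Failures never
abort a stream: a record with ``error`` set takes the failed input's
place, so output row count always equals input count.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .classify import (
    EditClass,
    NormalizedEdit,
    TermPath,
    classify_variation_type,
    genomic_level_paths,
    classify_affected_level,
    most_specific,
    validate_branch_terms,
    RegionModel,
)
from .errors import EvidenceFormatError, VariOError
from .hgvs_dna import EditKind, HgvsDescription, parse_hgvs, to_string
from .term_model import AnnotationLabel, OntologyGraph, load_packaged_graph, parse_label

logger = logging.getLogger(__name__)

_ECO_RE = re.compile(r"^ECO:\d{7}$")

#: Branch keys of a record, in output column order.
BRANCH_KEYS = ("type", "level", "origin", "function", "property", "structure")

#: Branches that accept manually supplied accessions.
MANUAL_BRANCHES = ("origin", "function", "property", "structure")

#: Column-name preset for export toward LOVD instances.
LOVD_COLUMNS = {
    "variant": "VariantOnGenome/DNA",
    "type_labels": "VariantOnGenome/VariO/Type",
    "level_labels": "VariantOnGenome/VariO/Level",
    "origin_labels": "VariantOnGenome/VariO/Origin",
    "function_labels": "VariantOnGenome/VariO/Function",
    "property_labels": "VariantOnGenome/VariO/Property",
    "structure_labels": "VariantOnGenome/VariO/Structure",
    "flags": "VariantOnGenome/VariO/Flags",
    "evidence": "VariantOnGenome/VariO/Evidence",
    "error": "VariantOnGenome/VariO/Error",
}

COLUMNS = (
    "variant",
    "type_labels",
    "level_labels",
    "origin_labels",
    "function_labels",
    "property_labels",
    "structure_labels",
    "flags",
    "evidence",
    "error",
)


@dataclass
class AnnotationRecord:
    """One variant's VariO labels grouped by branch."""

    variant: str
    labels: dict[str, list[AnnotationLabel]] = field(
        default_factory=lambda: {k: [] for k in BRANCH_KEYS}
    )
    flags: list[str] = field(default_factory=list)
    evidence: list[str] = field(default_factory=list)
    error: str | None = None


def attach_evidence(record: AnnotationRecord, eco_code: str) -> AnnotationRecord:
    """Append an ECO evidence code (``ECO:NNNNNNN``); duplicates are ignored."""
    if not _ECO_RE.match(eco_code):
        raise EvidenceFormatError(
            f"evidence code must match ECO:NNNNNNN, got {eco_code!r}"
        )
    if eco_code not in record.evidence:
        record.evidence.append(eco_code)
    return record


def _emit(path: TermPath, graph: OntologyGraph, full_path: bool) -> list[AnnotationLabel]:
    accs = list(path) if full_path else [path.deepest]
    return [AnnotationLabel.from_term(graph.get_term(a)) for a in accs]


def _validated_manual(
    manual: dict[str, list[int]] | None, graph: OntologyGraph
) -> dict[str, list[int]]:
    """Branch-validate the manual term map once, up front."""
    out: dict[str, list[int]] = {}
    if not manual:
        return out
    for branch, accessions in manual.items():
        if branch not in MANUAL_BRANCHES:
            raise ValueError(
                f"manual terms accept branches {MANUAL_BRANCHES}, got {branch!r}"
            )
        report = validate_branch_terms(list(accessions), branch, graph)
        if not report.ok:
            detail = "; ".join(f"{a}: {why}" for a, why in report.violations)
            raise VariOError(f"manual {branch} terms invalid: {detail}")
        out[branch] = most_specific(report.valid, graph)
    return out


def annotate_stream(
    variants: Iterable,
    regions: RegionModel | None = None,
    manual: dict[str, list[int]] | None = None,
    graph: OntologyGraph | None = None,
    full_path: bool = False,
    sequence: str | None = None,
) -> Iterator[AnnotationRecord]:
    """Annotate a stream of variants, one record per input, order preserved.

    Accepted items: raw HGVS strings, parsed :class:`HgvsDescription`,
    :class:`NormalizedEdit`, or ``(identifier, NormalizedEdit)`` pairs
    (as produced from VCF records).  Per-item failures become records
    with ``error`` set; the stream itself never aborts.
    """
    graph = graph or load_packaged_graph()
    manual_labels = {
        branch: [AnnotationLabel.from_term(graph.get_term(a)) for a in accs]
        for branch, accs in _validated_manual(manual, graph).items()
    }
    n_ok = n_err = 0
    for item in variants:
        try:
            ident, desc, edit = _coerce(item)
        except VariOError as exc:
            record = AnnotationRecord(str(item).strip(), error=str(exc))
            n_err += 1
            yield record
            continue
        record = AnnotationRecord(ident)
        for branch, labels in manual_labels.items():
            record.labels[branch] = list(labels)
        try:
            target = desc if desc is not None else edit
            type_path = classify_variation_type(target)
            record.labels["type"] = _emit(type_path, graph, full_path)
            if desc is not None:
                if desc.edit_kind is EditKind.DUPLICATION:
                    record.flags.append("dup_as_insertion")
                level_paths = classify_affected_level(desc, regions, sequence)
            else:
                level_paths = genomic_level_paths(edit.position, regions, sequence)
            record.labels["level"] = [
                lab for p in level_paths for lab in _emit(p, graph, full_path)
            ]
            n_ok += 1
        except VariOError as exc:
            record.error = str(exc)
            n_err += 1
        logger.debug("annotated %s: error=%s", record.variant, record.error)
        yield record
    logger.info("annotated %d records, %d errors", n_ok, n_err)


def _coerce(item) -> tuple[str, HgvsDescription | None, NormalizedEdit | None]:
    if isinstance(item, str):
        desc = parse_hgvs(item)  # HgvsSyntaxError propagates to the caller
        return to_string(desc), desc, None
    if isinstance(item, HgvsDescription):
        return to_string(item), item, None
    if isinstance(item, NormalizedEdit):
        return f"{item.position}:{item.ref or '-'}>{item.alt or '-'}", None, item
    if isinstance(item, tuple) and len(item) == 2 and isinstance(item[1], NormalizedEdit):
        return str(item[0]), None, item[1]
    raise TypeError(f"cannot annotate {type(item).__name__}")


# -- serialization -------------------------------------------------------------


def _row(record: AnnotationRecord) -> dict[str, str]:
    row = {"variant": record.variant}
    for key in BRANCH_KEYS:
        row[f"{key}_labels"] = ";".join(l.rendered for l in record.labels[key])
    row["flags"] = ";".join(record.flags)
    row["evidence"] = ";".join(record.evidence)
    row["error"] = record.error or ""
    return row


def write_tsv(
    records: Iterable[AnnotationRecord], path: str | Path, lovd: bool = False
) -> None:
    """Write records as TSV, one row per record; ``lovd`` renames columns."""
    header = [LOVD_COLUMNS[c] if lovd else c for c in COLUMNS]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(header) + "\n")
        for record in records:
            row = _row(record)
            fh.write("\t".join(row[c] for c in COLUMNS) + "\n")


def read_tsv(path: str | Path, graph: OntologyGraph | None = None) -> list[AnnotationRecord]:
    """Read records written by :func:`write_tsv`; labels re-validated."""
    graph = graph or load_packaged_graph()
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0].split("\t")
    reverse = {v: k for k, v in LOVD_COLUMNS.items()}
    header = [reverse.get(c, c) for c in header]
    out = []
    for line in lines[1:]:
        cells = dict(zip(header, line.split("\t")))
        record = AnnotationRecord(cells["variant"])
        for key in BRANCH_KEYS:
            rendered = cells.get(f"{key}_labels", "")
            record.labels[key] = [
                parse_label(r, graph) for r in rendered.split(";") if r
            ]
        record.flags = [f for f in cells.get("flags", "").split(";") if f]
        record.evidence = [e for e in cells.get("evidence", "").split(";") if e]
        record.error = cells.get("error") or None
        out.append(record)
    return out


def write_json(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    """Write records as a JSON array mirroring the record structure."""
    payload = []
    for record in records:
        payload.append(
            {
                "variant": record.variant,
                "labels": {
                    key: [l.rendered for l in record.labels[key]]
                    for key in BRANCH_KEYS
                },
                "flags": record.flags,
                "evidence": record.evidence,
                "error": record.error,
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_json(path: str | Path, graph: OntologyGraph | None = None) -> list[AnnotationRecord]:
    """Read records written by :func:`write_json`; labels re-validated."""
    graph = graph or load_packaged_graph()
    out = []
    for entry in json.loads(Path(path).read_text(encoding="utf-8")):
        record = AnnotationRecord(entry["variant"])
        record.labels = {
            key: [parse_label(r, graph) for r in entry["labels"].get(key, [])]
            for key in BRANCH_KEYS
        }
        record.flags = list(entry.get("flags", []))
        record.evidence = list(entry.get("evidence", []))
        record.error = entry.get("error")
        out.append(record)
    return out


def summarize(records: Iterable[AnnotationRecord]) -> dict:
    """End-of-run counts: annotated / errored and per deepest type term."""
    summary: dict = {"annotated": 0, "errored": 0, "by_type": {}}
    for record in records:
        if record.error:
            summary["errored"] += 1
            continue
        summary["annotated"] += 1
        if record.labels["type"]:
            leaf = record.labels["type"][-1].rendered
            summary["by_type"][leaf] = summary["by_type"].get(leaf, 0) + 1
    return summary
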