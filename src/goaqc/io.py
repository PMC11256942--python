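"""Readers and writers for the flat-file dialects the pipeline touches.

All formats are local tab-separated or JSON-lines dialects modeled on the
public NCBI layouts (gene2go, GeneRIF), so the whole pipeline runs from
files with no network access.  PMID and gene identifiers are stored with
their prefixes (``PMID:``, ``Gene:``) exactly as instance keys print them.
Writers embed a provenance header (seed, config hash) as a ``#`` comment
line; readers skip such lines.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

from .synthesis import GoaInstance, Provenance
from .tagging import EntitySpan


class FormatError(ValueError):
    """Malformed row in a flat file; the message names the line number."""


def provenance_header(seed: int | None, config: Mapping | None = None) -> str:
    """``seed=… config_hash=…`` string embedded in every artifact file."""
    cfg_hash = hashlib.blake2b(
        json.dumps(config or {}, sort_keys=True, default=str).encode("utf-8"),
        digest_size=6,
    ).hexdigest()
    return f"goaqc seed={seed} config_hash={cfg_hash}"


# -- gene2go ---------------------------------------------------------------

@dataclass(frozen=True)
class Gene2GoRecord:
    """One row of the gene2go-style annotation table."""

    tax_id: str
    gene_id: str
    go_id: str
    evidence_code: str
    qualifier: str
    go_term_name: str
    pmids: tuple[str, ...]
    category: str


_GENE2GO_COLUMNS = [
    "tax_id", "GeneID", "GO_ID", "Evidence", "Qualifier", "GO_term",
    "PubMed", "Category",
]


def write_gene2go(records: Iterable[Gene2GoRecord], path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {provenance_header(seed)}\n")
        fh.write("\t".join(_GENE2GO_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.tax_id,
                        rec.gene_id,
                        rec.go_id,
                        rec.evidence_code,
                        rec.qualifier,
                        rec.go_term_name,
                        "|".join(rec.pmids) if rec.pmids else "-",
                        rec.category,
                    ]
                )
                + "\n"
            )


def read_gene2go(path) -> list[Gene2GoRecord]:
    """Read the tab-separated gene2go dialect (header row; # comments skipped)."""
    records: list[Gene2GoRecord] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != len(_GENE2GO_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_GENE2GO_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            pmids = tuple(p for p in parts[6].split("|") if p and p != "-")
            records.append(
                Gene2GoRecord(
                    tax_id=parts[0],
                    gene_id=parts[1],
                    go_id=parts[2],
                    evidence_code=parts[3],
                    qualifier=parts[4],
                    go_term_name=parts[5],
                    pmids=pmids,
                    category=parts[7],
                )
            )
    return records


def collect_existing(
    records: Sequence[Gene2GoRecord],
    gene_id: str,
    exclude_go_id: str | None = None,
) -> list[str]:
    """Existing annotations of a gene, minus the query instance's own term."""
    seen: list[str] = []
    for rec in records:
        if rec.gene_id != gene_id or rec.go_id == exclude_go_id:
            continue
        if rec.go_id not in seen:
            seen.append(rec.go_id)
    return seen


# -- GeneRIF ---------------------------------------------------------------

@dataclass(frozen=True)
class GeneRifRecord:
    """One GeneRIF statement: a short curated gene-function sentence."""

    tax_id: str
    gene_id: str
    pmids: tuple[str, ...]
    timestamp: str
    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise FormatError("GeneRIF statement text must be non-empty")


def write_generif(records: Iterable[GeneRifRecord], path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {provenance_header(seed)}\n")
        fh.write("tax_id\tGeneID\tPubMed\ttimestamp\tGeneRIF_text\n")
        for rec in records:
            fh.write(
                f"{rec.tax_id}\t{rec.gene_id}\t{'|'.join(rec.pmids)}\t"
                f"{rec.timestamp}\t{rec.text}\n"
            )


def read_generif(path) -> dict[tuple[str, str], list[GeneRifRecord]]:
    """Group GeneRIF rows by (PMID, gene id); one statement may serve many PMGs."""
    grouped: dict[tuple[str, str], list[GeneRifRecord]] = {}
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            rec = GeneRifRecord(
                tax_id=parts[0],
                gene_id=parts[1],
                pmids=tuple(p for p in parts[2].split("|") if p),
                timestamp=parts[3],
                text=parts[4],
            )
            for pmid in rec.pmids:
                grouped.setdefault((pmid, rec.gene_id), []).append(rec)
    for key in grouped:
        grouped[key].sort(key=lambda r: r.timestamp)
    return grouped


def generif_statement(
    grouped: Mapping[tuple[str, str], list[GeneRifRecord]],
    pmid: str,
    gene_id: str,
) -> str | None:
    """Single statement for a PMG: timestamp-ordered texts joined with '; '."""
    records = grouped.get((pmid, gene_id))
    if not records:
        return None
    return "; ".join(r.text for r in records)


# -- instance JSONL --------------------------------------------------------

def _span_to_json(span: EntitySpan) -> dict:
    return {
        "start": span.start,
        "end": span.end,
        "concept_type": span.concept_type,
        "matched_id": span.matched_id,
    }


def instance_to_json(inst: GoaInstance) -> dict:
    return {
        "go_id": inst.go_id,
        "gene_id": inst.gene_id,
        "pmid": inst.pmid,
        "evidence_text": inst.evidence_text,
        "label": inst.label,
        "generif_text": inst.generif_text,
        "entity_spans": [_span_to_json(s) for s in inst.entity_spans],
        "existing_go_ids": list(inst.existing_go_ids),
        "provenance": asdict(inst.provenance) if inst.provenance else None,
    }


def instance_from_json(obj: Mapping) -> GoaInstance:
    prov = obj.get("provenance")
    return GoaInstance(
        go_id=obj["go_id"],
        gene_id=obj["gene_id"],
        pmid=obj["pmid"],
        evidence_text=obj["evidence_text"],
        label=obj["label"],
        generif_text=obj.get("generif_text"),
        entity_spans=tuple(
            EntitySpan(
                start=s["start"],
                end=s["end"],
                concept_type=s["concept_type"],
                matched_id=s.get("matched_id"),
            )
            for s in obj.get("entity_spans") or ()
        ),
        existing_go_ids=tuple(obj.get("existing_go_ids") or ()),
        provenance=Provenance(**prov) if prov else None,
    )


def write_instances_jsonl(
    instances: Iterable[GoaInstance], path, seed: int | None = None,
    config: Mapping | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {provenance_header(seed, config)}\n")
        for inst in instances:
            fh.write(json.dumps(instance_to_json(inst), sort_keys=True) + "\n")


def read_instances_jsonl(path) -> list[GoaInstance]:
    instances: list[GoaInstance] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                instances.append(instance_from_json(json.loads(line)))
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return instances
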