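"""Readers and writers for the interchange formats.

FASTA for genomes and proteomes, GFF3 for gene models (1-based closed on
disk, 0-based half-open in memory) and a flat TSV for protein domain
annotations with columns ``protein_id  domain_type  start  end  score``.
"""

from __future__ import annotations

import math
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO

from .types import (
    AA_ALPHABET,
    DNA_ALPHABET,
    DomainHit,
    GeneModel,
    GenomeRecord,
    ProteinRecord,
)


class ParseError(ValueError):
    pass


def _first_bad_line(path: str | Path, bad_chars: set[str]) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad_chars:
                return lineno
    return -1


def read_fasta(path: str | Path, kind: str = "dna"):
    """Read a FASTA file as :class:`GenomeRecord` (``kind='dna'``) or
    :class:`ProteinRecord` (``kind='protein'``) objects, in file order.

    Sequences are upper-cased; whitespace is stripped by the parser. Illegal
    characters raise :class:`ParseError` naming the offending line.
    """
    if kind not in ("dna", "protein"):
        raise ValueError("kind must be 'dna' or 'protein'")
    alphabet = DNA_ALPHABET if kind == "dna" else AA_ALPHABET
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - alphabet
        if bad:
            lineno = _first_bad_line(path, bad)
            raise ParseError(
                f"{path}: illegal character(s) {sorted(bad)} in record "
                f"{rec.id!r} (line {lineno})"
            )
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {rec.id!r}")
        if kind == "dna":
            if rec.id in seen:
                raise ParseError(f"{path}: duplicate scaffold id {rec.id!r}")
            seen.add(rec.id)
            records.append(GenomeRecord(rec.id, seq))
        else:
            records.append(ProteinRecord(rec.id, seq))
    return records


def write_fasta(records, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rid = rec.scaffold_id if isinstance(rec, GenomeRecord) else rec.protein_id
            fh.write(f">{rid}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3: one :class:`GeneModel` per mRNA feature.

    CDS rows must carry ``Parent`` linkage to an mRNA; overlapping CDS within
    one model or orphan CDS raise :class:`ParseError`.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    mrna_ids = set()
    models = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        mrna_ids.add(mrna.id)
        cds = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds:
            raise ParseError(f"{path}: mRNA {mrna.id} has no CDS")
        exons = [(c.start - 1, c.end) for c in cds]  # to 0-based half-open
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        protein_id = mrna.attributes.get("protein_id", [mrna.id])[0]
        try:
            models.append(
                GeneModel(gene_id, mrna.seqid, mrna.strand, exons, protein_id)
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    for c in db.features_of_type("CDS"):
        parents = c.attributes.get("Parent")
        if not parents or parents[0] not in mrna_ids:
            raise ParseError(f"{path}: CDS {c.id} without mRNA parent")
    return models


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            lo, hi = m.span
            fh.write(
                f"{m.scaffold_id}\tdbdrescue\tgene\t{lo + 1}\t{hi}\t.\t"
                f"{m.strand}\t.\tID={m.gene_id}\n"
            )
            tid = f"{m.gene_id}.t1"
            fh.write(
                f"{m.scaffold_id}\tdbdrescue\tmRNA\t{lo + 1}\t{hi}\t.\t"
                f"{m.strand}\t.\tID={tid};Parent={m.gene_id};"
                f"protein_id={m.protein_id}\n"
            )
            for i, (s, e) in enumerate(sorted(m.exons), start=1):
                fh.write(
                    f"{m.scaffold_id}\tdbdrescue\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t0\tID={tid}.cds{i};Parent={tid}\n"
                )


_DOMAIN_COLS = ["protein_id", "domain_type", "start", "end", "score"]


def read_domain_tsv(path: str | Path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"protein_id": str})
    missing = set(_DOMAIN_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return [
        DomainHit(
            r.protein_id, r.domain_type, int(r.start), int(r.end),
            math.nan if pd.isna(r.score) else float(r.score),
        )
        for r in df.itertuples()
    ]


def write_domain_tsv(hits: list[DomainHit], path: str | Path) -> None:
    rows = [
        {
            "protein_id": h.protein_id,
            "domain_type": h.domain_type,
            "start": h.start,
            "end": h.end,
            "score": "." if math.isnan(h.score) else h.score,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=_DOMAIN_COLS).to_csv(path, sep="\t", index=False)
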