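"""Readers and writers: gene-table TSV, GenBank flat files, FASTA.

The gene-table dialect has the tab-separated header
``Gene Strand Location Length Anticodon StartCodon StopCodon OVL_ITS``
with ``Location`` formatted ``start-end`` (1-based inclusive) and ``-``
for missing values.  The ``OVL_ITS`` column is retained on read for
cross-checking but junction gaps are always recomputed from coordinates.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import Feature, GeneTable, GenomeRecord, ValidationError

__all__ = [
    "TABLE_COLUMNS",
    "ParseError",
    "read_gene_table",
    "write_gene_table",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
]

TABLE_COLUMNS = [
    "Gene",
    "Strand",
    "Location",
    "Length",
    "Anticodon",
    "StartCodon",
    "StopCodon",
    "OVL_ITS",
]

_MISSING = {"", "-", ".", "NA"}


class ParseError(ValueError):
    """A file could not be parsed in the expected dialect."""


def classify_gene(name: str) -> str:
    """Infer the feature class (PCG/tRNA/rRNA/control) from a gene symbol."""
    low = name.lower()
    if low.startswith("trn"):
        return "tRNA"
    if low.startswith("rrn"):
        return "rRNA"
    if "control" in low or low in {"d-loop", "dloop", "at_rich", "at-rich"}:
        return "control"
    return "PCG"


def _opt(value: str | None) -> str | None:
    if value is None or value.strip() in _MISSING:
        return None
    return value.strip()


def read_gene_table(path, genome_length: int, circular: bool = True) -> GeneTable:
    """Read a gene-coordinate TSV into a :class:`GeneTable`."""
    path = Path(path)
    features: list[Feature] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ParseError(f"{path}: no features (empty file)")
        missing = set(("Gene", "Strand", "Location")) - set(reader.fieldnames)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            name = (row.get("Gene") or "").strip()
            if not name:
                continue
            loc = (row.get("Location") or "").strip()
            try:
                start_s, end_s = loc.split("-", 1)
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path} line {i} ({name}): malformed location {loc!r}; "
                    "expected 'start-end'"
                ) from None
            length_s = _opt(row.get("Length"))
            ovl_s = _opt(row.get("OVL_ITS"))
            features.append(
                Feature(
                    name=name,
                    klass=classify_gene(name),
                    strand=_opt(row.get("Strand")),
                    start=start,
                    end=end,
                    anticodon=_opt(row.get("Anticodon")),
                    start_codon=_opt(row.get("StartCodon")),
                    stop_codon=_opt(row.get("StopCodon")),
                    declared_length=int(length_s) if length_s is not None else None,
                    declared_ovl_its=int(ovl_s) if ovl_s is not None else None,
                )
            )
    if not features:
        raise ParseError(f"{path}: no features")
    return GeneTable(features=features, genome_length=genome_length, circular=circular)


def _fmt(value) -> str:
    return "-" if value is None else str(value)


def _table_rows(table: GeneTable, gaps: str) -> list[list[str]]:
    from .organization import junction_gaps  # local import: avoid cycle

    if gaps not in ("computed", "declared"):
        raise ValueError("gaps must be 'computed' or 'declared'")
    computed: dict[str, int] = {}
    if gaps == "computed":
        computed = {g.upstream: g.gap for g in junction_gaps(table)}
    rows = [list(TABLE_COLUMNS)]
    last = table.features[-1] if table.features else None
    for f in table.features:
        if gaps == "computed":
            gap = computed.get(f.name)
            if table.circular and f is last:
                gap = None
        else:
            gap = f.declared_ovl_its
        rows.append(
            [
                f.name,
                _fmt(f.strand),
                f"{f.start}-{f.end}",
                _fmt(
                    f.declared_length
                    if f.declared_length is not None
                    else f.span_length(table.genome_length)
                ),
                _fmt(f.anticodon),
                _fmt(f.start_codon),
                _fmt(f.stop_codon),
                _fmt(gap),
            ]
        )
    return rows


def write_gene_table(table: GeneTable, path, gaps: str = "computed") -> None:
    """Write a gene table in the standard dialect.

    ``gaps="computed"`` (default) fills OVL_ITS from the junction-gap
    arithmetic; ``gaps="declared"`` echoes whatever the features carry.
    On a circular table the last row's wrap-around junction is written
    as ``-`` to match the conventional display.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerows(_table_rows(table, gaps))


_GENBANK_CLASS = {
    "CDS": "PCG",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "misc_feature": "control",
    "D-loop": "control",
}


def read_genbank(path) -> tuple[GenomeRecord, GeneTable]:
    """Read a GenBank flat file (subset: LOCUS, FEATURES, ORIGIN).

    ``complement(..)`` locations map to strand L.  A record without an
    ORIGIN block yields ``GenomeRecord.sequence is None`` (annotation-only
    mode).  Origin-spanning ``join`` locations collapse to a single
    wrapped interval with ``end < start``.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: not a readable GenBank flat file: {exc}") from None
    try:
        sequence: str | None = str(rec.seq)
    except UndefinedSequenceError:
        sequence = None
    topology = rec.annotations.get("topology", "circular")
    length = len(rec.seq)
    record = GenomeRecord(
        id=rec.id or rec.name,
        length=length,
        circular=(topology != "linear"),
        sequence=sequence,
    )
    features: list[Feature] = []
    seen: set[str] = set()
    for gf in rec.features:
        klass = _GENBANK_CLASS.get(gf.type)
        if klass is None:
            continue
        quals = gf.qualifiers
        name = (quals.get("gene") or quals.get("product") or quals.get("note") or [gf.type])[0]
        if name in seen:
            continue  # gene + CDS pairs describe the same feature
        seen.add(name)
        parts = gf.location.parts
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        if end > length or start > length:
            raise ValidationError(
                f"{path}: feature {name} coordinates exceed LOCUS length {length}"
            )
        features.append(
            Feature(
                name=name,
                klass=klass,
                strand=None if klass == "control" else ("L" if gf.location.strand == -1 else "H"),
                start=start,
                end=end,
                anticodon=(quals.get("anticodon") or [None])[0],
            )
        )
    table = GeneTable(features=features, genome_length=length, circular=record.circular)
    return record, table


def write_genbank(record: GenomeRecord, table: GeneTable, path, organism: str = "synthetic") -> None:
    """Write a minimal GenBank flat file for a record + gene table."""
    if record.sequence is None:
        raise ValidationError("cannot write GenBank without sequence")
    rec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id.replace(".", "_")[:16],
        description=f"{organism} mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "control": "misc_feature"}
    for f in table:
        loc = FeatureLocation(f.start - 1, f.end, strand=(-1 if f.strand == "L" else 1))
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        rec.features.append(SeqFeature(loc, type=type_of[f.klass], qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA into ``[(id, uppercase sequence), ...]``.

    Raises on symbols outside the IUPAC nucleotide alphabet (``-`` is
    tolerated for alignment input).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = sorted(set(seq.replace("-", "")) - set("ACGTURYSWKMBDHVN"))
        if bad:
            raise ParseError(
                f"{path}: record {rec.id} has non-IUPAC symbols: "
                + ", ".join(repr(b) for b in bad)
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def table_to_tsv_string(table: GeneTable, gaps: str = "computed") -> str:
    """The gene table serialized to a TSV string (for reports)."""
    buf = _io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerows(_table_rows(table, gaps))
    return buf.getvalue()
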