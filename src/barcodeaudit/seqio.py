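"""Sequence and metadata I/O: FASTA, delimited metadata/taxonomy tables,
dataset join, and NCBI 5-column feature-table output."""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import Dataset, SpecimenRecord, TaxonomyIndex, parse_genus

IUPAC_DNA = set("ACGTRYSWKMBDHVN")

_COLUMN_ALIASES = {
    "specimen_id": {"specimen_id", "id", "specimen", "voucher", "accession"},
    "taxon_name": {"taxon_name", "taxon", "species", "species_name", "binomial", "name"},
    "genus": {"genus"},
    "family": {"family"},
    "order_name": {"order", "order_name"},
    "collection_year": {"collection_year", "year", "date", "collection_date"},
    "pcr_positive": {"pcr_positive", "pcr", "pcr_success"},
    "sequence_positive": {"sequence_positive", "seq_positive", "sequencing_positive", "sequencing_success"},
}

_TRUTHY = {"1", "true", "t", "yes", "y", "+", "positive", "pos"}
_FALSY = {"0", "false", "f", "no", "n", "-", "negative", "neg"}


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` map.

    Sequences are uppercased and U→T normalized; IUPAC ambiguity codes are
    preserved.  Duplicate IDs and non-IUPAC characters are hard errors.
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        for pos, ch in enumerate(seq):
            if ch not in IUPAC_DNA:
                raise ValueError(
                    f"non-IUPAC character {ch!r} at position {pos} in record {rec.id!r}"
                )
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path: Union[str, Path]) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def _canonical_columns(columns) -> dict[str, str]:
    """Map canonical field name → actual column name in the file."""
    norm = {c: re.sub(r"\s+", "_", str(c).strip().lower()) for c in columns}
    out: dict[str, str] = {}
    for canon, aliases in _COLUMN_ALIASES.items():
        for col, n in norm.items():
            if n in aliases and canon not in out:
                out[canon] = col
    return out


def _parse_year(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s:
        return None
    m = re.search(r"\b(1[0-9]{3}|2[0-9]{3})\b", s)
    return int(m.group(1)) if m else None


def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    return None


def read_metadata(path: Union[str, Path], delimiter: Optional[str] = None) -> list[SpecimenRecord]:
    """Read a specimen-metadata table into sequence-less records.

    The delimiter is auto-sniffed among tab/comma/semicolon unless given.
    ``specimen_id`` and ``taxon_name`` columns (under common alias spellings)
    are mandatory; everything else is optional and never imputed.
    """
    path = Path(path)
    text = path.read_text()
    if delimiter is None:
        delimiter = _sniff_delimiter(text[:4096])
    df = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str, skipinitialspace=True)
    cols = _canonical_columns(df.columns)
    missing = [c for c in ("specimen_id", "taxon_name") if c not in cols]
    if missing:
        raise ValueError(
            f"metadata file {path} lacks mandatory column(s) {missing}; "
            f"available headers: {list(df.columns)}"
        )
    records: list[SpecimenRecord] = []
    for _, row in df.iterrows():
        def get(canon: str):
            col = cols.get(canon)
            if col is None:
                return None
            v = row[col]
            if isinstance(v, str):
                v = v.strip()
            return None if (v is None or (isinstance(v, float) and pd.isna(v)) or v == "") else v

        taxon = str(get("taxon_name") or "")
        rec = SpecimenRecord(
            specimen_id=str(get("specimen_id")),
            taxon_name=taxon,
            genus=str(get("genus") or "") or parse_genus(taxon),
            family=str(get("family") or ""),
            order_name=str(get("order_name") or ""),
            collection_year=_parse_year(get("collection_year")),
            pcr_positive=_parse_bool(get("pcr_positive")),
            sequence_positive=_parse_bool(get("sequence_positive")),
        )
        records.append(rec)
    return records


def read_taxonomy(path: Union[str, Path], delimiter: Optional[str] = None) -> TaxonomyIndex:
    """Read a 3-column (genus, family, order) table into a TaxonomyIndex."""
    path = Path(path)
    text = path.read_text()
    if delimiter is None:
        delimiter = _sniff_delimiter(text[:4096])
    index = TaxonomyIndex()
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    for i, row in enumerate(reader):
        row = [c.strip() for c in row if c.strip()]
        if not row:
            continue
        if i == 0 and row[0].lower() in {"genus"}:
            continue
        genus = row[0]
        family = row[1] if len(row) > 1 else ""
        order = row[2] if len(row) > 2 else ""
        index.add(genus, family, order)
    return index


@dataclass
class JoinReport:
    n_joined: int = 0
    n_metadata_only: int = 0
    n_sequence_only: int = 0
    sequence_only_ids: list[str] = field(default_factory=list)


def join_dataset(
    seqs: dict[str, str],
    metadata: list[SpecimenRecord],
    taxonomy: Optional[TaxonomyIndex] = None,
) -> tuple[Dataset, JoinReport]:
    """Attach sequences to metadata records by specimen ID.

    Mismatches are reported, never fatal: metadata rows without a sequence
    stay sequence-less, and sequence IDs absent from the metadata are listed
    in the report.
    """
    report = JoinReport()
    records = []
    for rec in metadata:
        seq = seqs.get(rec.specimen_id)
        if seq is not None:
            rec.sequence = seq
            report.n_joined += 1
        else:
            report.n_metadata_only += 1
        records.append(rec)
    meta_ids = {r.specimen_id for r in metadata}
    report.sequence_only_ids = sorted(set(seqs) - meta_ids)
    report.n_sequence_only = len(report.sequence_only_ids)
    return Dataset(records=records, taxonomy=taxonomy or TaxonomyIndex()), report


def write_feature_table(dataset: Dataset, path: Union[str, Path]) -> int:
    """Write an NCBI 5-column feature annotation table for the dataset.

    Records with ``region_coords`` get ITS1 / 5.8S rRNA / ITS2 features;
    records without get a single full-length misc_RNA spanning the sequence.
    Output coordinates are 1-based inclusive.  Returns the number of records
    written; sequence-less records are skipped.
    """
    import warnings

    lines: list[str] = []
    n = 0
    for rec in dataset.records:
        if not rec.sequence:
            warnings.warn(f"record {rec.specimen_id} has no sequence; skipped in feature table")
            continue
        n += 1
        length = len(rec.sequence)
        lines.append(f">Feature {rec.specimen_id}")
        if rec.region_coords is not None:
            its1_end, s58_start, s58_end = rec.region_coords
            lines.append(f"1\t{its1_end}\tmisc_RNA")
            lines.append("\t\t\tproduct\tinternal transcribed spacer 1")
            lines.append(f"{s58_start + 1}\t{s58_end}\trRNA")
            lines.append("\t\t\tproduct\t5.8S ribosomal RNA")
            if s58_end < length:
                lines.append(f"{s58_end + 1}\t{length}\tmisc_RNA")
                lines.append("\t\t\tproduct\tinternal transcribed spacer 2")
        else:
            lines.append(f"1\t{length}\tmisc_RNA")
            lines.append("\t\t\tproduct\tinternal transcribed spacer region")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    return n


# --- dataset (de)serialization -------------------------------------------------

def dataset_to_json(dataset: Dataset, path: Union[str, Path]) -> None:
    payload = {
        "records": [
            {
                "specimen_id": r.specimen_id,
                "taxon_name": r.taxon_name,
                "sequence": r.sequence,
                "genus": r.genus,
                "family": r.family,
                "order_name": r.order_name,
                "collection_year": r.collection_year,
                "pcr_positive": r.pcr_positive,
                "sequence_positive": r.sequence_positive,
                "region_coords": list(r.region_coords) if r.region_coords else None,
            }
            for r in dataset.records
        ],
        "taxonomy": dataset.taxonomy.as_rows(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def dataset_from_json(path: Union[str, Path]) -> Dataset:
    payload = json.loads(Path(path).read_text())
    taxonomy = TaxonomyIndex()
    for genus, family, order in payload.get("taxonomy", []):
        taxonomy.add(genus, family, order)
    records = []
    for d in payload["records"]:
        coords = d.get("region_coords")
        records.append(
            SpecimenRecord(
                specimen_id=d["specimen_id"],
                taxon_name=d.get("taxon_name", ""),
                sequence=d.get("sequence"),
                genus=d.get("genus", ""),
                family=d.get("family", ""),
                order_name=d.get("order_name", ""),
                collection_year=d.get("collection_year"),
                pcr_positive=d.get("pcr_positive"),
                sequence_positive=d.get("sequence_positive"),
                region_coords=tuple(coords) if coords else None,
            )
        )
    return Dataset(records=records, taxonomy=taxonomy)
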