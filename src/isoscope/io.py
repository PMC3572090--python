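"""Readers and writers for the plain-text formats the pipeline touches.

Formats
-------
* FASTA for aligned haplotype sequences (description line is the sample id).
* Two-column TSV population map: ``sample_id <TAB> population``.
* Wide TSV for STR profiles: ``sample_id, population, <locus...>`` columns,
  repeat counts as integers, ``NA`` for a missing call.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .datasets import (
    MISSING_REPEAT,
    SequenceDataset,
    SequenceRecord,
    StrDataset,
    StrRecord,
)
from .errors import EmptyDatasetError, MappingError, ParseError, ShapeError


def read_popmap(popmap_path) -> dict[str, str]:
    """Read a two-column (sample_id, population) TSV into a dict."""
    popmap: dict[str, str] = {}
    with open(popmap_path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ShapeError(
                    f"{popmap_path}:{lineno}: expected 2 tab-separated columns, got {len(row)}"
                )
            popmap[row[0].strip()] = row[1].strip()
    return popmap


def read_sequences(fasta_path, popmap_path, region_label: str = "region") -> SequenceDataset:
    """Read aligned sequences from FASTA with populations from a popmap TSV.

    Record order is preserved from the FASTA file. Every FASTA record must be
    present in the popmap; sequences are upper-cased before validation.
    """
    popmap = read_popmap(popmap_path)
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sample_id = rec.id
        if sample_id not in popmap:
            raise MappingError(
                f"sample {sample_id!r} from {fasta_path} is missing from the population map"
            )
        records.append(
            SequenceRecord(sample_id, popmap[sample_id], str(rec.seq).upper())
        )
    if not records:
        raise EmptyDatasetError(f"no FASTA records found in {fasta_path}")
    return SequenceDataset(records, region_label=region_label)


def write_sequences(dataset: SequenceDataset, fasta_path, popmap_path) -> None:
    bio_records = [
        BioSeqRecord(Seq(r.sequence), id=r.sample_id, description="")
        for r in dataset.records
    ]
    SeqIO.write(bio_records, str(fasta_path), "fasta")
    with open(popmap_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for r in dataset.records:
            writer.writerow([r.sample_id, r.population])


def read_str_table(tsv_path) -> StrDataset:
    """Read a wide STR TSV (sample_id, population, one column per locus)."""
    # keep_default_na=False: "NA" is our explicit missing sentinel, not NaN
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    expected_lead = ["sample_id", "population"]
    if list(df.columns[:2]) != expected_lead:
        raise ShapeError(
            f"{tsv_path}: header must start with {expected_lead}, got {list(df.columns[:2])}"
        )
    loci = list(df.columns[2:])
    if not loci:
        raise ShapeError(f"{tsv_path}: no locus columns found")
    if df.empty:
        raise EmptyDatasetError(f"{tsv_path}: header-only table, no records")
    records = []
    for _, row in df.iterrows():
        if any(pd.isna(v) or str(v).strip() == "" for v in row):
            raise ShapeError(f"{tsv_path}: ragged or empty cell in row for {row.iloc[0]!r}")
        repeats = []
        for locus in loci:
            cell = str(row[locus]).strip()
            if cell.upper() == "NA":
                repeats.append(MISSING_REPEAT)
                continue
            try:
                repeats.append(int(cell))
            except ValueError as exc:
                raise ParseError(
                    f"{tsv_path}: non-integer repeat value {cell!r} at locus {locus} "
                    f"for sample {row['sample_id']!r}"
                ) from exc
        records.append(StrRecord(str(row["sample_id"]), str(row["population"]), tuple(repeats)))
    return StrDataset(loci, records)


def write_str_table(dataset: StrDataset, tsv_path) -> None:
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "population", *dataset.loci])
        for r in dataset.records:
            cells = ["NA" if v == MISSING_REPEAT else str(v) for v in r.repeats]
            writer.writerow([r.sample_id, r.population, *cells])


def convert_sequence_table(tsv_path, fasta_path, popmap_path,
                           region_label: str = "region") -> SequenceDataset:
    """One-time conversion of a flat (sample_id, population, sequence) TSV.

    Bridge for spreadsheet exports of raw haplotype tables: export the sheet
    as TSV with those three columns, then convert to the FASTA + popmap pair
    the pipeline reads.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    needed = ["sample_id", "population", "sequence"]
    if list(df.columns[:3]) != needed:
        raise ShapeError(f"{tsv_path}: header must start with {needed}")
    records = [
        SequenceRecord(str(r.sample_id), str(r.population), str(r.sequence).upper())
        for r in df.itertuples(index=False)
    ]
    dataset = SequenceDataset(records, region_label=region_label)
    write_sequences(dataset, fasta_path, popmap_path)
    return dataset


def ensure_parent(path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    return path
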