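"""Readers and writers for all external table formats.

FASTA is parsed with Biopython; tabular inputs and outputs are
tab-separated with a mandatory header.  Every writer emits a leading '#'
comment line recording the tool version and the parameters used, so each
output table carries its own provenance.  Rows rejected during validation
are collected into a rejection report (one row per rejected input row,
with a reason code) rather than silently dropped.

Real-world exports (PhosphoSitePlus site tables, cBioPortal MAF subsets)
use different column names; a column-mapping dict translates them onto
the native schema without code changes.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .model import (
    AMINO_ACIDS,
    FormatError,
    MutationRecord,
    MutationSource,
    PSSM,
    PTMSite,
    ProteinRecord,
    ValidationError,
    check_ptm_compatibility,
)

__version__ = "0.1.0"

PTM_COLUMNS = ["protein_id", "position", "residue", "ptm_type", "evidence_refs", "is_protein_group"]
MUTATION_COLUMNS = ["protein_id", "position", "wt_residue", "mut_residue", "sample_id", "context_label"]

_TRUE_STRINGS = {"true", "1", "yes", "t"}


@dataclass
class RejectionReport:
    """Rows dropped during parsing, each with a machine-readable reason code."""

    rows: list[dict] = field(default_factory=list)

    def add(self, source_row: int, reason: str, detail: str) -> None:
        self.rows.append({"source_row": source_row, "reason": reason, "detail": detail})

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["source_row", "reason", "detail"])


def _provenance_line(params: dict | None = None, deterministic: bool = False) -> str:
    parts = [f"ptmut v{__version__}"]
    if not deterministic:
        parts.append(datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"))
    if params:
        parts.extend(f"{k}={v}" for k, v in sorted(params.items()))
    return "# " + " ".join(parts)


def write_table(
    frame: pd.DataFrame,
    path: str | os.PathLike,
    params: dict | None = None,
    deterministic_header: bool = False,
) -> None:
    """Write a TSV with a '#' provenance comment line above the header."""
    with open(path, "w") as fh:
        fh.write(_provenance_line(params, deterministic_header) + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def _read_tsv(path: str | os.PathLike, required: Sequence[str], column_map: dict | None = None) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty table") from exc
    if column_map:
        frame = frame.rename(columns=column_map)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return frame


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Parse protein sequences; the header token before the first whitespace
    becomes the accession, and sequences are uppercased."""
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        try:
            records.append(ProteinRecord(protein_id=entry.id, sequence=seq))
        except ValidationError as exc:
            raise ValidationError(f"{path}: record {entry.id}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(proteins: Iterable[ProteinRecord], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in proteins:
            fh.write(f">{rec.protein_id}\n")
            for start in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[start : start + width] + "\n")


def index_proteome(proteins: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    index: dict[str, ProteinRecord] = {}
    for rec in proteins:
        if rec.protein_id in index:
            raise ValidationError(f"duplicate accession {rec.protein_id}")
        index[rec.protein_id] = rec
    return index


# ---------------------------------------------------------------------------
# PTM site tables

def read_ptm_table(
    path: str | os.PathLike,
    proteome: dict[str, ProteinRecord] | None = None,
    column_map: dict | None = None,
    validate_compatibility: bool = True,
) -> tuple[list[PTMSite], RejectionReport]:
    """Read and validate a PTM site table.

    When a proteome index is supplied, rows whose residue disagrees with
    the sequence at the stated position are rejected (reason
    ``residue_mismatch``) and reported.  Residue/PTM-type compatibility for
    the four main types is enforced unless ``validate_compatibility`` is
    off, in which case incompatible rows raise no error.
    """
    frame = _read_tsv(path, PTM_COLUMNS, column_map)
    sites: list[PTMSite] = []
    report = RejectionReport()
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        position = _parse_position(row.position, path, idx)
        site = PTMSite(
            protein_id=str(row.protein_id),
            position=position,
            residue=str(row.residue).upper(),
            ptm_type=str(row.ptm_type),
            evidence_refs=int(row.evidence_refs or 0),
            is_protein_group=str(row.is_protein_group).lower() in _TRUE_STRINGS,
        )
        if validate_compatibility:
            try:
                check_ptm_compatibility(site)
            except ValidationError as exc:
                raise ValidationError(f"{path} row {idx}: {exc}") from exc
        if proteome is not None and site.protein_id in proteome:
            protein = proteome[site.protein_id]
            if site.position > len(protein) or protein.residue(site.position) != site.residue:
                report.add(
                    idx,
                    "residue_mismatch",
                    f"{site.protein_id} pos {site.position}: table says {site.residue}, "
                    f"sequence disagrees",
                )
                continue
        sites.append(site)
    return sites, report


def write_ptm_table(sites: Iterable[PTMSite], path: str | os.PathLike, **kwargs) -> None:
    frame = pd.DataFrame(
        [
            {
                "protein_id": s.protein_id,
                "position": s.position,
                "residue": s.residue,
                "ptm_type": s.ptm_type,
                "evidence_refs": s.evidence_refs,
                "is_protein_group": str(s.is_protein_group).lower(),
            }
            for s in sites
        ],
        columns=PTM_COLUMNS,
    )
    write_table(frame, path, **kwargs)


# ---------------------------------------------------------------------------
# Mutation tables

def _parse_position(raw, path, idx) -> int:
    try:
        position = int(raw)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path} row {idx}: non-integer position {raw!r}") from exc
    if position < 1:
        raise ValidationError(f"{path} row {idx}: position {position} must be >= 1")
    return position


def read_mutation_table(
    path: str | os.PathLike,
    source: MutationSource | str,
    column_map: dict | None = None,
) -> tuple[list[MutationRecord], RejectionReport]:
    """Read a missense mutation table.

    Only missense rows are retained: synonymous rows (wt == mut) and rows
    with nonsense '*' or other non-standard residues are dropped with a
    warning and a rejection-report entry.  Exact duplicates of
    (protein, position, wt, mut, sample) collapse to one record.
    """
    source = MutationSource(source)
    frame = _read_tsv(path, MUTATION_COLUMNS, column_map)
    records: list[MutationRecord] = []
    report = RejectionReport()
    seen: set[tuple] = set()
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        wt = str(row.wt_residue).upper()
        mut = str(row.mut_residue).upper()
        if wt == mut:
            report.add(idx, "synonymous", f"{row.protein_id} pos {row.position}: wt == mut ({wt})")
            warnings.warn(f"{path} row {idx}: synonymous row dropped", stacklevel=2)
            continue
        if wt not in AMINO_ACIDS or mut not in AMINO_ACIDS:
            report.add(
                idx, "not_missense", f"{row.protein_id} pos {row.position}: {wt}->{mut}"
            )
            warnings.warn(f"{path} row {idx}: non-missense row dropped ({wt}->{mut})", stacklevel=2)
            continue
        position = _parse_position(row.position, path, idx)
        key = (str(row.protein_id), position, wt, mut, str(row.sample_id))
        if key in seen:
            report.add(idx, "duplicate", f"duplicate of {key}")
            continue
        seen.add(key)
        records.append(
            MutationRecord(
                protein_id=str(row.protein_id),
                position=position,
                wt_residue=wt,
                mut_residue=mut,
                source=source,
                sample_id=str(row.sample_id),
                context_label=str(row.context_label),
            )
        )
    return records, report


def write_mutation_table(mutations: Iterable[MutationRecord], path: str | os.PathLike, **kwargs) -> None:
    frame = pd.DataFrame(
        [
            {
                "protein_id": m.protein_id,
                "position": m.position,
                "wt_residue": m.wt_residue,
                "mut_residue": m.mut_residue,
                "sample_id": m.sample_id,
                "context_label": m.context_label,
            }
            for m in mutations
        ],
        columns=MUTATION_COLUMNS,
    )
    write_table(frame, path, **kwargs)


# ---------------------------------------------------------------------------
# PSSM matrices

def read_pssm(path: str | os.PathLike) -> PSSM:
    """Read one PSSM from a TSV matrix.

    Layout: '#' metadata lines (``# kinase_name=...``, ``# kinase_group=...``,
    optionally ``# pad_score=...``), then a header row ``offset`` + 20 amino
    acids, then one row per offset -w..+w.
    """
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                text = line[1:].strip()
                if "=" in text:
                    key, _, value = text.partition("=")
                    meta[key.strip()] = value.strip()
            elif line.strip():
                body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no matrix body")
    frame = pd.read_csv(io.StringIO("".join(body_lines)), sep="\t")
    if frame.columns[0] != "offset":
        raise FormatError(f"{path}: first column must be 'offset'")
    aa_cols = list(frame.columns[1:])
    if sorted(aa_cols) != sorted(AMINO_ACIDS):
        raise FormatError(
            f"{path}: expected 20 amino-acid columns, got {len(aa_cols)}: {aa_cols}"
        )
    offsets = [int(o) for o in frame["offset"]]
    half_width = max(abs(o) for o in offsets) if offsets else 0
    expected_offsets = list(range(-half_width, half_width + 1))
    if sorted(offsets) != expected_offsets or len(offsets) != len(set(offsets)):
        raise FormatError(f"{path}: offsets must cover -{half_width}..+{half_width} exactly once")
    weights: dict[tuple[int, str], float] = {}
    for _, row in frame.iterrows():
        off = int(row["offset"])
        for aa in aa_cols:
            try:
                weights[(off, aa)] = float(row[aa])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"{path}: non-numeric weight at ({off}, {aa})") from exc
    try:
        pad_score = float(meta.get("pad_score", 0.0))
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric pad_score metadata") from exc
    return PSSM(
        kinase_name=meta.get("kinase_name", os.path.splitext(os.path.basename(path))[0]),
        kinase_group=meta.get("kinase_group", ""),
        half_width=half_width,
        pad_score=pad_score,
        weights=weights,
    )


def write_pssm(pssm: PSSM, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kinase_name={pssm.kinase_name}\n")
        fh.write(f"# kinase_group={pssm.kinase_group}\n")
        fh.write(f"# pad_score={pssm.pad_score!r}\n")
        fh.write("offset\t" + "\t".join(AMINO_ACIDS) + "\n")
        for off in range(-pssm.half_width, pssm.half_width + 1):
            row = "\t".join(repr(pssm.weights[(off, aa)]) for aa in AMINO_ACIDS)
            fh.write(f"{off}\t{row}\n")


def read_pssm_dir(directory: str | os.PathLike) -> list[PSSM]:
    paths = sorted(
        os.path.join(directory, name)
        for name in os.listdir(directory)
        if name.endswith(".tsv")
    )
    if not paths:
        raise FormatError(f"{directory}: no PSSM .tsv files found")
    return [read_pssm(p) for p in paths]
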