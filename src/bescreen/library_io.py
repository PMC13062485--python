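"""Readers and writers for guide libraries, transcript models, count tables
and clinical-class maps.

All tabular formats are tab-separated, UTF-8, with a required header row;
lines starting with ``#`` are ignored.  Coordinates are 0-based half-open
everywhere except human-facing protein-change strings (``Q161*``), which are
1-based.  Every reader validates its input fully so downstream modules only
ever see well-formed records.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

PROTOSPACER_RE = re.compile(r"^[ACGT]{20}$")
PAM_RE = re.compile(r"^[ACGT]GG$")

CONTROL_CLASSES = (
    "targeting",
    "istop_control",
    "aavs1_control",
    "nontargeting_control",
    "empty_window_control",
)

CLINICAL_CLASSES = ("BLB", "VUS", "PLP")

TIMEPOINTS = ("T0", "TEND")

NA_TOKENS = {"", "NA", "nan", "None"}


class ValidationError(ValueError):
    """Raised when an input file violates its schema or an invariant."""


@dataclass(frozen=True)
class Placement:
    """Location of a protospacer on a transcript.

    ``strand`` is relative to the transcript (``sense`` means the protospacer
    reads off the transcript-forward strand); ``offset`` is the 0-based
    position of the protospacer footprint's transcript-forward 5' end.
    """

    transcript_id: str
    strand: str  # "sense" | "antisense"
    offset: int

    def __post_init__(self) -> None:
        if self.strand not in ("sense", "antisense"):
            raise ValidationError(f"invalid strand {self.strand!r}")
        if self.offset < 0:
            raise ValidationError(f"negative placement offset {self.offset}")


@dataclass(frozen=True)
class GuideRecord:
    guide_id: str
    protospacer: str
    pam: str
    gene: Optional[str]
    placements: tuple[Placement, ...]
    control_class: str
    on_target_score: Optional[float]

    def __post_init__(self) -> None:
        if not PROTOSPACER_RE.match(self.protospacer):
            raise ValidationError(
                f"guide {self.guide_id}: protospacer must be 20 nt over ACGT, "
                f"got {self.protospacer!r}"
            )
        if not PAM_RE.match(self.pam):
            raise ValidationError(
                f"guide {self.guide_id}: PAM must match NGG, got {self.pam!r}"
            )
        if self.control_class not in CONTROL_CLASSES:
            raise ValidationError(
                f"guide {self.guide_id}: unknown control class {self.control_class!r}"
            )
        if self.control_class == "nontargeting_control" and self.placements:
            raise ValidationError(
                f"guide {self.guide_id}: non-targeting guides must have no placements"
            )
        if self.on_target_score is not None and not (0.0 <= self.on_target_score <= 1.0):
            raise ValidationError(
                f"guide {self.guide_id}: on_target_score outside [0, 1]"
            )


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure plus pre-mRNA sequence for one transcript.

    ``exons`` are 0-based half-open intervals in ``sequence`` coordinates,
    sorted and non-overlapping.  For coding transcripts ``cds_start`` /
    ``cds_end`` delimit the coding span in the same coordinates; the CDS
    itself is the concatenation of exonic bases inside that span.
    """

    transcript_id: str
    gene: str
    is_coding: bool
    sequence: str
    exons: tuple[tuple[int, int], ...]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    cds_valid: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if not re.match(r"^[ACGT]+$", self.sequence):
            raise ValidationError(
                f"transcript {self.transcript_id}: sequence has non-ACGT characters"
            )
        prev_end = 0
        for start, end in self.exons:
            if start < prev_end or end <= start:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons must be sorted, "
                    f"non-overlapping, non-empty"
                )
            prev_end = end
        if self.exons and self.exons[-1][1] > len(self.sequence):
            raise ValidationError(
                f"transcript {self.transcript_id}: exon beyond sequence end"
            )
        if self.is_coding:
            if self.cds_start is None or self.cds_end is None:
                raise ValidationError(
                    f"transcript {self.transcript_id}: coding transcript lacks CDS span"
                )
            if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
                raise ValidationError(
                    f"transcript {self.transcript_id}: CDS span out of bounds"
                )

    def cds_positions(self) -> list[int]:
        """Sequence positions of the spliced CDS, 5' to 3'."""
        if not self.is_coding:
            return []
        out: list[int] = []
        for start, end in self.exons:
            lo = max(start, self.cds_start)
            hi = min(end, self.cds_end)
            out.extend(range(lo, hi))
        return out

    def spliced_cds(self) -> str:
        return "".join(self.sequence[p] for p in self.cds_positions())

    def splice_site_positions(self) -> frozenset[int]:
        """The +/-2 intronic positions flanking every internal junction."""
        sites: set[int] = set()
        for (_, prev_end), (next_start, _) in zip(self.exons, self.exons[1:]):
            sites.update((prev_end, prev_end + 1, next_start - 2, next_start - 1))
        return frozenset(sites)

    def check_cds(self) -> list[str]:
        """Return a list of CDS invariant violations (empty when clean)."""
        if not self.is_coding:
            return []
        problems = []
        cds = self.spliced_cds()
        if len(cds) % 3 != 0:
            problems.append(f"CDS length {len(cds)} not divisible by 3")
        if not cds.startswith("ATG"):
            problems.append("CDS does not start with ATG")
        if len(cds) >= 3 and cds[-3:] not in ("TAA", "TAG", "TGA"):
            problems.append("CDS does not end with a stop codon")
        return problems


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    cell_line: str
    timepoint: str  # "T0" | "TEND"
    replicate: int

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"sample {self.sample_id}: timepoint must be T0 or TEND, "
                f"got {self.timepoint!r}"
            )
        if self.replicate < 1:
            raise ValidationError(f"sample {self.sample_id}: replicate must be >= 1")


@dataclass
class CountMatrix:
    """Guide x sample integer counts with per-sample metadata.

    ``counts`` is indexed by guide id with one column per sample id, in the
    sample-sheet order; ``genes`` maps guide id to its annotated gene.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]
    genes: pd.Series

    def __post_init__(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != sample_ids:
            raise ValidationError("count columns do not match sample metadata order")
        keys = [(s.cell_line, s.timepoint, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (cell_line, timepoint, replicate) in samples")
        if (self.counts.values < 0).any():
            raise ValidationError("negative counts")

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    def sample(self, cell_line: str, timepoint: str, replicate: int) -> str:
        for s in self.samples:
            if (s.cell_line, s.timepoint, s.replicate) == (cell_line, timepoint, replicate):
                return s.sample_id
        raise KeyError((cell_line, timepoint, replicate))


@dataclass
class ClinicalMap:
    """Three-level clinical classification keyed by (gene, protein change).

    Classes follow the benign/likely-benign (BLB), uncertain (VUS, including
    conflicting interpretations) and pathogenic/likely-pathogenic (PLP)
    collapse; variants absent from the map are treated as NA downstream.
    """

    entries: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        for key, cls in self.entries.items():
            if cls not in CLINICAL_CLASSES:
                raise ValidationError(f"unknown clinical class {cls!r} for {key}")

    def lookup(self, gene: Optional[str], protein_change: Optional[str]) -> Optional[str]:
        if gene is None or protein_change is None:
            return None
        return self.entries.get((gene, protein_change))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def parse_placements(text: str) -> tuple[Placement, ...]:
    """Parse ``tx1:sense:100;tx2:antisense:55`` into Placement tuples."""
    if text in NA_TOKENS:
        return ()
    out = []
    for token in text.split(";"):
        parts = token.split(":")
        if len(parts) != 3:
            raise ValidationError(f"malformed placement token {token!r}")
        tx, strand, offset = parts
        try:
            off = int(offset)
        except ValueError as exc:
            raise ValidationError(f"non-integer placement offset in {token!r}") from exc
        out.append(Placement(tx, strand, off))
    return tuple(out)


def format_placements(placements: Iterable[Placement]) -> str:
    toks = [f"{p.transcript_id}:{p.strand}:{p.offset}" for p in placements]
    return ";".join(toks) if toks else "NA"


def read_library(path: str | Path) -> list[GuideRecord]:
    """Read a guide-library TSV into validated :class:`GuideRecord` rows."""
    df = _read_tsv(
        path,
        ["guide_id", "protospacer", "pam", "gene", "placements", "control_class",
         "on_target_score"],
    )
    records: list[GuideRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            if row.guide_id in seen:
                raise ValidationError(f"duplicate guide_id {row.guide_id!r}")
            seen.add(row.guide_id)
            score = None if row.on_target_score in NA_TOKENS else float(row.on_target_score)
            rec = GuideRecord(
                guide_id=row.guide_id,
                protospacer=row.protospacer,
                pam=row.pam,
                gene=None if row.gene in NA_TOKENS else row.gene,
                placements=parse_placements(row.placements),
                control_class=row.control_class,
                on_target_score=score,
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from exc
        records.append(rec)
    return records


def write_library(records: Sequence[GuideRecord], path: str | Path,
                  header_lines: Sequence[str] = ()) -> None:
    df = pd.DataFrame(
        {
            "guide_id": [r.guide_id for r in records],
            "protospacer": [r.protospacer for r in records],
            "pam": [r.pam for r in records],
            "gene": [r.gene if r.gene is not None else "NA" for r in records],
            "placements": [format_placements(r.placements) for r in records],
            "control_class": [r.control_class for r in records],
            "on_target_score": [r.on_target_score for r in records],
        }
    )
    write_table(df, path, header_lines=header_lines)


def _parse_exons(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for token in text.split(";"):
        m = re.match(r"^(\d+)-(\d+)$", token)
        if not m:
            raise ValidationError(f"malformed exon interval {token!r}")
        out.append((int(m.group(1)), int(m.group(2))))
    return tuple(out)


def read_gene_models(seq_path: str | Path, structure_path: str | Path) -> list[TranscriptModel]:
    """Read transcript models from a FASTA + structure-TSV pair.

    The structure table carries columns ``transcript_id, gene, is_coding,
    exons, cds_start, cds_end`` with exons as ``start-end;start-end``.
    Coding transcripts failing a CDS invariant are kept but flagged
    ``cds_valid=False`` with a logged warning.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(seq_path), "fasta")}
    df = _read_tsv(structure_path,
                   ["transcript_id", "gene", "is_coding", "exons", "cds_start", "cds_end"])
    models: list[TranscriptModel] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.transcript_id not in seqs:
            raise ValidationError(
                f"{structure_path}, line {i}: no FASTA sequence for "
                f"{row.transcript_id!r}"
            )
        is_coding = row.is_coding.strip().lower() in ("true", "1", "yes")
        cds_start = None if row.cds_start in NA_TOKENS else int(row.cds_start)
        cds_end = None if row.cds_end in NA_TOKENS else int(row.cds_end)
        model = TranscriptModel(
            transcript_id=row.transcript_id,
            gene=row.gene,
            is_coding=is_coding,
            sequence=seqs[row.transcript_id],
            exons=_parse_exons(row.exons),
            cds_start=cds_start,
            cds_end=cds_end,
        )
        problems = model.check_cds()
        if problems:
            logger.warning("transcript %s: %s", model.transcript_id, "; ".join(problems))
            model = TranscriptModel(
                transcript_id=model.transcript_id, gene=model.gene,
                is_coding=model.is_coding, sequence=model.sequence,
                exons=model.exons, cds_start=model.cds_start,
                cds_end=model.cds_end, cds_valid=False,
            )
        models.append(model)
    return models


def write_gene_models(models: Sequence[TranscriptModel], seq_path: str | Path,
                      structure_path: str | Path) -> None:
    with open(seq_path, "w") as fh:
        for m in models:
            fh.write(f">{m.transcript_id}\n")
            for i in range(0, len(m.sequence), 70):
                fh.write(m.sequence[i:i + 70] + "\n")
    df = pd.DataFrame(
        {
            "transcript_id": [m.transcript_id for m in models],
            "gene": [m.gene for m in models],
            "is_coding": [str(m.is_coding).lower() for m in models],
            "exons": [";".join(f"{s}-{e}" for s, e in m.exons) for m in models],
            "cds_start": [m.cds_start if m.cds_start is not None else "NA" for m in models],
            "cds_end": [m.cds_end if m.cds_end is not None else "NA" for m in models],
        }
    )
    write_table(df, structure_path)


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = _read_tsv(path, ["sample_id", "cell_line", "timepoint", "replicate"])
    samples = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            samples.append(
                SampleMeta(row.sample_id, row.cell_line, row.timepoint, int(row.replicate))
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}, line {i}: {exc}") from exc
    keys = [(s.cell_line, s.timepoint, s.replicate) for s in samples]
    if len(set(keys)) != len(keys):
        raise ValidationError(f"{path}: duplicate (cell_line, timepoint, replicate)")
    if len({s.sample_id for s in samples}) != len(samples):
        raise ValidationError(f"{path}: duplicate sample_id")
    return samples


def read_count_table(path: str | Path, sample_sheet: str | Path) -> CountMatrix:
    """Read a MAGeCK-count-style table (sgRNA, gene, one column per sample).

    Columns are aligned to the sample-sheet order; any count column absent
    from the sheet, any sheet sample absent from the table, and any
    non-integer cell is an error.
    """
    samples = read_sample_sheet(sample_sheet)
    df = _read_tsv(path, ["sgRNA", "gene"])
    table_samples = [c for c in df.columns if c not in ("sgRNA", "gene")]
    sheet_ids = [s.sample_id for s in samples]
    unknown = sorted(set(table_samples) - set(sheet_ids))
    if unknown:
        raise ValidationError(f"{path}: count columns not in sample sheet: {unknown}")
    missing = sorted(set(sheet_ids) - set(table_samples))
    if missing:
        raise ValidationError(f"{path}: samples in sheet absent from table: {missing}")
    if df["sgRNA"].duplicated().any():
        dup = df.loc[df["sgRNA"].duplicated(), "sgRNA"].iloc[0]
        raise ValidationError(f"{path}: duplicate sgRNA {dup!r}")
    counts = pd.DataFrame(index=pd.Index(df["sgRNA"], name="sgRNA"))
    for sid in sheet_ids:
        col = pd.to_numeric(df[sid], errors="coerce")
        if col.isna().any():
            bad = df.loc[col.isna(), "sgRNA"].iloc[0]
            raise ValidationError(f"{path}: non-numeric count for guide {bad!r}, sample {sid}")
        if not np.allclose(col, np.round(col)):
            bad = df.loc[col != np.round(col), "sgRNA"].iloc[0]
            raise ValidationError(f"{path}: non-integer count for guide {bad!r}, sample {sid}")
        if (col < 0).any():
            raise ValidationError(f"{path}: negative count in sample {sid}")
        counts[sid] = col.astype(np.int64).values
    genes = pd.Series(df["gene"].values, index=counts.index, name="gene")
    return CountMatrix(counts=counts, samples=samples, genes=genes)


def write_count_table(cm: CountMatrix, path: str | Path,
                      header_lines: Sequence[str] = ()) -> None:
    df = cm.counts.copy()
    df.insert(0, "gene", cm.genes)
    df = df.reset_index().rename(columns={"index": "sgRNA"})
    write_table(df, path, header_lines=header_lines)


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "cell_line": [s.cell_line for s in samples],
            "timepoint": [s.timepoint for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    write_table(df, path)


def read_clinical_map(path: str | Path) -> ClinicalMap:
    df = _read_tsv(path, ["gene", "protein_change", "clinical_class"])
    entries: dict[tuple[str, str], str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.clinical_class not in CLINICAL_CLASSES:
            raise ValidationError(
                f"{path}, line {i}: unknown clinical class {row.clinical_class!r} "
                f"(expected one of {CLINICAL_CLASSES})"
            )
        key = (row.gene, row.protein_change)
        if key in entries:
            raise ValidationError(f"{path}, line {i}: duplicate key {key}")
        entries[key] = row.clinical_class
    return ClinicalMap(entries)


def write_clinical_map(cmap: ClinicalMap, path: str | Path) -> None:
    rows = [(g, pc, cls) for (g, pc), cls in cmap.entries.items()]
    df = pd.DataFrame(rows, columns=["gene", "protein_change", "clinical_class"])
    write_table(df, path)


# ---------------------------------------------------------------------------
# generic table writer
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path,
                header_lines: Sequence[str] = ()) -> None:
    """Write a result table as TSV: floats at 6 significant digits, NA as 'NA'.

    ``header_lines`` are emitted as leading ``#`` comments (provenance)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
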