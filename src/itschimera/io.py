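"""Sequence data model and file I/O.

The toolkit works on collections of fungal ITS sequences (ITS1–5.8S–ITS2).
Sequences are held as :class:`ItsRecord` objects; subregion boundaries, when
known, travel with the record as a :class:`RegionAnnotation` using 0-based
half-open coordinates throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

#: column order of the tab-separated detection results table
RESULTS_COLUMNS = ("score", "query", "parentA", "parentB", "crossover", "flag")

#: column order of the tab-separated region-annotation table
ANNOTATION_COLUMNS = (
    "id",
    "its1_start",
    "its1_end",
    "r58s_start",
    "r58s_end",
    "its2_start",
    "its2_end",
)


@dataclass(frozen=True)
class RegionAnnotation:
    """ITS1 / 5.8S / ITS2 intervals on the forward strand.

    All intervals are 0-based half-open ``[start, end)`` and must be ordered
    ITS1 < 5.8S < ITS2 without overlap.  ITS1 may be empty (``start == end``)
    when the 5.8S begins at position 0, and likewise for ITS2 at the 3' end.
    """

    its1: tuple[int, int]
    r58s: tuple[int, int]
    its2: tuple[int, int]

    def __post_init__(self) -> None:
        i1s, i1e = self.its1
        rs, re_ = self.r58s
        i2s, i2e = self.its2
        if not (0 <= i1s <= i1e <= rs < re_ <= i2s <= i2e):
            raise ValueError(
                f"regions must satisfy 0 <= ITS1 <= 5.8S < ITS2; got "
                f"its1={self.its1} r58s={self.r58s} its2={self.its2}"
            )

    def validate_against(self, seq: str) -> None:
        if self.its2[1] > len(seq):
            raise ValueError(
                f"annotation end {self.its2[1]} exceeds sequence length {len(seq)}"
            )


@dataclass(frozen=True)
class ItsRecord:
    """One ITS sequence with optional subregion annotation."""

    id: str
    seq: str
    description: str = ""
    regions: RegionAnnotation | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        seq = self.seq.upper()
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(seq) - IUPAC_CODES
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"record {self.id!r}: non-IUPAC character {seq[pos]!r} at position {pos}"
            )
        object.__setattr__(self, "seq", seq)
        if self.regions is not None:
            self.regions.validate_against(seq)

    def __len__(self) -> int:
        return len(self.seq)

    def slice_region(self, interval: tuple[int, int]) -> str:
        return self.seq[interval[0] : interval[1]]

    def with_regions(self, regions: RegionAnnotation | None) -> "ItsRecord":
        return replace(self, regions=regions)


@dataclass(frozen=True)
class ResultsRow:
    """One row of the detection results table (UCHIME-style, local dialect)."""

    score: float
    query_id: str
    parent_a_id: str
    parent_b_id: str
    crossover: int
    flag: bool

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be non-negative")


def _check_unique_ids(records: Iterable[ItsRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path: str | os.PathLike) -> list[ItsRecord]:
    """Read a FASTA file into a list of :class:`ItsRecord`.

    The header token before the first whitespace becomes the record id, the
    remainder the description.  Sequences are uppercased; duplicate ids,
    empty sequences and non-IUPAC characters raise ``ValueError``.
    """
    records: list[ItsRecord] = []
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            rid = parts[0] if parts else ""
            desc = parts[1] if len(parts) > 1 else ""
            records.append(ItsRecord(id=rid, seq=seq, description=desc))
    _check_unique_ids(records)
    return records


def write_fasta(
    records: Sequence[ItsRecord], path: str | os.PathLike, wrap: int = 80
) -> None:
    """Write records as FASTA with sequence lines wrapped at ``wrap``."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.seq), wrap):
                handle.write(rec.seq[i : i + wrap] + "\n")


def write_results_table(rows: Sequence[ResultsRow], path: str | os.PathLike) -> None:
    """Write detection results as TSV, sorted by descending score then query id."""
    ordered = sorted(rows, key=lambda r: (-r.score, r.query_id))
    df = pd.DataFrame(
        [
            {
                "score": f"{r.score:.6f}",
                "query": r.query_id,
                "parentA": r.parent_a_id,
                "parentB": r.parent_b_id,
                "crossover": r.crossover,
                "flag": "Y" if r.flag else "N",
            }
            for r in ordered
        ],
        columns=list(RESULTS_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_results_table(path: str | os.PathLike) -> list[ResultsRow]:
    """Parse a results TSV written by :func:`write_results_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return []
    return [
        ResultsRow(
            score=float(row["score"]),
            query_id=row["query"],
            parent_a_id=row["parentA"],
            parent_b_id=row["parentB"],
            crossover=int(row["crossover"]),
            flag=row["flag"] == "Y",
        )
        for _, row in df.iterrows()
    ]


def write_annotation_table(
    annotations: dict[str, RegionAnnotation], path: str | os.PathLike
) -> None:
    """Write per-record region annotations as TSV.

    Coordinates are 0-based half-open, as stated in the header comment line.
    """
    with open(path, "w") as handle:
        handle.write("# coordinates are 0-based, half-open [start, end)\n")
        handle.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for rid in sorted(annotations):
            ann = annotations[rid]
            fields = [
                rid,
                ann.its1[0],
                ann.its1[1],
                ann.r58s[0],
                ann.r58s[1],
                ann.its2[0],
                ann.its2[1],
            ]
            handle.write("\t".join(str(f) for f in fields) + "\n")


def read_annotation_table(path: str | os.PathLike) -> dict[str, RegionAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    out: dict[str, RegionAnnotation] = {}
    for _, row in df.iterrows():
        out[row["id"]] = RegionAnnotation(
            its1=(int(row["its1_start"]), int(row["its1_end"])),
            r58s=(int(row["r58s_start"]), int(row["r58s_end"])),
            its2=(int(row["its2_start"]), int(row["its2_end"])),
        )
    return out


def attach_annotations(
    records: Sequence[ItsRecord], annotations: dict[str, RegionAnnotation]
) -> list[ItsRecord]:
    """Return records with their annotation attached (missing ids unchanged)."""
    return [rec.with_regions(annotations.get(rec.id, rec.regions)) for rec in records]
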