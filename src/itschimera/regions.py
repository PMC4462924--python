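"""Locate the 5.8S gene and emit ITS1-only / ITS2-only views.

The 5.8S gene is highly conserved across fungi, so a single consensus
sequence aligned end-to-end against a record (with free overhangs on the
record side) pins down the gene's span; everything upstream is ITS1 and
everything downstream is ITS2.  This is a deliberately light-weight,
consensus-anchored stand-in for profile-HMM extractors: it assumes inputs
are forward-strand ITS amplicons without long SSU/LSU flanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import anchor_alignment
from .cluster import ReferenceSet
from .io import ItsRecord, RegionAnnotation

logger = logging.getLogger(__name__)

#: minimum anchor alignment score as a fraction of the consensus length
MIN_SCORE_FRAC = 0.5


class Region58SNotFound(ValueError):
    """Raised when no acceptable 5.8S placement exists in a record."""


def locate_58s(
    record: ItsRecord, consensus: str, min_score_frac: float = MIN_SCORE_FRAC
) -> RegionAnnotation:
    """Annotate ITS1/5.8S/ITS2 by anchoring a 5.8S consensus in the record.

    The consensus must align with score >= ``min_score_frac * len(consensus)``
    (match +1 / mismatch -1 scoring, so a random placement scores near zero
    while a conserved gene scores near its length); otherwise
    :class:`Region58SNotFound` is raised.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    if len(record.seq) <= len(consensus):
        raise ValueError(
            f"record {record.id!r} ({len(record.seq)} nt) is not longer than "
            f"the 5.8S consensus ({len(consensus)} nt)"
        )
    start, end, score = anchor_alignment(record.seq, consensus)
    if score < min_score_frac * len(consensus):
        raise Region58SNotFound(
            f"5.8S not found in record {record.id!r} "
            f"(best anchor score {score:.0f} < {min_score_frac * len(consensus):.0f})"
        )
    return RegionAnnotation(
        its1=(0, start), r58s=(start, end), its2=(end, len(record.seq))
    )


def annotate_records(
    records: list[ItsRecord], consensus: str, min_score_frac: float = MIN_SCORE_FRAC
) -> tuple[list[ItsRecord], list[str]]:
    """Attach 5.8S-anchored annotations; return (annotated records, failed ids)."""
    annotated: list[ItsRecord] = []
    failed: list[str] = []
    for rec in records:
        try:
            regions = locate_58s(rec, consensus, min_score_frac)
        except Region58SNotFound as exc:
            logger.warning("%s", exc)
            failed.append(rec.id)
            continue
        annotated.append(rec.with_regions(regions))
    return annotated, failed


@dataclass
class SubregionFiles:
    """ITS1-only and ITS2-only views of a reference set."""

    its1_records: list[ItsRecord]
    its2_records: list[ItsRecord]
    failed_ids: list[str]
    empty_its1_ids: list[str]
    empty_its2_ids: list[str]


def extract_subregions(
    refset: ReferenceSet | list[ItsRecord],
    consensus: str,
    min_score_frac: float = MIN_SCORE_FRAC,
) -> SubregionFiles:
    """Produce ITS1-only and ITS2-only record collections from a reference set.

    Records whose 5.8S cannot be located are excluded (with a warning), not
    fatal; empty subregions (5.8S flush against a sequence end) are dropped
    with a warning.  Ids carry a ``.ITS1`` / ``.ITS2`` suffix.
    """
    records = list(refset.records) if isinstance(refset, ReferenceSet) else list(refset)
    its1_out: list[ItsRecord] = []
    its2_out: list[ItsRecord] = []
    empty1: list[str] = []
    empty2: list[str] = []
    annotated, failed = annotate_records(records, consensus, min_score_frac)
    for rec in annotated:
        ann = rec.regions
        assert ann is not None
        its1_seq = rec.slice_region(ann.its1)
        its2_seq = rec.slice_region(ann.its2)
        if its1_seq:
            its1_out.append(
                ItsRecord(id=f"{rec.id}.ITS1", seq=its1_seq, description=rec.description)
            )
        else:
            logger.warning("record %s: empty ITS1 subregion dropped", rec.id)
            empty1.append(rec.id)
        if its2_seq:
            its2_out.append(
                ItsRecord(id=f"{rec.id}.ITS2", seq=its2_seq, description=rec.description)
            )
        else:
            logger.warning("record %s: empty ITS2 subregion dropped", rec.id)
            empty2.append(rec.id)
    logger.info(
        "subregion extraction: %d ITS1, %d ITS2, %d records without 5.8S",
        len(its1_out), len(its2_out), len(failed),
    )
    return SubregionFiles(
        its1_records=its1_out,
        its2_records=its2_out,
        failed_ids=failed,
        empty_its1_ids=empty1,
        empty_its2_ids=empty2,
    )
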