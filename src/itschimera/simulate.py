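"""Benchmark chimera simulation: 5.8S-midpoint bisection + derangement.

The benchmark turns a chimera-free reference set into a dataset consisting
*only* of chimeras: every sequence is bisected in the middle of its 5.8S
gene and the right halves are reassigned by a uniform random derangement,
so each chimera is ITS1 + half of the 5.8S from one parent and the rest of
the 5.8S + ITS2 from another, no fragment rejoins its own parent, and every
reference is used exactly once on each side.  Repeating the reshuffle gives
independent replicate datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import ReferenceSet
from .io import ItsRecord


@dataclass(frozen=True)
class ChimeraRecord:
    """A simulated two-parent chimera with a known breakpoint."""

    id: str
    seq: str
    left_parent_id: str
    right_parent_id: str
    breakpoint: int  # position in chimera coordinates: len(left fragment)

    def __post_init__(self) -> None:
        if self.left_parent_id == self.right_parent_id:
            raise ValueError("chimera parents must differ")

    def to_record(self) -> ItsRecord:
        return ItsRecord(
            id=self.id,
            seq=self.seq,
            description=(
                f"left={self.left_parent_id} right={self.right_parent_id} "
                f"breakpoint={self.breakpoint}"
            ),
        )


@dataclass(frozen=True)
class BenchmarkSpec:
    """Replication settings of the simulated-chimera benchmark."""

    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def bisect_at_58s_midpoint(record: ItsRecord) -> tuple[str, str]:
    """Split a record at the midpoint of its annotated 5.8S gene.

    The cut is at ``r58s.start + floor(len(5.8S) / 2)`` (floor rule for odd
    lengths); the two fragments concatenate back to the input exactly.
    """
    if record.regions is None:
        raise ValueError(f"record {record.id!r} has no region annotation")
    rs, re_ = record.regions.r58s
    cut = rs + (re_ - rs) // 2
    return record.seq[:cut], record.seq[cut:]


def random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """A uniformly distributed fixed-point-free permutation of ``range(n)``.

    Rejection-sampling of uniform permutations until none has a fixed point;
    the acceptance probability tends to 1/e, so the expected number of draws
    is about e regardless of ``n``.
    """
    if n < 2:
        raise ValueError("a derangement requires n >= 2")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def make_chimera_replicate(
    refs: ReferenceSet | list[ItsRecord],
    rng: np.random.Generator,
    replicate_label: str = "rep1",
) -> list[ChimeraRecord]:
    """One replicate: bisect every reference and derange the right halves."""
    records = list(refs.records) if isinstance(refs, ReferenceSet) else list(refs)
    if len(records) < 2:
        raise ValueError("at least 2 annotated references are required")
    halves = [bisect_at_58s_midpoint(rec) for rec in records]
    perm = random_derangement(len(records), rng)
    out: list[ChimeraRecord] = []
    for i, rec in enumerate(records):
        j = int(perm[i])
        left, _ = halves[i]
        _, right = halves[j]
        out.append(
            ChimeraRecord(
                id=f"chim_{replicate_label}_{i + 1:05d}",
                seq=left + right,
                left_parent_id=rec.id,
                right_parent_id=records[j].id,
                breakpoint=len(left),
            )
        )
    return out


def make_benchmark(
    refs: ReferenceSet | list[ItsRecord], spec: BenchmarkSpec = BenchmarkSpec()
) -> list[list[ChimeraRecord]]:
    """``spec.n_replicates`` independent chimera replicates from one seed.

    Replicate streams are derived with ``SeedSequence.spawn`` so each
    replicate is reproducible independently of the others.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_replicates)
    return [
        make_chimera_replicate(
            refs, np.random.default_rng(children[k]), replicate_label=f"rep{k + 1}"
        )
        for k in range(spec.n_replicates)
    ]
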