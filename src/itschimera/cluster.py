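"""Species-hypothesis clustering and chimera-reference-set construction.

The chimera-control reference set is built the way curated ITS databases
assemble theirs: the corpus is first clustered at ~80% identity into
genus-level groups; each group is re-clustered at the species level
(97–100% identity in 0.5% steps) into *species hypotheses* (SHs); for each
SH at the 98.5% level a representative sequence is chosen automatically as
the most frequent sequence type, unless a manually designated reference
sequence supersedes it; singleton SHs are excluded unless explicitly
sanctioned.  One sequence per SH forms the reference set.

Clustering is greedy centroid clustering: records are processed in
decreasing length order (ties by id) and each joins the first centroid it
matches at or above the threshold, else founds a new centroid.  Species
levels are produced by hierarchical refinement — each SH at a threshold is
re-clustered at the next higher threshold — so SHs nest across thresholds
by construction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import pairwise_identity
from .io import ItsRecord

DEFAULT_SH_THRESHOLDS = (0.97, 0.975, 0.98, 0.985, 0.99, 0.995, 1.0)


@dataclass(frozen=True)
class ShParams:
    """Thresholds of the two-stage clustering."""

    genus_threshold: float = 0.80
    sh_thresholds: tuple[float, ...] = DEFAULT_SH_THRESHOLDS
    representative_threshold: float = 0.985
    min_sh_size: int = 2

    def __post_init__(self) -> None:
        thr = self.sh_thresholds
        if not all(0 < t <= 1 for t in (self.genus_threshold, *thr)):
            raise ValueError("thresholds must be in (0, 1]")
        if list(thr) != sorted(thr):
            raise ValueError("sh_thresholds must be sorted ascending")
        if not any(abs(t - self.representative_threshold) < 1e-9 for t in thr):
            raise ValueError("representative_threshold must be one of sh_thresholds")
        if self.min_sh_size < 1:
            raise ValueError("min_sh_size must be >= 1")


@dataclass
class Cluster:
    """A greedy centroid cluster; the centroid is the first member."""

    centroid_id: str
    member_ids: list[str]


@dataclass
class SpeciesHypothesis:
    """A species-level cluster with a chosen representative."""

    sh_id: str
    threshold: float
    member_ids: list[str]
    representative_id: str
    is_reference: bool = False  # True when a manual reference supersedes
    sanctioned_singleton: bool = False


@dataclass
class ReferenceSet:
    """The chimera-control dataset: one sequence per species hypothesis."""

    records: list[ItsRecord]
    provenance: dict[str, tuple[str, str]]  # record id -> (sh_id, automatic|manual)
    membership: dict[str, str] = field(default_factory=dict)  # any record id -> sh_id
    species_hypotheses: list[SpeciesHypothesis] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sh_of(self, record_id: str) -> str:
        return self.membership[record_id]


def _clustering_order(records: Sequence[ItsRecord]) -> list[ItsRecord]:
    return sorted(records, key=lambda r: (-len(r.seq), r.id))


def greedy_cluster(records: Sequence[ItsRecord], threshold: float) -> list[Cluster]:
    """Greedy centroid clustering at a fractional identity threshold."""
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("record ids must be unique")
    by_id = {r.id: r for r in records}
    clusters: list[Cluster] = []
    for rec in _clustering_order(records):
        for cl in clusters:
            if pairwise_identity(rec.seq, by_id[cl.centroid_id].seq) >= threshold:
                cl.member_ids.append(rec.id)
                break
        else:
            clusters.append(Cluster(centroid_id=rec.id, member_ids=[rec.id]))
    return clusters


def _sh_id(member_ids: Iterable[str], threshold: float) -> str:
    key = "|".join(sorted(member_ids)) + f"@{threshold:.4f}"
    return "SH" + hashlib.sha1(key.encode()).hexdigest()[:10].upper()


def select_representative(members: Sequence[ItsRecord]) -> str:
    """Representative of an SH: the most frequent sequence type.

    Sequence types are classes of exact sequence equality.  The modal type
    wins; remaining ties are broken by sequence length (longest first) and
    then lexicographic id, making the choice fully deterministic.
    """
    if not members:
        raise ValueError("an SH must have at least one member")
    counts: dict[str, int] = {}
    for rec in members:
        counts[rec.seq] = counts.get(rec.seq, 0) + 1
    best = max(counts.values())
    pool = [r for r in members if counts[r.seq] == best]
    pool.sort(key=lambda r: (-len(r.seq), r.id))
    return pool[0].id


def build_species_hypotheses(
    cluster_records: Sequence[ItsRecord], params: ShParams = ShParams()
) -> dict[float, list[SpeciesHypothesis]]:
    """Species-level clustering of one genus cluster at every SH threshold.

    Returns a mapping threshold -> SH list.  Thresholds are processed in
    ascending order and each SH's members are re-clustered at the next
    threshold, so every SH at a threshold t is contained in exactly one SH
    at any lower threshold.
    """
    by_id = {r.id: r for r in cluster_records}
    out: dict[float, list[SpeciesHypothesis]] = {}
    groups: list[list[str]] = [[r.id for r in cluster_records]]
    for t in params.sh_thresholds:
        next_groups: list[list[str]] = []
        for group in groups:
            for cl in greedy_cluster([by_id[i] for i in group], t):
                next_groups.append(cl.member_ids)
        shs = []
        for member_ids in next_groups:
            members = [by_id[i] for i in member_ids]
            shs.append(
                SpeciesHypothesis(
                    sh_id=_sh_id(member_ids, t),
                    threshold=t,
                    member_ids=sorted(member_ids),
                    representative_id=select_representative(members),
                )
            )
        shs.sort(key=lambda s: s.member_ids[0])
        out[t] = shs
        groups = next_groups
    return out


def build_reference_dataset(
    records: Sequence[ItsRecord],
    params: ShParams = ShParams(),
    overrides: Mapping[str, str] | None = None,
    sanctioned_singletons: Iterable[str] | None = None,
) -> ReferenceSet:
    """Build the chimera-control reference set from a sequence corpus.

    ``overrides`` maps sh_id -> record id of a manually designated reference
    sequence, which supersedes the automatic representative.  Singleton SHs
    are dropped unless their member id appears in ``sanctioned_singletons``.
    """
    overrides = dict(overrides or {})
    sanctioned = set(sanctioned_singletons or ())
    by_id = {r.id: r for r in records}

    all_shs: list[SpeciesHypothesis] = []
    for genus_cluster in greedy_cluster(records, params.genus_threshold):
        members = [by_id[i] for i in genus_cluster.member_ids]
        levels = build_species_hypotheses(members, params)
        rep_level = next(
            t for t in params.sh_thresholds
            if abs(t - params.representative_threshold) < 1e-9
        )
        all_shs.extend(levels[rep_level])
    all_shs.sort(key=lambda s: s.member_ids[0])

    known_sh = {sh.sh_id: sh for sh in all_shs}
    for sh_id, rec_id in overrides.items():
        if sh_id not in known_sh:
            raise ValueError(f"override refers to unknown SH {sh_id!r}")
        if rec_id not in known_sh[sh_id].member_ids:
            raise ValueError(
                f"override record {rec_id!r} is not a member of SH {sh_id!r}"
            )

    kept_records: list[ItsRecord] = []
    provenance: dict[str, tuple[str, str]] = {}
    membership: dict[str, str] = {}
    kept_shs: list[SpeciesHypothesis] = []
    for sh in all_shs:
        if len(sh.member_ids) < params.min_sh_size:
            if not (len(sh.member_ids) == 1 and sh.member_ids[0] in sanctioned):
                continue
            sh.sanctioned_singleton = True
        if sh.sh_id in overrides:
            rep_id = overrides[sh.sh_id]
            sh.representative_id = rep_id
            sh.is_reference = True
            source = "manual"
        else:
            rep_id = sh.representative_id
            source = "automatic"
        kept_records.append(by_id[rep_id])
        provenance[rep_id] = (sh.sh_id, source)
        for mid in sh.member_ids:
            membership[mid] = sh.sh_id
        kept_shs.append(sh)

    kept_records.sort(key=lambda r: r.id)
    return ReferenceSet(
        records=kept_records,
        provenance=provenance,
        membership=membership,
        species_hypotheses=kept_shs,
    )
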