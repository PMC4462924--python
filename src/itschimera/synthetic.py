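"""Synthetic fungal-ITS-like corpora with known ground truth.

Real fungal ITS data (e.g. the UNITE/INSDC corpus) consists of a highly
conserved 5.8S gene flanked by two variable spacers, ITS1 and ITS2, with a
mean total length around 550 bp and a nested similarity structure:
conspecific sequences are nearly identical, congeneric species diverge by a
few percent, and genera are far apart.  The generator reproduces exactly
that structure — a shared 5.8S ancestor, per-genus spacer ancestors, species
templates and individual records — and records the true taxonomy and true
region boundaries for every sequence, so that clustering, region extraction
and chimera detection can all be validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .io import ItsRecord, RegionAnnotation

BASES = "ACGT"


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of a synthetic corpus.

    Divergences are expected per-position mutation fractions between the
    tiers of the taxonomy: record-from-species-template (``intra_species``),
    species-template-from-genus-ancestor (``inter_species``), and the 5.8S
    per-species drift (``r58s_div``).  Genus spacer ancestors are drawn
    independently, so between-genus spacer similarity is at the random
    background level (the nominal ``inter_genus_div`` tier is saturated).
    Length ranges default to a ~550 bp mean total, matching the average
    fungal ITS length.
    """

    n_genera: int
    species_per_genus: int
    seqs_per_species: int
    seed: int
    its1_len: tuple[int, int] = (170, 220)
    its2_len: tuple[int, int] = (175, 225)
    r58s_len: int = 158
    inter_genus_div: float = 0.25
    inter_species_div: float = 0.05
    intra_species_div: float = 0.005
    r58s_div: float = 0.002
    indel_fraction: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_genera, self.species_per_genus, self.seqs_per_species) < 1:
            raise ValueError("corpus dimensions must be positive")
        if self.r58s_len < 1 or self.its1_len[0] < 1 or self.its2_len[0] < 1:
            raise ValueError("lengths must be positive")
        if self.its1_len[0] > self.its1_len[1] or self.its2_len[0] > self.its2_len[1]:
            raise ValueError("length ranges must be (lo, hi) with lo <= hi")
        if not (
            0 <= self.intra_species_div < self.inter_species_div < self.inter_genus_div <= 1
        ):
            raise ValueError(
                "divergence tiers must satisfy intra < inter_species < inter_genus <= 1"
            )
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one generated record."""

    record_id: str
    genus: str
    species: str
    regions: RegionAnnotation
    template: str  # the species template sequence the record was mutated from


@dataclass
class TruthTable:
    """Per-record ground truth of a synthetic corpus."""

    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def __getitem__(self, record_id: str) -> TruthEntry:
        return self.entries[record_id]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TruthEntry]:
        return iter(self.entries.values())

    def species_of(self, record_id: str) -> str:
        return self.entries[record_id].species

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": e.record_id,
                "genus": e.genus,
                "species": e.species,
                "its1_start": e.regions.its1[0],
                "its1_end": e.regions.its1[1],
                "r58s_start": e.regions.r58s[0],
                "r58s_end": e.regions.r58s[1],
                "its2_start": e.regions.its2[0],
                "its2_end": e.regions.its2[1],
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def mutate_sequence(
    seq: str,
    divergence: float,
    indel_fraction: float,
    rng: np.random.Generator,
) -> str:
    """Mutate ``seq`` so an expected fraction ``divergence`` of positions change.

    A fraction ``indel_fraction`` of mutation events are single-base indels
    (insertions and deletions equally likely); the rest are substitutions
    that never reproduce the original base.
    """
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    n = len(seq)
    if n == 0 or divergence == 0:
        return seq
    hit = rng.random(n) < divergence
    positions = np.flatnonzero(hit)
    chars = list(seq)
    # apply right-to-left so indels do not shift pending positions
    for pos in positions[::-1]:
        if indel_fraction > 0 and rng.random() < indel_fraction:
            if rng.random() < 0.5:
                del chars[pos]
            else:
                chars.insert(pos, BASES[rng.integers(4)])
        else:
            orig = chars[pos]
            choices = [b for b in BASES if b != orig] or list(BASES)
            chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars)


def generate_corpus(spec: CorpusSpec) -> tuple[list[ItsRecord], TruthTable]:
    """Generate a corpus and its ground truth, deterministically from the seed.

    Structure: one corpus-wide 5.8S ancestor, mutated per species at
    ``r58s_div`` (substitutions only, so the anchor keeps its length); per
    genus, independently drawn ITS1/ITS2 ancestors; per species, spacer
    templates mutated from the genus ancestors at ``inter_species_div``; per
    record, spacers mutated from the species template at
    ``intra_species_div`` while the species 5.8S is carried unchanged.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor_58s = random_sequence(spec.r58s_len, rng)

    records: list[ItsRecord] = []
    truth = TruthTable()
    for gi in range(1, spec.n_genera + 1):
        genus = f"G{gi:03d}"
        its1_anc = random_sequence(int(rng.integers(spec.its1_len[0], spec.its1_len[1] + 1)), rng)
        its2_anc = random_sequence(int(rng.integers(spec.its2_len[0], spec.its2_len[1] + 1)), rng)
        for si in range(1, spec.species_per_genus + 1):
            species = f"{genus}S{si:02d}"
            sp_58s = mutate_sequence(ancestor_58s, spec.r58s_div, 0.0, rng)
            sp_its1 = mutate_sequence(
                its1_anc, spec.inter_species_div, spec.indel_fraction, rng
            )
            sp_its2 = mutate_sequence(
                its2_anc, spec.inter_species_div, spec.indel_fraction, rng
            )
            template = sp_its1 + sp_58s + sp_its2
            for ri in range(1, spec.seqs_per_species + 1):
                rid = f"{species}R{ri:02d}"
                r_its1 = mutate_sequence(
                    sp_its1, spec.intra_species_div, spec.indel_fraction, rng
                )
                r_its2 = mutate_sequence(
                    sp_its2, spec.intra_species_div, spec.indel_fraction, rng
                )
                seq = r_its1 + sp_58s + r_its2
                regions = RegionAnnotation(
                    its1=(0, len(r_its1)),
                    r58s=(len(r_its1), len(r_its1) + len(sp_58s)),
                    its2=(len(r_its1) + len(sp_58s), len(seq)),
                )
                rec = ItsRecord(
                    id=rid,
                    seq=seq,
                    description=f"genus={genus} species={species}",
                    regions=regions,
                )
                records.append(rec)
                truth.entries[rid] = TruthEntry(
                    record_id=rid,
                    genus=genus,
                    species=species,
                    regions=regions,
                    template=template,
                )
    return records, truth


def corpus_58s_consensus(spec: CorpusSpec) -> str:
    """The 5.8S ancestor a given spec would generate (the natural anchor probe)."""
    rng = np.random.default_rng(spec.seed)
    return random_sequence(spec.r58s_len, rng)
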