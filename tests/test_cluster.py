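import numpy as np
import pytest

from itschimera import (
    ItsRecord,
    ShParams,
    build_reference_dataset,
    build_species_hypotheses,
    greedy_cluster,
    mutate_sequence,
    pairwise_identity,
    select_representative,
)


def _rec(rid, seq):
    return ItsRecord(id=rid, seq=seq)


def test_greedy_cluster_all_identical():
    records = [_rec(f"r{i}", "ACGT" * 30) for i in range(5)]
    clusters = greedy_cluster(records, 0.9)
    assert len(clusters) == 1
    assert sorted(clusters[0].member_ids) == [f"r{i}" for i in range(5)]


def test_greedy_cluster_threshold_one_unique_sequences(rng):
    records = [
        _rec(f"r{i}", "".join(rng.choice(list("ACGT"), size=60))) for i in range(6)
    ]
    clusters = greedy_cluster(records, 1.0)
    assert len(clusters) == len(records)


def test_greedy_cluster_separates_divergent_groups(rng):
    """Two groups at mutual identity ~0.70 split at threshold 0.80."""
    base_a = "".join(rng.choice(list("ACGT"), size=200))
    base_b = mutate_sequence(base_a, 0.40, 0.0, rng)
    assert pairwise_identity(base_a, base_b) < 0.80
    records = [
        _rec("a1", base_a),
        _rec("a2", mutate_sequence(base_a, 0.02, 0.0, rng)),
        _rec("b1", base_b),
        _rec("b2", mutate_sequence(base_b, 0.02, 0.0, rng)),
    ]
    clusters = greedy_cluster(records, 0.80)
    parts = sorted(sorted(c.member_ids) for c in clusters)
    assert parts == [["a1", "a2"], ["b1", "b2"]]


def test_greedy_cluster_duplicate_ids_rejected():
    with pytest.raises(ValueError):
        greedy_cluster([_rec("x", "ACGT"), _rec("x", "ACGT")], 0.9)


def test_select_representative_modal_type_and_tie_breaks():
    members = [_rec("A", "ACGT"), _rec("B", "ACGT"), _rec("C", "ACGG")]
    assert select_representative(members) == "A"  # modal type, then id order


def test_select_representative_single_member():
    assert select_representative([_rec("only", "ACGT")]) == "only"


def test_select_representative_modal_count_fixture(rng):
    base = "".join(rng.choice(list("ACGT"), size=80))
    variant1 = mutate_sequence(base, 0.05, 0.0, rng)
    variant2 = mutate_sequence(base, 0.05, 0.0, rng)
    members = (
        [_rec(f"m{i}", base) for i in range(5)]
        + [_rec(f"v{i}", variant1) for i in range(3)]
        + [_rec(f"w{i}", variant2) for i in range(2)]
    )
    rep = select_representative(members)
    assert rep in {f"m{i}" for i in range(5)}


def test_sh_params_validation():
    with pytest.raises(ValueError):
        ShParams(representative_threshold=0.984)
    with pytest.raises(ValueError):
        ShParams(sh_thresholds=(0.99, 0.97, 0.985))


def test_species_hypotheses_singleton_cluster():
    levels = build_species_hypotheses([_rec("solo", "ACGT" * 40)])
    for t, shs in levels.items():
        assert len(shs) == 1
        assert shs[0].member_ids == ["solo"]
        assert shs[0].representative_id == "solo"


def test_species_hypotheses_two_species_at_097(rng):
    base = "".join(rng.choice(list("ACGT"), size=300))
    sp2 = mutate_sequence(base, 0.05, 0.0, rng)
    records = [
        _rec("s1a", base),
        _rec("s1b", mutate_sequence(base, 0.004, 0.0, rng)),
        _rec("s2a", sp2),
        _rec("s2b", mutate_sequence(sp2, 0.004, 0.0, rng)),
    ]
    levels = build_species_hypotheses(records)
    shs = levels[0.97]
    assert len(shs) == 2
    assert sorted(sorted(s.member_ids) for s in shs) == [["s1a", "s1b"], ["s2a", "s2b"]]


def test_sh_nesting_across_thresholds(small_corpus):
    """Every SH at a threshold is contained in exactly one SH at any lower
    threshold (monotone refinement)."""
    _, records, _ = small_corpus
    params = ShParams()
    for genus_cluster in greedy_cluster(records, params.genus_threshold):
        members = [r for r in records if r.id in set(genus_cluster.member_ids)]
        levels = build_species_hypotheses(members, params)
        thresholds = params.sh_thresholds
        for lo, hi in zip(thresholds, thresholds[1:]):
            parents = {m: sh.sh_id for sh in levels[lo] for m in sh.member_ids}
            for sh in levels[hi]:
                containers = {parents[m] for m in sh.member_ids}
                assert len(containers) == 1


def test_reference_set_counts_match_sh_count(small_corpus):
    _, records, _ = small_corpus
    refset = build_reference_dataset(records)
    assert len(refset.records) == len(refset.species_hypotheses)
    assert len({r.id for r in refset.records}) == len(refset.records)


def test_singleton_policy_and_sanctioning(rng):
    base = "".join(rng.choice(list("ACGT"), size=300))
    lone = mutate_sequence(base, 0.05, 0.0, rng)
    records = [
        _rec("dup1", base),
        _rec("dup2", mutate_sequence(base, 0.004, 0.0, rng)),
        _rec("lone", lone),
    ]
    refset = build_reference_dataset(records)
    assert {r.id for r in refset.records} == {"dup1"}  # singleton excluded
    refset2 = build_reference_dataset(records, sanctioned_singletons=["lone"])
    assert {r.id for r in refset2.records} == {"dup1", "lone"}
    sanctioned_sh = [
        sh for sh in refset2.species_hypotheses if sh.member_ids == ["lone"]
    ]
    assert sanctioned_sh and sanctioned_sh[0].sanctioned_singleton


def test_manual_override_supersedes_automatic(rng):
    base = "".join(rng.choice(list("ACGT"), size=300))
    records = [
        _rec("a", base),
        _rec("b", base),
        _rec("c", mutate_sequence(base, 0.004, 0.0, rng)[:290]),
    ]
    auto = build_reference_dataset(records)
    (sh,) = auto.species_hypotheses
    assert auto.provenance[sh.representative_id][1] == "automatic"
    manual = build_reference_dataset(records, overrides={sh.sh_id: "c"})
    assert {r.id for r in manual.records} == {"c"}
    assert manual.provenance["c"] == (sh.sh_id, "manual")


def test_override_errors(rng):
    base = "".join(rng.choice(list("ACGT"), size=300))
    records = [_rec("a", base), _rec("b", base)]
    refset = build_reference_dataset(records)
    (sh,) = refset.species_hypotheses
    with pytest.raises(ValueError, match="unknown SH"):
        build_reference_dataset(records, overrides={"SHBOGUS": "a"})
    with pytest.raises(ValueError, match="not a member"):
        build_reference_dataset(records, overrides={sh.sh_id: "zzz"})


def test_reference_set_deterministic(small_corpus):
    _, records, _ = small_corpus
    r1 = build_reference_dataset(records)
    r2 = build_reference_dataset(list(records), ShParams())
    assert [r.id for r in r1.records] == [r.id for r in r2.records]
    assert r1.provenance == r2.provenance
    assert r1.membership == r2.membership


def test_sh_count_tracks_species_count():
    """The number of multi-member SHs at 98.5% stays close to the number of
    true species: conspecific pairs sit ~1% apart on average, so occasional
    Poisson fluctuations past the 1.5% threshold may split off a few."""
    from itschimera import CorpusSpec, generate_corpus

    spec = CorpusSpec(n_genera=5, species_per_genus=3, seqs_per_species=3, seed=77)
    records, truth = generate_corpus(spec)
    refset = build_reference_dataset(records)
    n_species = len({e.species for e in truth})
    assert abs(len(refset.species_hypotheses) - n_species) <= max(2, 0.15 * n_species)
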