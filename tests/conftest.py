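import logging

import numpy as np
import pytest

from itschimera import (
    BenchmarkSpec,
    CorpusSpec,
    build_reference_dataset,
    corpus_58s_consensus,
    generate_corpus,
    make_benchmark,
)
from itschimera.regions import annotate_records

logging.getLogger("itschimera").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_corpus():
    """A 4-genus x 3-species x 3-record corpus with ground truth."""
    spec = CorpusSpec(n_genera=4, species_per_genus=3, seqs_per_species=3, seed=500)
    records, truth = generate_corpus(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def small_refset(small_corpus):
    """Reference set + 5.8S-annotated reference records of the small corpus."""
    spec, records, _ = small_corpus
    refset = build_reference_dataset(records)
    consensus = corpus_58s_consensus(spec)
    annotated, failed = annotate_records(refset.records, consensus)
    assert not failed
    return refset, annotated, consensus


@pytest.fixture(scope="session")
def benchmark_run():
    """The full scaled benchmark used by the acceptance checks.

    ~120 species with >=2 sequences each (40 genera x 3 species x 3 records),
    inter-species ITS divergence 0.05 and near-invariant 5.8S; the reference
    set is built with default SH clustering, annotated by 5.8S anchoring, and
    10 derangement-chimera replicates are screened against it at the default
    0.28 threshold, alongside a self-excluded screen of the clean references.
    """
    from itschimera import DetectorParams, screen_corpus

    spec = CorpusSpec(n_genera=40, species_per_genus=3, seqs_per_species=3, seed=11)
    records, truth = generate_corpus(spec)
    refset = build_reference_dataset(records)
    consensus = corpus_58s_consensus(spec)
    annotated, failed = annotate_records(refset.records, consensus)
    assert not failed
    benchmark = make_benchmark(annotated, BenchmarkSpec(n_replicates=10, seed=12))
    replicate_calls = []
    for replicate in benchmark:
        calls, _ = screen_corpus(
            [c.to_record() for c in replicate], annotated, DetectorParams()
        )
        replicate_calls.append(calls)
    clean_calls, _ = screen_corpus(
        annotated, annotated, DetectorParams(self_exclude=True)
    )
    return {
        "spec": spec,
        "records": records,
        "truth": truth,
        "refset": refset,
        "annotated": annotated,
        "benchmark": benchmark,
        "replicate_calls": replicate_calls,
        "clean_calls": clean_calls,
    }
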