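from pathlib import Path

import pytest

import semlink as sl

DATA = Path(__file__).parent / "data"

#: four-gene corpus on the five-term demo ontology: propagated counts are
#: C:1, A:2, B:2, D:0, R:4, hence IC(A)=IC(B)=ln 2 and IC(C)=ln 4
D5_ANNOTATIONS = {"g1": {"C"}, "g2": {"A"}, "g3": {"B"}, "g4": {"B"}}


@pytest.fixture(scope="session")
def d5_dag() -> sl.OntologyDAG:
    return sl.parse_obo(DATA / "d5.obo")


@pytest.fixture(scope="session")
def d5_corpus(d5_dag) -> sl.AnnotationCorpus:
    return sl.propagate_counts(d5_dag, D5_ANNOTATIONS)


@pytest.fixture(scope="session")
def d5_ic(d5_corpus) -> sl.ICTable:
    return sl.compute_ic(d5_corpus, "BP")
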