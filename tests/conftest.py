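import pytest

import mitolepi as ml

#: one fixed seed for the shared simulated genome used across test modules
SIM_SEED = 7


@pytest.fixture(scope="session")
def t1():
    """Packaged H. persimilis annotation (376 bp control region, 15,252 bp)."""
    return ml.packaged_annotation("hestina_persimilis")


@pytest.fixture(scope="session")
def t2():
    """Packaged H. nama annotation (390 bp control region, 15,208 bp)."""
    return ml.packaged_annotation("hestinalis_nama")


@pytest.fixture(scope="session")
def sim():
    """One simulated mitogenome from the default template, with ground truth."""
    rec, truth = ml.simulate_mitogenome(ml.default_template(), seed=SIM_SEED)
    return rec, truth


@pytest.fixture(scope="session")
def code():
    return ml.invertebrate_mito_code()


def tiny_record(seq: str, name: str = "cox1", strand: str = "F") -> ml.MitogenomeRecord:
    """A record with one feature spanning the whole sequence."""
    feat = ml.GeneFeature(name=name, strand=strand, start=1, end=len(seq))
    ann = ml.MitogenomeAnnotation(species="tiny", genome_length=len(seq), features=[feat])
    return ml.MitogenomeRecord(annotation=ann, sequence=seq)
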