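import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tibrep.clone_io import CloneRecord, Repertoire

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_clone(
    cdr3_nt="TGTGCAAGATGG",
    v="IGHV3-23*01",
    j="IGHJ4*01",
    c="IGHG1",
    count=5,
    cdr3_aa=None,
    sample_id="S1",
):
    if cdr3_aa is None:
        rec = CloneRecord(cdr3_nt, "", (v,), (j,), (c,) if c else (), count, sample_id)
        cdr3_aa = rec.translate() if len(cdr3_nt) % 3 == 0 else ""
    return CloneRecord(
        cdr3_nt, cdr3_aa, (v,), (j,), (c,) if c else (), count, sample_id
    )


def make_repertoire(clones, sample_id="S1", total_reads=None, qc_pass=True, **kw):
    return Repertoire(
        sample_id=sample_id,
        clones=list(clones),
        total_reads=total_reads,
        qc_pass=qc_pass,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_repertoire():
    """Three clonotypes with distinct counts, genes and CDR3s."""
    return make_repertoire(
        [
            make_clone("TGTGCAAGATGG", "IGHV3-23*01", "IGHJ4*01", "IGHG1", 5),
            make_clone("TGTGCCCGATGG", "IGHV1-18*01", "IGHJ6*01", "IGHG2", 3),
            make_clone("TGTTTTAGATGG", "IGHV3-23*01", "IGHJ4*01", "IGHA1", 2),
        ]
    )
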