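"""Shared fixtures: one synthetic input set and one populated store."""

from __future__ import annotations

import numpy as np
import pytest

from rsnpscan import run_pipeline
from rsnpscan.simulate import make_fixture
from rsnpscan.store import ResultStore

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Synthetic genome/annotation/VCF/PWM set with 5+5+5 planted events."""
    out = tmp_path_factory.mktemp("fixture")
    manifest = make_fixture(FIXTURE_SEED, out)
    return out, manifest


@pytest.fixture(scope="session")
def populated_store(fixture_dir):
    """The fixture run end-to-end into an in-memory store."""
    out, manifest = fixture_dir
    store = ResultStore()
    result = run_pipeline(out / "genome.fa", out / "genes.gff3",
                          out / "snps.vcf", out / "pwms.transfac", store)
    return store, manifest, result


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_pwm(rng, width, pwm_id="V$RND_01", **kw):
    """A random frequency matrix via per-row Dirichlet draws."""
    from rsnpscan.pwm import PWM
    freq = rng.dirichlet(np.ones(4), size=width)
    return PWM(pwm_id, freq, **kw)
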