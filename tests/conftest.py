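import numpy as np
import pytest

from pansv.model import VariantClass as VC
from pansv.simulate import (
    VariantSpec,
    implant_variants,
    simulate_reference,
)


@pytest.fixture(scope="session")
def ref_small():
    """Single 300 kb chromosome, fixed seed."""
    return simulate_reference(1, 300_000, gc=0.35, seed=11)


@pytest.fixture(scope="session")
def implanted_small(ref_small):
    """Small genome with all pointwise variant classes implanted (no TRANS)."""
    spec = VariantSpec(
        counts={
            VC.SNP: 10,
            VC.SMALL_INS: 5,
            VC.SMALL_DEL: 5,
            VC.CAN_INS: 8,
            VC.CAN_DEL: 8,
            VC.COM_INS: 4,
            VC.COM_DEL: 4,
            VC.INV: 1,
        },
        inv_range=(2_000, 5_000),
    )
    derived, truth = implant_variants(ref_small, spec, seed=12, accession_id="acc1")
    return derived, truth


@pytest.fixture(scope="session")
def called_small(ref_small, implanted_small):
    from pansv.discovery import call_variants

    derived, truth = implanted_small
    return call_variants(ref_small, derived), derived, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
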