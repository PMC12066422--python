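import pytest

from asipbpk import (
    CompoundRecord,
    load_compound_library,
    reference_subject,
)
from asipbpk.compounds import KP_TISSUES


@pytest.fixture(scope="session")
def library():
    return load_compound_library()


@pytest.fixture(scope="session")
def records(library):
    return {r.name: r for r in library}


@pytest.fixture(scope="session")
def subject70():
    return reference_subject(70.0)


@pytest.fixture(scope="session")
def make_compound():
    """Factory for synthetic test compounds with uniform partition behaviour."""

    def _make(
        name="probe",
        kp=1.0,
        bpr=1.0,
        cl_app=10.0,
        gi_ka=1.0,
        kp_scaler=1.0,
        f_up=0.5,
        mw=300.0,
        ic50_cyp11b1=100.0,
        ic50_cyp11b2=10.0,
    ):
        return CompoundRecord(
            name=name,
            smiles="C",
            mw=mw,
            f_up=f_up,
            bpr=bpr,
            gi_ka=gi_ka,
            cl_app=cl_app,
            vss_per_kg=1.0,
            kp={t: kp for t in KP_TISSUES},
            kp_scaler=kp_scaler,
            ic50_cyp11b1=ic50_cyp11b1,
            ic50_cyp11b2=ic50_cyp11b2,
        )

    return _make
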