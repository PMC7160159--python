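import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

import otodiet as od

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_reference(fish_id, species, ol, sl, cl, ftl=None, fw=None,
                   side="right", nodules="unrecorded"):
    return od.ReferenceOtolith(fish_id=fish_id, species=species, side=side,
                               ol_mm=ol, sl_mm=sl, cl_mm=cl, ftl_mm=ftl,
                               fw_g=fw, nodules=nodules)


def make_prey(dolphin_id, species="croaker", side="right", grade="2",
              broken=False, ol=None, sl=None, cl=None, weight=None,
              nodules="unrecorded"):
    o = od.PreyOtolith(dolphin_id=dolphin_id, species_initial=species,
                       side=side, grade=grade, broken=broken, ol_mm=ol,
                       sl_mm=sl, cl_mm=cl, nodules=nodules)
    o.est_weight_g = weight
    return o


def make_stomach(dolphin_id, date="2005-07-15", length=None, otoliths=()):
    st = od.StomachRecord(dolphin_id=dolphin_id,
                          stranding_date=dt.date.fromisoformat(date),
                          predator_length_cm=length)
    st.otoliths = list(otoliths)
    return st


@pytest.fixture(scope="session")
def ratio_reference():
    """Reference otoliths of the two Cynoscion species with ratios drawn
    from the default generator (tails straddling the 0.49-0.50 band)."""
    cfgs = od.default_species_configs()
    sub = {sp: cfgs[sp] for sp in (od.Species.SPOTTED_SEATROUT,
                                   od.Species.WEAKFISH)}
    ref, _ = od.simulate_reference(sub, n_per_species=110, seed=11)
    return ref


@pytest.fixture(scope="session")
def packaged_models():
    return od.load_packaged_models()
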