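import pytest

from nipiscreen.normalize import NormalizedWell


def make_normalized_well(
    ngfp=1.0,
    nred=1.0,
    ntof=1.0,
    clone="clone",
    condition="infected",
    round_label=1,
    replicate=1,
    plate="P001",
    well="A01",
    n_worms=100,
    qc=False,
):
    """A NormalizedWell with the given normalized values (raw means filled in)."""
    return NormalizedWell(
        plate_id=plate,
        well_id=well,
        clone_id=clone,
        condition=condition,
        round=round_label,
        replicate_index=replicate,
        n_worms=n_worms,
        mean_gfp_tof=ngfp,
        mean_red_tof=2.0 * nred,
        mean_tof=100.0 * ntof,
        qc_low_count=qc,
        ngfp=ngfp,
        nred=nred,
        ntof=ntof,
    )


@pytest.fixture
def well_factory():
    return make_normalized_well
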