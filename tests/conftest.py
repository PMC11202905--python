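import numpy as np
import pytest

from dsbdyn import MotionParams, generate_fbm_3d


@pytest.fixture(scope="session")
def fbm_params():
    """The passive-motion parameters used throughout: alpha=0.5, K=20."""
    return MotionParams(alpha=0.5, k_alpha=20.0, dt=1.0, n_steps=1024)


@pytest.fixture(scope="session")
def fbm_ensemble(fbm_params):
    """1000 independent FBM trajectories at the default parameters."""
    return [generate_fbm_3d(fbm_params, seed=1, end_id=i) for i in range(1000)]


def make_break_end(end_id, position, *, dsb_id=None, partner=None, chrom_id=0,
                   locus=0.3, side="left", interval=(0.0, 0.3), centromere=False,
                   state=None):
    """Hand-built BreakEnd for join/classification tests."""
    from dsbdyn.damage import BreakEnd
    from dsbdyn.repair import RepairState

    end = BreakEnd(
        end_id=end_id,
        dsb_id=end_id // 2 if dsb_id is None else dsb_id,
        partner_end_id=(end_id ^ 1) if partner is None else partner,
        chrom_id=chrom_id,
        break_locus=locus,
        side=side,
        fragment_interval=interval,
        has_centromere=centromere,
        position=np.asarray(position, dtype=float),
    )
    end.repair_state = int(RepairState.PKCS_BOUND if state is None else state)
    return end
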