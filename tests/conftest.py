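import numpy as np
import pandas as pd
import pytest

from elenta import synth
from elenta.feature_table import make_feature_table


@pytest.fixture
def small_table():
    """6 features x (4 culture + 4 control + 2 blank) raw-intensity table."""
    rng = np.random.default_rng(7)
    fids = [f"F{i}" for i in range(6)]
    sids = [f"c{i}" for i in range(4)] + [f"k{i}" for i in range(4)] + ["b0", "b1"]
    vals = pd.DataFrame(
        10 ** rng.uniform(4, 5, size=(6, 10)), index=fids, columns=sids
    )
    roles = {s: ("blank" if s.startswith("b") else "sample") for s in sids}
    groups = {s: ("blank" if s.startswith("b") else "culture" if s.startswith("c") else "control")
              for s in sids}
    reps = {s: int(s[1]) if not s.startswith("b") else int(s[1]) for s in sids}
    return make_feature_table(
        vals,
        mz=pd.Series(rng.uniform(100, 500, 6), index=fids),
        rt=pd.Series(rng.uniform(1, 10, 6), index=fids),
        sample_roles=roles,
        sample_groups=groups,
        sample_replicates=reps,
    )


@pytest.fixture
def toy_spec():
    return synth.gen_toy_model()


@pytest.fixture
def toy_spec_full():
    """Toy network with the agmatine pathway and a futile cycle."""
    return synth.gen_toy_model(agmatine_uptake=5.0, with_futile_cycle=True)
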