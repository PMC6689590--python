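import math

import pytest

from unitcomp.params import CompetitionParams


@pytest.fixture
def ln2_params() -> CompetitionParams:
    """Worked-example bundle: lam=2, u/Rbar=ln 2 so that e^{u/Rbar}-1 = 1."""
    return CompetitionParams(lam=2.0, u=math.log(2.0), Rbar=1.0, s=2)
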