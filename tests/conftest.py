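import numpy as np
import pytest

import cantrace as ct


def make_panel(seqs, fragments=None, **kwargs):
    """Small hand-built panel: seqs is a list of (id, species, sequence)."""
    length = len(seqs[0][2])
    frags = fragments or {"AB": ct.FragmentDef("AB", 1, length)}
    records = [ct.RefRecord(id=i, species=sp, sequence=s) for i, sp, s in seqs]
    return ct.ReferencePanel(
        records=records, alignment_length=length, fragments=frags, **kwargs
    )


@pytest.fixture(scope="session")
def default_panel():
    """Default synthetic panel plus its planted diagnostic-column map."""
    return ct.synthesize_panel(ct.SyntheticPanelSpec(), seed=11)


@pytest.fixture(scope="session")
def default_study(default_panel):
    panel, planted = default_panel
    records = ct.simulate_study(
        ct.StudyDesign(), panel, ct.DegradationParams(), seed=12,
        planted_diagnostics=planted,
    )
    return panel, planted, records


@pytest.fixture()
def rng():
    return np.random.default_rng(202)
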