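"""Shared fixtures.

The desk-scale run (synthetic cohort generation + end-to-end MIL training +
whole-slide inference) takes a few minutes and is shared session-wide by the
interpretability, correspondence and acceptance tests.
"""

import pytest


@pytest.fixture(scope="session")
def desk_run():
    from spongemil.pipeline import desk_scale_run

    return desk_scale_run()
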