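"""Shared study cohort for the numbered analysis drivers.

Eight users, 6 codes x 150 presentations at 1000 Hz, between-user spread in
amplitude/latency/shape, ~5% blink epochs.  Deterministic for SEED so every
driver sees the same cohort without passing files around; driver 01 writes
the sessions to disk for inspection and CLI use.
"""

import erpleak as el

SEED = 1
N_USERS = 8


def build_cohort():
    cfg = el.SessionConfig()
    return el.simulate_cohort(N_USERS, seed=SEED, spread=1.0, config=cfg)
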