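"""Shared fixtures: the canonical example walking systems.

The running example throughout the package: eigenfrequency 3.13 s^-1
(leg length ~1 m), step time 0.5 s (cadence 120 steps/min), gains
b_p = 2.5, b_d = 0.6 s — a stable system in both stepping modes.
"""

import pytest

from gaitstab import WalkerParams

OMEGA = 3.13
T_STEP = 0.5


@pytest.fixture
def prog_params() -> WalkerParams:
    return WalkerParams(
        omega=OMEGA, b_o=-0.05, b_p=2.5, b_d=0.6, t_step=T_STEP, mode="progressive"
    )


@pytest.fixture
def alt_params() -> WalkerParams:
    return WalkerParams(
        omega=OMEGA, b_o=0.02, b_p=2.5, b_d=0.6, t_step=T_STEP, mode="alternating"
    )
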