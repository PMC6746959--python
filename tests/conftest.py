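"""Shared fixtures: call factories and a small simulated cohort."""

from __future__ import annotations

import pytest

from cnvtrio.model import CnvCall, GenomicInterval


def make_call(
    call_id: str,
    chrom: str = "chr1",
    start: int = 1000,
    end: int = 2000,
    sample_id: str = "S1",
    family_id: str | None = None,
    role: str = "proband",
    cohort: str = "discovery",
    platform: str = "wes",
    cnv_type: str = "DEL",
    quality: float | None = None,
    support: str | None = None,
) -> CnvCall:
    return CnvCall(
        call_id=call_id,
        sample_id=sample_id,
        family_id=family_id if family_id is not None else f"F_{sample_id}",
        role=role,
        cohort=cohort,
        platform=platform,
        interval=GenomicInterval(chrom, start, end),
        cnv_type=cnv_type,
        quality=quality,
        support=support,
    )


@pytest.fixture
def call_factory():
    return make_call


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort, shared across tests."""
    from cnvtrio.simulate import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(master_seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    from cnvtrio.simulate import SimulationConfig, simulate_cohort

    return simulate_cohort(SimulationConfig(master_seed=11).noiseless())
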