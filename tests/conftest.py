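import datetime as dt

import pytest

from econsult_cba.fee_model import FeeSchedule, default_codes
from econsult_cba.money import to_cents
from econsult_cba.synthetic import GeneratorConfig
from econsult_cba.utilization import ConsultRecord


@pytest.fixture
def default_schedule() -> FeeSchedule:
    """Two phone-consult codes at $2.68/MSU with a flat $174.17 specialist fee."""
    return FeeSchedule(
        2.68,
        default_codes(),
        {"internal_medicine": to_cents("174.17"), "psychiatry": to_cents("174.17")},
    )


def make_log(counts: dict[str, int]) -> list[ConsultRecord]:
    """A consult log with exactly the given per-specialty counts."""
    log = []
    i = 0
    for specialty, n in counts.items():
        for _ in range(n):
            log.append(ConsultRecord(f"C{i:05d}", specialty, dt.date(2023, 1, 1)))
            i += 1
    return log


@pytest.fixture
def small_config() -> GeneratorConfig:
    """A scaled-down generator config for fast end-to-end tests."""
    return GeneratorConfig(seed=7)
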