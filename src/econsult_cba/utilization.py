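"""Platform-utilization tallies: consults by specialty and the provider mix.

Reproduces the two utilization tables of a feasibility evaluation: counts and
shares of completed consults per specialty (with a top-N cut at a minimum
consult volume) and counts/shares of registered providers by role.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .money import round_half_up


class Role(str, Enum):
    PRIMARY_CARE = "primary_care"
    SPECIALIST = "specialist"


@dataclass(frozen=True)
class ConsultRecord:
    consult_id: str
    specialty: str
    date: dt.date
    completed: bool = True
    requesting_role: Role = Role.PRIMARY_CARE


@dataclass(frozen=True)
class ProviderRecord:
    provider_id: str
    role: Role
    join_date: dt.date


@dataclass(frozen=True)
class SpecialtyTally:
    specialty: str
    count: int
    share: float  # proportion of total qualifying consults


@dataclass(frozen=True)
class ProviderMix:
    counts: dict[str, int]  # role value -> count
    total: int

    @property
    def shares(self) -> dict[str, float] | None:
        """Role -> proportion; None (undefined) for an empty registry."""
        if self.total == 0:
            return None
        return {role: n / self.total for role, n in self.counts.items()}

    def share_percent(self, role: Role | str) -> int | None:
        shares = self.shares
        if shares is None:
            return None
        key = role.value if isinstance(role, Role) else role
        return int(round_half_up(100 * shares.get(key, 0.0)))


def filter_window(
    records: Iterable[ConsultRecord],
    start: dt.date | None = None,
    end: dt.date | None = None,
) -> list[ConsultRecord]:
    """Restrict a consult log to a study window (inclusive bounds)."""
    out = []
    for r in records:
        if start is not None and r.date < start:
            continue
        if end is not None and r.date > end:
            continue
        out.append(r)
    return out


def tally_by_specialty(
    log: Iterable[ConsultRecord], completed_only: bool = True
) -> list[SpecialtyTally]:
    """One tally per distinct specialty, descending count then alphabetical.

    Shares are unrounded proportions of the qualifying total; an empty log
    yields an empty list.
    """
    counts: Counter[str] = Counter(
        r.specialty for r in log if r.completed or not completed_only
    )
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [SpecialtyTally(s, n, n / total) for s, n in ordered]


def top_specialties(
    tallies: Sequence[SpecialtyTally], min_consults: int = 100
) -> tuple[list[SpecialtyTally], float]:
    """Specialties with at least ``min_consults`` consults, plus their combined share.

    The combined share is taken over the grand total of all tallies, so with
    ``min_consults=1`` it is exactly 1.
    """
    if min_consults < 1:
        raise ValueError("min_consults must be >= 1")
    total = sum(t.count for t in tallies)
    subset = [t for t in tallies if t.count >= min_consults]
    combined = sum(t.count for t in subset) / total if total else 0.0
    return subset, combined


def provider_mix(registry: Iterable[ProviderRecord]) -> ProviderMix:
    """Per-role provider counts; shares undefined when the registry is empty."""
    counts = {role.value: 0 for role in Role}
    for p in registry:
        counts[Role(p.role).value] += 1
    return ProviderMix(counts=counts, total=sum(counts.values()))
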