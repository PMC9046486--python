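"""Synthetic TBARS storage studies with the structure the analysis assumes.

Each study mimics the experimental design: 14 sample groups (control + 13
extract treatments), storage at 4/8/12/16/20 degC, triplicate series, longer
sampling schedules at chill temperatures (13 days) than at abuse temperatures
(5 days).  True dynamics follow first-order growth of TBARS% with a rate
constant from each group's ground-truth temperature law; observations carry
unit-mean multiplicative lognormal noise, so replicate scatter grows with the
mean as it does in the assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dataio import TBARSSeries
from .primary import normalize_percent
from .secondary import GAS_CONSTANT

__all__ = [
    "ArrheniusTruth",
    "LogLogisticTruth",
    "SynthSpec",
    "generate_study",
    "published_study_spec",
]


@dataclass(frozen=True)
class ArrheniusTruth:
    """Ground-truth Arrhenius law: k(T) = k0 exp(-ea/(R T))."""

    ea: float
    k0: float

    def rate(self, temperature: float) -> float:
        return self.k0 * np.exp(-self.ea / (GAS_CONSTANT * temperature))


@dataclass(frozen=True)
class LogLogisticTruth:
    """Ground-truth softplus law: k(T) = m' ln(1 + exp(c (T - tc)))."""

    c: float
    tc: float
    m_prime: float = 1.0

    def rate(self, temperature: float) -> float:
        return self.m_prime * np.logaddexp(0.0, self.c * (temperature - self.tc))


#: Cut between the 13-day and the 5-day sampling schedule (12 degC inclusive).
_SCHEDULE_CUT_K = 285.16


@dataclass
class SynthSpec:
    """Design of a synthetic storage study.

    ``groups`` maps sample labels to ground-truth temperature laws.
    ``schedule_long`` applies at temperatures up to 12 degC, ``schedule_short``
    above.  ``noise_cv`` is the relative SD of the multiplicative lognormal
    observation noise; ``initial_tbars_raw`` is the day-0 TBARS level in
    mg MDA/kg meat.
    """

    groups: Mapping[str, ArrheniusTruth | LogLogisticTruth]
    temperatures: Sequence[float] = (277.15, 281.15, 285.15, 289.15, 293.15)
    schedule_long: Sequence[float] = (0, 1, 3, 5, 7, 9, 11, 13)
    schedule_short: Sequence[float] = (0, 1, 2, 3, 4, 5)
    n_replicates: int = 3
    noise_cv: float = 0.05
    initial_tbars_raw: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.schedule_long[0] != 0 or self.schedule_short[0] != 0:
            raise ValueError("sampling schedules must start at day 0")
        if any(T <= 0 for T in self.temperatures):
            raise ValueError("temperatures must be positive kelvins")

    def schedule_for(self, temperature: float) -> np.ndarray:
        sched = (
            self.schedule_long if temperature <= _SCHEDULE_CUT_K else self.schedule_short
        )
        return np.asarray(sched, dtype=float)


def generate_study(spec: SynthSpec) -> list[TBARSSeries]:
    """Draw one full study; byte-identical for a given ``spec.seed``.

    Observed raw values are ``initial * (true_percent/100) * exp(eps)`` with
    ``eps ~ N(-sigma^2/2, sigma^2)`` and ``sigma = sqrt(ln(1 + cv^2))`` — a
    unit-mean multiplicative noise, applied at every day including day 0.
    Percent values are re-anchored at 100 by normalization.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    out: list[TBARSSeries] = []
    for label in sorted(spec.groups):
        law = spec.groups[label]
        for T in spec.temperatures:
            times = spec.schedule_for(T)
            k = law.rate(T)
            true_percent = 100.0 * np.exp(k * times)
            for rep in range(1, spec.n_replicates + 1):
                if sigma > 0:
                    eps = rng.normal(-0.5 * sigma**2, sigma, size=times.size)
                else:
                    eps = np.zeros(times.size)
                raw = spec.initial_tbars_raw * (true_percent / 100.0) * np.exp(eps)
                series = TBARSSeries(
                    sample_label=label,
                    temperature=float(T),
                    replicate_id=rep,
                    times=times,
                    raw_values=raw,
                )
                out.append(normalize_percent(series))
    return out


def published_study_spec(seed: int = 0, noise_cv: float = 0.05) -> SynthSpec:
    """Study spec whose 14 groups carry the published Arrhenius parameters."""
    from .dataio import load_secondary_fixture

    fixture = load_secondary_fixture()
    groups = {
        label: ArrheniusTruth(ea=p.ea, k0=p.k0) for label, p in fixture.items()
    }
    return SynthSpec(groups=groups, noise_cv=noise_cv, seed=seed)
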