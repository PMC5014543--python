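"""Shared fixtures and independent oracles for the trajsat test suite."""

from __future__ import annotations

import math
from datetime import datetime, timedelta

import numpy as np
import pytest

from trajsat.gbtm import GbtmModel
from trajsat.ingest import SpeedObservation, SpeedSeries, VisitRecord


def make_series(pid: str, speeds, times=None) -> SpeedSeries:
    """Build a SpeedSeries directly from speed values (unit durations)."""
    if times is None:
        times = range(len(speeds))
    obs = tuple(
        SpeedObservation(participant_id=pid, coded_time=int(t), duration=1.0, speed=float(y))
        for t, y in zip(times, speeds)
    )
    return SpeedSeries(participant_id=pid, observations=obs)


def make_records(n: int, *, start_visit: int = 50, n_visits: int = 9,
                 duration_s: float = 600.0, word_count: int = 1200) -> list[VisitRecord]:
    """n well-formed records laid out over participants x visits."""
    base = datetime(2009, 1, 1, 9, 0, 0)
    records = []
    i = 0
    while len(records) < n:
        pid = f"Q{i:05d}"
        for v in range(start_visit, start_visit + n_visits):
            if len(records) == n:
                break
            start = base + timedelta(days=len(records) % 365)
            records.append(
                VisitRecord(
                    participant_id=pid,
                    visit=v,
                    start_time=start,
                    end_time=start + timedelta(seconds=duration_s),
                    word_count=word_count,
                )
            )
        i += 1
    return records


def toy_model(pi, beta, sigma=1.0, order=None) -> GbtmModel:
    """Hand-assembled GbtmModel (for operations that only read its parameters)."""
    if np.isscalar(beta[0]):
        rows = [np.asarray(beta, dtype=float)]
    else:
        rows = [np.atleast_1d(np.asarray(b, dtype=float)) for b in beta]
    width = max(len(r) for r in rows)  # ragged rows are zero-padded
    beta = np.vstack([np.pad(r, (0, width - len(r))) for r in rows])
    pi = np.asarray(pi, dtype=float)
    if order is None:
        order = beta.shape[1] - 1
    return GbtmModel(
        pi=pi,
        beta=beta,
        sigma=np.asarray(sigma, dtype=float),
        shared_sigma=np.asarray(sigma).ndim == 0,
        order=order,
        loglik=0.0,
        n_params=0,
        bic=0.0,
        converged=True,
        n_participants=1,
    )


def brute_force_loglik(pi, beta, sigma, series) -> float:
    """Unvectorised mixture log-likelihood: plain per-observation products."""
    total = 0.0
    for s in series:
        mix = 0.0
        for j, p in enumerate(pi):
            prod = p
            for obs in s.observations:
                mu = sum(b * obs.coded_time**m for m, b in enumerate(beta[j]))
                z = (obs.speed - mu) / sigma
                prod *= math.exp(-0.5 * z * z) / (sigma * math.sqrt(2 * math.pi))
            mix += prod
        total += math.log(mix)
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
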