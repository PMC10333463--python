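"""Taylor-diagram statistics for model-vs-observation comparison.

Pattern agreement between a modeled field m and observations o is
summarized by three linked quantities with population (1/N) normalizers:

    r     = (1/N) sum (m - mbar)(o - obar) / (sigma_m sigma_o)
    sigma = sqrt((1/N) sum (x - xbar)^2)
    rmsd  = sqrt((1/N) sum [(m - mbar) - (o - obar)]^2)   (centered)

tied together by the law-of-cosines identity

    rmsd^2 = sigma_m^2 + sigma_o^2 - 2 sigma_m sigma_o r,

which every computed row must satisfy.  All statistics use only
pairwise-complete (jointly unmasked) samples.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TaylorStats", "pearson_r", "std_dev", "centered_rmsd", "taylor_table"]


def _pairwise_complete(m, o) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(m, dtype=float).ravel()
    o = np.asarray(o, dtype=float).ravel()
    if m.size != o.size:
        raise ValueError(f"series length mismatch: {m.size} vs {o.size}")
    ok = ~(np.isnan(m) | np.isnan(o))
    return m[ok], o[ok]


def pearson_r(m, o) -> float:
    """Product-moment correlation over pairwise-complete samples.

    Requires at least 3 complete pairs and nonzero variance in both series;
    a flat series makes the correlation undefined, which is an error here
    rather than a silent NaN.
    """
    m, o = _pairwise_complete(m, o)
    if m.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {m.size}")
    ma, oa = m - m.mean(), o - o.mean()
    sm, so = ma.std(), oa.std()  # population by numpy default
    if sm == 0 or so == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.mean(ma * oa) / (sm * so))


def std_dev(x) -> float:
    """Population (1/N) standard deviation."""
    x = np.asarray(x, dtype=float).ravel()
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("need >= 2 samples for a standard deviation")
    return float(x.std(ddof=0))


def centered_rmsd(m, o) -> float:
    """Centered pattern RMS difference: RMS of the anomaly differences.

    Invariant to adding a constant to either series — it measures pattern
    mismatch, not bias.
    """
    m, o = _pairwise_complete(m, o)
    if m.size < 2:
        raise ValueError("need >= 2 complete pairs")
    d = (m - m.mean()) - (o - o.mean())
    return float(np.sqrt(np.mean(d * d)))


@dataclass(frozen=True)
class TaylorStats:
    name: str
    r: float
    sd_model: float
    sd_obs: float
    rmsd: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r}")
        if self.sd_model < 0 or self.sd_obs < 0 or self.rmsd < 0:
            raise ValueError("sd and rmsd must be nonnegative")


def taylor_table(models: dict[str, np.ndarray], obs: np.ndarray) -> pd.DataFrame:
    """One comparison row per model plus the observation's self-row.

    The 'Obs' row anchors the diagram: r = 1, rmsd = 0, sd = sd_obs.
    Rows are computed on each model's pairwise-complete overlap with obs.
    """
    if not models:
        raise ValueError("no models to compare")
    rows = []
    obs_flat = np.asarray(obs, dtype=float).ravel()
    rows.append(
        TaylorStats("Obs", 1.0, std_dev(obs_flat), std_dev(obs_flat), 0.0,
                    int(np.count_nonzero(~np.isnan(obs_flat))))
    )
    for name, series in models.items():
        m, o = _pairwise_complete(series, obs_flat)
        if m.size == 0:
            raise ValueError(f"model {name!r} has no overlap with obs")
        rows.append(
            TaylorStats(
                name,
                pearson_r(m, o),
                std_dev(m),
                std_dev(o),
                centered_rmsd(m, o),
                m.size,
            )
        )
    return pd.DataFrame(
        {
            "model": [s.name for s in rows],
            "SD": [s.sd_model for s in rows],
            "RMSD": [s.rmsd for s in rows],
            "R": [s.r for s in rows],
            "n": [s.n for s in rows],
        }
    )
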