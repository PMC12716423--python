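"""Per-capita assembly rates, quantile envelopes, interchange matrices.

Events are binned into 1-Ma age windows.  A window is labeled by its
younger edge: an event of age ``a`` goes to the bin ``ceil(a) - 1``, so an
event exactly on an edge falls into the younger window.  Series run
oldest to present.

The regional lineage count n(t) is the running balance of in situ
speciation, subset speciation, niche expansion and colonization minus
local extinction, evaluated at the end of each window; the per-capita
rate of a process in window t is lam(t) = s(t) / n(t-1), the event count
divided by the lineage count at the end of the previous (older) window,
and defined as 0 when n(t-1) = 0.  Quantile envelopes (median and the
25-75% interval) are taken across replicate histories, and the masking
rule zeroes every value older than the last zero-valued window of each
quantile trajectory, independently per trajectory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .history import AssemblyEvent, Process

__all__ = [
    "bin_label",
    "bin_labels",
    "event_count_series",
    "lineage_count_series",
    "per_capita_rates",
    "quantile_envelope",
    "mask_leading",
    "RateSeries",
    "compute_rate_series",
    "interchange_totals",
    "migration_balance",
    "assembly_proportions",
]

#: processes adding to the regional lineage balance
_GAINS = (Process.IN_SITU_SPECIATION, Process.SUBSET_SPECIATION,
          Process.NICHE_EXPANSION, Process.COLONIZATION)


def bin_label(age: float) -> int:
    """Bin label (younger edge) for an event age; edge events go younger."""
    if age < 0:
        raise ValueError("ages must be nonnegative")
    return max(0, int(math.ceil(age)) - 1)


def bin_labels(max_age: float) -> np.ndarray:
    """Labels oldest to present for a record reaching back ``max_age`` Ma."""
    oldest = bin_label(max_age) if max_age > 0 else 0
    return np.arange(oldest, -1, -1)


def event_count_series(events: Sequence[AssemblyEvent], region: int,
                       process: str, max_age: float) -> np.ndarray:
    """s(t): events of one process in one region per window, oldest first."""
    labels = bin_labels(max_age)
    s = np.zeros(labels.size)
    offset = labels[0]
    for ev in events:
        if ev.region == region and ev.process == process:
            lb = bin_label(ev.age)
            if lb > offset:
                raise ValueError(f"event age {ev.age} older than max_age")
            s[offset - lb] += 1
    return s


def lineage_count_series(
    events: Sequence[AssemblyEvent],
    region: int,
    max_age: float,
    subtract_niche_contraction: bool = False,
) -> np.ndarray:
    """n(t): regional lineage balance at the end of each window.

    Cumulative sum of in situ speciation, subset speciation, niche
    expansion and colonization minus local extinction (optionally also
    minus niche contraction).  Floored at zero with a warning, since a
    negative balance indicates events outside the tracked vocabulary.
    """
    labels = bin_labels(max_age)
    delta = np.zeros(labels.size)
    offset = labels[0]
    for ev in events:
        if ev.region != region:
            continue
        if ev.process in _GAINS:
            d = 1.0
        elif ev.process == Process.LOCAL_EXTINCTION:
            d = -1.0
        elif ev.process == Process.NICHE_CONTRACTION:
            d = -1.0 if subtract_niche_contraction else 0.0
        else:
            raise ValueError(f"unclassified process {ev.process!r}")
        lb = bin_label(ev.age)
        if lb > offset:
            raise ValueError(f"event age {ev.age} older than max_age")
        delta[offset - lb] += d
    n = np.cumsum(delta)
    if (n < 0).any():
        warnings.warn("lineage balance went negative; flooring at 0",
                      stacklevel=2)
        run = 0.0
        for i, d in enumerate(delta):
            run = max(0.0, run + d)
            n[i] = run
    return n


def per_capita_rates(counts: np.ndarray, lineage_counts: np.ndarray) -> np.ndarray:
    """lam(t) = s(t) / n(t-1), 0 where the lagged count is 0.

    Both inputs are ordered oldest to present on the same windows; the
    lagged count for the oldest window is taken as 0.
    """
    s = np.asarray(counts, dtype=float)
    n = np.asarray(lineage_counts, dtype=float)
    if s.shape != n.shape:
        raise ValueError("bin misalignment between counts and lineage counts")
    lagged = np.concatenate([[0.0], n[:-1]])
    return np.divide(s, lagged, out=np.zeros_like(s), where=lagged > 0)


def quantile_envelope(rates_by_replicate: np.ndarray,
                      qs: Sequence[float] = (25.0, 50.0, 75.0)) -> dict:
    """Binwise quantiles across replicates (linear-interpolation rule).

    Input is a (replicates x windows) array; returns ``{"q25", "median",
    "q75"}`` (or the requested percentiles keyed ``q<value>``).
    """
    arr = np.asarray(rates_by_replicate, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a replicates x windows array "
                         "(ragged replicate lengths are not allowed)")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 replicates for an envelope")
    out = {}
    for q in qs:
        key = "median" if q == 50 else f"q{q:g}"
        out[key] = np.percentile(arr, q, axis=0, method="linear")
    return out


def mask_leading(series: np.ndarray) -> np.ndarray:
    """Zero every value strictly older than the last zero-valued window.

    The series is ordered oldest to present.  Idempotent; series without
    zeros pass through unchanged.  Applied independently per quantile
    trajectory by the callers.
    """
    arr = np.array(series, dtype=float)
    zeros = np.flatnonzero(arr == 0)
    if zeros.size:
        arr[: zeros[-1]] = 0.0
    return arr


@dataclass
class RateSeries:
    """Binned per-capita rates for one region and process across replicates."""

    region: int
    process: str
    labels: np.ndarray                  # window labels, oldest -> present
    counts: np.ndarray                  # (replicates, windows) s(t)
    lineages: np.ndarray                # (replicates, windows) n(t)
    rates: np.ndarray                   # (replicates, windows) lam(t)
    envelopes: dict = field(default_factory=dict)
    masked_envelopes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep in range(self.rates.shape[0]):
            for b, lb in enumerate(self.labels):
                rows.append((self.region, self.process, int(lb), rep,
                             self.counts[rep, b], self.lineages[rep, b],
                             self.rates[rep, b]))
        return pd.DataFrame(rows, columns=[
            "region", "process", "bin", "replicate", "count", "lineages",
            "rate"])

    def envelope_frame(self, masked: bool = True) -> pd.DataFrame:
        env = self.masked_envelopes if masked else self.envelopes
        df = pd.DataFrame({"bin": self.labels.astype(int)})
        for k, v in env.items():
            df[k] = v
        return df


def compute_rate_series(
    events_per_replicate: Iterable[Sequence[AssemblyEvent]],
    region: int,
    process: str,
    max_age: float,
    subtract_niche_contraction: bool = False,
) -> RateSeries:
    """Full chain: counts, lineage balances, per-capita rates, envelopes."""
    labels = bin_labels(max_age)
    counts, lineages, rates = [], [], []
    for events in events_per_replicate:
        s = event_count_series(events, region, process, max_age)
        n = lineage_count_series(events, region, max_age,
                                 subtract_niche_contraction)
        counts.append(s)
        lineages.append(n)
        rates.append(per_capita_rates(s, n))
    counts = np.asarray(counts)
    lineages = np.asarray(lineages)
    rates = np.asarray(rates)
    env = quantile_envelope(rates) if rates.shape[0] >= 2 else {}
    masked = {k: mask_leading(v) for k, v in env.items()}
    return RateSeries(region=region, process=process, labels=labels,
                      counts=counts, lineages=lineages, rates=rates,
                      envelopes=env, masked_envelopes=masked)


def _colonization_matrix(events: Sequence[AssemblyEvent], n_regions: int,
                         period: tuple[float, float],
                         weighted: bool = True) -> np.ndarray:
    age_old, age_young = period
    if age_old <= age_young:
        raise ValueError("period must be (older_age, younger_age)")
    lo = int(math.ceil(age_young))
    hi = int(math.floor(age_old)) - 1
    mat = np.zeros((n_regions, n_regions))
    for ev in events:
        if ev.process != Process.COLONIZATION:
            continue
        lb = bin_label(ev.age)
        if not (lo <= lb <= hi):
            continue
        for src, w in ev.source_regions:
            mat[src, ev.region] += w if weighted else 1.0 / len(ev.source_regions)
    return mat


def interchange_totals(
    events_per_replicate: Iterable[Sequence[AssemblyEvent]],
    period: tuple[float, float],
    n_regions: int,
) -> np.ndarray:
    """Median cumulative colonization counts per ordered region pair.

    Sums weighted colonization events into region j attributed to source
    region i over all whole 1-Ma windows inside ``period`` (an
    ``(older_age, younger_age)`` pair), then takes the median across
    replicates.  The diagonal is zero by construction.
    """
    mats = [_colonization_matrix(ev, n_regions, period)
            for ev in events_per_replicate]
    if not mats:
        raise ValueError("no replicates")
    return np.median(np.stack(mats), axis=0)


def migration_balance(
    events_per_replicate: Iterable[Sequence[AssemblyEvent]],
    period: tuple[float, float],
    n_regions: int,
    weighted: bool = True,
) -> pd.DataFrame:
    """Median emigration, immigration and their difference per region.

    ``weighted`` distributes each colonization over its source regions by
    weight; otherwise each event contributes one unit split equally (the
    two conventions coincide under equal-weight attribution but differ for
    alternative attributions).
    """
    emi, imm = [], []
    for events in events_per_replicate:
        e = np.zeros(n_regions)
        m = np.zeros(n_regions)
        age_old, age_young = period
        lo, hi = int(math.ceil(age_young)), int(math.floor(age_old)) - 1
        for ev in events:
            if ev.process != Process.COLONIZATION:
                continue
            lb = bin_label(ev.age)
            if not (lo <= lb <= hi):
                continue
            m[ev.region] += 1.0
            for src, w in ev.source_regions:
                e[src] += w if weighted else 1.0 / len(ev.source_regions)
        emi.append(e)
        imm.append(m)
    emi = np.median(np.stack(emi), axis=0)
    imm = np.median(np.stack(imm), axis=0)
    return pd.DataFrame({"region": np.arange(n_regions), "emigration": emi,
                         "immigration": imm, "balance": emi - imm})


def assembly_proportions(
    events_per_replicate: Iterable[Sequence[AssemblyEvent]],
    region: int,
) -> dict:
    """Relative contributions of assembly processes in one region.

    Takes median cumulative event counts per process across replicates and
    normalizes over the three assembly routes: cladogenesis (in situ +
    subset), colonization and niche expansion.  Also reports the in situ
    share within cladogenesis.  When the total is zero the shares are
    undefined and flagged.
    """
    procs = (Process.IN_SITU_SPECIATION, Process.SUBSET_SPECIATION,
             Process.COLONIZATION, Process.NICHE_EXPANSION)
    per_rep = []
    for events in events_per_replicate:
        c = {p: 0 for p in procs}
        for ev in events:
            if ev.region == region and ev.process in c:
                c[ev.process] += 1
        per_rep.append(c)
    if not per_rep:
        raise ValueError("no replicates")
    med = {p: float(np.median([c[p] for c in per_rep])) for p in procs}
    clado = med[Process.IN_SITU_SPECIATION] + med[Process.SUBSET_SPECIATION]
    total = clado + med[Process.COLONIZATION] + med[Process.NICHE_EXPANSION]
    out = {"median_counts": med, "defined": total > 0}
    if total > 0:
        out["shares"] = {
            "cladogenesis": clado / total,
            "colonization": med[Process.COLONIZATION] / total,
            "niche_expansion": med[Process.NICHE_EXPANSION] / total,
        }
        out["in_situ_within_cladogenesis"] = (
            med[Process.IN_SITU_SPECIATION] / clado if clado > 0
            else float("nan"))
    else:
        out["shares"] = {"cladogenesis": float("nan"),
                         "colonization": float("nan"),
                         "niche_expansion": float("nan")}
        out["in_situ_within_cladogenesis"] = float("nan")
    return out
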