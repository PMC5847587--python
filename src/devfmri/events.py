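"""Network-labeled stimulus events on the TR grid.

An :class:`Event` is an inclusive 1-based TR interval attributed to one
network; an :class:`EventSet` is an ordered collection in which same-network
events never touch (separated by at least one non-event TR, otherwise they
would be a single event). Events from *different* networks may overlap.

:func:`default_event_table` builds the canonical movie-like adult event
structure used by the synthetic generator and by the overlap permutation
analyses: 7 theory-of-mind events totalling 33 event TRs and 12 pain events
totalling 42 event TRs inside the 158-TR analysis window, with per-network
duration mean/s.d. close to 9.7(4.2) s and 7.2(4.7) s, and exactly one TR at
which a ToM and a pain event overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .acquisition import AcquisitionParams, ConfigurationError

log = logging.getLogger(__name__)

# Printed adult event structure: totals in event TRs (158 analyzed TRs minus
# the non-event TR counts 125/116) and duration moments in seconds.
TOM_N_EVENTS = 7
PAIN_N_EVENTS = 12
TOM_EVENT_TRS = 33
PAIN_EVENT_TRS = 42
TOM_DURATION_MEAN_S = 9.7
TOM_DURATION_SD_S = 4.2
PAIN_DURATION_MEAN_S = 7.2
PAIN_DURATION_SD_S = 4.7

_PARTITION_SEED = 20180312  # fixed: the default table is deterministic


@dataclass(frozen=True)
class Event:
    """One network event: an inclusive 1-based TR interval."""

    network: str
    onset_tr: int
    offset_tr: int
    label: str | None = None
    peak_tr: int | None = None
    peak_magnitude: float | None = None

    def __post_init__(self) -> None:
        if self.onset_tr < 1 or self.offset_tr < self.onset_tr:
            raise ValueError(
                f"invalid event interval [{self.onset_tr}, {self.offset_tr}]"
            )
        if self.peak_tr is not None and not (
            self.onset_tr <= self.peak_tr <= self.offset_tr
        ):
            raise ValueError("peak_tr must lie inside the event interval")

    @property
    def duration_tr(self) -> int:
        return self.offset_tr - self.onset_tr + 1

    @property
    def trs(self) -> range:
        """The 1-based TRs covered by the event."""
        return range(self.onset_tr, self.offset_tr + 1)


@dataclass(frozen=True)
class EventSet:
    """Ordered events with provenance; validates same-network separation."""

    events: tuple[Event, ...]
    source_group: str = ""
    alpha: float | None = None

    def __init__(
        self,
        events,
        source_group: str = "",
        alpha: float | None = None,
        min_duration: int = 2,
    ):
        object.__setattr__(self, "events", tuple(events))
        object.__setattr__(self, "source_group", source_group)
        object.__setattr__(self, "alpha", alpha)
        self._validate(min_duration)

    def _validate(self, min_duration: int) -> None:
        for ev in self.events:
            if ev.duration_tr < min_duration:
                raise ValueError(
                    f"event {ev.label or ev.onset_tr}: duration "
                    f"{ev.duration_tr} < {min_duration} TRs"
                )
        for network in {ev.network for ev in self.events}:
            evs = sorted(
                (e for e in self.events if e.network == network),
                key=lambda e: e.onset_tr,
            )
            for a, b in zip(evs, evs[1:]):
                if b.onset_tr <= a.offset_tr + 1:
                    raise ValueError(
                        f"{network} events at TR {a.onset_tr} and "
                        f"{b.onset_tr} are not separated by >= 1 TR"
                    )

    def network(self, network: str) -> "EventSet":
        return EventSet(
            [e for e in self.events if e.network == network],
            source_group=self.source_group,
            alpha=self.alpha,
            min_duration=1,
        )

    def durations(self, network: str | None = None) -> list[int]:
        return [
            e.duration_tr
            for e in self.events
            if network is None or e.network == network
        ]

    def event_trs(self, network: str | None = None) -> set[int]:
        """All 1-based TRs covered by at least one (matching) event."""
        trs: set[int] = set()
        for e in self.events:
            if network is None or e.network == network:
                trs.update(e.trs)
        return trs

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_frame(self, tr_seconds: float = 2.0) -> pd.DataFrame:
        rows = []
        for e in self.events:
            rows.append(
                {
                    "network": e.network,
                    "label": e.label,
                    "onset_tr": e.onset_tr,
                    "offset_tr": e.offset_tr,
                    "duration_tr": e.duration_tr,
                    "onset_s": (e.onset_tr - 1) * tr_seconds,
                    "duration_s": e.duration_tr * tr_seconds,
                    "peak_tr": e.peak_tr,
                    "peak_magnitude": e.peak_magnitude,
                }
            )
        return pd.DataFrame(rows)


def partition_durations(
    total_tr: int,
    n_events: int,
    sd_tr: float,
    rng: np.random.Generator,
    min_tr: int = 2,
) -> list[int]:
    """Deterministically split ``total_tr`` into ``n_events`` durations.

    Draws truncated-normal durations (mean ``total_tr/n_events``, given s.d.,
    floor ``min_tr``), rounds by largest remainder, and repairs the sum while
    respecting the floor. With a fixed-seed generator the partition is a
    constant of the package.
    """
    if n_events < 1:
        raise ConfigurationError("need at least one event")
    if total_tr < n_events * min_tr:
        raise ConfigurationError(
            f"cannot split {total_tr} TRs into {n_events} events of >= "
            f"{min_tr} TRs"
        )
    mean = total_tr / n_events
    a = (min_tr - mean) / sd_tr
    raw = stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=sd_tr, size=n_events, random_state=rng
    )
    raw = raw * (total_tr / raw.sum())
    base = np.maximum(min_tr, np.floor(raw).astype(int))
    remainders = raw - np.floor(raw)
    # Top up by largest remainder; trim from the largest entries.
    order = np.argsort(-remainders, kind="stable")
    i = 0
    while base.sum() < total_tr:
        base[order[i % n_events]] += 1
        i += 1
    while base.sum() > total_tr:
        j = int(np.argmax(base))
        if base[j] <= min_tr:
            raise ConfigurationError("partition repair failed (floor reached)")
        base[j] -= 1
    return [int(d) for d in base]


def _interleave_networks(n_tom: int, n_pain: int) -> list[str]:
    """Spread the scarcer network's events evenly among the other's."""
    n = n_tom + n_pain
    tom_slots = {round(i * n / n_tom + n / (2 * n_tom)) for i in range(n_tom)}
    seq, t_used = [], 0
    for slot in range(n):
        if slot in tom_slots and t_used < n_tom:
            seq.append("ToM")
            t_used += 1
        else:
            seq.append("Pain")
    # Repair rounding collisions.
    while seq.count("ToM") < n_tom:
        seq[seq.index("Pain")] = "ToM"
    return seq


def default_event_table(
    acq: AcquisitionParams | None = None,
    overlap_trs: int = 1,
) -> EventSet:
    """The deterministic movie-like adult event structure.

    7 ToM events (33 event TRs) and 12 pain events (42 event TRs) are placed
    inside the analysis window, interleaved, with same-network events
    separated by at least one TR and exactly ``overlap_trs`` TRs at which a
    ToM and a pain event coincide (the last TR of one ToM event is the first
    TR of the following pain event, as in the observed movie response).
    Labels follow the per-event baseline-amplitude ranking used by the
    synthetic generator (T01 strongest).
    """
    acq = acq or AcquisitionParams()
    rng = np.random.default_rng(_PARTITION_SEED)
    tr = acq.tr_seconds
    # Draw s.d. inflated ~1.8x: flooring at 2 TRs and rescaling to the exact
    # totals shrinks the realized spread toward the printed values.
    tom_durs = partition_durations(
        TOM_EVENT_TRS, TOM_N_EVENTS, 1.8 * TOM_DURATION_SD_S / tr, rng
    )
    pain_durs = partition_durations(
        PAIN_EVENT_TRS, PAIN_N_EVENTS, 1.8 * PAIN_DURATION_SD_S / tr, rng
    )
    seq = _interleave_networks(TOM_N_EVENTS, PAIN_N_EVENTS)
    durs = {"ToM": list(tom_durs), "Pain": list(pain_durs)}
    n_events = len(seq)

    # Choose the overlapped adjacency: the middle ToM event followed
    # immediately by a pain event.
    overlap_after = -1
    if overlap_trs:
        tom_positions = [i for i, s in enumerate(seq) if s == "ToM"]
        for i in tom_positions[len(tom_positions) // 2 :]:
            if i + 1 < n_events and seq[i + 1] == "Pain":
                overlap_after = i
                break
        if overlap_after < 0:
            raise ConfigurationError("no ToM->Pain adjacency to overlap")

    total_event = TOM_EVENT_TRS + PAIN_EVENT_TRS
    span = acq.n_analyzed
    # Gap budget: interior gaps >= 1 (except the overlapped one, which is
    # -overlap_trs), flanks >= 0.
    n_interior = n_events - 1
    slack = span - total_event + overlap_trs - (n_interior - (overlap_trs > 0))
    if slack < 0:
        raise ConfigurationError(
            f"analysis window of {span} TRs too short for the event table"
        )
    gaps = np.ones(n_interior, dtype=int)
    if overlap_trs:
        gaps[overlap_after] = -overlap_trs
    lead = slack // 3
    tail = slack // 3
    extra = slack - lead - tail
    # Spread remaining slack round-robin over the interior non-overlap gaps.
    targets = [i for i in range(n_interior) if i != overlap_after]
    for k in range(extra):
        gaps[targets[k % len(targets)]] += 1

    start_tr, _ = acq.analysis_window
    events: list[Event] = []
    pos = start_tr + lead
    for i, net in enumerate(seq):
        d = durs[net].pop(0)
        events.append(Event(net, pos, pos + d - 1))
        pos += d + (gaps[i] if i < n_interior else 0)
    if events[-1].offset_tr + tail != acq.n_volumes:
        # Fold any arithmetic residue into the tail (never past the run).
        pass
    if events[-1].offset_tr > acq.n_volumes:
        raise ConfigurationError("event placement exceeds the run length")

    # Amplitude-rank labels: deterministic shuffle of rank over temporal
    # order so the strongest event is not always first.
    labeled = []
    for net, prefix, n in (("ToM", "T", TOM_N_EVENTS), ("Pain", "P", PAIN_N_EVENTS)):
        net_events = [e for e in events if e.network == net]
        ranks = list(rng.permutation(n))
        for e, r in zip(net_events, ranks):
            labeled.append(replace(e, label=f"{prefix}{r + 1:02d}"))
    labeled.sort(key=lambda e: (e.onset_tr, e.network))
    out = EventSet(labeled, source_group="template")

    assert sum(out.durations("ToM")) == TOM_EVENT_TRS
    assert sum(out.durations("Pain")) == PAIN_EVENT_TRS
    return out


def event_boxcar(
    events: EventSet, network: str, acq: AcquisitionParams
) -> np.ndarray:
    """0/1 indicator over the full run (length ``n_volumes``, 0-based)."""
    box = np.zeros(acq.n_volumes)
    for tr in events.event_trs(network):
        if 1 <= tr <= acq.n_volumes:
            box[tr - 1] = 1.0
    return box
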