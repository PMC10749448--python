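"""Exchange-event detection, taxonomy and residence times (direct method).

A raw region change is *committed* only if the molecule does not re-enter
its former region within a threshold time (0.1 ps by default); shorter
excursions are erased as temporary fluctuations and the series is treated
as if the molecule had never left.

Committed transitions are grouped per molecule into events of four
undirected categories, following each departure until it resolves:
tight↔loose (T–L), loose↔bulk (L–B), tight↔bulk directly (T–B), and
tight↔bulk through the loose shell (T–L–B).  A tight departure whose
molecule reaches bulk before re-entering tight is T–L–B (consuming the
loose→bulk leg); one that returns to tight is a single T–L event.
Inbound chains (bulk→loose→tight, …) mirror the outbound rules and are
counted in the same categories, so the printed totals are undirected.

Residence times use the direct method: MRT = t_sim · n̄ / N_ex, where n̄
is the time-averaged occupancy of the shell and N_ex the total number of
exchange events involving it (tight: T–L + T–B + T–L–B; loose: T–L +
L–B + T–L–B).  The normalized mean residence time is NMRT = MRT / n̄ =
t_sim / N_ex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_geometry import ContractError, UndefinedNMRTError
from .shells import ShellLabels

__all__ = [
    "DEFAULT_THRESHOLD_PS",
    "Transition",
    "ExchangeEvent",
    "ExchangeSummary",
    "CATEGORIES",
    "committed_transitions",
    "categorize_events",
    "nmrt",
    "exchange_summary",
]

DEFAULT_THRESHOLD_PS = 0.1
CATEGORIES = ("T-L", "L-B", "T-B", "T-L-B")

# directional label -> undirected Table-style category
_UNDIRECTED = {
    "T-L": "T-L", "L-T": "T-L",
    "L-B": "L-B", "B-L": "L-B",
    "T-B": "T-B", "B-T": "T-B",
    "T-L-B": "T-L-B", "B-L-T": "T-L-B",
}


@dataclass(frozen=True)
class Transition:
    """One committed region change of one molecule."""

    water_id: int
    t_leave: float      # ps, time of the change point
    from_region: str
    to_region: str


@dataclass(frozen=True)
class ExchangeEvent:
    """One resolved exchange event (possibly spanning two transitions)."""

    water_id: int
    t_leave: float
    from_region: str
    to_region: str
    category: str       # directional, e.g. 'B-L-T'

    @property
    def undirected_category(self) -> str:
        return _UNDIRECTED[self.category]


def committed_transitions(
    region_series,
    dt: float,
    threshold: float = DEFAULT_THRESHOLD_PS,
    t0: float = 0.0,
    water_id: int = -1,
) -> list[Transition]:
    """Scan one molecule's region series for committed transitions.

    A change at time t is committed iff the molecule does not re-enter the
    pre-change region within (t, t + threshold]; otherwise the excursion is
    erased and scanning resumes after the return point.
    """
    if dt <= 0:
        raise ContractError("dt must be positive")
    if threshold < dt:
        raise ContractError(f"threshold {threshold} ps is below dt {dt} ps")
    s = list(region_series)
    window = int(np.floor(threshold / dt + 1e-9))
    out: list[Transition] = []
    if not s:
        return out
    cur = s[0]
    i = 1
    while i < len(s):
        if s[i] == cur:
            i += 1
            continue
        # raw change at index i; look for a return to `cur` within the window
        ret = None
        for j in range(i + 1, min(i + window, len(s) - 1) + 1):
            if s[j] == cur:
                ret = j
                break
        if ret is not None:
            i = ret + 1          # excursion erased; the molecule "stayed"
        else:
            out.append(
                Transition(
                    water_id=water_id,
                    t_leave=t0 + i * dt,
                    from_region=cur,
                    to_region=s[i],
                )
            )
            cur = s[i]
            i += 1
    return out


def categorize_events(transitions: list[Transition]) -> list[ExchangeEvent]:
    """Resolve time-ordered committed transitions of one molecule into events.

    Departures from tight or bulk consume their resolving leg (the return,
    or the continuation through loose); a trailing unresolved departure
    counts as the two-region event of its first leg.
    """
    events: list[ExchangeEvent] = []
    i = 0
    n = len(transitions)
    while i < n:
        tr = transitions[i]
        pair = (tr.from_region, tr.to_region)
        nxt = transitions[i + 1] if i + 1 < n else None
        if pair == ("T", "L"):
            if nxt is not None and nxt.to_region == "B":
                cat, to, step = "T-L-B", "B", 2
            elif nxt is not None and nxt.to_region == "T":
                cat, to, step = "T-L", "T", 2   # departure resolved back
            else:
                cat, to, step = "T-L", "L", 1
        elif pair == ("B", "L"):
            if nxt is not None and nxt.to_region == "T":
                cat, to, step = "B-L-T", "T", 2
            elif nxt is not None and nxt.to_region == "B":
                cat, to, step = "B-L", "B", 2
            else:
                cat, to, step = "B-L", "L", 1
        elif pair == ("T", "B"):
            cat, to, step = "T-B", "B", 1
        elif pair == ("B", "T"):
            cat, to, step = "B-T", "T", 1
        elif pair == ("L", "T"):
            cat, to, step = "L-T", "T", 1       # journey starting in loose
        elif pair == ("L", "B"):
            cat, to, step = "L-B", "B", 1
        else:
            raise ContractError(f"impossible transition {pair}")
        events.append(
            ExchangeEvent(
                water_id=tr.water_id,
                t_leave=tr.t_leave,
                from_region=tr.from_region,
                to_region=to,
                category=cat,
            )
        )
        i += step
    return events


@dataclass
class ExchangeSummary:
    """Undirected event counts and direct-method residence times."""

    counts: dict[str, int]      # per undirected category
    n_bar_tight: float
    n_bar_loose: float
    t_sim: float                # ps

    @property
    def n_ex_tight(self) -> int:
        return self.counts["T-L"] + self.counts["T-B"] + self.counts["T-L-B"]

    @property
    def n_ex_loose(self) -> int:
        return self.counts["T-L"] + self.counts["L-B"] + self.counts["T-L-B"]

    def _n_ex(self, shell: str) -> int:
        if shell == "T":
            return self.n_ex_tight
        if shell == "L":
            return self.n_ex_loose
        raise ContractError(f"shell must be 'T' or 'L', got {shell!r}")

    def mrt(self, shell: str) -> float:
        """Mean residence time: t_sim · n̄ / N_ex (ps)."""
        n_ex = self._n_ex(shell)
        if n_ex == 0:
            raise UndefinedNMRTError(f"no exchange events involve shell {shell!r}")
        n_bar = self.n_bar_tight if shell == "T" else self.n_bar_loose
        return self.t_sim * n_bar / n_ex

    def nmrt(self, shell: str) -> float:
        """Normalized mean residence time: MRT / n̄ = t_sim / N_ex (ps)."""
        n_ex = self._n_ex(shell)
        if n_ex == 0:
            raise UndefinedNMRTError(f"no exchange events involve shell {shell!r}")
        return self.t_sim / n_ex


def nmrt(counts: dict[str, int], n_bar: dict[str, float], t_sim: float) -> ExchangeSummary:
    """Build an ExchangeSummary from undirected category counts, shell
    occupancies {'T': .., 'L': ..} and the production span (ps)."""
    full = {c: int(counts.get(c, 0)) for c in CATEGORIES}
    if any(v < 0 for v in full.values()) or t_sim <= 0:
        raise ContractError("counts must be non-negative and t_sim positive")
    return ExchangeSummary(
        counts=full,
        n_bar_tight=float(n_bar.get("T", 0.0)),
        n_bar_loose=float(n_bar.get("L", 0.0)),
        t_sim=float(t_sim),
    )


def exchange_summary(
    labels: ShellLabels, threshold: float = DEFAULT_THRESHOLD_PS
) -> tuple[ExchangeSummary, list[ExchangeEvent]]:
    """Detect, filter and categorize all exchange events of a labeled run."""
    all_events: list[ExchangeEvent] = []
    for w, wid in enumerate(labels.water_ids):
        trans = committed_transitions(
            labels.region[:, w], labels.dt, threshold, water_id=int(wid)
        )
        all_events.extend(categorize_events(trans))
    counts = {c: 0 for c in CATEGORIES}
    for ev in all_events:
        counts[ev.undirected_category] += 1
    summary = nmrt(
        counts,
        {"T": labels.occupancy("T"), "L": labels.occupancy("L")},
        labels.t_sim,
    )
    return summary, all_events
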